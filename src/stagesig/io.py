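"""Core data containers and TSV/GMT readers and writers.

The canonical on-disk formats are the ones RSEM-style quantification
pipelines emit: a features-by-samples abundance TSV per level (gene and
isoform), a per-sample clinical TSV, a two-column isoform-to-gene mapping
TSV, and a standard GMT gene-set collection.  Tab is the canonical
delimiter; gzip-compressed inputs are accepted transparently (by file
extension, as pandas does).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STAGES = ("I", "II", "III", "IV")
VALID_LEVELS = ("gene", "isoform")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Non-negative features-by-samples abundance table (TPM-like units).

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
    level
        ``"gene"`` or ``"isoform"``.
    """

    data: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in VALID_LEVELS:
            raise ValueError(f"level must be one of {VALID_LEVELS}, got {self.level!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing/non-numeric value at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}: {values[r, c]}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)], self.level)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.level)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: stage, age, gender, follow-up, event.

    ``age``/``gender``/``time``/``event`` may be missing (NaN); survival
    operations reject samples with missing follow-up, multivariate models
    drop samples with missing age or gender.
    """

    data: pd.DataFrame  # index: sample_id; columns: stage, age, gender, time, event

    def __post_init__(self) -> None:
        required = {"stage", "age", "gender", "time", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        bad = set(self.data["stage"]) - set(VALID_STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        ev = self.data["event"].dropna()
        if not ev.isin([0, 1]).all():
            bad_ev = sorted(set(ev[~ev.isin([0, 1])]))
            raise ValueError(f"event indicator must be 0/1, got {bad_ev}")
        t = self.data["time"].dropna()
        if (t < 0).any():
            raise ValueError("negative follow-up time")
        g = self.data["gender"].dropna()
        bad_g = set(g) - {"male", "female"}
        if bad_g:
            raise ValueError(f"unknown gender labels: {sorted(bad_g)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def stages(self, sample_ids=None) -> pd.Series:
        if sample_ids is None:
            return self.data["stage"]
        return self.data.loc[list(sample_ids), "stage"]

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def stage_subset(self, stages) -> "ClinicalTable":
        mask = self.data["stage"].isin(list(stages))
        return ClinicalTable(self.data[mask])


@dataclass
class FeatureMap:
    """Many-to-one isoform id -> gene id mapping."""

    mapping: pd.Series  # index: isoform_id, values: gene_id

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            dups = self.mapping.index[self.mapping.index.duplicated()].unique().tolist()
            raise ValueError(f"isoform mapped more than once: {dups}")

    def gene_of(self, isoform_id: str) -> str:
        return self.mapping[isoform_id]

    def __contains__(self, isoform_id: str) -> bool:
        return isoform_id in self.mapping.index

    def genes_for(self, isoform_ids) -> pd.Series:
        return self.mapping.reindex(list(isoform_ids))

    def isoforms_of(self, gene_id: str) -> list[str]:
        return self.mapping.index[self.mapping == gene_id].tolist()

    @property
    def isoform_ids(self) -> list[str]:
        return self.mapping.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.mapping.unique())


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            # de-duplicate preserving order
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, level: str) -> ExpressionMatrix:
    """Read a features-by-samples abundance TSV (header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(df, level)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with columns sample, stage, age, gender, time, event.

    Stage labels are normalized case-insensitively, tolerating a
    ``stage ``/``stage_`` prefix (``"Stage i"`` -> ``"I"``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "stage", "age", "gender", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical file missing columns: {sorted(missing)}")
    df = df.set_index("sample")
    df["stage"] = [normalize_stage(s) for s in df["stage"]]
    df["gender"] = df["gender"].astype("string").str.lower()
    return ClinicalTable(df[["stage", "age", "gender", "time", "event"]])


def normalize_stage(label) -> str:
    s = str(label).strip().upper()
    for prefix in ("STAGE_", "STAGE "):
        if s.startswith(prefix):
            s = s[len(prefix):]
    if s not in VALID_STAGES:
        raise ValueError(f"unknown stage label: {label!r}")
    return s


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")


def read_feature_map(path) -> FeatureMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("feature map must have two columns: isoform_id, gene_id")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    return FeatureMap(ser)


def write_feature_map(fmap: FeatureMap, path) -> None:
    pd.DataFrame(
        {"isoform_id": fmap.mapping.index, "gene_id": fmap.mapping.values}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> member [<TAB> member ...]."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 fields, got {len(fields)}")
            name, desc, *members = fields
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def harmonize_samples(
    expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Align expression columns to clinical row order.

    Samples present in only one of the two sources are dropped with a
    logged warning; the returned objects share an identical sample order.
    """
    shared = [s for s in clinical.sample_ids if s in set(expr.sample_ids)]
    dropped = (set(expr.sample_ids) | set(clinical.sample_ids)) - set(shared)
    if dropped:
        logger.warning(
            "dropping %d samples present in only one source: %s",
            len(dropped), sorted(dropped)[:10],
        )
    if not shared:
        raise ValueError("no samples shared between expression and clinical data")
    return expr.subset_samples(shared), clinical.subset(shared)
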