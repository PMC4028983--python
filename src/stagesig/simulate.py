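"""Synthetic stage-labelled RNA-seq cohort with planted, recorded structure.

The generator emulates a two-stage discovery cohort (early = stage I,
late = stage IV) plus an independent stage II/III validation cohort, at
gene and isoform resolution:

* per gene, a log-normal baseline abundance is split across its isoforms
  by Dirichlet-distributed proportions skewed towards a dominant "major"
  isoform (Dirichlet alpha 0.5, calibrated so that roughly 62% of major
  isoforms carry more than 0.8 of their gene's abundance overall, about
  40% among multi-isoform genes);
* the gene matrix is the per-sample sum of its isoform rows, exactly;
* planted effects are multiplicative (``2**(+/-log2_effect)``) on
  late-stage samples: whole-gene shifts (``gene_de``), single minor-isoform
  shifts that leave the gene total below the 2-fold threshold
  (``isoform_only_de``), and isoform switches — two isoforms of one gene
  moving in opposite directions with proportions chosen so the gene total
  is unchanged in expectation (``switch_member``);
* validation samples carry no stage effect; instead a latent binary risk
  group shifts every prognostic feature and multiplies the exponential
  hazard by ``exp(log_hazard_ratio)``, with administrative Uniform(0, tau)
  censoring, tau solved for the requested censor rate.

Every planted feature's label, direction and magnitude is recorded in a
:class:`SyntheticTruth` so downstream recovery is checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, FeatureMap, GeneSetCollection

#: within-gene isoform proportion concentration; calibrated by Monte-Carlo so
#: ~62% of major isoforms have ratio > 0.8 (all genes), ~41% (multi-isoform).
DIRICHLET_ALPHA = 0.5

DEFAULT_ISOFORM_COUNTS = {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the package targets: 234 early-stage
    and 81 late-stage discovery samples and 165 stage II/III validation
    samples.  ``n_genes`` defaults to a desk-scale 2000 genes.
    """

    n_early: int = 234
    n_late: int = 81
    n_validation: int = 165
    n_genes: int = 2000
    isoform_count_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOFORM_COUNTS)
    )
    frac_gene_de: float = 0.05
    frac_isoform_only_de: float = 0.05
    frac_switch: float = 0.02
    log2_effect: float = 2.0
    noise_sd: float = 0.5          # log2-scale
    frac_prognostic: float = 0.3   # fraction of planted features with a survival effect
    log_hazard_ratio: float = 1.25
    censor_rate: float = 0.6
    baseline_median_months: float = 90.0
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_gene_de, self.frac_isoform_only_de, self.frac_switch,
                 self.frac_prognostic, self.censor_rate)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.frac_gene_de + self.frac_isoform_only_de + self.frac_switch > 1.0:
            raise ValueError("frac_gene_de + frac_isoform_only_de + frac_switch > 1")
        if min(self.n_early, self.n_late, self.n_validation, self.n_genes) < 2:
            raise ValueError("sample and gene counts must be >= 2")
        if self.log2_effect <= 0:
            raise ValueError("log2_effect must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        probs = np.array(list(self.isoform_count_distribution.values()), dtype=float)
        if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("isoform_count_distribution must be a probability vector")
        if any(k < 1 for k in self.isoform_count_distribution):
            raise ValueError("isoform counts must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted labels for every feature plus the latent per-sample risk group.

    ``features`` is indexed by feature id with columns ``level`` (gene /
    isoform), ``gene_id``, ``label`` (gene_de | isoform_only_de |
    switch_member | null), ``direction`` (+1 / -1 / 0), ``log2_effect``
    and ``prognostic`` (bool).  ``risk_group`` maps validation sample ids
    to the 0/1 high-hazard indicator.
    """

    features: pd.DataFrame
    risk_group: pd.Series

    def planted(self, label: str, level: str | None = None) -> list[str]:
        mask = self.features["label"] == label
        if level is not None:
            mask &= self.features["level"] == level
        return self.features.index[mask].tolist()

    @property
    def switch_genes(self) -> list[str]:
        members = self.features[self.features["label"] == "switch_member"]
        return sorted(members["gene_id"].unique())

    def prognostic_features(self, level: str | None = None) -> list[str]:
        mask = self.features["prognostic"]
        if level is not None:
            mask &= self.features["level"] == level
        return self.features.index[mask].tolist()

    def null_features(self, level: str) -> list[str]:
        mask = (self.features["label"] == "null") & (self.features["level"] == level)
        return self.features.index[mask].tolist()


class Cohort(NamedTuple):
    gene: ExpressionMatrix
    isoform: ExpressionMatrix
    clinical: ClinicalTable
    feature_map: FeatureMap
    truth: SyntheticTruth


def _censoring_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Solve Uniform(0, tau) administrative censoring for a target censor rate.

    For T ~ Exp(r), C ~ U(0, tau): P(C < T) = (1 - exp(-r tau)) / (r tau).
    Averaged over the cohort's rates, solved for tau by bisection.
    """
    if censor_rate <= 0:
        return float("inf")
    if censor_rate >= 1:
        return 1e-9

    def p_censor(tau: float) -> float:
        x = rates * tau
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if p_censor(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate gene/isoform matrices, clinical table, map and truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_disc = config.n_early + config.n_late
    n_total = n_disc + config.n_validation
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    stages = (
        ["I"] * config.n_early + ["IV"] * config.n_late
        + ["II"] * (config.n_validation // 2)
        + ["III"] * (config.n_validation - config.n_validation // 2)
    )
    late_mask = np.array([s == "IV" for s in stages])
    valid_mask = np.array([s in ("II", "III") for s in stages])

    # --- gene architecture -------------------------------------------------
    counts = np.array(sorted(config.isoform_count_distribution), dtype=int)
    probs = np.array([config.isoform_count_distribution[int(k)] for k in counts])
    iso_counts = rng.choice(counts, size=config.n_genes, p=probs)

    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    baseline_log2 = rng.normal(4.0, 1.5, size=config.n_genes)

    # planted label assignment; isoform-level plants need >=2 isoforms
    n_gene_de = round(config.frac_gene_de * config.n_genes)
    n_iso_only = round(config.frac_isoform_only_de * config.n_genes)
    n_switch = round(config.frac_switch * config.n_genes)
    multi = np.flatnonzero(iso_counts >= 2)
    if n_iso_only + n_switch > multi.size:
        raise ValueError("not enough multi-isoform genes for requested isoform-level plants")
    multi_pick = rng.permutation(multi)
    switch_genes = multi_pick[:n_switch]
    iso_only_genes = multi_pick[n_switch:n_switch + n_iso_only]
    remaining = np.setdiff1d(
        np.arange(config.n_genes), np.concatenate([switch_genes, iso_only_genes])
    )
    gene_de_genes = rng.permutation(remaining)[:n_gene_de]

    f = 2.0 ** config.log2_effect

    iso_ids: list[str] = []
    iso_gene: list[str] = []
    base_iso: list[np.ndarray] = []      # per-isoform baseline linear abundance
    effect_log2: list[float] = []        # per-isoform planted stage effect (log2)
    labels: list[str] = []               # per-isoform truth label
    gene_label = np.array(["null"] * config.n_genes, dtype=object)
    gene_label[gene_de_genes] = "gene_de"
    gene_dir = np.zeros(config.n_genes)
    gene_dir[gene_de_genes] = rng.choice([-1.0, 1.0], size=gene_de_genes.size)

    switch_set = set(switch_genes.tolist())
    iso_only_set = set(iso_only_genes.tolist())

    for g in range(config.n_genes):
        k = int(iso_counts[g])
        props = np.array([1.0]) if k == 1 else rng.dirichlet([DIRICHLET_ALPHA] * k)
        eff = np.zeros(k)
        lab = ["null"] * k
        if gene_label[g] == "gene_de":
            eff[:] = gene_dir[g] * config.log2_effect
            lab = ["gene_de"] * k
        elif g in switch_set:
            # two isoforms move oppositely; within their combined mass s the
            # proportions (1/(f+1), f/(f+1)) make s*(f/(f+1) + 1/(f+1)) = s,
            # so the gene total is exactly unchanged in expectation.
            a, b = rng.choice(k, size=2, replace=False)
            s = props[a] + props[b]
            props[a] = s * 1.0 / (f + 1.0)
            props[b] = s * f / (f + 1.0)
            eff[a] = config.log2_effect
            eff[b] = -config.log2_effect
            lab[a] = lab[b] = "switch_member"
        elif g in iso_only_set:
            # one isoform shifted; its proportion p = 1/(2(f-1)) keeps the
            # expected gene-level fold at 1 + p(f-1) = 1.5 < 2 (sub-threshold).
            a = int(rng.integers(k))
            p_target = min(0.5, 1.0 / (2.0 * (f - 1.0))) if f > 1 else 0.25
            other = np.delete(np.arange(k), a)
            props[other] *= (1.0 - p_target) / props[other].sum()
            props[a] = p_target
            eff[a] = float(rng.choice([-1.0, 1.0])) * config.log2_effect
            lab[a] = "isoform_only_de"
        base = (2.0 ** baseline_log2[g]) * props
        for j in range(k):
            iso_ids.append(f"{gene_ids[g]}.i{j + 1}")
            iso_gene.append(gene_ids[g])
            effect_log2.append(float(eff[j]))
            labels.append(lab[j])
        base_iso.append(base)

    base_iso_arr = np.concatenate(base_iso)           # (n_isoforms,)
    effect_arr = np.array(effect_log2)                # (n_isoforms,)
    n_iso = base_iso_arr.size

    # --- prognostic features ----------------------------------------------
    feat_gene = np.array(iso_gene)
    planted_iso_mask = np.array(labels) == "isoform_only_de"
    gene_is_de = gene_label == "gene_de"
    # candidate prognostic features: planted genes (gene level) and planted
    # single isoforms (isoform level)
    prog_gene_idx = gene_de_genes.copy()
    prog_iso_idx = np.flatnonzero(planted_iso_mask)
    n_prog_gene = round(config.frac_prognostic * prog_gene_idx.size)
    n_prog_iso = round(config.frac_prognostic * prog_iso_idx.size)
    prog_genes = set(rng.permutation(prog_gene_idx)[:n_prog_gene].tolist())
    prog_isos = set(rng.permutation(prog_iso_idx)[:n_prog_iso].tolist())

    risk = rng.integers(0, 2, size=n_total)           # latent risk axis
    risk[~valid_mask] = 0                              # only meaningful in validation

    # per-isoform log2 multiplier matrix is assembled implicitly below
    gene_of_iso_idx = np.repeat(np.arange(config.n_genes), iso_counts)
    iso_prog_dir = np.zeros(n_iso)
    for gi in prog_genes:
        sel = gene_of_iso_idx == gi
        iso_prog_dir[sel] = gene_dir[gi]
    for ii in prog_isos:
        iso_prog_dir[ii] = np.sign(effect_arr[ii])

    # --- expression sampling ----------------------------------------------
    noise = rng.normal(0.0, config.noise_sd, size=(n_iso, n_total))
    log2_mult = np.zeros((n_iso, n_total))
    log2_mult[:, late_mask] += effect_arr[:, None]
    log2_mult[:, valid_mask] += (
        iso_prog_dir[:, None] * config.log2_effect * risk[valid_mask][None, :]
    )
    iso_values = base_iso_arr[:, None] * (2.0 ** (log2_mult + noise))

    iso_df = pd.DataFrame(iso_values, index=iso_ids, columns=sample_ids)
    gene_df = iso_df.groupby(feat_gene, sort=False).sum()
    gene_df = gene_df.loc[gene_ids]                   # stable gene order

    # --- clinical ----------------------------------------------------------
    age = np.clip(rng.normal(60.0, 12.0, size=n_total), 30.0, 90.0).round(1)
    gender = np.where(rng.random(n_total) < 0.65, "male", "female")
    rate0 = math.log(2.0) / config.baseline_median_months
    rates = rate0 * np.exp(config.log_hazard_ratio * risk * valid_mask)
    t_event = rng.exponential(1.0 / rates)
    tau = _censoring_horizon(rates, config.censor_rate)
    c_time = rng.uniform(0.0, tau, size=n_total) if np.isfinite(tau) else np.full(n_total, np.inf)
    event = (t_event <= c_time).astype(int)
    time = np.minimum(t_event, c_time)

    clinical = ClinicalTable(pd.DataFrame(
        {"stage": stages, "age": age, "gender": gender,
         "time": np.round(time, 4), "event": event},
        index=pd.Index(sample_ids, name="sample"),
    ))

    # --- truth -------------------------------------------------------------
    gene_truth = pd.DataFrame({
        "level": "gene",
        "gene_id": gene_ids,
        "label": gene_label,
        "direction": gene_dir,
        "log2_effect": np.where(gene_is_de, config.log2_effect, 0.0),
        "prognostic": [g in prog_genes for g in range(config.n_genes)],
    }, index=pd.Index(gene_ids, name="feature_id"))
    iso_truth = pd.DataFrame({
        "level": "isoform",
        "gene_id": iso_gene,
        "label": labels,
        "direction": np.sign(effect_arr),
        "log2_effect": np.abs(effect_arr),
        "prognostic": [i in prog_isos for i in range(n_iso)],
    }, index=pd.Index(iso_ids, name="feature_id"))
    truth = SyntheticTruth(
        features=pd.concat([gene_truth, iso_truth]),
        risk_group=pd.Series(risk, index=sample_ids, name="risk_group")[valid_mask],
    )

    fmap = FeatureMap(pd.Series(iso_gene, index=iso_ids))
    return Cohort(
        gene=ExpressionMatrix(gene_df, "gene"),
        isoform=ExpressionMatrix(iso_df, "isoform"),
        clinical=clinical,
        feature_map=fmap,
        truth=truth,
    )


def write_cohort(cohort: Cohort, directory) -> dict[str, str]:
    """Write the cohort as the TSV set :mod:`stagesig.io` reads.

    Output is byte-stable for a fixed seed (fixed float formatting).
    Returns the mapping of logical name -> file path.
    """
    from pathlib import Path

    from .io import write_clinical, write_expression, write_feature_map

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene": out / "gene_expression.tsv",
        "isoform": out / "isoform_expression.tsv",
        "clinical": out / "clinical.tsv",
        "feature_map": out / "isoform_map.tsv",
        "truth": out / "truth.tsv",
        "risk_group": out / "risk_group.tsv",
    }
    write_expression(cohort.gene, paths["gene"])
    write_expression(cohort.isoform, paths["isoform"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_feature_map(cohort.feature_map, paths["feature_map"])
    cohort.truth.features.to_csv(paths["truth"], sep="\t", float_format="%.17g")
    cohort.truth.risk_group.to_csv(paths["risk_group"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def synthetic_gene_sets(
    truth: SyntheticTruth,
    n_random_sets: int = 20,
    set_size: int = 25,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene-set collection for end-to-end enrichment runs: one set enriched
    in planted DE genes plus random sets drawn from all genes."""
    rng = np.random.default_rng(seed)
    genes = truth.features.index[truth.features["level"] == "gene"].to_numpy()
    planted = truth.features.index[
        (truth.features["level"] == "gene") & (truth.features["label"] == "gene_de")
    ].to_numpy()
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    if planted.size >= 2:
        n_take = min(set_size, planted.size)
        members = rng.choice(planted, size=n_take, replace=False).tolist()
        pad = set_size - n_take
        if pad > 0:
            members += rng.choice(
                np.setdiff1d(genes, planted), size=pad, replace=False
            ).tolist()
        sets["planted_de_program"] = members
        descriptions["planted_de_program"] = "synthetic set enriched in planted DE genes"
    for i in range(n_random_sets):
        name = f"random_set_{i + 1:02d}"
        sets[name] = rng.choice(genes, size=min(set_size, genes.size), replace=False).tolist()
        descriptions[name] = "synthetic random background set"
    return GeneSetCollection(sets, descriptions)
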