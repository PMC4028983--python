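"""Isoform-level structure: expression filtering, major-isoform ratios,
expressed-isoform fractions and gene-vs-isoform fold-change correlation.

The "major" isoform of a gene is the isoform with the highest mean
abundance across samples; its relative abundance ratio (major / gene
total) summarises how dominated a gene is by a single transcript.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix, FeatureMap

logger = logging.getLogger(__name__)


def filter_expressed_isoforms(
    iso: ExpressionMatrix,
    clinical: ClinicalTable,
    threshold: float = 0.001,
    groups: tuple[str, str] = ("I", "IV"),
) -> ExpressionMatrix:
    """Keep isoforms expressed (> threshold, strict) in at least half of the
    samples of either comparison group; row order is preserved."""
    stages = clinical.stages(iso.sample_ids)
    keep = np.zeros(iso.n_features, dtype=bool)
    values = iso.values
    any_group = False
    for g in groups:
        mask = (stages == g).to_numpy()
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        any_group = True
        need = math.ceil(n_g / 2)
        keep |= (values[:, mask] > threshold).sum(axis=1) >= need
    if not any_group:
        raise ValueError(f"no samples in any of the groups {groups}")
    if not keep.any():
        raise ValueError(
            f"no isoform passes the expression filter (> {threshold} in at least "
            f"half of either group); review the threshold"
        )
    return ExpressionMatrix(iso.data.loc[keep], iso.level)


@dataclass
class RatioSummary:
    """Per-gene major isoform and ratio, with cohort summaries per stratum.

    ``per_gene`` is indexed by gene with columns major_isoform,
    n_isoforms, ratio.  ``summaries`` maps stratum name (``all_genes``,
    ``multi_isoform_genes``) to mean / median / sd / frac_gt_0.8.
    """

    per_gene: pd.DataFrame
    summaries: dict[str, dict[str, float]]
    excluded_genes: list[str]


def major_isoform_ratios(
    iso: ExpressionMatrix,
    gene: ExpressionMatrix,
    fmap: FeatureMap,
    mode: str = "per_sample",
) -> RatioSummary:
    """Major-isoform relative abundance ratio per gene.

    The major isoform is the one with the largest mean abundance across
    samples (ties broken by lexicographically smallest id, logged).  With
    ``mode="per_sample"`` (default) the ratio is the mean over samples
    with nonzero gene abundance of major/gene; ``mode="ratio_of_means"``
    divides the mean abundances instead.  Genes with zero abundance in
    every sample are excluded and reported.
    """
    if mode not in ("per_sample", "ratio_of_means"):
        raise ValueError(f"unknown mode {mode!r}")
    genes_of = fmap.genes_for(iso.feature_ids)
    if genes_of.isna().any():
        missing = genes_of.index[genes_of.isna()].tolist()
        raise ValueError(f"isoforms missing from feature map: {missing[:10]}")
    unknown = set(genes_of) - set(gene.feature_ids)
    if unknown:
        raise ValueError(f"mapped genes absent from gene matrix: {sorted(unknown)[:10]}")

    iso_means = iso.data.mean(axis=1)
    rows = []
    excluded: list[str] = []
    n_ties = 0
    for g, grp in iso.data.groupby(genes_of.values, sort=True):
        means = iso_means[grp.index]
        best = means.max()
        candidates = sorted(means.index[means == best])
        if len(candidates) > 1:
            n_ties += 1
        major = candidates[0]
        gvals = gene.data.loc[g].to_numpy(dtype=float)
        mvals = grp.loc[major].to_numpy(dtype=float)
        nonzero = gvals > 0
        if not nonzero.any():
            excluded.append(g)
            continue
        if mode == "per_sample":
            ratio = float(np.mean(mvals[nonzero] / gvals[nonzero]))
        else:
            ratio = float(mvals.mean() / gvals[nonzero].mean())
        rows.append((g, major, len(grp), ratio))
    if n_ties:
        logger.info("%d genes had tied major-isoform means; smallest id chosen", n_ties)
    if excluded:
        logger.warning("%d genes with zero abundance in all samples excluded", len(excluded))

    per_gene = pd.DataFrame(
        rows, columns=["gene", "major_isoform", "n_isoforms", "ratio"]
    ).set_index("gene")

    def summarize(frame: pd.DataFrame) -> dict[str, float]:
        r = frame["ratio"]
        if len(r) == 0:
            return {k: float("nan") for k in ("mean", "median", "sd", "frac_gt_0.8", "n")}
        return {
            "mean": float(r.mean()),
            "median": float(r.median()),
            "sd": float(r.std(ddof=1)) if len(r) > 1 else float("nan"),
            "frac_gt_0.8": float((r > 0.8).mean()),
            "n": float(len(r)),
        }

    summaries = {
        "all_genes": summarize(per_gene),
        "multi_isoform_genes": summarize(per_gene[per_gene["n_isoforms"] >= 2]),
    }
    return RatioSummary(per_gene=per_gene, summaries=summaries, excluded_genes=excluded)


def expressed_isoform_fraction(
    iso: ExpressionMatrix, fmap: FeatureMap, threshold: float = 0.001
) -> pd.Series | None:
    """Per sample: among genes with >=2 annotated isoforms, the fraction
    expressing (> threshold) two or more of them.

    Genes with at least two isoforms in the map stand in for multi-exon
    genes (exon models are not an input).  Returns ``None`` with a warning
    if no gene qualifies.
    """
    genes_of = fmap.genes_for(iso.feature_ids)
    counts = fmap.mapping.value_counts()
    multi_genes = set(counts.index[counts >= 2])
    mask = genes_of.isin(multi_genes).to_numpy()
    if not mask.any():
        logger.warning("no gene with >=2 annotated isoforms; fraction undefined")
        return None
    sub = iso.data.loc[mask]
    expressed = (sub > threshold).groupby(genes_of[mask].values).sum()
    # genes annotated multi but with <2 isoforms present still count in the
    # denominator only if they appear in the matrix at all
    frac = (expressed >= 2).mean(axis=0)
    frac.name = "fraction_multi_isoform_expressed"
    return frac


def fc_correlation(x_log2fc, y_log2fc) -> tuple[float, float]:
    """Squared Pearson correlation of two log2 fold-change vectors and its
    two-sided significance."""
    x = np.asarray(x_log2fc, dtype=float)
    y = np.asarray(y_log2fc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite fold changes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)
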