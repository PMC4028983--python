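"""Two-group moderated-t differential expression and signature selection.

The moderated t-statistic shrinks each feature's residual variance toward
a prior estimated across features by empirical Bayes.  With per-feature
pooled variance s^2 on d = n1 + n2 - 2 degrees of freedom, the prior
(d0, s0^2) is estimated by method-of-moments on log s^2 using
digamma/trigamma inversion, the posterior variance is

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and t = log2fc / (s_tilde * sqrt(1/n1 + 1/n2)) is referred to a
t-distribution with d0 + d degrees of freedom (a normal reference when
the estimated d0 is effectively infinite).

Signatures are features passing both a fold-change and a BH FDR
threshold; at combination time, genes significant at the gene level take
priority over their own isoforms (the gene-priority dedup rule), and an
isoform switch is a gene with two or more selected isoforms moving in
opposite directions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, FeatureMap

logger = logging.getLogger(__name__)

#: estimated prior degrees of freedom above this are treated as infinite
PRIOR_DF_CAP = 1e6


def log_transform(expr, pseudocount: float = 0.01) -> pd.DataFrame:
    """Elementwise ``log2(x + pseudocount)`` of a non-negative matrix
    (an :class:`~stagesig.io.ExpressionMatrix` or a DataFrame)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    if (np.asarray(data) < 0).any():
        raise ValueError("expression must be non-negative")
    return np.log2(data + pseudocount)


def trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) to variances.

    Works on e = log(s^2) - digamma(d/2) + log(d/2), whose mean is
    log(s0^2) + digamma(d0/2) - log(d0/2) and whose excess variance over
    trigamma(d/2) is trigamma(d0/2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return float("inf"), float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
    else:
        d0 = float("inf")
    if d0 >= PRIOR_DF_CAP:
        if np.isfinite(d0):
            logger.info("prior df %.3g capped at %g (treated as infinite)", d0, PRIOR_DF_CAP)
        # no spread beyond sampling noise: all true variances equal s0^2,
        # whose MLE under s^2 ~ s0^2 chi2_d / d is the plain mean
        d0 = float("inf")
        s0_2 = float(np.mean(s2[ok]))
    else:
        # E[e] = log s0^2 + log(d0/2) - digamma(d0/2); invert for s0^2
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    log_expr: pd.DataFrame,
    group_labels,
    early=None,
    late=None,
    level: str = "gene",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature moderated two-group comparison on log2 expression.

    Parameters
    ----------
    log_expr
        log2-scale features x samples DataFrame.
    group_labels
        one label per column; exactly two distinct values.
    early, late
        which label is the reference / comparison group; default: the two
        labels in sorted order.  ``log2fc`` is late minus early.
    prior_df
        override the estimated prior degrees of freedom.  ``0`` gives the
        ordinary pooled t-test; ``inf`` fully shrinks every variance to
        the prior.

    Returns
    -------
    DataFrame indexed by feature with columns mean_early, mean_late,
    log2fc, s2, t_mod, p, fdr, level.
    """
    labels = np.asarray(list(group_labels))
    if labels.size != log_expr.shape[1]:
        raise ValueError("one group label per sample column required")
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if early is None:
        early, late = uniq
    elif late is None:
        late = [u for u in uniq if u != early][0]
    m_early = labels == early
    m_late = labels == late
    n1, n2 = int(m_early.sum()), int(m_late.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples (got {n1} and {n2})")

    x = log_expr.to_numpy(dtype=float)
    mean_e = x[:, m_early].mean(axis=1)
    mean_l = x[:, m_late].mean(axis=1)
    log2fc = mean_l - mean_e
    ss = x[:, m_early].var(axis=1, ddof=1) * (n1 - 1) + x[:, m_late].var(axis=1, ddof=1) * (n2 - 1)
    d = n1 + n2 - 2
    s2 = ss / d

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, d)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2, d)
        if d0 >= PRIOR_DF_CAP:
            d0 = float("inf")

    if d0 == 0:
        s2_post = s2.copy()
        df_total = float(d)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = float("inf")
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    zero_var = se == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} features with zero residual and prior variance; "
            "p set to 0 (nonzero fold change) or 1", stacklevel=2,
        )
        t_mod = np.where(zero_var, np.where(log2fc != 0, np.inf * np.sign(log2fc), 0.0), t_mod)
        p = np.where(zero_var, np.where(log2fc != 0, 0.0, 1.0), p)

    result = pd.DataFrame(
        {
            "mean_early": mean_e,
            "mean_late": mean_l,
            "log2fc": log2fc,
            "s2": s2,
            "t_mod": t_mod,
            "p": p,
            "fdr": bh_adjust(p),
            "level": level,
        },
        index=log_expr.index,
    )
    result.attrs["prior_df"] = d0
    result.attrs["prior_var"] = s0_2
    result.attrs["residual_df"] = d
    return result


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# signature selection and combination
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """Selected features with direction and selection provenance.

    ``table`` is indexed by feature id with columns log2fc, t_mod, p,
    fdr, direction (+1 up in late / -1 down), level, and — after
    combination — ``provenance`` in {gene_only, isoform_only, both}.
    """

    table: pd.DataFrame
    fc_min: float = 2.0
    fdr_max: float = 0.001
    level: str = "mixed"

    @property
    def feature_ids(self) -> list[str]:
        return self.table.index.tolist()

    def __len__(self) -> int:
        return len(self.table)


def select_signatures(
    de: pd.DataFrame, fc_min: float = 2.0, fdr_max: float = 0.001
) -> SignatureSet:
    """Features with |log2fc| >= log2(fc_min) and fdr <= fdr_max."""
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    keep = (de["log2fc"].abs() >= np.log2(fc_min)) & (de["fdr"] <= fdr_max)
    table = de.loc[keep, ["log2fc", "t_mod", "p", "fdr", "level"]].copy()
    table["direction"] = np.sign(table["log2fc"]).astype(int)
    level = de["level"].iloc[0] if len(de) else "mixed"
    return SignatureSet(table, fc_min=fc_min, fdr_max=fdr_max, level=level)


def combine_signatures(
    gene_sigs: SignatureSet, iso_sigs: SignatureSet, fmap: FeatureMap
) -> SignatureSet:
    """Gene-priority union of gene- and isoform-level signatures.

    Any isoform signature whose gene is itself significant at the gene
    level is dropped (the gene feature represents it, tagged ``both``);
    isoform signatures of non-significant genes are kept
    (``isoform_only``); remaining gene features are ``gene_only``.
    """
    missing = [i for i in iso_sigs.feature_ids if i not in fmap]
    if missing:
        raise ValueError(f"isoform signatures absent from feature map: {missing}")
    iso_genes = fmap.genes_for(iso_sigs.feature_ids)
    sig_genes = set(gene_sigs.feature_ids)

    gene_tab = gene_sigs.table.copy()
    genes_with_sig_iso = set(iso_genes.values)
    gene_tab["provenance"] = [
        "both" if g in genes_with_sig_iso else "gene_only" for g in gene_tab.index
    ]
    keep_iso = ~iso_genes.isin(sig_genes).values
    iso_tab = iso_sigs.table.loc[keep_iso].copy()
    iso_tab["provenance"] = "isoform_only"

    combined = pd.concat([gene_tab, iso_tab])
    return SignatureSet(
        combined, fc_min=gene_sigs.fc_min, fdr_max=gene_sigs.fdr_max, level="mixed"
    )


def detect_switches(iso_sigs: SignatureSet, fmap: FeatureMap) -> list[str]:
    """Genes with >=2 selected isoforms changing in opposite directions."""
    if len(iso_sigs) == 0:
        return []
    genes = fmap.genes_for(iso_sigs.feature_ids)
    tab = iso_sigs.table.assign(gene=genes.values)
    out = []
    for gene, grp in tab.groupby("gene"):
        if len(grp) >= 2 and (grp["direction"] > 0).any() and (grp["direction"] < 0).any():
            out.append(gene)
    return sorted(out)


def signature_overlap(
    gene_sigs: SignatureSet, iso_sigs: SignatureSet, fmap: FeatureMap
) -> dict[str, float]:
    """Venn counts of gene-significant genes vs genes with significant isoforms.

    Returns counts (gene_only / isoform_only / both, by gene identity) and
    the two derived percentages: share of gene signatures that also have a
    significant isoform, and share of isoform-signature genes invisible at
    the gene level.
    """
    gene_set = set(gene_sigs.feature_ids)
    iso_gene_set = set(fmap.genes_for(iso_sigs.feature_ids).dropna().values)
    both = gene_set & iso_gene_set
    counts = {
        "n_gene_sig_genes": len(gene_set),
        "n_isoform_sig_genes": len(iso_gene_set),
        "n_both": len(both),
        "n_gene_only": len(gene_set - iso_gene_set),
        "n_isoform_only": len(iso_gene_set - gene_set),
    }
    counts["pct_gene_with_sig_isoform"] = (
        100.0 * len(both) / len(gene_set) if gene_set else float("nan")
    )
    counts["pct_isoform_genes_not_gene_sig"] = (
        100.0 * len(iso_gene_set - gene_set) / len(iso_gene_set) if iso_gene_set else float("nan")
    )
    return counts


def rank_signatures(sigs: SignatureSet) -> list[str]:
    """Order signatures by ascending FDR, ties broken by descending |log2fc|."""
    tab = sigs.table.assign(_abs_fc=sigs.table["log2fc"].abs())
    tab = tab.sort_values(["fdr", "_abs_fc"], ascending=[True, False], kind="mergesort")
    return tab.index.tolist()


def write_de_table(de: pd.DataFrame, path) -> None:
    out = de.copy()
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    out.to_csv(path, sep="\t", index_label="feature", float_format="%.6g")


def write_signatures(sigs: SignatureSet, path) -> None:
    sigs.table.to_csv(path, sep="\t", index_label="feature", float_format="%.6g")
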