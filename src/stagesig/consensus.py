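"""Resampling-based consensus clustering and the classification stability score.

Patients are repeatedly subsampled together with a subset of candidate
signature features; each resampled dataset is partitioned into two
clusters.  The consensus matrix M(i, j) is the fraction of resamples
co-sampling patients i and j in which the pair clustered together.  The
classification stability score against known stage labels s is

    SS = sum_{i<j} A_ij * M(i, j) / ES,   A_ij = +1 if s_i = s_j else -1,

where ES — the score of the perfect consensus matrix (M = 1 on same-label
pairs, 0 on different-label pairs) — is the number of unordered
same-label pairs.  SS = 1 exactly for the perfect matrix; label-ignorant
consensus drives it toward or below zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

ENGINES = ("hierarchical", "kmeans")


def round_half_up(x: float, ndigits: int = 1) -> float:
    scale = 10.0 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def expected_perfect_score(stage_labels) -> int:
    """Number of unordered same-label pairs (the SS normalizer ES)."""
    labels = pd.Series(list(stage_labels))
    if len(labels) < 2:
        raise ValueError("need at least 2 samples")
    es = int(sum(n * (n - 1) // 2 for n in labels.value_counts()))
    if es == 0:
        raise ValueError("all labels distinct: perfect score is 0, SS undefined")
    return es


@dataclass
class ConsensusRunSet:
    """The raw resampling runs: which patients each run included and how it
    partitioned them."""

    n_samples: int
    runs: list[tuple[np.ndarray, np.ndarray]]  # (patient indices, cluster labels)
    sample_fraction: float = 1.0
    feature_fraction: float = 1.0
    engine: str = "hierarchical"
    seed: int | None = None


@dataclass
class ConsensusResult:
    matrix: np.ndarray                 # consensus M, symmetric, unit diagonal
    co_sampling_counts: np.ndarray     # sum_h I^(h)(i, j)
    ss: float
    es: int
    partition: np.ndarray              # final 2-cluster labels in {0, 1}
    n_misclassified: int
    accuracy: float                    # percent, rounded half-up to 1 decimal
    engine: str
    sample_ids: list[str] = field(default_factory=list)
    degenerate: bool = False


def consensus_matrix(runs: ConsensusRunSet) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate M(i,j) = sum_h M^h(i,j) / sum_h I^h(i,j).

    Pairs never co-sampled get M = 0.5 (maximal uncertainty) with a logged
    warning.  Returns (M, co-sampling counts).
    """
    if not runs.runs:
        raise ValueError("need at least one run")
    n = runs.n_samples
    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for idx, labels in runs.runs:
        idx = np.asarray(idx)
        labels = np.asarray(labels)
        co_sampled[np.ix_(idx, idx)] += 1.0
        same = labels[:, None] == labels[None, :]
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(co_sampled > 0, together / np.maximum(co_sampled, 1), 0.5)
    never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning("%d patient pairs never co-sampled; consensus set to 0.5",
                       int(never.sum()) // 2)
    np.fill_diagonal(m, 1.0)
    return m, co_sampled


def stability_score(m: np.ndarray, stage_labels) -> float:
    """SS = sum_{i<j} A_ij M_ij / ES with A = +1 same-label, -1 different."""
    labels = np.asarray(list(stage_labels))
    n = labels.size
    if m.shape != (n, n):
        raise ValueError("consensus matrix shape does not match label count")
    es = expected_perfect_score(labels)
    a = np.where(labels[:, None] == labels[None, :], 1.0, -1.0)
    iu = np.triu_indices(n, k=1)
    return float(np.sum(a[iu] * m[iu]) / es)


def _cluster_hierarchical(x: np.ndarray) -> np.ndarray:
    """2-cluster average-linkage cut of 1 - Spearman between patient columns."""
    d = _spearman_dissimilarity(x)
    z = linkage(squareform(d, checks=False), method="average")
    return fcluster(z, t=2, criterion="maxclust") - 1


def _spearman_dissimilarity(x: np.ndarray) -> np.ndarray:
    """1 - Spearman rank correlation between patient profiles (columns of x)."""
    ranks = rankdata(x, axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=0))
    norms[norms == 0] = 1.0
    c = (ranks.T @ ranks) / np.outer(norms, norms)
    d = 1.0 - np.clip(c, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _cluster_kmeans(x: np.ndarray, seed: int) -> np.ndarray:
    """k = 2 k-means on per-feature rank-transformed, standardized profiles —
    a Euclidean surrogate for Spearman dissimilarity."""
    ranks = rankdata(x, axis=1).astype(float)
    sd = ranks.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (ranks - ranks.mean(axis=1, keepdims=True)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed % (2 ** 31))
    return km.fit_predict(z.T)


def run_consensus(
    expr_subset,
    stage_labels,
    n_resamples: int = 500,
    fraction: float = 0.8,
    engine: str = "hierarchical",
    seed: int | None = None,
    feature_fraction: float | None = None,
) -> ConsensusResult:
    """Consensus clustering of patients on a feature subset.

    Parameters
    ----------
    expr_subset
        features x patients array or DataFrame (rows are the candidate
        signatures being evaluated).
    stage_labels
        known stage per patient; used only for scoring, never for
        clustering.
    n_resamples, fraction
        number of resamples and the patient subsampling proportion
        (``floor(fraction * n)`` drawn without replacement).
        ``feature_fraction`` defaults to the same proportion.
    engine
        ``"hierarchical"`` (average linkage on 1 - Spearman) or
        ``"kmeans"`` (rank-based Euclidean surrogate).
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    x = expr_subset.to_numpy(dtype=float) if hasattr(expr_subset, "to_numpy") else np.asarray(expr_subset, dtype=float)
    sample_ids = list(expr_subset.columns) if hasattr(expr_subset, "columns") else []
    labels = np.asarray(list(stage_labels))
    n_feat, n_pat = x.shape
    if labels.size != n_pat:
        raise ValueError("one stage label per patient column required")
    if feature_fraction is None:
        feature_fraction = fraction
    n_pat_draw = max(2, math.floor(fraction * n_pat))
    n_feat_draw = max(1, math.floor(feature_fraction * n_feat))

    master = np.random.default_rng(seed)
    runs: list[tuple[np.ndarray, np.ndarray]] = []
    for h in range(n_resamples):
        rng = np.random.default_rng(master.integers(2 ** 31))
        feat_idx = rng.choice(n_feat, size=n_feat_draw, replace=False)
        pat_idx = rng.choice(n_pat, size=n_pat_draw, replace=False)
        sub = x[np.ix_(feat_idx, pat_idx)]
        if engine == "hierarchical":
            cl = _cluster_hierarchical(sub)
        else:
            cl = _cluster_kmeans(sub, seed=int(rng.integers(2 ** 31)))
        runs.append((pat_idx, cl))

    run_set = ConsensusRunSet(
        n_samples=n_pat, runs=runs, sample_fraction=fraction,
        feature_fraction=feature_fraction, engine=engine, seed=seed,
    )
    m, counts = consensus_matrix(run_set)
    ss = stability_score(m, labels)
    partition, degenerate = final_partition(m, return_flag=True)
    n_mis, acc = cluster_accuracy(partition, labels)
    return ConsensusResult(
        matrix=m, co_sampling_counts=counts, ss=ss,
        es=expected_perfect_score(labels), partition=partition,
        n_misclassified=n_mis, accuracy=acc, engine=engine,
        sample_ids=sample_ids, degenerate=degenerate,
    )


def final_partition(m: np.ndarray, return_flag: bool = False):
    """2-cluster average-linkage partition of the consensus dissimilarity 1 - M.

    A degenerate consensus (all patients merging into one cluster, e.g.
    M identically 1) is forcibly split by moving the first patient into
    its own cluster, flagged and logged.
    """
    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    part = fcluster(z, t=2, criterion="maxclust") - 1
    degenerate = False
    if len(np.unique(part)) < 2:
        degenerate = True
        logger.warning("degenerate consensus: single cluster; forcing a minimal split")
        part = part.copy()
        part[0] = 1 - part[0]
    if return_flag:
        return part, degenerate
    return part


def cluster_accuracy(partition, stage_labels) -> tuple[int, float]:
    """Match the 2 clusters to the 2 label classes maximizing agreement.

    Returns (n_misclassified, accuracy %) with accuracy rounded half-up
    to one decimal.
    """
    part = np.asarray(list(partition))
    labels = np.asarray(list(stage_labels))
    n = labels.size
    if part.size != n:
        raise ValueError("partition and labels differ in length")
    classes = sorted(pd.unique(labels))
    clusters = sorted(pd.unique(part))
    if len(classes) != 2 or len(clusters) > 2:
        raise ValueError("expect 2 label classes and at most 2 clusters")
    lab01 = (labels == classes[-1]).astype(int)
    part01 = (part == clusters[-1]).astype(int) if len(clusters) == 2 else np.zeros(n, int)
    mis = int(np.minimum((part01 != lab01).sum(), (part01 == lab01).sum()))
    accuracy = round_half_up(100.0 * (n - mis) / n, 1)
    return mis, accuracy


def stability_curve(
    ranked_features: list[str],
    expr,
    stage_labels,
    grid,
    engines=("hierarchical", "kmeans"),
    n_resamples: int = 500,
    fraction: float = 0.8,
    seed: int | None = None,
    source: str = "",
) -> pd.DataFrame:
    """SS and accuracy versus number of top-ranked signatures.

    ``expr`` must contain every ranked feature as a row (features x
    patients).  Duplicate grid values are evaluated once; values beyond
    the number of available signatures are truncated with a warning.
    """
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise ValueError("empty signature-count grid")
    rows = []
    for engine in engines:
        for j, k in enumerate(grid):
            k_eff = min(k, len(ranked_features))
            if k_eff < k:
                logger.warning("grid value %d exceeds %d available signatures; truncated",
                               k, len(ranked_features))
            feats = ranked_features[:k_eff]
            sub = expr.loc[feats] if hasattr(expr, "loc") else expr[:k_eff]
            res = run_consensus(
                sub, stage_labels, n_resamples=n_resamples, fraction=fraction,
                engine=engine, seed=None if seed is None else seed + 7919 * j,
            )
            rows.append({
                "source": source, "engine": engine, "k": k_eff,
                "ss": res.ss, "n_misclassified": res.n_misclassified,
                "accuracy": res.accuracy,
            })
    return pd.DataFrame(rows)
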