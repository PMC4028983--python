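"""Hypergeometric over-representation analysis of signature gene lists.

For a universe of N genes, a set with K universe members and a signature
of n genes overlapping the set in k, the enrichment p-value is the upper
tail P(X >= k) of Hypergeometric(N, K, n); p-values are BH-adjusted
across all tested sets.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import FeatureMap, GeneSetCollection

logger = logging.getLogger(__name__)


def map_to_genes(feature_ids, fmap: FeatureMap) -> set[str]:
    """Convert a mixed feature list to a de-duplicated gene id set.

    Isoform ids are translated through the map; ids absent from the map
    (gene-level features) pass through unchanged (counts logged).
    """
    genes: set[str] = set()
    n_pass = 0
    for fid in feature_ids:
        if fid in fmap:
            genes.add(fmap.gene_of(fid))
        else:
            genes.add(fid)
            n_pass += 1
    if n_pass:
        logger.info("%d ids not in the isoform map passed through as gene ids", n_pass)
    return genes


def hypergeom_enrich(
    signature_genes,
    universe_genes,
    sets: GeneSetCollection,
    fdr_max: float = 0.05,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Per-set upper-tail hypergeometric enrichment with BH adjustment.

    Signature genes outside the universe are dropped with a warning; set
    members are intersected with the universe; sets with fewer than
    ``min_set_size`` universe members (or zero overlap with the universe)
    are skipped.  Rows with ``fdr <= fdr_max`` are flagged ``selected``.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    signature = set(signature_genes)
    if not signature:
        raise ValueError("empty signature list")
    outside = signature - universe
    if outside:
        logger.warning("%d signature genes outside the universe dropped", len(outside))
        signature &= universe
        if not signature:
            raise ValueError("no signature gene inside the universe")

    n_universe = len(universe)
    n_sig = len(signature)
    rows = []
    for name, members in sets.items():
        in_universe = universe.intersection(members)
        big_k = len(in_universe)
        if big_k == 0 or big_k < min_set_size:
            continue
        overlap = sorted(signature.intersection(in_universe))
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_sig))
        rows.append({
            "set": name, "N": n_universe, "K": big_k, "n": n_sig, "k": k,
            "p": min(p, 1.0), "members": ";".join(overlap),
        })
    if not rows:
        return pd.DataFrame(
            columns=["set", "N", "K", "n", "k", "p", "fdr", "selected", "members"]
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["selected"] = table["fdr"] <= fdr_max
    return table.sort_values(["p", "set"]).reset_index(drop=True)[
        ["set", "N", "K", "n", "k", "p", "fdr", "selected", "members"]
    ]
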