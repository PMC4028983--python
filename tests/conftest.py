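import math

import numpy as np
import pandas as pd
import pytest

from stagesig.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale discovery+validation cohort with planted structure."""
    cfg = SyntheticConfig(
        n_early=100, n_late=40, n_validation=60, n_genes=500,
        frac_gene_de=0.05, frac_isoform_only_de=0.05, frac_switch=0.02,
        log2_effect=2.0, seed=1,
    )
    return generate_cohort(cfg)


def make_blobs(seed, n_feat=20, n=100, effect=3.0, base_sd=2.0, noise=1.0):
    """Two separable patient groups on a log-expression-like scale: shared
    per-feature baselines plus a signed per-feature group effect."""
    rng = np.random.default_rng(seed)
    base = rng.normal(4.0, base_sd, n_feat)
    signs = effect * np.resize([-1.0, 1.0], n_feat)  # balanced up/down effects
    rng.shuffle(signs)
    x = base[:, None] + rng.normal(0.0, noise, (n_feat, n))
    x[:, n // 2:] += signs[:, None]
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return pd.DataFrame(x), labels


def naive_bh(p):
    """O(m^2) step-up BH reference: fdr_i = min over j with p_j >= p_i of
    m * p_j / rank(p_j), clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, m * p[i] / (pos + 1))
        adj[i] = running_min
    return np.clip(adj, 0, 1)


def cox_score_test(times, events, x):
    """Score test of the Cox model at beta = 0 (tie-free data).

    U = sum over events of (x_i - mean of x over the risk set),
    V = sum over events of the risk-set variance of x; U^2 / V ~ chi2(1).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    u = 0.0
    v = 0.0
    for i in np.flatnonzero(d == 1):
        risk = x[t >= t[i]]
        u += x[i] - risk.mean()
        v += risk.var()
    stat = u * u / v
    from scipy.stats import chi2

    return stat, float(chi2.sf(stat, df=1))


def enumerate_hypergeom_upper(N, K, n, k):
    """Exact upper-tail hypergeometric P(X >= k) by combinatorial counting."""
    total = math.comb(N, n)
    count = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return count / total
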