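"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity from its definition, by enumeration or
closed form, without touching the implementation paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom, rankdata


def pooled_z(x1, n1, x2, n2):
    """Pooled two-proportion z statistic, written out independently."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)


def exact_two_proportion_p(x1, n1, x2, n2, alternative="greater", mid_p=True):
    """Exact unconditional p over the 2x2 binomial outcome space at the
    pooled MLE: P(Z(Y1,Y2) at least as extreme as the observed z)."""
    z_obs = float(pooled_z(x1, n1, x2, n2))
    phat = (x1 + x2) / (n1 + n2)
    y1 = np.arange(n1 + 1)
    y2 = np.arange(n2 + 1)
    pm = np.outer(binom.pmf(y1, n1, phat), binom.pmf(y2, n2, phat))
    z = np.asarray(pooled_z(y1[:, None], n1, y2[None, :], n2))
    eps = 1e-9
    if alternative == "greater":
        strict = pm[z > z_obs + eps].sum()
        tie = pm[np.abs(z - z_obs) <= eps].sum()
    elif alternative == "less":
        strict = pm[z < z_obs - eps].sum()
        tie = pm[np.abs(z - z_obs) <= eps].sum()
    else:
        strict = pm[np.abs(z) > abs(z_obs) + eps].sum()
        tie = pm[np.abs(np.abs(z) - abs(z_obs)) <= eps].sum()
    return float(strict + (0.5 * tie if mid_p else tie))


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values straight from the step-up
    definition: adjusted_(i) = min_{j >= i} m p_(j) / j, clipped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adjusted_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def wilcoxon_enumeration_p(a, b, alternative="two_sided"):
    """Exact rank-sum p by full enumeration of all C(n1+n2, n1) splits of
    the combined sample's (mid)ranks; two-sided = 2 min(one-sided), capped."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ranks = rankdata(np.concatenate([a, b]))
    n1, n = a.size, a.size + b.size
    w_obs = ranks[:n1].sum()
    sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), n1)])
    eps = 1e-9
    p_greater = float((sums >= w_obs - eps).mean())
    p_less = float((sums <= w_obs + eps).mean())
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def expected_rarefied_richness(counts, depth):
    """Closed-form expectation of observed richness after drawing ``depth``
    reads without replacement: E[S_d] = sum_i (1 - C(N-N_i, d)/C(N, d))."""
    counts = np.asarray(counts, float)
    total = counts.sum()

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expectation = 0.0
    for n_i in counts:
        if total - n_i < depth:
            expectation += 1.0
        else:
            expectation += 1.0 - np.exp(
                log_comb(total - n_i, depth) - log_comb(total, depth)
            )
    return float(expectation)


def bray_curtis_pair(x, y):
    """Direct evaluation of d = sum|x-y| / sum(x+y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.abs(x - y).sum() / (x + y).sum())
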