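"""One-sided one-sample Wilcoxon signed-rank and rank-sum p-values.

These back the per-miRNA enrichment test: a focal miRNA's score is compared
to every other miRNA's score through the paired differences
``d_j = x_focal - x_j``.  For small samples the exact conditional null
distribution (given the observed tie pattern) is computed by dynamic
programming over rank sums; larger samples use the normal approximation
with midrank tie correction and a 0.5 continuity correction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["signed_rank_greater", "rank_sum_greater", "EXACT_LIMIT"]

#: largest number of non-zero differences for which the exact distribution is used
EXACT_LIMIT = 25


def _exact_sf(double_ranks: np.ndarray, observed_double: float) -> float:
    """P(W+ >= observed) under random signs, by convolution over rank sums.

    Ranks are doubled so midranks (k.5) become integers; the distribution of
    the doubled positive-rank sum is built by dynamic programming.
    """
    dr = np.rint(double_ranks).astype(np.int64)
    total = int(dr.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    top = 0
    for r in dr:
        new = counts.copy()
        new[r : top + r + 1] += counts[: top + 1]
        counts = new
        top += r
    obs = int(np.ceil(observed_double - 1e-9))
    return float(counts[obs:].sum() / counts.sum())


def signed_rank_greater(diffs: np.ndarray, exact_limit: int = EXACT_LIMIT) -> float:
    """One-sided one-sample signed-rank p-value for H1: differences > 0.

    Zero differences are dropped (Wilcoxon reduction); if all differences are
    zero the p-value is 1.  With at most ``exact_limit`` non-zero differences
    the exact conditional distribution is enumerated, otherwise the normal
    approximation with tie and continuity correction is used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m <= exact_limit:
        return _exact_sf(2.0 * ranks, 2.0 * w_plus)
    # E[W+] = sum(r)/2, Var[W+] = sum(r^2)/4 (midranks absorb the tie correction)
    mean = ranks.sum() / 2.0
    var = float((ranks**2).sum()) / 4.0
    if var == 0:
        return 1.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(sps.norm.sf(z))


def rank_sum_greater(x: float, others: np.ndarray) -> float:
    """One-sided rank-sum (Mann-Whitney) p-value for a single focal value.

    Exact: with one focal observation, U = #{others < x} + #{ties}/2 and the
    null distribution of U is uniform over the n+1 possible insertion points.
    """
    others = np.asarray(others, dtype=float)
    n = others.size
    if n == 0:
        return 1.0
    u = float(np.sum(others < x) + 0.5 * np.sum(others == x))
    # P(U* >= u) with U* uniform on {0, ..., n}
    k = int(np.ceil(u - 1e-9))
    return float((n - k + 1) / (n + 1))
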