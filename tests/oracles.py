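"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — pure-Python loops and exhaustive
enumeration — and shares no code with the package implementation.
"""

from __future__ import annotations

import math
from itertools import combinations, product


def naive_features(values, n_bins: int = 32) -> dict:
    """Single-pass loop evaluation of all seven texture features."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    sd = math.sqrt(ss / (n - 1)) if n > 1 else float("nan")
    m2 = ss / n
    if m2 > 0:
        m3 = sum((v - mean) ** 3 for v in values) / n
        m4 = sum((v - mean) ** 4 for v in values) / n
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:
        skew = kurt = float("nan")

    lo, hi = min(values), max(values)
    counts = [0] * n_bins
    if hi == lo:
        counts[0] = n
        energy = 1.0
    else:
        width = (hi - lo) / n_bins
        for v in values:
            i = int(math.floor((v - lo) / width))
            counts[min(i, n_bins - 1)] += 1
        energy = sum(((v - lo) / (hi - lo)) ** 2 for v in values) / n
    probs = [c / n for c in counts]
    uniformity = sum(p * p for p in probs)
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    return {
        "mean": mean,
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "uniformity": uniformity,
        "energy": energy,
        "entropy": entropy,
        "counts": counts,
    }


def naive_binning(values, n_bins: int) -> list[int]:
    return naive_features(values, n_bins)["counts"]


def mannwhitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group splits."""
    pooled = sorted(list(a) + list(b))
    n1 = len(a)

    def u_stat(group_a_vals):
        u = 0.0
        rest = list(pooled)
        for v in group_a_vals:
            rest.remove(v)
        for x in group_a_vals:
            for y_ in rest:
                u += (x > y_) + 0.5 * (x == y_)
        return u

    u_obs = u_stat(list(a))
    n1n2 = n1 * (len(pooled) - n1)
    dev_obs = abs(u_obs - n1n2 / 2)
    hits = total = 0
    for combo in combinations(range(len(pooled)), n1):
        vals = [pooled[i] for i in combo]
        total += 1
        if abs(u_stat(vals) - n1n2 / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def signed_rank_exact_p(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating sign flips."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    mags = sorted(abs(d) for d in diffs)
    ranks = {m: i + 1 for i, m in enumerate(mags)}  # assumes tie-free |d|
    w_obs = sum(ranks[abs(d)] for d in diffs if d > 0)
    dist = []
    for signs in product([0, 1], repeat=n):
        dist.append(sum(r for r, s in zip(range(1, n + 1), signs) if s))
    total = len(dist)
    cdf = sum(w <= w_obs for w in dist) / total
    sf = sum(w >= w_obs for w in dist) / total
    return min(1.0, 2 * min(cdf, sf))


def auc_pair_enumeration(scores, labels) -> float:
    """AUC as the fraction of positive-negative pairs correctly ordered."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            wins += (p > q) + 0.5 * (p == q)
    return wins / total


def icc2_mean_squares(a, b) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares, written out by hand."""
    n = len(a)
    k = 2
    grand = (sum(a) + sum(b)) / (n * k)
    row_means = [(x + y_) / 2 for x, y_ in zip(a, b)]
    col_means = [sum(a) / n, sum(b) / n]
    msr = k * sum((r - grand) ** 2 for r in row_means) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col_means) / (k - 1)
    sse = 0.0
    for i in range(n):
        for j, col in enumerate((a, b)):
            sse += (col[i] - row_means[i] - col_means[j] + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
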