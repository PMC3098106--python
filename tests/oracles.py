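"""Independent naive reference implementations used only by the tests.

Everything here is written with explicit Python loops and elementary
formulas, deliberately avoiding the package's vectorised code paths (and
scipy's ranking), so agreement between the two is a meaningful check.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np


def naive_median(xs) -> float:
    xs = sorted(xs)
    n = len(xs)
    mid = n // 2
    return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2.0


def naive_align(values: np.ndarray) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for i in range(values.shape[0]):
        med = naive_median(list(values[i, :]))
        for j in range(values.shape[1]):
            out[i, j] = values[i, j] - med
    return out


def naive_column_ranks(column) -> list[float]:
    """Midranks: 1 + #smaller + (#equal - 1)/2, by direct counting."""
    ranks = []
    for v in column:
        smaller = sum(1 for u in column if u < v)
        equal = sum(1 for u in column if u == v)
        ranks.append(1.0 + smaller + (equal - 1) / 2.0)
    return ranks


def naive_rank_matrix(aligned: np.ndarray) -> np.ndarray:
    m, n = aligned.shape
    ranks = np.empty((m, n))
    for j in range(n):
        ranks[:, j] = naive_column_ranks(list(aligned[:, j]))
    return ranks


def naive_rank_statistic(ranks: np.ndarray, mask) -> float:
    """Squared distance between group-average rank vectors, element-wise."""
    idx1 = [j for j, in1 in enumerate(mask) if in1]
    idx2 = [j for j, in1 in enumerate(mask) if not in1]
    s = 0.0
    for i in range(ranks.shape[0]):
        w1 = sum(ranks[i, j] for j in idx1) / len(idx1)
        w2 = sum(ranks[i, j] for j in idx2) / len(idx2)
        s += (w1 - w2) ** 2
    return s


def naive_exhaustive_pvalue(ranks: np.ndarray, mask) -> tuple[float, int]:
    """Enumerate every choice of n1 subjects as group 1; count S >= S_obs."""
    n = ranks.shape[1]
    n1 = sum(1 for b in mask if b)
    s_obs = naive_rank_statistic(ranks, mask)
    count = 0
    total = 0
    for idx1 in combinations(range(n), n1):
        pm = [j in idx1 for j in range(n)]
        total += 1
        if naive_rank_statistic(ranks, pm) >= s_obs - 1e-9:
            count += 1
    return count / total, total


def naive_snr(values: np.ndarray, mask) -> list[float]:
    idx1 = [j for j, b in enumerate(mask) if b]
    idx2 = [j for j, b in enumerate(mask) if not b]
    out = []
    for i in range(values.shape[0]):
        x1 = [values[i, j] for j in idx1]
        x2 = [values[i, j] for j in idx2]
        m1 = sum(x1) / len(x1)
        m2 = sum(x2) / len(x2)
        s1 = (sum((v - m1) ** 2 for v in x1) / (len(x1) - 1)) ** 0.5
        s2 = (sum((v - m2) ** 2 for v in x2) / (len(x2) - 1)) ** 0.5
        out.append((m1 - m2) / (s1 + s2))
    return out


def naive_enrichment_score(snr, member, signed: bool = False) -> float:
    """Tabulate both ECDFs explicitly at every position of the ordering."""
    order = sorted(range(len(snr)), key=lambda i: (-snr[i], i))
    n_hit = sum(1 for b in member if b)
    n_miss = len(member) - n_hit
    best_top, best_bottom = -np.inf, np.inf
    hits = misses = 0
    for i in order:
        if member[i]:
            hits += 1
        else:
            misses += 1
        diff = hits / n_hit - misses / n_miss
        best_top = max(best_top, diff)
        best_bottom = min(best_bottom, diff)
    if signed:
        return best_top if best_top >= -best_bottom else best_bottom
    return max(best_top, 0.0)


def naive_global_q(values: np.ndarray, mask) -> float:
    """Quadratic form via the explicit n x n matrix and a double loop."""
    m, n = values.shape
    centred = np.empty_like(values, dtype=float)
    for i in range(m):
        mean_i = sum(values[i, :]) / n
        centred[i, :] = [values[i, j] - mean_i for j in range(n)]
    a = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            a[j, k] = sum(centred[i, j] * centred[i, k] for i in range(m))
    ybar = sum(1.0 for b in mask if b) / n
    z = [(1.0 if b else 0.0) - ybar for b in mask]
    mu2 = sum(v * v for v in z) / n
    q = 0.0
    for j in range(n):
        for k in range(n):
            q += z[j] * a[j, k] * z[k]
    return q / (mu2 * m)
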