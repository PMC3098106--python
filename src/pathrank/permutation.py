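"""Sample-relabelling machinery shared by all permutation-calibrated tests.

Under the null hypothesis the subjects in the two groups are interchangeable,
so the null distribution of any set-level statistic is obtained by recomputing
it over relabellings of the samples: choices of which ``n1`` of the ``n``
subjects form group 1.  When the number of distinct relabellings C(n, n1) is
no larger than the permutation budget, all of them are enumerated exactly once
(the p-value is then exact); otherwise the budget is filled with uniformly
random relabellings, with the observed labelling always included once so the
p-value can never fall below 1/N.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "PermutationScheme",
    "n_distinct_relabelings",
    "relabeling_masks",
    "pvalue_from_null",
]


@dataclass(frozen=True)
class PermutationScheme:
    """Configuration of a permutation null distribution.

    ``n_perms`` is the budget of relabellings (default 1000, the convention
    for this family of tests); ``seed`` drives the random draws so any result
    is reproducible and independent of the order in which pathways are
    evaluated.
    """

    n_perms: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def n_distinct_relabelings(n: int, n1: int) -> int:
    """Number of distinct assignments of n1 of n subjects to group 1."""
    return math.comb(n, n1)


def relabeling_masks(
    observed_mask: np.ndarray,
    n_perms: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Build the matrix of group-1 membership masks for a permutation null.

    Parameters
    ----------
    observed_mask
        Boolean vector (length n) marking the observed group-1 samples.
    n_perms
        Permutation budget.
    rng
        Source of randomness for the non-exhaustive case.

    Returns
    -------
    masks : (P, n) boolean array
        Row 0 is the observed labelling in the random regime; in the
        exhaustive regime every distinct relabelling appears exactly once
        (the observed one among them).
    exhaustive : bool
        Whether all C(n, n1) relabellings were enumerated.
    """
    observed_mask = np.asarray(observed_mask, dtype=bool)
    n = observed_mask.size
    n1 = int(observed_mask.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")
    total = n_distinct_relabelings(n, n1)
    if total <= n_perms:
        masks = np.zeros((total, n), dtype=bool)
        for row, idx in enumerate(combinations(range(n), n1)):
            masks[row, list(idx)] = True
        return masks, True
    masks = np.zeros((n_perms, n), dtype=bool)
    masks[0] = observed_mask
    if n_perms > 1:
        # vectorised draw of uniform n1-subsets: first n1 positions of random orders
        order = np.argsort(rng.random((n_perms - 1, n)), axis=1)[:, :n1]
        rows = np.repeat(np.arange(1, n_perms), n1)
        masks[rows, order.ravel()] = True
    return masks, False


def pvalue_from_null(null_stats: np.ndarray, observed: float) -> float:
    """Permutation p-value: fraction of null statistics >= the observed one.

    The observed labelling's statistic is part of ``null_stats``, so the
    count is at least 1 and the p-value at least 1/len(null_stats).
    """
    null_stats = np.asarray(null_stats, dtype=float)
    return float(np.count_nonzero(null_stats >= observed)) / null_stats.size
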