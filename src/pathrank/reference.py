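"""Comparator set-level statistics: the two-ECDF GSEA enrichment score and
the Global test Q-statistic, both calibrated by sample-label permutation.

**GSEA (unweighted two-ECDF form).**  Genes are ordered by decreasing
signal-to-noise ratio SNR = (mu1 − mu2)/(sd1 + sd2) (group means and sample
standard deviations; group 1 is the condition of interest).  Walking down
the ordered list, two empirical CDFs are maintained — the fraction of the
gene set's genes seen so far (F_hit) and the fraction of the complement
seen so far (F_miss).  The enrichment score is the maximum of
F_hit − F_miss over positions, floored at zero: a high score means the set
concentrates near the top of the ranking.  A configuration flag switches to
the signed maximum-deviation variant.  This is the original ECDF-difference
statistic, not the later weighted running-sum.

**Global test.**  For a binary outcome Y (1 = condition of interest) and
the pathway's column-centred n x N_G expression submatrix X_G, the
goodness-of-fit statistic of the underlying generalized linear model is the
quadratic form

    Q = Z' X_G X_G' Z / (mu2 * N_G),     Z = Y − Ybar,

where mu2 = mean(Z^2) is the second central moment of Y under the null.
Q is large when at least one gene's expression covaries with the outcome.
Here Q is calibrated by sample-label permutation, consistent with how the
rank and GSEA p-values are produced (the asymptotic calibration is out of
scope); the normalisation by mu2 * N_G makes Q comparable across set sizes
but any positive constant leaves the permutation p-value unchanged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GeneSet, ValidationError, subset_to_pathway
from .permutation import PermutationScheme, pvalue_from_null, relabeling_masks
from .results import TestResult

logger = logging.getLogger("pathrank")

__all__ = [
    "SnrRanking",
    "snr_ranking",
    "gsea_enrichment_score",
    "gsea_test",
    "global_q",
    "global_test",
    "GseaTest",
    "GlobalTest",
]

# GSEA-desktop convention for degenerate standard deviations:
# sd_i <- max(sd_i, SD_FLOOR_FRACTION * |mean_i|), absolute floor when mean is 0
SD_FLOOR_FRACTION = 0.2
SD_FLOOR_ABSOLUTE = 0.2


@dataclass
class SnrRanking:
    """Per-gene signal-to-noise ratios and the induced decreasing order."""

    gene_ids: list[str]
    snr: np.ndarray
    order: np.ndarray  # gene indices sorted by decreasing SNR, stable in input order

    def __post_init__(self) -> None:
        self.snr = np.asarray(self.snr, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        if not (len(self.gene_ids) == self.snr.size == self.order.size):
            raise ValueError("gene_ids, snr and order must have equal length")


def _floored_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    floor = np.maximum(SD_FLOOR_FRACTION * np.abs(mean), 0.0)
    floor = np.where(floor == 0.0, SD_FLOOR_ABSOLUTE, floor)
    return np.maximum(sd, np.where(sd == 0.0, floor, 0.0))


def _snr_matrix(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """SNR of every gene under every relabelling; (G, P) for masks (P, n)."""
    n1 = int(masks[0].sum())
    n2 = masks.shape[1] - n1
    m = masks.T.astype(float)  # (n, P)
    sum1 = values @ m
    sumsq1 = (values**2) @ m
    tot = values.sum(axis=1, keepdims=True)
    totsq = (values**2).sum(axis=1, keepdims=True)
    mean1 = sum1 / n1
    mean2 = (tot - sum1) / n2
    var1 = np.maximum(sumsq1 - n1 * mean1**2, 0.0) / (n1 - 1)
    var2 = np.maximum((totsq - sumsq1) - n2 * mean2**2, 0.0) / (n2 - 1)
    sd1 = _floored_sd(np.sqrt(var1), mean1)
    sd2 = _floored_sd(np.sqrt(var2), mean2)
    return (mean1 - mean2) / (sd1 + sd2)


def snr_ranking(X: ExpressionMatrix) -> SnrRanking:
    """Rank all array genes by decreasing signal-to-noise ratio.

    SNR = (mean in classes[0] − mean in classes[1]) / (sd1 + sd2) with
    sample standard deviations (denominator n_i − 1).  A zero denominator
    (both groups constant for the gene) is floored at the GSEA-desktop
    convention and logged.  Ties are broken by gene input order.
    """
    n1, n2 = X.group_sizes
    if min(n1, n2) < 2:
        raise ValidationError("SNR needs >= 2 samples per group")
    mask = X.group_mask()
    g1 = X.values[:, mask]
    g2 = X.values[:, ~mask]
    mean1, mean2 = g1.mean(axis=1), g2.mean(axis=1)
    sd1, sd2 = g1.std(axis=1, ddof=1), g2.std(axis=1, ddof=1)
    zero = (sd1 + sd2) == 0.0
    if zero.any():
        logger.warning(
            "%d gene(s) constant in both groups; standard deviations floored",
            int(zero.sum()),
        )
    snr = (mean1 - mean2) / (_floored_sd(sd1, mean1) + _floored_sd(sd2, mean2))
    order = np.argsort(-snr, kind="stable")
    return SnrRanking(gene_ids=list(X.gene_ids), snr=snr, order=order)


def _es_from_membership(hit_ordered: np.ndarray, signed: bool) -> np.ndarray:
    """Enrichment score(s) from ordered hit indicators; works on (G,) or (G, P)."""
    hit = hit_ordered.astype(float)
    n_hit = hit.sum(axis=0)
    n_miss = hit.shape[0] - n_hit
    f_hit = np.cumsum(hit, axis=0) / n_hit
    f_miss = np.cumsum(1.0 - hit, axis=0) / n_miss
    diff = f_hit - f_miss
    top = diff.max(axis=0)
    if signed:
        bottom = diff.min(axis=0)
        return np.where(top >= -bottom, top, bottom)
    return np.maximum(top, 0.0)


def gsea_enrichment_score(
    ranking: SnrRanking, g: GeneSet, signed: bool = False
) -> float:
    """Maximum difference between the hit and miss ECDFs along the ranking.

    By default the positive-deviation form (floored at 0): a high score is
    achieved when the set contains many highly ranked genes.  ``signed=True``
    returns the maximum deviation in magnitude, keeping its sign.
    """
    member = np.array([gid in g.genes for gid in ranking.gene_ids], dtype=bool)
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValidationError(f"gene set {g.name!r} shares no genes with the array")
    if n_hit == member.size:
        raise ValidationError(
            f"gene set {g.name!r} covers the whole array; the miss ECDF is undefined"
        )
    return float(_es_from_membership(member[ranking.order], signed))


def gsea_test(
    X: ExpressionMatrix,
    g: GeneSet,
    scheme: PermutationScheme | None = None,
    signed: bool = False,
) -> TestResult:
    """GSEA with a sample-relabelling permutation p-value.

    The SNR ranking and the enrichment score are recomputed under every
    relabelling; p is the fraction of relabellings (observed included) with
    an enrichment score at least the observed one.
    """
    scheme = scheme or PermutationScheme()
    member = np.array([gid in g.genes for gid in X.gene_ids], dtype=bool)
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValidationError(f"gene set {g.name!r} shares no genes with the array")
    if n_hit == X.n_genes:
        raise ValidationError(
            f"gene set {g.name!r} covers the whole array; the miss ECDF is undefined"
        )
    masks, exhaustive = relabeling_masks(X.group_mask(), scheme.n_perms, scheme.rng())
    snr = _snr_matrix(X.values, masks)  # (G, P)
    order = np.argsort(-snr, axis=0, kind="stable")
    hit_ordered = member[order]  # (G, P)
    null = _es_from_membership(hit_ordered, signed)
    obs_row = int(np.flatnonzero((masks == X.group_mask()).all(axis=1))[0])
    es_obs = float(null[obs_row])
    p = pvalue_from_null(null, es_obs)
    return TestResult(
        statistic=es_obs,
        p_value=p,
        n_perms_used=masks.shape[0],
        method="gsea",
        set_name=g.name,
        set_size=n_hit,
        exhaustive=exhaustive,
        extras={"signed": signed},
    )


def global_q(X: ExpressionMatrix, g: GeneSet | None = None, min_genes: int = 1) -> float:
    """The Global test Q-statistic for one gene set.

    Q = Z' X_G X_G' Z / (mu2 * N_G) with Z the centred binary outcome and
    X_G the column-centred pathway submatrix; Q >= 0, and Q = 0 when every
    gene is constant across samples or expression is orthogonal to the
    outcome.
    """
    sub = X if g is None else subset_to_pathway(X, g, min_genes=min_genes)
    y = sub.group_mask().astype(float)
    z = y - y.mean()
    mu2 = float((z**2).mean())
    if mu2 == 0.0:
        raise ValidationError("outcome has a single class; mu2 = 0")
    centred = sub.values - sub.values.mean(axis=1, keepdims=True)  # genes centred
    xz = centred @ z  # (M,)
    return float((xz**2).sum() / (mu2 * sub.n_genes))


def _global_q_over_masks(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Vectorised Q for every relabelling; values (M, n), masks (P, n)."""
    n = masks.shape[1]
    n1 = int(masks[0].sum())
    z = masks.astype(float) - n1 / n  # (P, n), each row the centred outcome
    mu2 = (n1 / n) * (1 - n1 / n)
    centred = values - values.mean(axis=1, keepdims=True)
    xz = centred @ z.T  # (M, P)
    return (xz**2).sum(axis=0) / (mu2 * values.shape[0])


def global_test(
    X: ExpressionMatrix,
    g: GeneSet | None = None,
    scheme: PermutationScheme | None = None,
    min_genes: int = 1,
) -> TestResult:
    """Global test Q with a sample-relabelling permutation p-value."""
    scheme = scheme or PermutationScheme()
    sub = X if g is None else subset_to_pathway(X, g, min_genes=min_genes)
    mask = sub.group_mask()
    masks, exhaustive = relabeling_masks(mask, scheme.n_perms, scheme.rng())
    null = _global_q_over_masks(sub.values, masks)
    # read Q_obs off the null array so the observed labelling compares equal
    # to itself bit-for-bit
    obs_row = int(np.flatnonzero((masks == mask).all(axis=1))[0])
    q_obs = float(null[obs_row])
    p = pvalue_from_null(null, q_obs)
    return TestResult(
        statistic=q_obs,
        p_value=p,
        n_perms_used=masks.shape[0],
        method="global",
        set_name=g.name if g is not None else None,
        set_size=sub.n_genes,
        exhaustive=exhaustive,
        extras={"null_mean": float(null.mean())},
    )


class GseaTest:
    """Model-style interface for the ECDF-difference GSEA test."""

    method = "gsea"

    def __init__(self, data: ExpressionMatrix, gene_set: GeneSet, signed: bool = False):
        self.data = data
        self.gene_set = gene_set
        self.signed = signed

    def fit(self, n_perms: int = 1000, seed: int = 0) -> TestResult:
        scheme = PermutationScheme(n_perms=n_perms, seed=seed)
        return gsea_test(self.data, self.gene_set, scheme, signed=self.signed)


class GlobalTest:
    """Model-style interface for the permutation-calibrated Global test."""

    method = "global"

    def __init__(
        self,
        data: ExpressionMatrix,
        gene_set: GeneSet | None = None,
        min_genes: int = 1,
    ):
        self.data = data
        self.gene_set = gene_set
        self.min_genes = min_genes

    def fit(self, n_perms: int = 1000, seed: int = 0) -> TestResult:
        scheme = PermutationScheme(n_perms=n_perms, seed=seed)
        return global_test(
            self.data, self.gene_set, scheme, min_genes=self.min_genes
        )
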