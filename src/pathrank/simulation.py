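"""Multivariate-normal power study for the set-level tests.

One pathway of M genes (default 46, the average KEGG pathway size on the
arrays that motivated the method) is simulated for two groups of equal
size.  Controls are always i.i.d. standard normal, N(0, I).  The treated
group is perturbed under one of four scenarios:

* ``no_change`` — N(0, I), identical to the controls (type-I error);
* ``mean_change`` — the first ``shifted_genes`` genes (default 3) get mean
  ``shift`` (default 2), identity covariance;
* ``correlation_change`` — N(0, Sigma) with unit variances and every
  pairwise covariance ``rho`` (default 0.9, exchangeable / compound
  symmetric);
* ``both`` — the mean shift and the exchangeable covariance combined.

Each gene row is then centred by its pooled-sample median.  Power is the
Monte-Carlo fraction of replicates whose permutation p-value is <= alpha
(inclusive), at alpha = 0.1 and 1000 permutations by default.

GSEA needs genes outside the tested set to form its miss-ECDF, which the
single-pathway design does not provide; ``background_genes`` adds a block
of i.i.d. N(0, 1) genes (in both groups) for GSEA runs.  GSEA power
therefore depends on this extra choice and is reproducible only
qualitatively.

Seeding is hierarchical — master seed -> (method, replicate) seeds ->
per-test permutation seeds — so every table is a pure function of the
master seed and adding a method never perturbs another method's replicate
stream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet
from .permutation import PermutationScheme
from .rank import rank_test_pathway
from .reference import global_test, gsea_test

logger = logging.getLogger("pathrank")

__all__ = [
    "Scenario",
    "PowerEstimate",
    "SCENARIO_KINDS",
    "METHODS",
    "simulate_dataset",
    "scenario_gene_set",
    "estimate_power",
    "pre_family_error_rate",
    "power_table",
    "default_grid",
]

SCENARIO_KINDS = ("no_change", "mean_change", "correlation_change", "both")
METHODS = ("rank", "global", "gsea")
_METHOD_CODE = {m: i + 1 for i, m in enumerate(METHODS)}

#: background block used for GSEA when a scenario does not set one
DEFAULT_GSEA_BACKGROUND = 500


@dataclass(frozen=True)
class Scenario:
    """One simulation condition.

    ``m_genes`` pathway genes per subject; ``n_per_group`` subjects in each
    of the two groups; ``shifted_genes`` genes get mean ``shift`` in the
    treated group under the mean scenarios; ``rho`` is the common pairwise
    covariance (unit variances) under the correlation scenarios;
    ``background_genes`` i.i.d. N(0, 1) genes are appended for GSEA runs.
    """

    kind: str
    m_genes: int = 46
    n_per_group: int = 5
    shifted_genes: int = 3
    shift: float = 2.0
    rho: float = 0.9
    background_genes: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"kind must be one of {SCENARIO_KINDS}, got {self.kind!r}")
        if self.m_genes < 2:
            raise ValueError("m_genes must be >= 2")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0 <= self.shifted_genes <= self.m_genes):
            raise ValueError("shifted_genes must lie in [0, m_genes]")
        if self.background_genes < 0:
            raise ValueError("background_genes must be >= 0")
        if self.kind in ("correlation_change", "both"):
            if not (-1.0 / (self.m_genes - 1) < self.rho < 1.0):
                raise ValueError(
                    f"rho={self.rho} gives a non-positive-definite exchangeable "
                    f"covariance for M={self.m_genes}"
                )


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection-rate estimate for one (method, scenario) cell."""

    method: str
    scenario: Scenario
    alpha: float
    n_reps: int
    n_rejections: int

    @property
    def power(self) -> float:
        return self.n_rejections / self.n_reps

    @property
    def mc_se(self) -> float:
        """Binomial standard error sqrt(p(1-p)/n_reps)."""
        p = self.power
        return float(np.sqrt(p * (1.0 - p) / self.n_reps))


def _exchangeable_draw(
    rng: np.random.Generator, n: int, m: int, rho: float
) -> np.ndarray:
    """n samples (columns) from N(0, Sigma), Sigma exchangeable (1, rho)."""
    if rho >= 0.0:
        # one-factor representation: sqrt(rho) * common + sqrt(1-rho) * idiosyncratic
        common = rng.standard_normal((1, n))
        return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.standard_normal((m, n))
    sigma = np.full((m, m), rho)
    np.fill_diagonal(sigma, 1.0)
    chol = np.linalg.cholesky(sigma)  # raises if not positive definite
    return chol @ rng.standard_normal((m, n))


def simulate_dataset(
    s: Scenario,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    center: bool = True,
) -> ExpressionMatrix:
    """Generate one two-group dataset under scenario ``s``.

    Columns are the control samples followed by the treated samples; gene
    rows are the pathway genes ``g001..`` followed by any background genes
    ``bg001..``.  Each gene row is centred by its pooled-sample median
    unless ``center=False`` (useful for moment checks).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = s.n_per_group
    m = s.m_genes
    control = rng.standard_normal((m, n))
    if s.kind in ("correlation_change", "both"):
        treated = _exchangeable_draw(rng, n, m, s.rho)
    else:
        treated = rng.standard_normal((m, n))
    if s.kind in ("mean_change", "both"):
        treated[: s.shifted_genes, :] += s.shift
    values = np.hstack([control, treated])
    if s.background_genes:
        values = np.vstack(
            [values, rng.standard_normal((s.background_genes, 2 * n))]
        )
    if center:
        values = values - np.median(values, axis=1, keepdims=True)
    width = len(str(max(m, s.background_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(m)] + [
        f"bg{i + 1:0{width}d}" for i in range(s.background_genes)
    ]
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=[f"c{j + 1}" for j in range(n)] + [f"t{j + 1}" for j in range(n)],
        groups=["control"] * n + ["treated"] * n,
        classes=("treated", "control"),
    )


def scenario_gene_set(s: Scenario) -> GeneSet:
    """The simulated pathway (the first ``m_genes`` genes) as a GeneSet."""
    width = len(str(max(s.m_genes, s.background_genes)))
    return GeneSet(
        name="simulated_pathway",
        genes=frozenset(f"g{i + 1:0{width}d}" for i in range(s.m_genes)),
        description=f"simulated {s.m_genes}-gene pathway",
    )


def _run_method(
    method: str, X: ExpressionMatrix, g: GeneSet, scheme: PermutationScheme
) -> float:
    if method == "rank":
        return rank_test_pathway(X, g, scheme).p_value
    if method == "global":
        return global_test(X, g, scheme).p_value
    if method == "gsea":
        return gsea_test(X, g, scheme).p_value
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def estimate_power(
    method: str,
    s: Scenario,
    alpha: float = 0.1,
    n_reps: int = 1000,
    n_perms: int = 1000,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo rejection rate of ``method`` at level ``alpha`` under ``s``.

    Each replicate generates a fresh dataset, runs the test with its own
    permutation seed, and rejects when p <= alpha (inclusive, as printed).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method == "gsea" and s.background_genes == 0:
        raise ValueError(
            "GSEA needs genes outside the tested set to form its miss-ECDF; "
            "set Scenario.background_genes > 0 "
            f"(e.g. {DEFAULT_GSEA_BACKGROUND})"
        )
    g = scenario_gene_set(s)
    code = _METHOD_CODE[method]
    rejections = 0
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, code, r]))
        X = simulate_dataset(s, rng=rng)
        scheme = PermutationScheme(
            n_perms=n_perms, seed=int(rng.integers(0, 2**31 - 1))
        )
        p = _run_method(method, X, g, scheme)
        if p <= alpha:
            rejections += 1
    return PowerEstimate(
        method=method, scenario=s, alpha=alpha, n_reps=n_reps, n_rejections=rejections
    )


def pre_family_error_rate(n_pathways: int, alpha: float) -> float:
    """Expected number of false positives over a family of independent tests.

    Testing 194 pathways at alpha = 0.01 gives a per-family error rate of
    194 * 0.01 = 1.94.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return n_pathways * alpha


def default_grid(
    n_per_group: tuple[int, ...] = (5, 20, 30),
    methods: tuple[str, ...] = METHODS,
    gsea_background: int = DEFAULT_GSEA_BACKGROUND,
) -> list[tuple[str, Scenario]]:
    """The full scenario x sample-size x method grid of the power table."""
    grid: list[tuple[str, Scenario]] = []
    for kind in SCENARIO_KINDS:
        for n in n_per_group:
            for method in methods:
                bg = gsea_background if method == "gsea" else 0
                grid.append((method, Scenario(kind=kind, n_per_group=n,
                                              background_genes=bg)))
    return grid


def power_table(
    config: list[tuple[str, Scenario]] | None = None,
    alpha: float = 0.1,
    n_reps: int = 1000,
    n_perms: int = 1000,
    seed: int = 0,
    gsea_background: int = DEFAULT_GSEA_BACKGROUND,
) -> pd.DataFrame:
    """Estimate power for every (method, scenario) cell of ``config``.

    ``config`` defaults to the full grid of four scenarios, three sample
    sizes and three methods.  A GSEA cell whose scenario has no background
    genes is silently given ``gsea_background`` of them (and logged), since
    GSEA is undefined without a complement.  Returns a tidy DataFrame with
    one row per cell: scenario, n_per_group, method, power, mc_se,
    n_rejections, n_reps.
    """
    if config is None:
        config = default_grid(gsea_background=gsea_background)
    if not config:
        raise ValueError("empty configuration: nothing to estimate")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for method, s in config:
        if method == "gsea" and s.background_genes == 0:
            logger.info(
                "adding %d background genes for GSEA under %s", gsea_background, s.kind
            )
            s = dc_replace(s, background_genes=gsea_background)
        est = estimate_power(
            method, s, alpha=alpha, n_reps=n_reps, n_perms=n_perms, seed=seed
        )
        rows.append(
            {
                "scenario": s.kind,
                "n_per_group": s.n_per_group,
                "method": method,
                "power": est.power,
                "mc_se": est.mc_se,
                "n_rejections": est.n_rejections,
                "n_reps": est.n_reps,
            }
        )
    return pd.DataFrame(rows)
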