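# Methods

## Model and procedure

`pathrank` tests, for one gene set at a time, the null hypothesis that the
joint distribution of the set's expression values is the same in two groups
of subjects, against alternatives that move the genes' means, their
correlation structure, or both.

The core statistic is built from within-subject ranks.  Expression values
are first *aligned*: each gene's pooled-sample median is subtracted from
its row.  Alignment is what couples the ranks to mean changes — after it,
an unaffected gene's values straddle zero in both groups, while a shifted
gene sits systematically above (or below) zero in the treated group and
therefore migrates toward one end of every treated subject's ranking.
Within each subject the M aligned values are ranked ascending (1 =
smallest, midranks for ties), reducing the subject to a rank vector that
encodes how that subject orders the pathway's genes.  The test statistic
is the squared Euclidean distance between the two group-average rank
vectors,

    S = (W̄₁ − W̄₂)′(W̄₁ − W̄₂).

Correlation changes are detected because common latent variation within a
group makes its subjects' rank vectors mutually consistent: the group
average W̄ then concentrates near a particular ordering rather than near
the flat profile (M+1)/2, and the two group averages separate.

Inference is by permutation.  Subjects are exchangeable under the null, so
the null distribution of S is its value over relabellings — choices of n₁
of the n subjects as group 1.  The p-value is the fraction of relabellings
with S_π ≥ S_obs, with the observed labelling always counted in numerator
and denominator (so p ∈ [1/N, 1] and p = 0 is impossible).  When
C(n, n₁) ≤ the permutation budget all relabellings are enumerated once and
the p-value is exact; otherwise the budget (default 1000) is filled with
uniformly random relabellings, sampled with replacement over the
relabelling space, plus the observed one.  Because relabelling does not
change within-subject ranks, the rank matrix is computed once per pathway
and each relabelling only re-averages its columns; all relabellings are
evaluated in a single matrix product.

### Form of S and p-value conventions

Only the distance-between-average-rank-vectors construction is pinned
down by the procedure's description; the squared Euclidean distance is
used here without any normalizing constant.  Every positive rescaling of
S (e.g. the constants appearing in distance-based rank statistics of the
Feigin–Alvo type) is a monotone transformation and leaves all permutation
p-values — and hence every power estimate — unchanged; only the raw
statistic values are implementation-defined.  Counting the observed
labelling is the standard conservative convention.  Midranks are used for
ties because they preserve the per-subject rank sum M(M+1)/2 exactly.
Ranking direction (ascending) is a pure convention: reflecting all rank
vectors leaves S unchanged.

## Competitive variant (modified rank test)

The rank test is *self-contained*: genes outside the set play no role.
The competitive question — is this set more perturbed than a random set of
the same size from this array? — is answered by restandardization.  Let
m\*, σ\* be the mean and standard deviation of S over random size-M gene
sets drawn uniformly without replacement from the array, each scored with
the true labels, and let m_s, σ_s be the mean and SD of the permutation
replicates of the tested set.  The adjusted comparison is

    p = #{ (S_π − m_s)/σ_s  ≥  (S_obs − m*)/σ* } / N .

Choices made here:

* m_s, σ_s are taken from the same permutation replicates used for the
  p-value (a single pass); nothing suggests an independent draw is needed.
* Random sets include the tested set's genes by default; exclusion is a
  flag (`exclude_set=True`).
* The count is clamped at ≥ 1 so p ∈ [1/N, 1] holds even when m\* < m_s
  pushes the adjusted observed value above every adjusted replicate.
* When the array has no genes beyond the pathway the competitive null is
  undefined; the implementation warns and falls back to the plain rank
  test, to which the procedure reduces exactly when the two moment pairs
  coincide.
* On a fully i.i.d. array m\* equals the permutation mean only in
  expectation over data realisations: all gene sets share the same few
  subjects, so within one dataset S at the fixed true labelling is shifted
  coherently across random sets.  Tests of this property therefore average
  over independent arrays.

## Comparator statistics

**GSEA (unweighted two-ECDF form).**  Genes are ordered by decreasing
signal-to-noise ratio SNR = (μ̂₁ − μ̂₂)/(σ̂₁ + σ̂₂), sample SDs with
denominator nᵢ − 1.  Walking the ordered list, F_hit is the fraction of
set genes seen and F_miss the fraction of non-set genes seen; the
enrichment score is max over positions of (F_hit − F_miss), floored at 0
(enrichment-only — a high score means the set crowds the top of the
ranking).  A `signed=True` flag switches to the signed maximum deviation.
The later weighted running-sum statistic is deliberately not implemented.
Conventions: SNR numerator is mean(classes[0]) − mean(classes[1]), where
`classes[0]` of the `ExpressionMatrix` is the condition of interest (the
first class listed in the class file; "treated" in the simulator).  SNR
ties are broken by gene input order (stable sort).  A zero denominator is
floored per group at max(σ̂, 0.2·|μ̂|), 0.2 absolute when μ̂ = 0, and
logged.

**Global test.**  For binary outcome Y and the pathway's column-centred
n × N_G submatrix X_G, Q = Z′X_G X_G′Z / (μ₂·N_G) with Z = Y − Ȳ and
μ₂ = mean(Z²).  Q is invariant to adding constants to gene rows and to
swapping which group is coded 1.  The normalisation by μ₂·N_G makes Q
comparable across set sizes; any positive constant cancels in the
permutation p-value.  Q is calibrated here by the same sample-relabelling
scheme as the other tests, not by its asymptotic scaled-χ² distribution —
this keeps all four methods on one calibration and matches a simulation
protocol in which every p-value comes from 1000 permutations.  At larger
sample sizes a permutation-calibrated Q rejects at the nominal rate under
the null, whereas the asymptotic calibration can be conservative; the two
therefore need not agree away from n = 5.

All permutation p-values use the identical relabelling machinery, and the
observed statistic is read off the same vectorised null computation as
the replicates, so the self-comparison S_obs ≥ S_obs holds bit-for-bit.

## Synthetic-data generator

`simulate_dataset` emulates a single pathway of M = 46 genes (a typical
KEGG pathway size on 22K two-colour arrays) measured in two groups of
equal size n ∈ {5, 20, 30}; five per group is the realistic microarray
regime, the larger sizes probe large-sample behaviour.  Controls are
i.i.d. N(0, I).  The treated group is one of:

* `no_change` — N(0, I);
* `mean_change` — the first 3 genes get mean 2 (a strong, localized
  shift), identity covariance;
* `correlation_change` — N(0, Σ) with unit variances and exchangeable
  (compound-symmetric) covariance, every off-diagonal 0.9;
* `both` — both perturbations.

Each gene row is then centred by its pooled median (the alignment step is
idempotent, so the rank test is unaffected by whether the generator or
the test performs it).  Exchangeable draws with ρ ≥ 0 use the one-factor
representation √ρ·z₀ + √(1−ρ)·ε (exact for this covariance); negative ρ
falls back to a Cholesky factor, and ρ outside (−1/(M−1), 1) is rejected
as non-positive-definite.

Power is the fraction of replicates (default 1000) with p ≤ α = 0.1,
*inclusive*.  Seeding is hierarchical: master seed → (method, replicate)
seed sequences → per-test permutation seeds, so a power table is a pure
function of the master seed and the configuration, and adding a method
leaves every other method's replicate stream untouched.

What the generator does **not** emulate: heavy-tailed or skewed
intensities, gene-specific variances, unequal group sizes, more than two
groups, block- or hub-structured covariance, missing values, and
array-level artefacts (dye bias, batch effects).  Passing power tests
therefore demonstrate behaviour under an idealized multivariate-normal
pathway, not performance guarantees on real arrays.

GSEA cannot run on the bare single-pathway design — with no genes outside
the set its miss-ECDF is undefined — so GSEA runs append a block of
i.i.d. N(0, 1) background genes (default 500).  GSEA's power depends on
this extra, essentially arbitrary choice, so its simulation results are
qualitative (low power under mean change at n = 5, chance-level under
correlation change), while the rank and Global results are quantitative.

## Numerical and interface choices

* Gene identifiers match by exact, case-sensitive string equality; no
  probe-to-symbol mapping.  Rows with any missing value are dropped at
  load time with a warning; duplicate gene ids keep the first row's name
  and suffix later ones.
* Sets overlapping the array in fewer than `min_genes` (default 2) genes
  raise a skip signal that collection-level drivers catch and log.
  `global_q` itself accepts single-gene sets (the quadratic form is
  well-defined there); the default pipeline still filters at 2.
* p-value comparisons use plain `>=` on floats; replicate and observed
  statistics come from the same vectorised expression, so exact ties are
  represented identically.
* Problem sizes in the test suite: power cells are checked at 200
  Monte-Carlo replicates (tolerance ±0.09 against the 1000-replicate
  reference values) and calibration at 500 replicates within 3 binomial
  SEs, which keeps the suite at desk scale; `scripts/acceptance.py` reruns
  the headline cells at the full 1000 × 1000.

## Known limitations

* The raw magnitude of S is implementation-defined (unscaled); compare S
  across pathways of equal M only, or rely on p-values.
* Random (non-exhaustive) permutation p-values have Monte-Carlo error of
  order 1/√N; at N = 1000 the smallest attainable p is 0.001.
* The competitive moments m\*, σ\* are Monte-Carlo estimates (default
  1000 random sets); very small arrays make them noisy.
* Permutation calibration needs enough subjects for a usable relabelling
  space: with 3 + 3 subjects the smallest attainable p-value is
  1/C(6,3) = 0.05.
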