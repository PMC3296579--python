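# Methods

## Model and procedure

`collapsar` tests association between a binary trait and a genetic region
through collapsed burden scores in a logistic framework,
`logit P(Y_i = 1) = β₀ + β₁ S_i`, with `H₀: β₁ = 0`.  Two test routes are
used: the Rao score statistic `Ts = U²/V` with `U = Σᵢ (Yᵢ − Ȳ) Sᵢ` and
`V = Ȳ(1−Ȳ) Σᵢ (Sᵢ − S̄)²` (asymptotically χ²₁), and the likelihood-ratio
test via a full maximum-likelihood fit.  For binary `Y` the score
statistic reduces exactly to `N · Cor(S, Y)²` because `Var(Y) = Ȳ(1−Ȳ)`;
the selective procedures exploit this identity.

### Weighted selective collapsing (wSC / wSCd)

The selection is described in the README.  Decisions that the procedure's
verbal description leaves open, and how this implementation resolves
them:

- **Round-robin growth.** `S₊` and `S₋` grow alternately (`S₊` first)
  from a shared candidate pool; a variant accepted into one component is
  removed from the other's pool.  Growing them strictly sequentially is
  the other defensible reading; round-robin was chosen so neither
  component can starve the other of shared-signal variants, and the
  growth order is deterministic.
- **Strict improvement.** A step is accepted only if it improves the
  component's correlation (in its own direction) by more than `1e-10`.
  This prevents infinite loops on duplicated columns and makes perfectly
  redundant variants inert.
- **Ties.** Candidate gains within `1e-12` of the best are treated as
  exact ties and the lowest variant index wins.  The tolerance matters:
  the permutation engine computes correlations by incremental covariance
  updates while the reference implementation computes them from vectors,
  and the two arithmetic paths can disagree at the last ulp on genuinely
  tied candidates.
- **Degenerate cases.** Correlation with a constant (or empty) score is
  defined as 0, so empty components lose every argmax naturally; rare
  variants with no carriers get `p_k = 0`; if every `p_k` is 0 the weight
  normalisation is undefined and all weights fall back to 1; if all four
  candidates are empty the test returns `p = 1`.
- **Common SNPs are unweighted** (`w = 1`) in Step 1; the adaptive weight
  applies to rare variants only.
- **Permutation.** Labels are shuffled, genotypes never (LD is
  preserved); the adaptive weights, both forward selections and the
  final argmax are recomputed on every shuffle, because they are all part
  of the statistic — freezing any of them would leak selection bias into
  the p-value.  The add-one estimator
  `p = (1 + #{T_b ≥ T_obs})/(B + 1)` is used throughout, so `p ≥ 1/(B+1)`
  and the p-value is valid under exchangeability.

The permutation path runs on a compiled covariance-update kernel
(`collapsar._engine`): all candidate correlations are functions of the
K×K column covariance matrix, the per-shuffle column–phenotype
covariances and carrier case-fractions (two matrix products for all
shuffles at once), so one full selection costs O(K²) per accepted step
instead of O(NK).  The kernel is verified against the plain-vector
implementation in the test suite.

### Comparators

- **Burden tests**: indicator `I(Σ X_ik > 0)`, sum `Σ X_ik` over rare
  variants; weighted sum over all variants with Madsen–Browning-style
  control-frequency weights `w_k = 1/√(q̂_k(1−q̂_k))`,
  `q̂_k = (Σ_controls X_ik + 1)/(2N₀ + 2)`.  The source the weight is
  cited from uses the square-root form; the non-square-root reading of
  the formula is available via `sqrt_form=False`.  Because `q̂` is
  data-driven, the weighted-sum test is calibrated by permutation.
- **CMC-style multivariate tests**: logistic LRT of the common SNPs plus
  a collapsed rare score, df = retained predictors; collinear columns
  are dropped by sequential Gram–Schmidt against the retained set at
  relative tolerance `1e-8`.
- **SSU / SSUw**: `U'U` and `U'Diag(V)⁻¹U` with
  `V = Ȳ(1−Ȳ) Σᵢ(Xᵢ−X̄)(Xᵢ−X̄)'`; null distributions are eigenvalue
  mixtures `Σ λⱼ χ²₁`, evaluated by Satterthwaite two-moment matching
  (`a·χ²_d`, `a = Σλ²/Σλ`, `d = (Σλ)²/Σλ²`) by default or Imhof's
  inversion integral behind `pvalue_method="imhof"`.  Satterthwaite is
  the default because it is what large simulation loops can afford and
  its mid-tail accuracy is adequate at these dimensions.
- **Adaptive sum tests** take the minimum base-test p-value over growing
  variant prefixes (optionally after ordering variants by the
  single-marker statistic `U_k²/V_kk`, descending); the minimum is
  calibrated by permutation with ordering and prefixes recomputed per
  shuffle.
- **ORWSS** weights each variant by its amended log odds ratio from a
  per-variant 2×2 **allele-count** table (+0.5 per cell; genotype-count
  tables are the other possible reading) and rank-sums the weighted
  scores over cases, mid-ranks for ties, permutation p.  The optional
  `c·σ` thresholding of weights is off by default, matching how the test
  behaves in small panels.
- **Kernel-machine test**: `Q = (Y−Ȳ)'K(Y−Ȳ)/2` with the linear kernel
  `K = GG'`, for which `Q = SSU/2` holds exactly (asserted to `1e-10` in
  the tests); other kernels are out of scope.

## Simulator

One replicate emulates a candidate-gene region of 33 latent variants:
five common SNPs (MAF ~ U(0.1, 0.3)) of which the middle one is causal
but **unobserved**, and two independent rare blocks — 20 non-causal and 8
causal variants (MAF ~ U(0.001, 0.005)).  Haplotype alleles are
thresholded latent normals (Gaussian copula): common SNPs share latent
correlation 0.4, with correlation `a·0.4` to the hidden SNP where the
sign `a = ±1` is drawn once per replicate (a per-SNP sign can make the
latent correlation matrix non-positive-definite, so a shared sign is the
only consistent reading); each rare block has AR-style correlation
`0.4^|i−j|`.  Genotypes are sums of two independent haplotypes.  Disease
status follows `logit P(case) = β₀ + Σ_k log(OR_k) X_ik` over the causal
variants, and exactly `n_case` cases and `n_control` controls are accrued
by rejection sampling from the population model (retrospective sampling
made exact).  The hidden SNP's column is then dropped and the 32 observed
columns are shuffled so variant order carries no information.

Scenario odds-ratio structures, driven by one knob `OR`:

| scenario | causal rare ORs | hidden common OR |
|---|---|---|
| A | all 1 (null) | 1 |
| B | (OR ×4, OR+1 ×4) | 1 |
| C | as B | 1.5 |
| D | (OR, OR, 1/OR, 1/OR, OR+1, OR+1, 1/(OR+1), 1/(OR+1)) | 1 |
| E | as D | 1.5 |

The mixed-direction odds-ratio vectors are conventionally printed in a
form that is ambiguous between reciprocals and literal values (e.g. "12"
for the protective counterpart of 2); the reciprocal reading `1/OR` is
the default here because the intent is opposite effect directions, and
the literal reading is selectable with `literal_reciprocals=True` rather
than silently discarded.

Two parameters the scenario descriptions do not pin down:

- **Baseline prevalence** `β₀ = logit(0.05)` (5% — a typical complex-trait
  figure), configurable per `ScenarioSpec`.  Case-control power is *not*
  insensitive to this choice: higher prevalence saturates the
  probability-scale contrast and lowers every test's power at fixed OR.
  It is the main reason reproduced power values can sit a few points from
  any particular published table computed with an unstated `β₀`.
- **Rare/common classification of simulated data** uses the generator's
  population MAFs, so the region is always 4 common + 28 rare by
  construction.  Classifying on the sample MAF instead (what `io` does
  for real data, and what an analyst must do) lets strongly case-enriched
  causal variants drift above the 0.01 threshold at high OR and leave the
  rare set, which measurably weakens rare-only burden tests.

What the generator does **not** emulate: genotyping error and missing
calls, population stratification, covariates, realistic site-frequency
spectra (MAFs are uniform in narrow bands), LD between common and rare
variants, and regions larger than a few dozen variants.  Passing
reproduction tests therefore show the statistics behave as designed under
this stylised model, not that the power figures transfer to any real
cohort.

## Study harness and problem sizes

`run_scenario` / `run_table` estimate rejection proportions at α = 0.05
over replicates, reporting binomial Monte-Carlo standard errors
`√(p̂(1−p̂)/n)`.  Per-replicate simulation and permutation seeds derive
from `(base seed, scenario, OR, replicate)`, so cells are individually
reproducible and different tests see identical (paired) replicates.
Package defaults are desk scale: 500 permutations per test; the
reproduction suite uses 500 null replicates, 300 power replicates per
cell, and 1000 replicates for asymptotic-only cells; reproduction checks
use 3-standard-error bands, never exact equality.  A pooled-null mode
(`NullPool`) can substitute a large pooled permutation sample for
per-dataset permutation when scanning many cells; per-dataset permutation
is the default because it is exact for data-driven statistics.

## Known limitations

- The forward selection is greedy: it attains the exhaustive-search
  optimum on the small toys the tests enumerate, but carries no global
  optimality guarantee in general.
- Quantitative traits and covariate adjustment are out of scope (the
  logistic framework extends to both, but nothing here implements them).
- The CLI accepts arbitrary region sizes but the engine is tuned for
  candidate-gene K (tens of variants); genome-wide sliding-window scans
  would need batching across windows.
- Logistic LRT fits fall back to a lightly ridged fit under complete
  separation; the score-test route does not have this issue and is used
  in all large loops.
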