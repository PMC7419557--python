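# Methods

## The generative model behind the synthetic studies

Cross-cohort microbiome data are access-restricted almost everywhere, so
`conetdiff` defines its own study conditions through a logistic-normal–
multinomial generator (`conetdiff.synth`). For each cohort c and sample s:

1. log absolute ("basis") abundances
   y ~ N(μ + β_age·(age − 45) + β_sex·sex, D Σ_c D), where Σ_c is the
   cohort's basis correlation matrix and D = diag of per-feature log-scale
   SDs (drawn once, uniform on [0.5, 1.5], to emulate the heavy-tailed
   spread of real taxa; overridable);
2. structural zeros: feature i is removed from the basis with probability
   π_i before closure (jointly for configured feature pairs, which is what
   the co-occurrence network detects); a sample losing every feature is
   redrawn, up to 100 attempts;
3. composition x = w/Σw with w = exp(y)·keep, and observed counts
   ~ Multinomial(depth, x). Age is uniform on [20, 70) years, sex is
   Bernoulli(1/2).

Σ_c matrices are built by placing requested correlations on an identity
matrix and projecting to the nearest positive-definite correlation
(eigenvalue clipping at 1e−6, rescale to unit diagonal, iterated); the
*post-projection* values are recorded as the truth, so planted edges remain
well-defined even when a request is not jointly satisfiable. Planting a
cohort-specific edge re-projects that cohort's Σ and fails loudly if any
previously planted value would move by more than 0.1.

Because SparCC's estimand is exactly the correlation of log basis
abundances, this model makes "truth" well-defined for every downstream
recovery test. What the generator does **not** emulate: phylogenetic
correlation structure, strain-level variation, longitudinal
autocorrelation, batch effects, or abundance-dependent detection limits
(zeros are structural, not sampling zeros). Passing benchmarks therefore
demonstrate correctness of the machinery under the stated model, not
performance on any particular real cohort.

All randomness flows from numpy's `default_rng` (PCG64); a master seed is
expanded into per-stage child seeds with `SeedSequence`, so studies are
bit-reproducible across platforms for a given numpy major version.

## Estimation choices

**SparCC.** Fractions are Dirichlet-posterior means (c+1)/(depth+p) (or
full Dirichlet draws inside the resampling loop, n_inner = 20 by default,
averaged). The basis-variance system is solved exactly
(`numpy.linalg.solve`); the exclusion heuristic removes the strongest
remaining pair with |ρ| > 0.1 from the row sums, up to 10 rounds, but never
drops a feature below three remaining partners (the system becomes singular
otherwise). Solved variances ≤ 0 are floored at machine epsilon and
flagged; more than p/2 flagged features aborts. ρ is clamped to [−1, 1].

**Permutation FDR.** All significance machinery is one estimator: each
permutation destroys the structure under test (feature shuffles for edges,
cohort-label shuffles for heterogeneity), p = (1 + #{perm ≥ obs})/(B + 1),
and q at an observed statistic is the plug-in ratio
E[permuted discoveries]/observed discoveries, monotonized to be
non-increasing in the statistic. With B permutations the smallest
attainable p is 1/(B+1); B < 20 triggers a warning. Where a single
operational threshold is needed (the heterogeneity gate re-applied inside
permutations for specificity and key-node calibration), it is the largest
threshold at which the estimated FDR curve stays ≤ α — defined on the full
curve, not on the selected set, because the gap between strong planted
edges and the null bulk otherwise makes the "last selected p" degenerate.

**StARS.** Subsample size min(⌊10√n⌋, 0.8n), 50 subsamples, a 20-point
log-spaced λ path from λ_max (smallest penalty giving an empty graph on
standardized CLR data) down to 0.01·λ_max, instability D(λ) = mean over
edges of 2θ̂(1−θ̂) monotonized along increasing density, β = 0.05. The
selected graph is refit on the full data; if no λ qualifies the sparsest
graph is returned with a warning flag.

**Cochran-Q.** Correlations enter on the Fisher-z scale with
se = 1/√(n−3); this is the standard effect/SE pair for correlations and is
empirically well calibrated for the SparCC estimator at the benchmark
dimensions (measured SD of null estimates ≈ 0.97 of nominal at p = 21,
n = 300, depth 50,000). Cohorts with incomputable effects are dropped with
df reduced; fewer than two usable cohorts marks the record untestable.
Classification: heterogeneous iff q_perm < 0.05; stable iff Q-p > 0.05;
indeterminate otherwise (the two thresholds do not partition the space).

**Quartile outlier rule.** Type-7 (linear interpolation) quartiles of the
four cohort effects; bounds Q1 − 2·IQR and Q3 + 2·IQR; strict inequalities
with a 1e−9 tie tolerance so floating-point round-off in the interpolation
cannot flip an exact boundary; an edge is specific only when exactly one
extreme lies outside its bound. Effects are Fisher-z values, and
covariate-adjusted re-tests (`adjust_specificity`) also use
atanh(partial r) so both passes operate on one scale. Quartile convention
and the key-node cutoff rule (97.5th percentile of permutation maxima vs
mean + 1.96·SD) are configurable.

**Co-occurrence.** Pearson χ² without continuity correction (expected
cells < 5 warn rather than abort; n ≥ 20 enforced); odds ratio with +0.5 on
all cells iff any cell is zero; direction by OR vs 1, with the literal
concordant-vs-discordant cell-count rule available as an alternative.
Features present or absent in every sample give degenerate margins and are
skipped, not counted against the FDR denominator.

**Covariate adjustment** operates on CLR-transformed abundances — the
compositionally coherent scale shared with the sparsifier — with the
raw-abundance route available through `partial_corr_xy` directly.
Multi-covariate partials invert the correlation matrix
(−P_ij/√(P_ii·P_jj)), which reduces to the textbook single-covariate
formula (verified to 1e−12).

## Benchmark study conditions

All benchmarks live in `conetdiff.benchmarks`; the acceptance script and
the acceptance tests call the same functions, so reported numbers are
always recomputed. Problem sizes were chosen as the smallest studies at
which the statistical claims are meaningful: single-cohort recovery and
null calibration use p = 30 features, n = 400 samples, depth 50,000,
100 permutations; heterogeneity uniformity/power use 4 cohorts × 300
samples on p = 21 (210 edges), with power measured on ten edges shifted by
Δz = 0.4 in one cohort; the specificity/key-node study plants ten
scattered one-cohort edges at ρ = 0.6 plus a 15-edge hub (50 permutations).

Two geometric constraints shaped the hub design. A star of 15 edges at
ρ = 0.6 on otherwise uncorrelated partners is far outside the
positive-definite cone (the equal-strength limit is 1/√15 ≈ 0.26), so hub
partners share within-quartet correlations of 0.4 **in every cohort** —
homogeneous, hence never heterogeneous or specific — while the hub spokes
at 0.6 are planted per cohort (3–4 each). Scattered specific edges are
assigned to different cohorts so that no single cohort contains a
correlated triangle, which would attenuate SparCC's estimates.

The confounder benchmark calibrates an age loading of 0.055/yr on two
features (log-SD 1.3) so the marginal CLR correlation is ≈ 0.25, and uses
p = 100 features so the CLR closure artifact (≈ −2·var/p between two
high-variance features) stays well below the 0.05 partial-correlation
bound being tested; at p = 30 the closure term alone is ≈ −0.05.

## Known limitations

- The 2×IQR rule on four effects is conservative by construction: with an
  outlier at atanh(0.6) ≈ 0.69 and null effects at the n = 300 Fisher-z
  noise floor (σ ≈ 0.058), its per-edge recall is ≈ 0.73 (Monte Carlo of
  the rule itself). Benchmark recovery counts around 7–8 of 10 scattered
  edges are the expected behaviour of the published rule at this sample
  size, not an estimator defect; recall rises quickly with n.
- The key-node cutoff is permutation-calibrated, so its absolute value
  scales with the study: label permutations of an exchangeable synthetic
  study produce almost no false specific calls, pinning the cutoff at 1–2
  for studies with ~20 specific edges (the cutoff-to-observed-calls ratio,
  ~5–10%, is the stable quantity). In such small studies every feature
  touching a specific edge can clear the cutoff; the cutoff becomes
  discriminating only at larger edge counts.
- SparCC's sparsity approximation biases estimates on features embedded in
  dense correlated blocks (hub spokes read ≈ 0.55–0.65 for a planted 0.6),
  and compositional closure leaks small positive correlations into
  unrelated features when a large block co-varies.
- The co-occurrence network is only defined for features with
  presence/absence variation; with deep sequencing and no structural
  zeros, every pair is degenerate and the network is empty by design.
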