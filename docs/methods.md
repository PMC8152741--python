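# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `geoerr`.

## Error model: three-parameter log-normal by order statistics

Assay errors are positive, positively skewed ppm quantities. The package
models a metal's error marginal as a shifted log-normal: ln(y + δ) is
Normal(α + β·s, σ²) where s is the Blom normal score
Φ⁻¹[(r − 3/8)/(n + 1/4)] of the observation's rank (out-of-sample scoring
replaces n by n + 1 in the denominator; ties receive average ranks). α and
β come from ordinary least squares of ln(y + δ) on the scores; the
regression MSE estimates the transformed-scale variance, and the log-normal
moment formulas give back-transformed means and SDs in ppm.

**Offset search.** δ is chosen over (−min(y) + 10⁻⁶, −min(y) + 10³·max(|min(y)|, 1))
by minimizing the scale-invariant lack of fit 1 − R² of the rankit
regression (coarse geometric grid bracketing, then a bounded scalar
minimizer to 10⁻¹⁰). The raw MSE cannot serve as the objective: ln(y + δ)
flattens as δ grows, so its MSE vanishes at the search boundary regardless
of fit quality, whereas 1 − R² is invariant to that rescaling. Negative δ
is allowed as long as min(y) + δ > 0.

**Identifiability.** When the shape parameter is small (β ≲ 0.1 — i.e. the
data are nearly symmetric), the offset is weakly identified: R²(δ) is
almost flat above the true value and δ̂ can drift far upward while the
fitted distribution, back-transformed moments and diagnostics remain
essentially unchanged. Offset recovery should only be expected for clearly
skewed marginals.

**Diagnostics.** K-S and A-D statistics compare ln(y + δ̂) with a Normal
whose moments are estimated from the transformed values; they are
descriptive statistics, not tests (no small-sample correction, no
p-values). The back-transformed pseudo-R² is the squared Pearson
correlation of y with its back-transformed fitted values. The outlier
percentage uses iterated Huber M-estimation of location (tuning constant
1.345, convergence 10⁻⁸) with scale fixed at the normal-consistent MAD;
outliers are |standardized residual| > 3.

## Synthetic survey generator

The generator produces the study conditions every downstream stage
assumes: a rectangular grid tessellation (default 3 × 19 = 57 unit-square
tracts, queen contiguity), uneven per-tract sample counts (truncated
Poisson, mean 58, minimum 5 — about 3,300 samples), and 15 metal error
columns with planted structure. Per factor j, a tract-level surface solves
(I − ρ_j W)s = ε with row-standardized queen weights and is standardized;
per sample, the factor score is √(1−w)·(tract surface) + √w·(sample-level
Normal), with w = 0.5 the within-tract factor share. Metal m's transformed
error is α_m + β_m·(Λ_m·g + √u_m·e) with communality + uniqueness = 1, and
the ppm error is −δ_m + exp(z) (regeneration guard against non-positive
values; never triggered under the default parameterization). Assay values
couple to errors linearly on the log scale (coupling 0.5, log-noise SD
0.3), placing most values above their exceedance thresholds for the toxic
metals, as urban surveys show.

The default per-metal means, SDs, offsets and the 15 × 4 loading matrix
are published descriptive values for an urban 15-metal XRF survey, shipped
as a YAML data file; α and β derive from mean/SD/δ by moment matching.
The four SAR parameters (0.264, 0.435, 0.527, 0.484) plant weak positive
tract-level autocorrelation.

**Why a within-tract factor share?** If all common-factor variation lived
on the tract surface, within-tract variance would equal the uniqueness
(~0.005–0.2), tract-stratified bootstrap would barely perturb anything,
and measurement error would rival sampling error — contradicting how
point-sample surveys behave (point-level factor structure is noisier than
tract-level structure; samples within a tract are far from identical).
Splitting each factor score half-and-half between the spatial surface and
the sample preserves all marginals and cross-metal correlations exactly
while giving tracts realistic internal heterogeneity. The share was fixed
at 0.5 once, on that reasoning.

**What the generator does not emulate:** XRF physics, detection limits,
censoring below detection, geodetic coordinates, irregular tract shapes
(adjacency, not shape, drives every statistic used), or spatially
structured uniqueness noise. Passing tests therefore demonstrate that the
pipeline recovers planted structure under the stated generative model, not
that real surveys satisfy that model.

## Error-source simulation

All sources perturb the n-sample survey and are summarized as tract means
of the perturbed errors (ppm scale — aggregation precedes analysis, as in
survey practice):

* **analytical (log-normal)** — per sample, z ~ Normal(μ̂_i, MSE) on the
  transformed scale, back-transformed; the draw from the fitted error
  model conditioned on the sample's rank.
* **sampling** — within each tract independently, resample that tract's
  samples with replacement (counts preserved; whole rows, so cross-metal
  structure is kept).
* **gamma / beta (specification)** — per sample, a conditional family
  variate with mean equal to the assumption regression's back-transformed
  fitted value and dispersion governed by the family's marginal
  moment-fitted shape: Gamma(a, ŷ_i/a) with a = mean²/var, or
  Beta(p̂_i·ν, (1−p̂_i)·ν)·10⁶ on the ppm-as-proportion scale with
  ν = m(1−m)/v − 1. Believing a heavily dispersed family means simulating
  with its dispersion; that is what makes specification error severe. The
  assumption regressions use the covariates ln[(r−3/8)/(n−r+5/8) + 1/4]
  (gamma) and ln[(r−3/8)/(n−r+5/8)] (beta, the logit of the plotting
  position).
* **uniform (specification)** — per sample, a rank probability drawn
  uniformly from the six-sigma order-statistic interval
  p ± 3·√(r(n−r+1)/[(n+2)(n+1/4)²]), pushed through the fitted p-covariate
  regression; no residual noise. Simulation noise is negligible by
  construction; the corruption is purely systematic.
* **mixture** — a stratified bootstrap of the sample rows followed by
  analytical draws conditioned on the resampled fitted values.

On the default survey the induced tract-mean dispersion orders as
analytical ≈ uniform ≪ sampling ≈ mixture < beta ≈ gamma, and the same
ordering appears in downstream factor-loading perturbation. Which of
gamma/beta is more severe depends on the moment-fitted shapes of the
marginals at hand; the package makes no claim about their relative order.

## Factor dimensions

Tract × metal matrices are analyzed by principal-component extraction of
the correlation matrix: the first k = 4 eigenvectors scaled by the square
roots of their eigenvalues, then varimax rotation. Varimax uses Kaiser row
normalization and the classical pairwise planar rotations with the exact
optimal angle per pair (4φ = atan2(D − 2AB/p, C − (A² − B²)/p)); the
pairwise form escapes the symmetric saddle configurations where
simultaneous gradient-style updates stall, and agrees with standard
implementations to ~10⁻⁵ elsewhere. Columns are ordered by explained
variance with the dominant loading made positive.

Replicated solutions are aligned to a reference before averaging: the
4 × 4 Tucker-congruence matrix is maximized in total absolute value over
column assignments (Hungarian algorithm), with sign flips where congruence
is negative. Summaries report element-wise mean loadings r̄, SDs, and a
prominence flag: the row-maximal |r̄| provided it exceeds the threshold
(default 0.49), with unassigned metals reported as "—". Factor scores for
mapping and spatial propagation use the regression (Thomson) method,
Z R⁺ Λ.

## Spatial statistics

MC and GR use binary queen weights (the classic index definitions); their
standard errors use the standard closed forms under both the normality and
randomization (kurtosis-adjusted) nulls, validated against 10,000-permutation
experiments. Attainable extremes come from the weights spectrum: MC_max
from the largest eigenvalue of the doubly centered symmetrized weights,
GR_min from the smallest non-null Laplacian eigenvalue.

The pure SAR model x = μ + ρW(x − μ) + ε uses row-standardized queen
weights (required for ρ ∈ (1/λ_min, 1)), μ̂ = the sample mean, and profile
maximum likelihood with the eigenvalue form of ln|I − ρW| (the spectrum is
real because row-standardized W from a symmetric relation is similar to a
symmetric matrix). σ̂² is the naive sample variance; σ̂²_adjusted is the
mean squared spatially filtered residual ‖(I − ρ̂W)(x − x̄)‖²/n, which is
≤ σ̂² whenever ρ̂ > 0. Their ratio measures autocorrelation-induced
variance inflation. The inflation at fixed ρ depends strongly on the
contiguity graph: the closed-form expectation tr(MΣ)/(n−1) gives ~8.7% on
a 30×30 queen lattice at ρ = 0.4, rising toward ~20% only on small, sparse
irregular graphs (few dozen units, average degree ≲ 4–5) or larger ρ.
Variance decomposition subtracts named per-source variance losses from the
total, flagging (not failing) a negative residual, since interacting error
sources can overdecompose.

## Classification

Per-tract 95% intervals are value ± 1.96·SE, with either the analytical
SE (tract mean of back-transformed theoretical SDs over √n_t) or the
resampling SE (bootstrap SD of tract means) as the uncertainty input. The
separability of a break between sorted neighbors with intervals [l₁,h₁],
[l₂,h₂] is 1 if the gap d = l₂ − h₁ exceeds the mean half-width (clearly
disjoint), otherwise clip((d + hw)/union, 0, 1) — 0 for identical
intervals, partial for partial overlap, invariant under joint affine
rescaling. This is the package's own concrete criterion in the spirit of
separability-based uncertainty classification; fidelity to any specific
software's internal formula is not claimed. Break placement is exact
dynamic programming on the sorted order (objective additive over class
segments and break positions), maximizing mean separability or
w·GVF + (1−w)·mean separability with w = 0.5; ties break toward equal
class sizes. Quantile breaks (tertiles for k = 3) are the baseline, falling
back to distinct-value quantiles under massive ties.

## Pipeline scale and seeds

The default experiment uses 57 tracts, ~3,300 samples and 200 replications
per error source — sizes at which every stage's summary statistics are
stable while a full run completes in seconds on one CPU; replication counts
are configuration values and can be raised (the tables' SDs shrink as
expected). A single master seed spawns independent substreams per stage
and per error source, so any stage can be rerun in isolation and identical
seeds give byte-identical outputs.

## Known limitations

* The offset δ̂ is unidentifiable for near-symmetric marginals (see above).
* At 57 tracts the per-metal MC of tract-averaged log errors has sampling
  SD ≈ 0.09; metals whose planted surface share is small can realize
  slightly negative MC even though the generating tendency is positive.
* SAR ρ̂ on factor scores of raw-ppm tract averages is attenuated for
  strongly skewed metals (the exponential back-transform adds heavy-tailed
  within-tract noise), so planted ρ is recovered from score surfaces, not
  through the full raw-scale factor pipeline.
* The six-sigma rank interval uses ±3 standard deviations of the
  order-statistic probability; uniform-assumption draws are therefore
  small but not vanishing.
* No CAR or spatial-error alternatives, no kriging, no oblique rotations,
  no censored-data handling.
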