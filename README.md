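# geoerr

Error geography for trace-metal soil surveys: how analytical (assay)
measurement error, sampling error, and specification error propagate
through the spatial analysis of soil contamination data.

## The problem

XRF assays of urban soil samples report, for each metal, both a
concentration and an analytical error (a standard deviation, in ppm =
mg/kg). When thousands of point samples are aggregated to administrative
tracts and analyzed — correlation structure among the 15 metal errors,
spatial autocorrelation of tract surfaces, choropleth classification —
three error sources distort the results in different ways and to different
degrees:

* **measurement error** — the assay's own uncertainty;
* **sampling error** — which soil samples happened to be collected,
  quantified by tract-stratified bootstrap resampling;
* **specification error** — assuming the wrong error distribution family
  (gamma, beta, or uniform instead of log-normal).

`geoerr` implements the full pipeline as a library, with a synthetic-survey
generator that plants known structure (log-normal error marginals, a
4-factor loading matrix, SAR-autocorrelated tract surfaces) so every stage
is testable against ground truth.

## The models

**Three-parameter log-normal by rankit regression.** For positive,
positively skewed errors y with ranks r of n,

    ln(y_o + δ) = α + β·Φ⁻¹[(r_o − 3/8)/(n + 1/4)] + ε_o,

with the offset δ chosen by maximizing the regression R², and
back-transformation ŷ = −δ + exp(μ̂ + MSE/2),
sd = √(exp(2μ̂ + MSE)(exp(MSE) − 1)).

**Spatial statistics.** Moran coefficient MC = (n/S₀)·z'Wz/z'z and Geary
ratio GR = ((n−1)/2S₀)·Σw_ij(x_i−x_j)²/z'z with closed-form standard
errors under the normality and randomization nulls, attainable bounds from
the weights spectrum, and the pure SAR model x = μ + ρW(x−μ) + ε fitted by
maximum likelihood. Positive ρ inflates the naive variance of x; the
filtered residual variance σ̂²_adjusted removes the inflation.

**Factor dimensions.** Principal-component extraction of the tract × metal
correlation matrix, Kaiser-normalized varimax rotation (exact pairwise
angles), Tucker-congruence alignment of replicated solutions, and
mean/SD/prominence summaries across simulation replications.

**Uncertainty-aware classification.** Class breaks scored by the
separability of the 95% confidence intervals straddling them
(gap-plus-half-width over pair union, in [0,1]) and placed exactly by
dynamic programming, optionally combined 50/50 with the Jenks
goodness-of-variance fit; quantile/tertile maps as the baseline.

## Worked example

```sh
python examples/03_error_sources.py
```

```
mean tract-mean SD across replications (relative to the analytical source):
  analytical     0.0241   (   1.0x)
  uniform        0.0431   (   1.8x)
  sampling       0.7974   (  33.1x)
  mixture        0.7937   (  33.0x)
  beta           1.0706   (  44.5x)
  gamma          1.1589   (  48.2x)
```

Bootstrap resampling perturbs tract mean errors ~33× more than analytical
measurement draws, and the misspecified gamma/beta families perturb them
more still — the severity ranking measurement < sampling < specification.
`examples/04_factor_stability.py` carries the same replications through the
factor analysis: the median loading distance from the error-free reference
is 0.007 under measurement error versus 0.102 under sampling error, while
the dimension assignment of all 15 metals (e.g. the geogenic {Mo, Zr}
dimension) survives both. The other examples cover survey generation,
log-normal fitting, spatial indices with SAR variance inflation, and
uncertainty-aware class breaks.

A `geoerr` command-line interface wraps the pipeline
(`geoerr run|fit|simulate|factor|spatial|classify`); `geoerr run --seed 1
--out results/` writes every table the pipeline produces (fit diagnostics,
factor-stability summaries per error source, spatial-index propagation, SAR
variance tables, dimension-assignment comparison, classification breaks) as
CSV plus a GeoJSON tessellation.

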