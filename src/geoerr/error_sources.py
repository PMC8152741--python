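"""Generators for the four error sources propagated through the pipeline.

* analytical measurement error — per-sample draws from the fitted
  three-parameter log-normal: Normal noise with the rankit-regression MSE
  around each sample's fitted value on the transformed scale;
* sampling error — tract-tessellation stratified bootstrap resampling;
* specification error — per-sample draws from the wrong distributional
  family. Gamma and beta draws are conditional family variates whose mean
  is the assumption regression's back-transformed fitted value and whose
  dispersion is governed by the family's marginal moment-fitted shape
  parameter, so assuming a heavily dispersed family injects heavy
  per-sample noise; uniform draws push a rank probability drawn from the
  six-sigma order-statistic interval through the fitted regression line
  (negligible simulation noise, pure systematic distortion);
* mixture — bootstrap resampling followed by analytical draws conditioned
  on the resampled fitted values.

Assay errors are ppm quantities; the beta family treats them as proportions
(ppm / 1e6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .rankit import RankitFit, _regress, _scores_for
from .synthetic import SampleTable

__all__ = [
    "AssumptionFit",
    "DrawConfig",
    "rank_probability",
    "six_sigma_interval",
    "specification_covariate",
    "fit_assumption_regression",
    "draw_errors",
    "draw_transformed",
    "bootstrap_indices",
    "bootstrap_resample",
    "mixture_draw",
    "mixture_transformed",
]

log = logging.getLogger(__name__)

ASSUMPTIONS = ("lognormal", "gamma", "beta", "uniform")


def rank_probability(r, n: int):
    """Blom plotting position p = (r - 3/8) / (n + 1/4) for rank r of n."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 1) or np.any(r > n):
        raise ValueError("rank out of range")
    return (r - 0.375) / (n + 0.25)


def six_sigma_interval(r, n: int):
    """Six-sigma interval for the order-statistic probability of rank r.

    The probability integral transform of the r-th order statistic follows
    a Beta(r, n - r + 1); the plotting position has (approximate) variance
    r(n - r + 1) / [(n + 2)(n + 1/4)^2], and the interval is the plotting
    position +/- 3 standard deviations, clipped into (0, 1).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 1) or np.any(r > n):
        raise ValueError("rank out of range")
    p = rank_probability(r, n)
    var = r * (n - r + 1.0) / ((n + 2.0) * (n + 0.25) ** 2)
    half = 3.0 * np.sqrt(var)
    lo = np.clip(p - half, 1e-9, 1 - 1e-9)
    hi = np.clip(p + half, 1e-9, 1 - 1e-9)
    return lo, hi


def specification_covariate(assumption: str, r, n: int):
    """Rank covariate implied by each distributional assumption.

    lognormal: the Blom normal score Phi^{-1}(p);
    gamma:     ln[(r - 3/8)/(n - r + 5/8) + 1/4];
    beta:      ln[(r - 3/8)/(n - r + 5/8)]  (the logit of p);
    uniform:   p itself.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 1) or np.any(r > n):
        raise ValueError("rank out of range")
    p = rank_probability(r, n)
    if assumption == "lognormal":
        return stats.norm.ppf(p)
    odds = (r - 0.375) / (n - r + 0.625)
    if assumption == "gamma":
        return np.log(odds + 0.25)
    if assumption == "beta":
        return np.log(odds)
    if assumption == "uniform":
        return p
    raise ValueError(f"unknown assumption {assumption!r}")


PPM_SCALE = 1e6  # ppm -> proportion


@dataclass
class AssumptionFit:
    """OLS fit of ln(y + delta) on a distributional-assumption covariate.

    For the gamma and beta assumptions, ``cond_shape`` holds the marginal
    moment-fitted shape parameter (gamma shape, or beta concentration
    a + b) and ``cond_mean_ppm`` the per-sample back-transformed fitted
    means used as conditional draw centers.
    """

    assumption: str
    alpha_hat: float
    beta_hat: float
    mse: float
    pseudo_r2: float
    delta_hat: float
    n: int
    ranks: np.ndarray
    covariate: np.ndarray
    fitted: np.ndarray
    cond_shape: float | None = None
    cond_mean_ppm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.pseudo_r2 <= 1 + 1e-12):
            raise ValueError("pseudo_r2 out of [0, 1]")
        if self.mse < 0:
            raise ValueError("negative MSE")


@dataclass
class DrawConfig:
    n_draws: int = 200
    seed: int = 0
    add_residual_noise: bool = True
    floor_eps: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def fit_assumption_regression(
    y: np.ndarray, assumption: str, delta_hat: float
) -> AssumptionFit:
    """Regress ln(y + delta_hat) on the assumption's rank covariate.

    With ``assumption="lognormal"`` this reproduces the rankit regression at
    the given offset. Ties receive average ranks.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.any(y + delta_hat <= 0):
        raise ValueError("y + delta_hat must be positive")
    ranks, _ = _scores_for(y)
    cov = specification_covariate(assumption, ranks, n)
    if np.ptp(cov) == 0:
        raise ValueError("degenerate covariate")
    t = np.log(y + delta_hat)
    alpha, beta, mse, r2 = _regress(t, cov)
    fitted = alpha + beta * cov
    cond_shape = None
    cond_mean = None
    if assumption in ("gamma", "beta"):
        cond_mean = np.maximum(
            -delta_hat + np.exp(fitted + mse / 2.0), 1e-12
        )
        if assumption == "gamma":
            cond_shape = float(y.mean() ** 2 / y.var())
        else:
            yp = y / PPM_SCALE
            m, v = yp.mean(), yp.var()
            cond_shape = float(m * (1 - m) / v - 1.0)
            if cond_shape <= 0:
                raise ValueError("beta moment fit failed: variance too large")
    return AssumptionFit(
        assumption=assumption,
        alpha_hat=alpha,
        beta_hat=beta,
        mse=mse,
        pseudo_r2=max(0.0, min(1.0, r2)),
        delta_hat=delta_hat,
        n=n,
        ranks=ranks,
        covariate=cov,
        fitted=fitted,
        cond_shape=cond_shape,
        cond_mean_ppm=cond_mean,
    )


def _as_fitted(fit) -> tuple[np.ndarray, float, float, str]:
    """(fitted, mse, delta, assumption) from an AssumptionFit or RankitFit."""
    if isinstance(fit, RankitFit):
        return fit.fitted, fit.mse, fit.delta_hat, "lognormal"
    return fit.fitted, fit.mse, fit.delta_hat, fit.assumption


def draw_transformed(
    fit, cfg: DrawConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Replicated lognormal/uniform draws on the transformed (log) scale.

    lognormal: z ~ Normal(fitted_i, MSE) per sample — draws from the fitted
    log-normal (noise-free if ``add_residual_noise`` is off).
    uniform: each sample's rank probability is redrawn uniformly from its
    six-sigma order-statistic interval and pushed through the fitted
    regression line, with no residual noise.

    Gamma/beta draws live on the ppm scale (see :func:`draw_errors`).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fitted, mse, _, assumption = _as_fitted(fit)
    n = fitted.size
    if assumption == "lognormal":
        z = np.broadcast_to(fitted, (cfg.n_draws, n)).copy()
        if cfg.add_residual_noise and mse > 0:
            z += np.sqrt(mse) * rng.standard_normal((cfg.n_draws, n))
        return z
    if assumption == "uniform":
        lo, hi = six_sigma_interval(fit.ranks, n)
        p = rng.uniform(lo, hi, size=(cfg.n_draws, n))
        return fit.alpha_hat + fit.beta_hat * p
    raise ValueError(
        f"{assumption} draws are conditional family variates in ppm; "
        "use draw_errors"
    )


def _to_ppm(z: np.ndarray, delta: float, eps: float) -> np.ndarray:
    err = -delta + np.exp(z)
    n_floored = int((err <= eps).sum())
    if n_floored:
        log.warning("floored %d non-positive back-transformed draws", n_floored)
        err = np.maximum(err, eps)
    return err


def draw_errors(
    fit, ranks=None, n: int | None = None, cfg: DrawConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Replicated assay-error draws in ppm, shape (n_draws, n_samples).

    lognormal/uniform back-transform :func:`draw_transformed` draws (any
    non-positive value is floored at ``cfg.floor_eps`` with a logged
    count). gamma/beta draw conditional family variates: per sample,
    Gamma(shape a, scale mean_i/a) or, on the proportion scale,
    Beta(p_i*nu, (1-p_i)*nu), with the shape/concentration taken from the
    family's marginal moment fit — assuming a wrong, heavily dispersed
    family therefore injects correspondingly heavy per-sample noise.
    """
    cfg = cfg or DrawConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    _, _, delta, assumption = _as_fitted(fit)
    if assumption in ("lognormal", "uniform"):
        z = draw_transformed(fit, cfg, rng=rng)
        return _to_ppm(z, delta, cfg.floor_eps)
    mean = fit.cond_mean_ppm
    shape = fit.cond_shape
    size = (cfg.n_draws, mean.size)
    if not cfg.add_residual_noise:
        return np.broadcast_to(mean, size).copy()
    if assumption == "gamma":
        return rng.gamma(shape, mean / shape, size=size)
    p = np.clip(mean / PPM_SCALE, 1e-12, 1 - 1e-12)
    draws = rng.beta(p * shape, (1.0 - p) * shape, size=size) * PPM_SCALE
    return np.maximum(draws, cfg.floor_eps)


def bootstrap_indices(
    tract_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Within-tract resampling indices, preserving per-tract counts."""
    tract_ids = np.asarray(tract_ids)
    out = np.empty(tract_ids.size, dtype=np.intp)
    for t in np.unique(tract_ids):
        pos = np.flatnonzero(tract_ids == t)
        if pos.size == 0:
            raise ValueError(f"empty tract {t}")
        out[pos] = rng.choice(pos, size=pos.size, replace=True)
    return out


def bootstrap_resample(
    samples: SampleTable, tess=None, seed: int | np.random.Generator = 0
) -> SampleTable:
    """Tract-tessellation stratified bootstrap of a sample table.

    Within each tract independently, samples are redrawn with replacement;
    per-tract counts are preserved. If a tessellation is given, every tract
    must contain at least one sample.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if tess is not None:
        present = set(np.unique(samples.tract_ids).tolist())
        empty = [t for t in tess.tract_ids if t not in present]
        if empty:
            raise ValueError(f"tracts without samples: {empty}")
    idx = bootstrap_indices(samples.tract_ids, rng)
    df = samples.df.iloc[idx].reset_index(drop=True)
    return SampleTable(df)


def mixture_transformed(
    samples: SampleTable,
    fits: Mapping[str, object],
    cfg: DrawConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Two-step mixture draws on the transformed scale, per metal.

    Step 1 draws a stratified bootstrap of the sample rows (shared across
    metals, preserving cross-metal structure); step 2 adds analytical
    log-normal residual noise around each resampled sample's fitted value.
    Returns {metal: (n_draws, n_samples) array}.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    metals = list(fits)
    fitted = {m: _as_fitted(fits[m])[0] for m in metals}
    mses = {m: _as_fitted(fits[m])[1] for m in metals}
    n = samples.n
    out = {m: np.empty((cfg.n_draws, n)) for m in metals}
    for d in range(cfg.n_draws):
        idx = bootstrap_indices(samples.tract_ids, rng)
        for m in metals:
            z = fitted[m][idx]
            if cfg.add_residual_noise and mses[m] > 0:
                z = z + np.sqrt(mses[m]) * rng.standard_normal(n)
            out[m][d] = z
    return out


def mixture_draw(
    samples: SampleTable,
    tess,
    fits: Mapping[str, object],
    cfg: DrawConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Two-step mixture draws in ppm, per metal (see mixture_transformed)."""
    if tess is not None:
        present = set(np.unique(samples.tract_ids).tolist())
        empty = [t for t in tess.tract_ids if t not in present]
        if empty:
            raise ValueError(f"tracts without samples: {empty}")
    z = mixture_transformed(samples, fits, cfg, rng=rng)
    return {
        m: _to_ppm(z[m], _as_fitted(fits[m])[2], cfg.floor_eps) for m in z
    }
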