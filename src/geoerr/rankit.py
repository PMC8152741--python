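"""Three-parameter log-normal fitting via order-statistics (rankit) regression.

The model for a positive, positively skewed variable y (an assay-error
standard deviation in ppm) is

    ln(y_o + delta) = alpha + beta * Phi^{-1}[(r_o - 3/8) / (n + 1/4)] + eps_o

where r_o is the rank of y_o and Phi the standard normal CDF. The Blom
plotting position (r - 3/8)/(n + 1/4) gives nearly unbiased normal scores;
scoring a value from outside the sample uses n + 1 in the denominator.
delta is chosen by a one-dimensional search minimizing the regression mean
squared error, and back-transformation to the ppm scale uses the log-normal
moment formulas with MSE as the transformed-scale variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RankitFit",
    "GofReport",
    "blom_scores",
    "fit_three_param_lognormal",
    "backtransform",
    "goodness_of_fit",
    "huber_outliers",
    "fit_table",
]


def blom_scores(n: int, out_of_sample: bool = False) -> np.ndarray:
    """Blom normal scores for ranks 1..n.

    In-sample scores use Phi^{-1}[(r - 3/8)/(n + 1/4)]; out-of-sample
    scoring replaces n by n + 1 in the denominator. Scores are strictly
    increasing and antisymmetric about the median rank.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = np.arange(1, n + 1, dtype=float)
    denom = (n + 1 + 0.25) if out_of_sample else (n + 0.25)
    return stats.norm.ppf((r - 0.375) / denom)


def _scores_for(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation Blom scores using average ranks for ties."""
    n = y.size
    ranks = stats.rankdata(y, method="average")
    scores = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return ranks, scores


@dataclass
class RankitFit:
    delta_hat: float
    alpha_hat: float
    beta_hat: float
    mse: float
    n: int
    ranks: np.ndarray
    scores: np.ndarray
    fitted: np.ndarray  # mu_hat_o on the transformed scale
    residuals: np.ndarray
    r2: float


def _regress(t: np.ndarray, scores: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of transformed values on scores; returns (alpha, beta, mse, r2)."""
    n = t.size
    sx = scores - scores.mean()
    beta = float((sx @ (t - t.mean())) / (sx @ sx))
    alpha = float(t.mean() - beta * scores.mean())
    resid = t - (alpha + beta * scores)
    sse = float(resid @ resid)
    sst = float(((t - t.mean()) ** 2).sum())
    mse = sse / (n - 2)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return alpha, beta, mse, r2


def fit_three_param_lognormal(
    y: np.ndarray, delta: float | None = None
) -> RankitFit:
    """Fit the three-parameter log-normal by rankit regression.

    The offset ``delta`` is found by a grid-bracketed bounded search over
    (-min(y) + 1e-6, -min(y) + max(|min(y)|, 1) * 1e3) minimizing the
    scale-invariant lack of fit 1 - R^2 of the rankit regression (the raw
    MSE is degenerate in delta: ln(y + delta) flattens as delta grows, so
    its MSE vanishes at the boundary regardless of fit quality). Negative
    offsets are allowed as long as min(y) + delta stays positive. Pass
    ``delta`` explicitly to skip the search.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if np.ptp(y) == 0:
        raise ValueError("degenerate sample: all values equal")

    ranks, scores = _scores_for(y)

    def lack_of_fit(d: float) -> float:
        return 1.0 - _regress(np.log(y + d), scores)[3]

    if delta is None:
        ymin = y.min()
        lo = -ymin + 1e-6
        hi = lo + max(abs(ymin), 1.0) * 1e3
        # Coarse bracketing grid, dense near the lower boundary where the
        # transformed skewness changes fastest.
        grid = lo + np.geomspace(1e-6, hi - lo, 80)
        vals = np.array([lack_of_fit(d) for d in grid])
        i = int(np.argmin(vals))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lack_of_fit, bounds=(blo, bhi), method="bounded",
            options={"xatol": 1e-10},
        )
        delta = float(res.x)

    if y.min() + delta <= 0:
        raise ValueError("min(y) + delta must be positive")
    t = np.log(y + delta)
    alpha, beta, mse, r2 = _regress(t, scores)
    if beta <= 0:
        raise RuntimeError("non-positive rankit slope")
    fitted = alpha + beta * scores
    return RankitFit(
        delta_hat=float(delta),
        alpha_hat=alpha,
        beta_hat=beta,
        mse=mse,
        n=n,
        ranks=ranks,
        scores=scores,
        fitted=fitted,
        residuals=t - fitted,
        r2=r2,
    )


def backtransform(fit: RankitFit, mu) -> tuple[np.ndarray, np.ndarray]:
    """Back-transform a transformed-scale value to ppm mean and SD.

    y_hat = -delta + exp(mu + MSE/2);
    sd_hat = sqrt(exp(2*mu + MSE) * (exp(MSE) - 1)).
    """
    mu = np.asarray(mu, dtype=float)
    y_hat = -fit.delta_hat + np.exp(mu + fit.mse / 2.0)
    sd_hat = np.sqrt(np.exp(2.0 * mu + fit.mse) * np.expm1(fit.mse))
    return y_hat, sd_hat


def huber_outliers(x: np.ndarray, c: float = 1.345, cutoff: float = 3.0) -> float:
    """Percentage of observations flagged as outliers by Huber M-estimation.

    Location by iterated Huber weighting (tuning constant 1.345), scale
    fixed at the normal-consistent median absolute deviation; iteration to
    1e-8. An observation is an outlier when its |standardized residual|
    exceeds 3.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    scale = stats.median_abs_deviation(x, scale="normal")
    if scale == 0:
        raise ValueError("zero scale: values too concentrated")
    mu = float(np.median(x))
    for _ in range(500):
        u = np.abs(x - mu) / scale
        wts = np.minimum(1.0, c / np.maximum(u, 1e-300))
        mu_new = float((wts * x).sum() / wts.sum())
        if abs(mu_new - mu) < 1e-8:
            mu = mu_new
            break
        mu = mu_new
    frac = float(np.mean(np.abs(x - mu) / scale > cutoff))
    return 100.0 * frac


@dataclass
class GofReport:
    ks_stat: float
    ad_stat: float
    pseudo_r2_transformed: float
    pseudo_r2_backtransformed: float
    outlier_fraction: float  # percent


def _anderson_darling(t: np.ndarray, mean: float, sd: float) -> float:
    """A-D statistic of t against Normal(mean, sd), no small-sample
    correction (used as a descriptive statistic, not a test)."""
    n = t.size
    u = stats.norm.cdf(np.sort(t), loc=mean, scale=sd)
    u = np.clip(u, 1e-15, 1 - 1e-15)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))))


def goodness_of_fit(fit: RankitFit, y: np.ndarray) -> GofReport:
    """Descriptive fit diagnostics for a rankit log-normal fit.

    K-S and A-D compare ln(y + delta_hat) with a Normal whose moments are
    estimated from the transformed values themselves; the transformed
    pseudo-R^2 is the rankit regression R^2, and the back-transformed one
    the squared Pearson correlation of y with its back-transformed fitted
    values.
    """
    y = np.asarray(y, dtype=float)
    if y.size != fit.n:
        raise ValueError("y length does not match the fit")
    t = np.log(y + fit.delta_hat)
    m, s = t.mean(), t.std(ddof=1)
    ks = float(stats.kstest(t, "norm", args=(m, s)).statistic)
    ad = _anderson_darling(t, m, s)
    y_hat, _ = backtransform(fit, fit.fitted)
    if np.ptp(y_hat) == 0:
        r2_bt = 1.0
    else:
        r2_bt = float(np.corrcoef(y, y_hat)[0, 1] ** 2)
    return GofReport(
        ks_stat=ks,
        ad_stat=ad,
        pseudo_r2_transformed=fit.r2,
        pseudo_r2_backtransformed=r2_bt,
        outlier_fraction=huber_outliers(t),
    )


def fit_table(samples) -> "pd.DataFrame":
    """Per-metal descriptive statistics and log-normal fit diagnostics.

    One row per metal: mean, sd, min, max (ppm), delta_hat, outlier_pct,
    ks, ad, pseudo_r2_t, pseudo_r2_bt.
    """
    import pandas as pd

    rows = []
    for metal in samples.metals:
        y = samples.errors(metal)
        fit = fit_three_param_lognormal(y)
        gof = goodness_of_fit(fit, y)
        rows.append(
            {
                "metal": metal,
                "mean": y.mean(),
                "sd": y.std(ddof=1),
                "min": y.min(),
                "max": y.max(),
                "delta_hat": fit.delta_hat,
                "alpha_hat": fit.alpha_hat,
                "beta_hat": fit.beta_hat,
                "mse": fit.mse,
                "outlier_pct": gof.outlier_fraction,
                "ks": gof.ks_stat,
                "ad": gof.ad_stat,
                "pseudo_r2_t": gof.pseudo_r2_transformed,
                "pseudo_r2_bt": gof.pseudo_r2_backtransformed,
            }
        )
    return pd.DataFrame(rows).set_index("metal")
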