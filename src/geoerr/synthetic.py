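"""Synthetic point-sample soil surveys with planted statistical structure.

A survey is generated so that each downstream stage of the pipeline sees the
structure the analysis assumes: per-metal assay errors whose marginals are
three-parameter log-normal, a planted 4-factor correlation structure among
the 15 metal log-errors, weak positive tract-level spatial autocorrelation
carried by SAR factor-score surfaces, and assay values positively coupled
to error sizes on the log scale.

The generative model, per metal m and sample o in tract t:

    tract_j = standardized solve of (I - rho_j * W) s = eps_j   (per factor)
    g_oj    = sqrt(1 - w) * tract_j(t) + sqrt(w) * own_oj       (own iid N(0,1))
    f_mo    = Lambda_m . g_o + sqrt(u_m) * e_o                  (e iid N(0,1))
    z_mo    = alpha_m + beta_m * f_mo
    error   = -delta_m + exp(z_mo)            (> 0)
    ln(value) = nu_m + c * (z_mo - alpha_m) + tau * e'_o

with communality + uniqueness u_m = 1 for every metal, so f has unit
variance and z has variance beta_m^2. The within-tract factor share w
splits factor variation between the spatially autocorrelated tract surface
and sample-level heterogeneity: soil samples within one tract are far from
identical, and tract averaging then sharpens the factor structure relative
to the point level (higher tract-level communalities), as aggregated assay
data exhibit.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .spatial import SpatialWeights
from .tessellation import Tessellation

__all__ = [
    "LandscapeConfig",
    "SampleTable",
    "default_config",
    "generate_survey",
    "exceedance_counts",
]


def _err_col(metal: str) -> str:
    return f"{metal}_err"


def _val_col(metal: str) -> str:
    return f"{metal}_val"


@dataclass
class SampleTable:
    """Point soil samples with per-metal assay errors and values.

    Wraps a DataFrame with columns ``sample_id, x, y, tract_id`` plus a
    ``<metal>_err`` / ``<metal>_val`` pair per metal. Assay errors must be
    strictly positive (only useful, positive analytical error values are
    analyzed).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "x", "y", "tract_id"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if not self.metals:
            raise ValueError("no <metal>_err columns found")
        for m in self.metals:
            bad = np.flatnonzero(~(self.df[_err_col(m)].to_numpy() > 0))
            if bad.size:
                raise ValueError(
                    f"non-positive assay error for {m} at rows {bad[:10].tolist()}"
                )

    @property
    def metals(self) -> list[str]:
        return [c[:-4] for c in self.df.columns if c.endswith("_err")]

    @property
    def n(self) -> int:
        return len(self.df)

    def errors(self, metal: str | None = None):
        if metal is not None:
            if metal not in self.metals:
                raise KeyError(f"unknown metal {metal!r}")
            return self.df[_err_col(metal)].to_numpy(dtype=float)
        return self.df[[_err_col(m) for m in self.metals]].to_numpy(dtype=float)

    def values_of(self, metal: str) -> np.ndarray:
        if metal not in self.metals:
            raise KeyError(f"unknown metal {metal!r}")
        return self.df[_val_col(metal)].to_numpy(dtype=float)

    @property
    def tract_ids(self) -> np.ndarray:
        return self.df["tract_id"].to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class LandscapeConfig:
    """Planted truth for a synthetic survey.

    alpha/beta are intercept and slope on the transformed (log) scale, so
    that ln(error + delta) ~ Normal(alpha, beta^2) marginally; loadings and
    uniqueness define the factor structure of the standardized transformed
    errors; factor_rho the SAR autocorrelation of tract-level factor scores.
    """

    rows: int
    cols: int
    samples_per_tract: int
    metals: list[str]
    loadings: np.ndarray  # (n_metals, k)
    delta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    factor_rho: np.ndarray
    uniqueness: np.ndarray | None = None
    within_tract_factor_share: float = 0.5
    value_coupling: float = 0.5
    value_noise_sd: float = 0.3
    log_value_mean: np.ndarray | None = None
    mpl: Mapping[str, float] = field(default_factory=dict)
    min_samples: int = 5
    on_nonpositive: str = "regenerate"  # or "error"
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.factor_rho = np.asarray(self.factor_rho, dtype=float)
        p, k = self.loadings.shape
        if len(self.metals) != p:
            raise ValueError("loadings rows must match number of metals")
        if self.factor_rho.size != k:
            raise ValueError("factor_rho length must match number of factors")
        if np.any(np.abs(self.factor_rho) >= 1):
            raise ValueError("|factor_rho| must be < 1")
        communality = (self.loadings**2).sum(axis=1)
        if self.uniqueness is None:
            if np.any(communality > 1 + 1e-9):
                raise ValueError("loadings rows with communality > 1")
            self.uniqueness = 1.0 - communality
        else:
            self.uniqueness = np.asarray(self.uniqueness, dtype=float)
            if np.any(np.abs(communality + self.uniqueness - 1.0) > 1e-9):
                raise ValueError("communality + uniqueness must equal 1")
        if np.any(self.beta <= 0):
            raise ValueError("beta must be positive")
        if not 0 <= self.within_tract_factor_share < 1:
            raise ValueError("within_tract_factor_share must be in [0, 1)")
        if self.log_value_mean is None:
            # Assay values an order of magnitude above their error SDs is a
            # realistic default for XRF soil assays.
            self.log_value_mean = np.log(
                10.0 * (-self.delta + np.exp(self.alpha + self.beta**2 / 2.0))
            )
        else:
            self.log_value_mean = np.asarray(self.log_value_mean, dtype=float)

    @property
    def n_tracts(self) -> int:
        return self.rows * self.cols

    @property
    def k_factors(self) -> int:
        return self.loadings.shape[1]


def _lognormal_alpha_beta(mean: float, sd: float, delta: float) -> tuple[float, float]:
    """Moment-match: if error + delta is log-normal with the given mean and
    SD on the ppm scale, return the Normal mean/SD of ln(error + delta)."""
    m = mean + delta
    if m <= 0:
        raise ValueError("mean + delta must be positive")
    s2 = np.log1p((sd / m) ** 2)
    return float(np.log(m) - s2 / 2.0), float(np.sqrt(s2))


def default_config(seed: int = 0, **overrides) -> LandscapeConfig:
    """Default 15-metal parameterization from the packaged landscape file."""
    ref = importlib.resources.files("geoerr").joinpath("data/default_landscape.yaml")
    doc = yaml.safe_load(ref.read_text())
    metals = list(doc["metals"])
    delta = np.array([doc["metals"][m]["delta"] for m in metals])
    alpha = np.empty(len(metals))
    beta = np.empty(len(metals))
    for i, m in enumerate(metals):
        alpha[i], beta[i] = _lognormal_alpha_beta(
            doc["metals"][m]["mean"], doc["metals"][m]["sd"], doc["metals"][m]["delta"]
        )
    cfg = dict(
        rows=doc["grid"]["rows"],
        cols=doc["grid"]["cols"],
        samples_per_tract=doc["samples_per_tract"],
        metals=metals,
        loadings=np.array([doc["metals"][m]["loadings"] for m in metals]),
        delta=delta,
        alpha=alpha,
        beta=beta,
        factor_rho=np.array(doc["factor_rho"]),
        value_coupling=doc["value_coupling"],
        value_noise_sd=doc["value_noise_sd"],
        mpl={m: doc["metals"][m]["mpl"] for m in metals},
        seed=seed,
    )
    cfg.update(overrides)
    return LandscapeConfig(**cfg)


def _sar_scores(
    tess: Tessellation, rho: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Tract-level factor scores from zero-mean SAR processes, standardized
    to unit variance so planted loadings are correlations."""
    w = SpatialWeights.from_tessellation(tess, style="row")
    W = w.matrix
    n = w.n
    scores = np.empty((n, rho.size))
    eye = np.eye(n)
    for j, r in enumerate(rho):
        eps = rng.standard_normal(n)
        A = eye - r * W
        s = np.linalg.solve(A, eps)
        sd = s.std(ddof=1)
        if sd == 0:
            raise RuntimeError("degenerate SAR scores")
        scores[:, j] = (s - s.mean()) / sd
    return scores


def _sample_points(
    tess: Tessellation, tract: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points within a tract polygon by bounding-box rejection."""
    poly = tess.polygons[tract]
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((size, 2))
    filled = 0
    from shapely.geometry import Point

    while filled < size:
        draw = size - filled
        xs = rng.uniform(minx, maxx, draw)
        ys = rng.uniform(miny, maxy, draw)
        for x, y in zip(xs, ys):
            if poly.contains(Point(x, y)) or poly.touches(Point(x, y)):
                out[filled] = (x, y)
                filled += 1
                if filled == size:
                    break
    return out


def generate_survey(tess: Tessellation, config: LandscapeConfig) -> SampleTable:
    """Generate a point-sample survey over ``tess`` from the planted model.

    Deterministic given ``config.seed``; every stochastic stage (per-tract
    counts, factor scores, uniqueness noise, values, point placement)
    consumes its own derived substream.
    """
    if tess.n_tracts != config.n_tracts:
        raise ValueError(
            f"tessellation has {tess.n_tracts} tracts, config expects {config.n_tracts}"
        )
    ss = np.random.SeedSequence(config.seed)
    rng_counts, rng_scores, rng_noise, rng_vals, rng_place = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    counts = np.maximum(
        config.min_samples,
        rng_counts.poisson(config.samples_per_tract, size=tess.n_tracts),
    )
    scores = _sar_scores(tess, config.factor_rho, rng_scores)

    p = len(config.metals)
    rows_tract = np.repeat(np.arange(tess.n_tracts), counts)
    n_total = rows_tract.size
    w_share = config.within_tract_factor_share
    g = np.sqrt(1.0 - w_share) * scores[rows_tract]
    if w_share > 0:
        g = g + np.sqrt(w_share) * rng_noise.standard_normal(
            (n_total, config.k_factors)
        )
    common = g @ config.loadings.T  # (n_total, p)
    sqrt_u = np.sqrt(config.uniqueness)

    def draw_z() -> np.ndarray:
        e = rng_noise.standard_normal((n_total, p))
        f = common + e * sqrt_u
        return config.alpha + config.beta * f

    z = draw_z()
    errors = -config.delta + np.exp(z)
    attempts = 0
    while np.any(errors <= 0):
        if config.on_nonpositive == "error":
            raise RuntimeError("generated non-positive assay error")
        attempts += 1
        if attempts > 100:
            raise RuntimeError("could not generate positive assay errors")
        bad = np.any(errors <= 0, axis=1)
        e = rng_noise.standard_normal((int(bad.sum()), p))
        z[bad] = config.alpha + config.beta * (common[bad] + e * sqrt_u)
        errors = -config.delta + np.exp(z)

    val_noise = rng_vals.standard_normal((n_total, p))
    ln_val = (
        config.log_value_mean
        + config.value_coupling * (z - config.alpha)
        + config.value_noise_sd * val_noise
    )
    values = np.exp(ln_val)

    xy = np.empty((n_total, 2))
    pos = 0
    for t, c in zip(tess.tract_ids, counts):
        xy[pos : pos + c] = _sample_points(tess, t, int(c), rng_place)
        pos += c

    data = {
        "sample_id": np.arange(n_total),
        "x": xy[:, 0],
        "y": xy[:, 1],
        "tract_id": np.asarray(tess.tract_ids)[rows_tract],
    }
    for i, m in enumerate(config.metals):
        data[_err_col(m)] = errors[:, i]
        data[_val_col(m)] = values[:, i]
    return SampleTable(pd.DataFrame(data))


def exceedance_counts(
    samples: SampleTable, thresholds: Mapping[str, float]
) -> pd.Series:
    """Per-metal count of samples whose assay value strictly exceeds the
    given threshold (e.g. a maximum permissible level in ppm)."""
    counts = {}
    for metal, thr in thresholds.items():
        if thr <= 0:
            raise ValueError(f"threshold for {metal} must be positive")
        counts[metal] = int((samples.values_of(metal) > thr).sum())
    return pd.Series(counts, name="n_exceeding")
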