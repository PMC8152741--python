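"""End-to-end experiment orchestration.

One call generates a synthetic survey, fits the per-metal three-parameter
log-normals, replicates each requested error source, factor-analyzes every
replication, propagates the replicated factor scores to spatial
autocorrelation indices and SAR variance estimates, decomposes tract-level
variance across error sources, and classifies the tract maps under
analytical and resampling uncertainty. All outputs are CSV (plus GeoJSON
for the tessellation) and fully reproducible from the master seed: every
stochastic stage consumes its own spawned substream.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import error_sources as es
from . import factors as fa
from . import spatial as sp
from .classify import optimize_breaks, quantile_breaks, tract_intervals
from .rankit import backtransform, fit_table, fit_three_param_lognormal
from .synthetic import LandscapeConfig, SampleTable, default_config, exceedance_counts, generate_survey
from .tessellation import Tessellation, make_tessellation

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "read_survey",
    "replicate_tract_matrices",
]

log = logging.getLogger(__name__)

SOURCES = ("analytical", "sampling", "gamma", "beta", "uniform", "mixture")


@dataclass
class ExperimentConfig:
    landscape: LandscapeConfig
    sources: Sequence[str] = ("analytical", "sampling", "mixture")
    n_draws: int = 200
    k_factors: int = 4
    k_classes: int = 5
    threshold: float = 0.49
    criterion: str = "separability"
    outdir: str | Path = "geoerr_out"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.sources) - set(SOURCES)
        if unknown:
            raise ValueError(f"unknown error sources: {sorted(unknown)}")
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        seed = int(doc.pop("seed", 0))
        landscape = default_config(seed=seed, **doc.pop("landscape", {}))
        return cls(landscape=landscape, seed=seed, **doc)


@dataclass
class ExperimentReport:
    paths: dict[str, str]
    metadata: dict = field(default_factory=dict)


def read_survey(path: str | Path) -> SampleTable:
    """Read and validate a sample-table CSV (round-trips write output)."""
    df = pd.read_csv(path)
    return SampleTable(df)


def _tract_matrix_transformed(
    samples: SampleTable, tess: Tessellation, deltas: Mapping[str, float]
) -> pd.DataFrame:
    return fa.tract_average(samples, tess, transform_log=True, delta=dict(deltas))


def _averaging_matrix(tract_ids: np.ndarray, order: np.ndarray) -> np.ndarray:
    """(n_tracts x n_samples) matrix averaging samples within tracts,
    tract rows in sorted-id order."""
    uniq = np.asarray(order)
    A = np.zeros((uniq.size, tract_ids.size))
    for i, t in enumerate(uniq):
        pos = np.flatnonzero(tract_ids == t)
        A[i, pos] = 1.0 / pos.size
    return A


def replicate_tract_matrices(
    samples: SampleTable,
    tess: Tessellation,
    source: str,
    fits: Mapping[str, object],
    n_draws: int,
    seed,
) -> list[np.ndarray]:
    """Replicated tract-averaged assay-error matrices for one source.

    Returns ``n_draws`` arrays of shape (n_tracts, n_metals) holding tract
    means of the perturbed errors in ppm. The bootstrap-based sources
    resample whole sample rows (shared across metals, preserving
    cross-metal structure); the distributional sources draw independently
    per metal.
    """
    rng = np.random.default_rng(seed)
    metals = samples.metals
    tract_order = np.sort(np.unique(samples.tract_ids))
    A = _averaging_matrix(samples.tract_ids, tract_order)
    err = samples.errors()
    out: list[np.ndarray] = []
    if source == "sampling":
        for _ in range(n_draws):
            idx = es.bootstrap_indices(samples.tract_ids, rng)
            out.append(A @ err[idx])
        return out
    if source == "mixture":
        cfg = es.DrawConfig(n_draws=n_draws)
        draws = es.mixture_draw(samples, tess, fits, cfg, rng=rng)
        for d in range(n_draws):
            out.append(A @ np.column_stack([draws[m][d] for m in metals]))
        return out

    assumption = {"analytical": "lognormal"}.get(source, source)
    cfg = es.DrawConfig(n_draws=n_draws)
    per_metal = []
    for m in metals:
        fit = fits[m]
        if assumption != "lognormal" or not hasattr(fit, "assumption"):
            fit = es.fit_assumption_regression(
                samples.errors(m), assumption, fits[m].delta_hat
            )
        per_metal.append(es.draw_errors(fit, cfg=cfg, rng=rng) @ A.T)
    for d in range(n_draws):
        out.append(np.column_stack([pm[d] for pm in per_metal]))
    return out


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run every stage of the experiment and write its table analogues."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    timings: dict[str, float] = {}
    ss = np.random.SeedSequence(config.seed)
    sub = {
        name: s
        for name, s in zip(
            ["survey", *SOURCES, "classify"], ss.spawn(len(SOURCES) + 2)
        )
    }

    def _save(name: str, df: pd.DataFrame, index: bool = True) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=index)
        paths[name] = str(p)

    t0 = time.perf_counter()
    land = config.landscape
    land.seed = int(sub["survey"].generate_state(1)[0] % (2**31))
    tess = make_tessellation(land.rows, land.cols)
    survey = generate_survey(tess, land)
    survey.to_csv(outdir / "survey.csv")
    paths["survey"] = str(outdir / "survey.csv")
    tess.to_geojson(outdir / "tessellation.geojson")
    paths["tessellation"] = str(outdir / "tessellation.geojson")
    tess.write_edgelist(outdir / "adjacency.txt")
    paths["adjacency"] = str(outdir / "adjacency.txt")
    timings["survey"] = time.perf_counter() - t0
    log.info("survey: %d samples in %d tracts", survey.n, tess.n_tracts)

    # Per-metal log-normal fits and diagnostics.
    t0 = time.perf_counter()
    table2 = fit_table(survey)
    _save("fit_table", table2)
    fits = {
        m: fit_three_param_lognormal(survey.errors(m)) for m in survey.metals
    }
    if land.mpl:
        _save("exceedance", exceedance_counts(survey, land.mpl).to_frame())
    timings["fits"] = time.perf_counter() - t0

    # Per-metal spatial autocorrelation of tract-averaged log errors.
    t0 = time.perf_counter()
    deltas = {m: fits[m].delta_hat for m in survey.metals}
    w_bin = sp.SpatialWeights.from_tessellation(tess, style="binary")
    log_mat = _tract_matrix_transformed(survey, tess, deltas)
    metal_rows = []
    for m in survey.metals:
        idx = sp.moran_geary(log_mat[m].to_numpy(), w_bin)
        metal_rows.append(
            {"metal": m, "mc": idx.mc, "gr": idx.gr,
             "mc_max": idx.mc_max, "gr_min": idx.gr_min}
        )
    _save("spatial_metals", pd.DataFrame(metal_rows), index=False)

    # Reference factor solution on the observed tract-averaged data (ppm).
    tract_mat = fa.tract_average(survey, tess)
    reference = fa.factor_solution(tract_mat, k=config.k_factors)
    ref_df = pd.DataFrame(
        reference.loadings,
        index=reference.metals,
        columns=[f"F{j + 1}" for j in range(config.k_factors)],
    )
    ref_df.loc["% variance"] = reference.pct_variance
    _save("reference_loadings", ref_df)
    w_row = w_bin.as_style("row")
    ref_scores = fa.factor_scores(reference, tract_mat)
    timings["reference"] = time.perf_counter() - t0

    # Error-source replications.
    score_reps: dict[str, list[np.ndarray]] = {}
    summaries: dict[str, fa.ReplicationSummary] = {}
    for source in config.sources:
        t0 = time.perf_counter()
        mats = replicate_tract_matrices(
            survey, tess, source, fits, config.n_draws, sub[source]
        )
        sols, scores = [], []
        for M in mats:
            sol = fa.factor_solution(M, k=config.k_factors)
            aligned = fa.align_factors(reference, sol)
            sols.append(aligned)
            scores.append(fa.factor_scores(aligned, M))
        summary = fa.replication_summary(sols, reference, config.threshold)
        summaries[source] = summary
        score_reps[source] = scores
        df = summary.to_frame()
        df.loc["% variance"] = list(
            np.repeat(summary.mean_pct_variance, 2)
        ) + [""]
        _save(f"factor_summary_{source}", df)
        timings[source] = time.perf_counter() - t0
        log.info("source %s: %d replications in %.1fs", source, len(mats), timings[source])

    # Spatial autocorrelation propagation (per source and factor).
    t0 = time.perf_counter()
    orig_rows = []
    for j in range(config.k_factors):
        idx = sp.moran_geary(ref_scores[:, j], w_bin)
        orig_rows.append(
            {
                "source": "original",
                "factor": j + 1,
                "mc_mean": idx.mc,
                "mc_sd": idx.se_mc_randomization,
                "gr_mean": idx.gr,
                "gr_sd": idx.se_gr_randomization,
            }
        )
    prop = pd.DataFrame(orig_rows)
    if score_reps:
        prop = pd.concat(
            [prop, sp.propagate_to_indices(score_reps, w_bin)], ignore_index=True
        )
    _save("spatial_indices", prop, index=False)

    # SAR variance table and decomposition.
    sar_rows = []
    sigma2 = {}
    for name, scores in [("original", [ref_scores])] + [
        (s, score_reps[s]) for s in config.sources
    ]:
        mean_scores = np.mean(scores, axis=0)
        for j in range(config.k_factors):
            fit = sp.sar_fit(mean_scores[:, j], w_row)
            sar_rows.append(
                {
                    "dataset": name,
                    "factor": j + 1,
                    "sigma2": fit.sigma2_hat,
                    "rho_hat": fit.rho_hat,
                    "sigma2_adjusted": fit.sigma2_adjusted,
                    "shapiro_wilk_p": fit.shapiro_wilk_p,
                }
            )
            sigma2[(name, j)] = fit.sigma2_hat
    _save("sar_table", pd.DataFrame(sar_rows), index=False)

    decomp_rows = []
    for j in range(config.k_factors):
        total = sigma2[("original", j)]
        comps = {
            s: max(0.0, total - sigma2[(s, j)])
            for s in config.sources
            if s in ("analytical", "sampling")
        }
        d = sp.variance_decomposition(total, comps)
        decomp_rows.append(
            {
                "factor": j + 1,
                "total": d["total"],
                **d["components"],
                "residual": d["residual"],
                "overdecomposed": d["overdecomposed"],
            }
        )
    _save("variance_decomposition", pd.DataFrame(decomp_rows), index=False)
    timings["spatial"] = time.perf_counter() - t0

    # Dimension-assignment comparison across sources.
    metals = survey.metals
    ref_assign = []
    for i in range(len(metals)):
        j = int(np.argmax(np.abs(reference.loadings[i])))
        ref_assign.append(
            j + 1 if abs(reference.loadings[i, j]) >= config.threshold else None
        )
    comp = pd.DataFrame({"original": ref_assign}, index=metals)
    for source in config.sources:
        comp[source] = summaries[source].assignment
    comp = comp.fillna("—")
    thr_row = {"original": float(np.max(np.abs(reference.loadings), axis=1).min())}
    pct_row = {"original": float(reference.pct_variance.sum())}
    for source in config.sources:
        thr_row[source] = summaries[source].derived_threshold
        pct_row[source] = float(summaries[source].mean_pct_variance.sum())
    comp.loc["threshold_abs_mean_loading"] = pd.Series(thr_row)
    comp.loc["pct_variance_total"] = pd.Series(pct_row)
    _save("comparison", comp)

    # Uncertainty-aware classification of tract mean errors.
    t0 = time.perf_counter()
    rng_cls = np.random.default_rng(sub["classify"])
    tract_order = np.sort(np.unique(survey.tract_ids))
    A = _averaging_matrix(survey.tract_ids, tract_order)
    counts = np.array(
        [(survey.tract_ids == t).sum() for t in tract_order], dtype=float
    )
    n_boot = min(config.n_draws, 200)
    boot_means = {m: [] for m in metals}
    err_mat = survey.errors()
    for _ in range(n_boot):
        idx = es.bootstrap_indices(survey.tract_ids, rng_cls)
        tm = A @ err_mat[idx]
        for i, m in enumerate(metals):
            boot_means[m].append(tm[:, i])
    cls_rows, brk_rows = [], []
    for i, m in enumerate(metals):
        vals = A @ err_mat[:, i]
        _, sd_hat = backtransform(fits[m], fits[m].fitted)
        analytical_se = (A @ sd_hat) / np.sqrt(counts)
        resampling_se = np.std(np.stack(boot_means[m]), axis=0, ddof=1)
        maps = {}
        for kind, se in (("analytical", analytical_se), ("resampling", resampling_se)):
            iv = tract_intervals(vals, se)
            cm = optimize_breaks(vals, iv, config.k_classes, config.criterion)
            maps[kind] = cm
            for b, (cut, s) in enumerate(zip(cm.breaks, cm.separability)):
                brk_rows.append(
                    {"metal": m, "uncertainty": kind, "break": b + 1,
                     "cut_ppm": cut, "separability": s}
                )
        tert = quantile_breaks(vals, 3)
        for t_i, t in enumerate(tract_order):
            cls_rows.append(
                {
                    "metal": m,
                    "tract_id": int(t),
                    "mean_error_ppm": vals[t_i],
                    "analytical_se": analytical_se[t_i],
                    "resampling_se": resampling_se[t_i],
                    "class_analytical": int(maps["analytical"].assignment[t_i]),
                    "class_resampling": int(maps["resampling"].assignment[t_i]),
                    "class_tertile": int(tert.assignment[t_i]),
                }
            )
    _save("classification", pd.DataFrame(cls_rows), index=False)
    _save("class_breaks", pd.DataFrame(brk_rows), index=False)
    timings["classification"] = time.perf_counter() - t0

    metadata = {
        "seed": config.seed,
        "n_draws": config.n_draws,
        "sources": list(config.sources),
        "n_samples": int(survey.n),
        "n_tracts": int(tess.n_tracts),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "report.json").write_text(json.dumps(metadata, indent=2))
    paths["report"] = str(outdir / "report.json")
    return ExperimentReport(paths=paths, metadata=metadata)
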