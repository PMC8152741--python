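import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import geoerr as g
from geoerr import error_sources as es


class TestRankProbability:
    def test_single_rank_is_median(self):
        assert es.rank_probability(1, 1) == pytest.approx(0.5)

    def test_middle_rank_is_half(self):
        assert es.rank_probability(5, 9) == pytest.approx(0.5)

    def test_top_rank_value(self):
        assert es.rank_probability(10, 10) == pytest.approx(9.625 / 10.25)

    @given(st.integers(min_value=2, max_value=1000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_strictly_increasing_in_open_interval(self, n):
        p = es.rank_probability(np.arange(1, n + 1), n)
        assert np.all(np.diff(p) > 0)
        assert p[0] > 0 and p[-1] < 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            es.rank_probability(0, 5)
        with pytest.raises(ValueError):
            es.rank_probability(6, 5)


class TestSixSigmaInterval:
    def test_half_width_from_rank_beta_variance(self):
        lo, hi = es.six_sigma_interval(5, 9)
        half = 3.0 * np.sqrt(25.0 / (11.0 * 9.25**2))
        assert half == pytest.approx(0.4889, abs=1e-4)
        assert lo == pytest.approx(0.5 - half)
        assert hi == pytest.approx(0.5 + half)

    def test_interval_contains_plotting_position(self):
        for n in (10, 100, 1000):
            r = np.arange(1, n + 1)
            lo, hi = es.six_sigma_interval(r, n)
            p = es.rank_probability(r, n)
            assert np.all((lo <= p) & (p <= hi))

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (10, 100, 1000):
            lo, hi = es.six_sigma_interval((n + 1) // 2, n)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_extreme_rank_clipped_into_unit_interval(self):
        lo, hi = es.six_sigma_interval(1, 10**6)
        assert lo >= 1e-9
        assert hi < 1


class TestSpecificationCovariate:
    def test_beta_is_logit_zero_at_median(self):
        assert es.specification_covariate("beta", 5, 9) == pytest.approx(0.0)

    def test_gamma_shifted_logit_at_median(self):
        assert es.specification_covariate("gamma", 5, 9) == pytest.approx(
            np.log(1.25), abs=1e-12
        )

    def test_uniform_equals_rank_probability(self):
        assert es.specification_covariate("uniform", 10, 10) == pytest.approx(
            es.rank_probability(10, 10)
        )

    def test_lognormal_equals_blom_score(self):
        np.testing.assert_allclose(
            es.specification_covariate("lognormal", np.arange(1, 11), 10),
            g.blom_scores(10),
        )

    def test_unknown_assumption_rejected(self):
        with pytest.raises(ValueError):
            es.specification_covariate("cauchy", 1, 10)


class TestAssumptionRegression:
    def test_lognormal_reproduces_rankit_fit(self, survey, fits):
        y = survey.errors("As")
        f = fits["As"]
        af = es.fit_assumption_regression(y, "lognormal", f.delta_hat)
        assert af.alpha_hat == pytest.approx(f.alpha_hat, rel=1e-12)
        assert af.beta_hat == pytest.approx(f.beta_hat, rel=1e-12)
        assert af.mse == pytest.approx(f.mse, rel=1e-12)

    def test_exact_beta_covariate_construction(self):
        n = 300
        cov = es.specification_covariate("beta", np.arange(1, n + 1), n)
        y = np.exp(1.0 + 0.2 * cov)  # delta = 0, exactly linear in logit
        bf = es.fit_assumption_regression(y, "beta", 0.0)
        lf = es.fit_assumption_regression(y, "lognormal", 0.0)
        assert bf.pseudo_r2 == pytest.approx(1.0, abs=1e-12)
        assert lf.pseudo_r2 < 1.0

    def test_lognormal_data_prefers_lognormal_assumption(self):
        """On log-normal data the probit covariate outfits the logit one in
        the vast majority of replicates."""
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = np.exp(1.0 + 0.5 * r.standard_normal(400))
            lf = es.fit_assumption_regression(y, "lognormal", 0.0)
            bf = es.fit_assumption_regression(y, "beta", 0.0)
            wins += lf.pseudo_r2 >= bf.pseudo_r2
        assert wins >= 90


class TestDraws:
    def test_noise_free_lognormal_draws_hit_fitted_values(self, fits):
        f = fits["Hg"]
        cfg = es.DrawConfig(n_draws=3, seed=1, add_residual_noise=False)
        draws = es.draw_errors(f, cfg=cfg)
        expected = -f.delta_hat + np.exp(f.fitted)
        np.testing.assert_allclose(draws, np.broadcast_to(expected, draws.shape))

    def test_lognormal_draw_mean_matches_closed_form(self, fits, rng):
        f = fits["As"]
        cfg = es.DrawConfig(n_draws=20_000, seed=3)
        z = es.draw_transformed(f, cfg, rng=rng)
        sample = -f.delta_hat + np.exp(z[:, 100])
        expected = -f.delta_hat + np.exp(f.fitted[100] + f.mse / 2.0)
        mc_se = sample.std() / np.sqrt(sample.size)
        assert abs(sample.mean() - expected) < 4 * mc_se

    def test_uniform_draw_dispersion_far_below_sampling(self, survey, tess, fits):
        """The six-sigma interval draw perturbs tract means far less than
        bootstrap resampling does."""
        from geoerr.pipeline import replicate_tract_matrices

        uni = replicate_tract_matrices(survey, tess, "uniform", fits, 40, 71)
        boot = replicate_tract_matrices(survey, tess, "sampling", fits, 40, 72)
        sd_uni = np.stack(uni).std(axis=0).mean()
        sd_boot = np.stack(boot).std(axis=0).mean()
        assert sd_uni < sd_boot / 10

    def test_gamma_beta_draws_positive_and_centered(self, survey, fits):
        cfg = es.DrawConfig(n_draws=400, seed=5)
        for assumption in ("gamma", "beta"):
            af = es.fit_assumption_regression(
                survey.errors("Cu"), assumption, fits["Cu"].delta_hat
            )
            draws = es.draw_errors(af, cfg=cfg)
            assert np.all(draws > 0)
            # conditional means track the fitted back-transformed values
            ratio = draws.mean(axis=0) / af.cond_mean_ppm
            assert np.median(np.abs(ratio - 1.0)) < 0.2

    def test_draws_deterministic_given_seed(self, fits):
        cfg = es.DrawConfig(n_draws=5, seed=42)
        a = es.draw_errors(fits["Zn"], cfg=cfg)
        b = es.draw_errors(fits["Zn"], cfg=cfg)
        np.testing.assert_array_equal(a, b)

    def test_no_floored_draws_on_default_survey(self, survey, fits):
        cfg = es.DrawConfig(n_draws=50, seed=6)
        for m in survey.metals:
            draws = es.draw_errors(fits[m], cfg=cfg)
            assert np.all(draws > cfg.floor_eps)


class TestBootstrap:
    def test_single_sample_tract_repeats(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            {
                "sample_id": [0, 1, 2],
                "x": [0.1, 0.2, 0.3],
                "y": [0.1, 0.2, 0.3],
                "tract_id": [0, 1, 1],
                "M_err": [1.0, 2.0, 3.0],
                "M_val": [1.0, 2.0, 3.0],
            }
        )
        sv = g.SampleTable(df)
        out = g.bootstrap_resample(sv, seed=0)
        assert (out.df.loc[out.df.tract_id == 0, "M_err"] == 1.0).all()

    def test_per_tract_counts_preserved(self, survey):
        out = g.bootstrap_resample(survey, seed=1)
        before = survey.df.groupby("tract_id").size()
        after = out.df.groupby("tract_id").size()
        assert before.equals(after)

    def test_bootstrap_tract_mean_unbiased(self, survey):
        """Average of resampled tract means converges on the tract's own
        sample mean."""
        tract = survey.df.tract_id.iloc[0]
        y = survey.df.loc[survey.df.tract_id == tract, "As_err"].to_numpy()
        rng = np.random.default_rng(9)
        means = []
        for _ in range(3000):
            means.append(rng.choice(y, size=y.size, replace=True).mean())
        mc_se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - y.mean()) < 4 * mc_se

    def test_empty_tract_rejected(self, survey):
        tess_big = g.make_tessellation(10, 10)
        with pytest.raises(ValueError):
            g.bootstrap_resample(survey, tess_big, seed=0)


class TestMixture:
    def test_zero_mse_mixture_reduces_to_bootstrap_of_fitted(self, survey, fits):
        import copy

        f = copy.copy(fits["Rb"])
        f.mse = 0.0
        cfg = es.DrawConfig(n_draws=3, seed=2)
        draws = g.mixture_draw(survey, None, {"Rb": f}, cfg)["Rb"]
        fitted_ppm = -f.delta_hat + np.exp(f.fitted)
        for d in range(3):
            assert set(np.round(draws[d], 10)) <= set(np.round(fitted_ppm, 10))

    def test_mixture_variance_exceeds_lognormal_only(self, survey, fits):
        cfg = es.DrawConfig(n_draws=300, seed=7)
        mix = g.mixture_draw(survey, None, {"As": fits["As"]}, cfg)["As"]
        ln = es.draw_errors(fits["As"], cfg=cfg)
        assert np.median(mix.var(axis=0)) > np.median(ln.var(axis=0))

    def test_mixture_deterministic(self, survey, fits):
        cfg = es.DrawConfig(n_draws=4, seed=11)
        a = g.mixture_draw(survey, None, {"Se": fits["Se"]}, cfg)["Se"]
        b = g.mixture_draw(survey, None, {"Se": fits["Se"]}, cfg)["Se"]
        np.testing.assert_array_equal(a, b)


def test_resampling_dispersion_exceeds_analytical(survey, tess, fits):
    """Tract-mean dispersion under bootstrap resampling is substantially
    larger than under analytical log-normal draws."""
    from geoerr.pipeline import replicate_tract_matrices

    boot = replicate_tract_matrices(survey, tess, "sampling", fits, 60, 21)
    ana = replicate_tract_matrices(survey, tess, "analytical", fits, 60, 22)
    sd_boot = np.stack(boot).std(axis=0).mean()
    sd_ana = np.stack(ana).std(axis=0).mean()
    assert sd_boot > 2 * sd_ana
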