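import numpy as np
import pandas as pd
import pytest

import geoerr as g


def rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestTractAverage:
    def test_single_sample_per_tract_is_identity(self):
        df = pd.DataFrame(
            {
                "sample_id": [0, 1],
                "x": [0.0, 0.0],
                "y": [0.0, 0.0],
                "tract_id": [0, 1],
                "M_err": [2.0, 4.0],
                "M_val": [1.0, 1.0],
            }
        )
        out = g.tract_average(g.SampleTable(df))
        assert out.loc[0, "M"] == 2.0 and out.loc[1, "M"] == 4.0

    def test_two_sample_mean(self):
        df = pd.DataFrame(
            {
                "sample_id": [0, 1],
                "x": [0.0, 0.0],
                "y": [0.0, 0.0],
                "tract_id": [0, 0],
                "M_err": [2.0, 4.0],
                "M_val": [1.0, 1.0],
            }
        )
        assert g.tract_average(g.SampleTable(df)).loc[0, "M"] == 3.0

    def test_matches_group_and_mean_oracle(self, survey):
        out = g.tract_average(survey)
        for tract in [0, 17, 56]:
            sub = survey.df[survey.df.tract_id == tract]
            for m in ("As", "Zr"):
                assert out.loc[tract, m] == pytest.approx(
                    sub[f"{m}_err"].mean(), abs=1e-12
                )

    def test_log_transform_with_offsets(self, survey, fits):
        deltas = {m: fits[m].delta_hat for m in survey.metals}
        out = g.tract_average(survey, transform_log=True, delta=deltas)
        sub = survey.df[survey.df.tract_id == 0]
        expected = np.log(sub["As_err"] + deltas["As"]).mean()
        assert out.loc[0, "As"] == pytest.approx(expected, abs=1e-12)

    def test_empty_tract_rejected(self, survey):
        with pytest.raises(ValueError):
            g.tract_average(survey, g.make_tessellation(10, 10))


class TestVarimaxAndSolution:
    def test_block_structure_is_fixed_point(self):
        """Loadings already in perfect simple structure are left alone."""
        L = np.zeros((6, 2))
        L[:3, 0] = [0.9, 0.8, 0.85]
        L[3:, 1] = [0.9, 0.85, 0.8]
        rotated = g.varimax(L)
        assert np.allclose(
            np.sort(np.abs(rotated), axis=None), np.sort(np.abs(L), axis=None),
            atol=1e-6,
        )

    def test_varimax_recovers_planted_axes_after_45_degree_mix(self):
        """Two planted orthogonal blocks mixed by 45 degrees are recovered
        exactly — including the symmetric pattern where gradient-style
        rotation updates stall at a saddle."""
        L = np.zeros((8, 2))
        L[:4, 0] = [0.9, 0.85, 0.8, 0.75]
        L[4:, 1] = [0.9, 0.85, 0.8, 0.75]
        mixed = L @ rotation(np.pi / 4)
        rec = g.varimax(mixed)
        cong = np.abs(rec.T @ L) / (
            np.linalg.norm(rec, axis=0)[:, None] * np.linalg.norm(L, axis=0)
        )
        best = cong.max(axis=1)
        assert np.all(best >= 0.999)

    def test_varimax_matches_r_stats_oracle(self):
        """Agrees with R's stats::varimax (Kaiser-normalized) up to column
        permutation and sign on a fixed random matrix."""
        X = np.array(
            [
                [-0.961933415919883, -0.716358490032977, -0.484455109150991],
                [-0.292525722878467, 0.252652369646215, -0.741072660721595],
                [0.258788216241251, 0.152045706655596, 1.16061577924134],
                [-1.15213188591513, -0.30765642967842, 1.01206712493423],
                [0.195782826286375, -0.953017330908122, -0.0720784740865598],
                [0.0301239446016315, -0.64824281144847, -1.13678229809932],
                [0.0854177316122717, 1.22431362428059, 0.90062472898267],
                [1.11661021271527, 0.19981160798297, 0.851770447092221],
                [-1.21885741557799, -0.578483721859972, 0.72771517415448],
                [1.26736872208989, -0.942300733477539, 0.73650214568861],
                [-0.744781596135141, -0.203728179661995, -0.352129616945692],
                [-1.13121857083574, -1.66647484003016, 0.705515513485513],
            ]
        )
        expected = np.array(
            [
                [-0.737146477593173, -0.662132051447176, -0.831491643197003],
                [0.291834579144943, -0.0362511711701838, -0.782375637342118],
                [-0.376971102045538, 0.579213759189719, 0.979552160014763],
                [-1.51898106508377, 0.370335125587705, 0.0434585470350235],
                [-0.210845711810858, -0.911583002624875, 0.276276617980893],
                [0.37080316080609, -1.06247053308427, -0.668626629868112],
                [0.0794971728289825, 1.4514461528545, 0.452050004760575],
                [0.438119513076808, 0.331461433148557, 1.30783812108414],
                [-1.52543419061176, 0.0220146842143334, -0.149639815733313],
                [0.139701275896554, -0.757701397635351, 1.56299766672324],
                [-0.438389752500958, -0.191884534860273, -0.700852919266178],
                [-1.8981779221725, -0.967987372650462, 0.120278881737678],
            ]
        )
        rec = g.varimax(X)
        from scipy.optimize import linear_sum_assignment

        cong = rec.T @ expected / (
            np.linalg.norm(rec, axis=0)[:, None]
            * np.linalg.norm(expected, axis=0)
        )
        row, col = linear_sum_assignment(-np.abs(cong))
        for i, j in zip(row, col):
            np.testing.assert_allclose(
                rec[:, i] * np.sign(cong[i, j]), expected[:, j], atol=1e-4
            )

    def test_communality_preserved_by_rotation(self, rng):
        L = rng.uniform(-0.7, 0.7, size=(10, 3))
        rotated = g.varimax(L)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-9
        )

    def test_solution_pct_variance_ordered_and_bounded(self, reference):
        pct = reference.pct_variance
        assert np.all(np.diff(pct) <= 0)
        assert np.all(pct > 0)
        assert pct.sum() <= 100 + 1e-9
        assert np.all(np.abs(reference.loadings) <= 1 + 1e-9)

    def test_constant_column_rejected(self, rng):
        X = rng.standard_normal((30, 5))
        X[:, 2] = 1.0
        with pytest.raises(ValueError):
            g.factor_solution(X, k=2)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            g.factor_solution(rng.standard_normal((4, 6)), k=4)


class TestAlign:
    def test_permutation_and_sign_flip_restored(self, reference):
        perm = [2, 0, 3, 1]
        flipped = reference.loadings[:, perm].copy()
        flipped[:, 1] *= -1
        cand = g.FactorSolution(
            loadings=flipped,
            pct_variance=reference.pct_variance[perm],
            communalities=reference.communalities,
            metals=reference.metals,
        )
        aligned = g.align_factors(reference, cand)
        np.testing.assert_allclose(aligned.loadings, reference.loadings, atol=1e-12)
        np.testing.assert_allclose(
            aligned.pct_variance, reference.pct_variance, atol=1e-12
        )

    def test_noisy_candidate_high_congruence(self, reference, rng):
        noisy = np.clip(
            reference.loadings + 0.02 * rng.standard_normal(reference.loadings.shape),
            -1,
            1,
        )
        cand = g.FactorSolution(
            loadings=noisy,
            pct_variance=reference.pct_variance,
            communalities=(noisy**2).sum(axis=1),
            metals=reference.metals,
        )
        aligned = g.align_factors(reference, cand)
        for j in range(4):
            assert (
                g.tucker_congruence(
                    reference.loadings[:, j], aligned.loadings[:, j]
                )
                >= 0.99
            )

    def test_alignment_idempotent(self, reference, rng):
        noisy = np.clip(
            reference.loadings + 0.05 * rng.standard_normal(reference.loadings.shape),
            -1,
            1,
        )
        cand = g.FactorSolution(
            loadings=noisy,
            pct_variance=reference.pct_variance,
            communalities=(noisy**2).sum(axis=1),
        )
        once = g.align_factors(reference, cand)
        twice = g.align_factors(reference, once)
        np.testing.assert_allclose(once.loadings, twice.loadings, atol=1e-12)

    def test_dimension_mismatch_rejected(self, reference):
        small = g.FactorSolution(
            loadings=reference.loadings[:, :3],
            pct_variance=reference.pct_variance[:3],
            communalities=reference.communalities,
        )
        with pytest.raises(ValueError):
            g.align_factors(reference, small)


class TestReplicationSummary:
    def test_identical_solutions_have_zero_sd(self, reference):
        summary = g.replication_summary([reference] * 5, reference)
        assert np.allclose(summary.sd_loadings, 0.0, atol=1e-12)
        np.testing.assert_allclose(summary.mean_loadings, reference.loadings)

    def test_threshold_above_everything_unassigns_all(self, reference):
        summary = g.replication_summary(
            [reference] * 3, reference, threshold=1.01
        )
        assert all(a is None for a in summary.assignment)
        assert not summary.prominent.any()

    def test_each_metal_at_most_one_prominent_factor(self, reference):
        summary = g.replication_summary([reference] * 3, reference)
        assert np.all(summary.prominent.sum(axis=1) <= 1)
        for i, a in enumerate(summary.assignment):
            if a is not None:
                assert abs(summary.mean_loadings[i, a - 1]) >= summary.threshold

    def test_single_solution_rejected(self, reference):
        with pytest.raises(ValueError):
            g.replication_summary([reference], reference)


def test_pct_variance_invariant_under_permutation_and_sign(reference):
    L = reference.loadings
    perm = [3, 1, 0, 2]
    Lp = L[:, perm] * np.array([1, -1, 1, -1])
    pct = (Lp**2).sum(axis=0) / L.shape[0] * 100
    np.testing.assert_allclose(np.sort(pct), np.sort(reference.pct_variance))


def test_measurement_perturbs_less_than_sampling(survey, tess, fits, reference):
    """Analytical measurement replications stay closer to the reference
    loadings than bootstrap resampling replications."""
    from geoerr.pipeline import replicate_tract_matrices

    def med_dist(source, seed):
        mats = replicate_tract_matrices(survey, tess, source, fits, 40, seed)
        return np.median(
            [
                np.linalg.norm(
                    g.align_factors(reference, g.factor_solution(M, 4)).loadings
                    - reference.loadings
                )
                for M in mats
            ]
        )

    assert med_dist("analytical", 31) < med_dist("sampling", 32)


def test_factor_scores_recover_planted_scores(rng):
    """Regression scores of an exact low-noise factor model track the
    generating scores."""
    n, p, k = 300, 12, 3
    S = rng.standard_normal((n, k))
    L = np.zeros((p, k))
    for j in range(k):
        L[j * 4 : (j + 1) * 4, j] = [0.9, 0.85, 0.8, 0.75]
    X = S @ L.T + 0.1 * rng.standard_normal((n, p))
    sol = g.factor_solution(X, k=k)
    scores = g.factor_scores(sol, X)
    assert scores.shape == (n, k)
    cong = np.abs(
        scores.T @ S / (n - 1)
    )  # both are ~standardized, so this is ~|correlation|
    best = cong.max(axis=1)
    assert np.all(best > 0.95)


def test_factor_scores_shape_on_survey(reference, tract_matrix):
    scores = g.factor_scores(reference, tract_matrix)
    assert scores.shape == (57, 4)
    # regression scores are centered and near-unit variance
    assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)
    assert np.all(scores.std(axis=0, ddof=1) < 1.2)
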