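"""Shape-function statistics: correlations, CCA, PLSR, sex comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hipsnap.stats import (
    CohortError,
    compare_sexes,
    composite_correlation_cca,
    discrete_measure_correlations,
    make_cohort_table,
    per_pc_correlations,
    plsr_consensus_shapes,
)

from _oracles import ols_multiple_correlation


def _toy_cohort(n=1000, t=5, seed=0, velocity=None, sex="male"):
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal((n, t)) * np.sqrt(np.arange(t, 0, -1))
    mah = scores / scores.std(axis=0)
    measures = rng.standard_normal((n, 5)) + [125, 10, 44, 29, 25]
    if velocity is None:
        velocity = rng.standard_normal(n)
    return make_cohort_table(sex, scores, mah, measures, velocity, np.ones(n, bool))


class TestPerPCCorrelations:
    def test_constructed_signal_isolated_to_one_mode(self):
        cohort = _toy_cohort(n=1000, seed=1)
        cohort["peak_velocity"] = cohort["m_1"]
        out = per_pc_correlations(cohort)
        assert np.isclose(out.loc[out.predictor == "m_1", "r"].iloc[0], 1.0)
        others = out.loc[out.predictor != "m_1", "r"].abs()
        assert (others < 0.08).all()

    def test_row_count_matches_mode_count(self):
        out = per_pc_correlations(_toy_cohort(t=7))
        assert len(out) == 7

    def test_null_calibration(self):
        """Under independent noise, ~5% of per-mode p-values fall below 0.05."""
        rng = np.random.default_rng(0)
        hits = total = 0
        scores = rng.standard_normal((50, 20))
        for _ in range(100):
            y = rng.standard_normal(50)
            r = (scores - scores.mean(0)).T @ (y - y.mean())
            r /= np.linalg.norm(scores - scores.mean(0), axis=0) * np.linalg.norm(y - y.mean())
            tstat = r * np.sqrt(48 / (1 - r**2))
            p = 2 * sps.t.sf(np.abs(tstat), 48)
            hits += (p < 0.05).sum()
            total += 20
        assert abs(hits / total - 0.05) < 0.02

    def test_degenerate_predictor_flagged(self):
        cohort = _toy_cohort(n=50)
        cohort["m_2"] = 1.0
        out = per_pc_correlations(cohort)
        assert bool(out.loc[out.predictor == "m_2", "degenerate"].iloc[0])

    def test_too_few_cases(self):
        with pytest.raises(CohortError):
            per_pc_correlations(_toy_cohort(n=2))


class TestCompositeCCA:
    def test_exact_linear_combination_gives_r_one(self):
        cohort = _toy_cohort(n=300, seed=2)
        cohort["peak_velocity"] = cohort["m_1"] + 0.5 * cohort["m_2"] - 2 * cohort["m_3"]
        r, p = composite_correlation_cca(cohort, n_permutations=200, seed=0)
        assert r > 1 - 1e-10
        assert p < 0.01

    def test_known_population_r_squared(self):
        """With true R^2 = 0.5 the canonical r converges to sqrt(0.5)."""
        rng = np.random.default_rng(3)
        n, t = 2000, 20
        scores = rng.standard_normal((n, t))
        beta = rng.standard_normal(t)
        signal = scores @ beta
        noise = rng.standard_normal(n) * signal.std()  # equal variance split
        cohort = _toy_cohort(n=n, t=t, seed=3)
        for i in range(t):
            cohort[f"m_{i + 1}"] = scores[:, i]
        cohort["peak_velocity"] = signal + noise
        r, _ = composite_correlation_cca(cohort, n_permutations=100, seed=0)
        assert abs(r - np.sqrt(0.5)) < 0.03

    def test_equals_least_squares_oracle(self):
        """Univariate-response CCA == multiple correlation of OLS."""
        for seed in (4, 5, 6):
            cohort = _toy_cohort(n=120, t=6, seed=seed)
            rng = np.random.default_rng(seed + 100)
            cohort["peak_velocity"] = (
                cohort["m_1"] - 0.7 * cohort["m_4"] + rng.standard_normal(120)
            )
            r, _ = composite_correlation_cca(cohort, n_permutations=50, seed=0)
            X = cohort[[f"m_{i}" for i in range(1, 7)]].to_numpy()
            r_ols = ols_multiple_correlation(X, cohort["peak_velocity"].to_numpy())
            assert abs(r - r_ols) < 1e-8

    def test_permutation_p_uniform_under_null(self):
        """KS test cannot reject uniformity of permutation p-values."""
        rng = np.random.default_rng(7)
        pvals = []
        scores = rng.standard_normal((40, 3))
        cohort = _toy_cohort(n=40, t=3, seed=7)
        for i in range(3):
            cohort[f"m_{i + 1}"] = scores[:, i]
        for rep in range(200):
            cohort["peak_velocity"] = rng.standard_normal(40)
            _, p = composite_correlation_cca(cohort, n_permutations=99, seed=rep)
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_asymptotic_option(self):
        cohort = _toy_cohort(n=200, seed=8)
        cohort["peak_velocity"] = cohort["m_1"] * 2 + np.random.default_rng(8).standard_normal(200)
        r_perm, _ = composite_correlation_cca(cohort, n_permutations=100, seed=0)
        r_asym, p_asym = composite_correlation_cca(cohort, method="asymptotic")
        assert np.isclose(r_perm, r_asym)
        assert 0 <= p_asym <= 1

    def test_needs_more_cases_than_modes(self):
        with pytest.raises(CohortError):
            composite_correlation_cca(_toy_cohort(n=6, t=5))


class TestPLSR:
    @pytest.fixture()
    def simple_model(self):
        from hipsnap.shape_model import ShapeModel

        t, n3 = 4, 30
        rng = np.random.default_rng(9)
        modes = np.linalg.qr(rng.standard_normal((n3, t)))[0].T
        return ShapeModel(
            mean_shape=rng.standard_normal(n3),
            modes=modes,
            eigenvalues=np.array([4.0, 3.0, 2.0, 1.0]),
            n_landmarks=n3 // 3,
        )

    def test_zero_sd_level_gives_cohort_mean_shape(self, simple_model):
        cohort = _toy_cohort(n=100, t=4, seed=10)
        low, high, *_ = plsr_consensus_shapes(simple_model, cohort, sd_level=0.0)
        b_bar = cohort[[f"b_{i}" for i in range(1, 5)]].to_numpy().mean(axis=0)
        expected = simple_model.reconstruct(b_bar)
        np.testing.assert_allclose(low, expected, atol=1e-8)
        np.testing.assert_allclose(high, expected, atol=1e-8)

    def test_consensus_shapes_mirror_about_mean(self, simple_model):
        cohort = _toy_cohort(n=100, t=4, seed=11)
        low, high, low_b, high_b = plsr_consensus_shapes(simple_model, cohort, sd_level=3.0)
        b_bar = cohort[[f"b_{i}" for i in range(1, 5)]].to_numpy().mean(axis=0)
        np.testing.assert_allclose(
            (low + high) / 2.0, simple_model.reconstruct(b_bar), atol=1e-8
        )
        np.testing.assert_allclose(low_b + high_b, 2 * np.mean([low_b, high_b], axis=0), atol=1e-8)

    def test_direction_is_covariance_direction(self, simple_model):
        """One-component PLS direction == cov(scores, standardized velocity)."""
        cohort = _toy_cohort(n=500, t=4, seed=12)
        rng = np.random.default_rng(12)
        y = cohort["b_2"] * 3 + rng.standard_normal(500) * 0.5
        cohort["peak_velocity"] = y
        low, high, low_b, high_b = plsr_consensus_shapes(simple_model, cohort)
        direction = high_b - low_b
        B = cohort[[f"b_{i}" for i in range(1, 5)]].to_numpy()
        y_std = (y - y.mean()) / y.std()
        cov_dir = (B - B.mean(0)).T @ y_std / len(y)
        cos = direction @ cov_dir / (np.linalg.norm(direction) * np.linalg.norm(cov_dir))
        assert cos > 0.999

    def test_implant_and_recover(self, default_config):
        """Velocity built on the anteversion-linked mode: the two consensus
        shapes differ in measured anteversion and in nothing else much."""
        from hipsnap.anatomy import build_anatomy, sample_parameters
        from hipsnap.morphometrics import compute_discrete_measures
        from hipsnap.shape_model import fit_shape_model

        params = sample_parameters("male", 200, seed=13, config=default_config)
        landmarks = [build_anatomy(p, default_config).landmarks for p in params]
        model = fit_shape_model(landmarks, align=False).truncated(6)
        scores = np.stack([model.project(lm).b for lm in landmarks])
        mah = scores / np.sqrt(model.eigenvalues)
        truth = np.stack([p.as_array() for p in params])
        measures = truth

        # implant the velocity on the anteversion axis itself
        rng = np.random.default_rng(13)
        av = truth[:, 1]
        velocity = (av - av.mean()) / av.std() + 0.05 * rng.standard_normal(len(av))
        cohort = make_cohort_table("male", scores, mah, measures, velocity, np.ones(len(av), bool))
        low, high, *_ = plsr_consensus_shapes(model, cohort, sd_level=3.0)

        labels = list(landmarks[0].labels)
        from hipsnap.anatomy import LandmarkSet

        m_low = compute_discrete_measures(LandmarkSet(low, labels)).as_array()
        m_high = compute_discrete_measures(LandmarkSet(high, labels)).as_array()
        diff = m_high - m_low
        sds = np.array([default_config.statistics["male"][f][1] for f in
                        ("neck_shaft_angle", "anteversion", "femoral_offset",
                         "ischiofemoral_distance", "head_radius")])
        assert diff[1] > 2.0  # anteversion separates
        # the implanted axis dominates: every uninvolved measure moves by
        # far fewer population SDs than anteversion does (at +/-3 SD the
        # linear shape model bleeds a little into the length measures)
        shifts = np.abs(diff) / sds
        assert (np.delete(shifts, 1) < 0.5 * shifts[1]).all()

    def test_zero_velocity_variance_rejected(self, simple_model):
        cohort = _toy_cohort(n=50, t=4, seed=14)
        cohort["peak_velocity"] = 1.0
        with pytest.raises(CohortError):
            plsr_consensus_shapes(simple_model, cohort)


class TestDiscreteMeasures:
    def test_constructed_offset_signal(self):
        cohort = _toy_cohort(n=400, seed=15)
        rng = np.random.default_rng(15)
        cohort["peak_velocity"] = -cohort["femoral_offset"] + 0.1 * rng.standard_normal(400)
        out = discrete_measure_correlations(cohort, n_permutations=100, seed=0)
        r_off = out.loc[out.predictor == "femoral_offset", "r"].iloc[0]
        assert r_off < -0.9
        assert set(out.predictor) == {
            "neck_shaft_angle",
            "anteversion",
            "femoral_offset",
            "ischiofemoral_distance",
            "head_radius",
            "femoral_shape_ssm",
        }


class TestCompareSexes:
    def test_identical_samples(self):
        a = _toy_cohort(n=50, seed=16)
        out = compare_sexes(a, a.copy())
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_power_at_half_sd_shift(self):
        """Two normals 0.5 SD apart at n=500/group: p < 0.001 in >= 95 of
        100 seeded replicates."""
        rng = np.random.default_rng(17)
        wins = 0
        for _ in range(100):
            m = rng.standard_normal(500)
            f = rng.standard_normal(500) + 0.5
            t, p = sps.ttest_ind(f, m, equal_var=False)
            wins += p < 1e-3
        assert wins >= 95

    def test_summary_fields(self):
        male = _toy_cohort(n=40, seed=18, velocity=np.full(40, 80.0))
        female = _toy_cohort(n=40, seed=19, velocity=np.full(40, 90.0), sex="female")
        # give them variance so the t-test is defined
        male["peak_velocity"] += np.random.default_rng(18).normal(scale=5, size=40)
        female["peak_velocity"] += np.random.default_rng(19).normal(scale=5, size=40)
        out = compare_sexes(male, female)
        for key in ("mean", "median", "min", "max", "n"):
            assert key in out["male"] and key in out["female"]
        assert out["female"]["mean"] > out["male"]["mean"]
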