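import warnings

import numpy as np
import pytest
from scipy import stats

from fishfolio import dfa
from fishfolio.ingest import Panel


def _panel(values):
    values = np.asarray(values, dtype=float)
    return Panel(
        entity_ids=[f"s{i}" for i in range(values.shape[0])],
        years=np.arange(1980, 1980 + values.shape[1]),
        values=values,
        kind="catch",
    )


class TestZscore:
    def test_textbook_row(self):
        z = dfa.zscore(_panel([[1.0, 2.0, 3.0], [5.0, 6.0, 9.0]]))
        assert np.allclose(z.values[0], [-1.0, 0.0, 1.0])
        assert z.means[0] == pytest.approx(2.0)
        assert z.sds[0] == pytest.approx(1.0)

    def test_idempotent_on_standardized_rows(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((4, 30))
        y = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, ddof=1, keepdims=True)
        z = dfa.zscore(_panel(y))
        assert np.allclose(z.values, y, atol=1e-12)

    def test_random_panel_means_and_sds(self):
        rng = np.random.default_rng(1)
        z = dfa.zscore(_panel(rng.uniform(5, 50, size=(5, 30))))
        assert np.abs(z.values.mean(axis=1)).max() < 1e-12
        assert np.abs(z.values.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_constant_row_fatal_names_entity(self):
        with pytest.raises(ValueError, match="s1"):
            dfa.zscore(_panel([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))


class TestLoglikOracle:
    def test_bivariate_closed_form(self):
        # n=1, T=2, Z=[1], R=0.5: stacked covariance [[1.5, 1.0], [1.0, 2.5]]
        y = np.array([[0.3, -0.2]])
        got = dfa.loglik_oracle(y, [[1.0]], [0.5])
        want = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.5, 1.0], [1.0, 2.5]]
        ).logpdf([0.3, -0.2])
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_loadings_reduce_to_independent_normals(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((3, 4))
        R = np.array([0.5, 1.0, 2.0])
        got = dfa.loglik_oracle(y, np.zeros((3, 1)), R)
        want = stats.norm(0, np.sqrt(R)[:, None]).logpdf(y).sum()
        assert got == pytest.approx(want, abs=1e-10)

    def test_large_r_limit_dominated_by_noise(self):
        y = np.array([[0.1, -0.1]])
        big = 1e8
        got = dfa.loglik_oracle(y, [[1.0]], [big])
        want = stats.norm(0, np.sqrt(big)).logpdf(y).sum()
        assert got == pytest.approx(want, rel=1e-6)


class TestKalmanLoglik:
    def test_matches_oracle_on_small_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n, T, m = rng.integers(1, 5), rng.integers(1, 7), rng.integers(1, 3)
            y = rng.standard_normal((n, T))
            Z = rng.standard_normal((n, m))
            R = rng.uniform(0.2, 2.0, n)
            assert dfa.kalman_loglik(y, Z, R)[0] == pytest.approx(
                dfa.loglik_oracle(y, Z, R), abs=1e-8
            )

    def test_single_step_closed_form(self):
        # T=1, n=1, Z=1, R=r: y_1 ~ N(0, 1 + r)
        r = 0.7
        y = np.array([[0.4]])
        logL, states, covs = dfa.kalman_loglik(y, [[1.0]], [r])
        assert logL == pytest.approx(stats.norm(0, np.sqrt(1 + r)).logpdf(0.4), abs=1e-12)
        # smoothed state: posterior mean of x_1 given y_1
        assert states[0, 0] == pytest.approx(0.4 / (1 + r), abs=1e-12)

    def test_noiseless_identity_recovers_observations(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.standard_normal((2, 8)), axis=1)
        _, states, _ = dfa.kalman_loglik(x, np.eye(2), np.full(2, 1e-12))
        assert np.allclose(states, x, atol=1e-5)

    def test_nonfinite_input_fatal(self):
        y = np.array([[np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            dfa.kalman_loglik(y, [[1.0]], [0.5])


class TestEMFit:
    def test_free_parameter_count(self):
        # n=10, m=2, unequal R: 10*2 - 1 constrained entry + 10 variances = 29
        assert dfa.n_free_params(10, 2, "diagonal_unequal") == 29
        assert dfa.n_free_params(10, 2, "diagonal_equal") == 20
        assert dfa.n_free_params(20, 1, "diagonal_unequal") == 40

    def test_identifiability_zeros_maintained(self):
        rng = np.random.default_rng(5)
        y = np.cumsum(rng.standard_normal((6, 40)), axis=1)
        y = (y - y.mean(1, keepdims=True)) / y.std(1, ddof=1, keepdims=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = dfa.em_fit(y, dfa.DFAModelSpec(m=2, max_iter=50))
        assert fit.Z[0, 1] == 0.0

    def test_monotone_loglik_and_aic_identity(self):
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.standard_normal(30))
        y = np.outer(rng.uniform(0.5, 1.5, 8), x) + 0.3 * rng.standard_normal((8, 30))
        y = (y - y.mean(1, keepdims=True)) / y.std(1, ddof=1, keepdims=True)
        for r_structure in ("diagonal_equal", "diagonal_unequal"):
            fit = dfa.em_fit(y, dfa.DFAModelSpec(m=1, r_structure=r_structure))
            assert np.diff(fit.loglik_trace).min() >= -1e-10
            assert fit.aic == pytest.approx(-2 * fit.logL + 2 * fit.n_params, abs=1e-12)

    def test_recovers_trend_on_synthetic_data(self):
        from fishfolio import simulate

        cfg = simulate.ScenarioConfig(
            n_fisheries=20, n_trends=1, years=(1801, 2000), regime_year=1900,
            obs_sd=0.3, seed=11,
        )
        panel, truth = simulate.gen_dfa_panel(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = dfa.em_fit(dfa.zscore(panel), dfa.DFAModelSpec(m=1))
        r = np.corrcoef(fit.states[0], truth.trends[0])[0, 1]
        assert abs(r) >= 0.95

    def test_too_few_series_fatal(self):
        y = np.random.default_rng(7).standard_normal((2, 10))
        with pytest.raises(ValueError, match="more series than trends"):
            dfa.em_fit(y, dfa.DFAModelSpec(m=2))


class TestSelectModel:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal((4, 12))
        spec = dfa.DFAModelSpec(m=1, max_iter=30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best, table = dfa.select_model(y, [spec])
        assert best.spec is spec
        assert len(table) == 1

    def test_tie_broken_toward_fewer_params(self):
        # two fits with identical AIC: the one with fewer parameters wins
        f_small = _fake_fit(aic=100.0, n_params=5)
        f_big = _fake_fit(aic=100.0, n_params=9)
        best = min(
            [f_big, f_small], key=lambda f: (round(f.aic / 1e-9) * 1e-9, f.n_params)
        )
        assert best is f_small

    def test_table_has_one_row_per_candidate(self):
        rng = np.random.default_rng(9)
        y = np.cumsum(rng.standard_normal((5, 25)), axis=1)
        y = (y - y.mean(1, keepdims=True)) / y.std(1, ddof=1, keepdims=True)
        cands = [
            dfa.DFAModelSpec(m=1, r_structure=r, max_iter=40)
            for r in ("diagonal_equal", "diagonal_unequal")
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best, table = dfa.select_model(y, cands)
        assert list(table["r_structure"]) == ["diagonal_equal", "diagonal_unequal"]
        assert best.aic == table["aic"].min()


def _fake_fit(aic, n_params):
    import dataclasses

    @dataclasses.dataclass
    class F:
        aic: float
        n_params: int

    return F(aic, n_params)


class TestRotateAndAlign:
    @pytest.fixture
    def two_trend_fit(self):
        from fishfolio import simulate

        cfg = simulate.ScenarioConfig(
            n_fisheries=10, n_trends=2, years=(1961, 2000), regime_year=1980,
            obs_sd=0.3, trend_step_sd=0.0, seed=12,
        )
        Z = np.zeros((10, 2))
        Z[:5, 0] = 1.0
        Z[5:, 1] = 1.0
        panel, _ = simulate.gen_dfa_panel(cfg, loadings=Z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return dfa.em_fit(dfa.zscore(panel), dfa.DFAModelSpec(m=2, max_iter=300))

    def test_likelihood_invariant_under_rotation(self, two_trend_fit):
        fit = two_trend_fit
        rotated = dfa.rotate_and_align(fit)
        logL_rot, _, _ = dfa.kalman_loglik(fit.y, rotated.Z, fit.R)
        assert logL_rot == pytest.approx(fit.logL, abs=1e-8)

    def test_loading_sums_nonnegative_after_alignment(self, two_trend_fit):
        rotated = dfa.rotate_and_align(two_trend_fit)
        assert (rotated.Z.sum(axis=0) >= 0).all()

    def test_negated_fit_restored(self, two_trend_fit):
        import dataclasses

        flipped = dataclasses.replace(
            two_trend_fit, Z=-two_trend_fit.Z, states=-two_trend_fit.states
        )
        out = dfa.rotate_and_align(flipped, rotate=False)
        assert (out.Z.sum(axis=0) >= 0).all()

    def test_m1_rotation_is_sign_flip_only(self):
        rng = np.random.default_rng(13)
        y = np.cumsum(rng.standard_normal((5, 20)), axis=1)
        y = (y - y.mean(1, keepdims=True)) / y.std(1, ddof=1, keepdims=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = dfa.em_fit(y, dfa.DFAModelSpec(m=1, max_iter=60))
        out = dfa.rotate_and_align(fit)
        assert np.allclose(np.abs(out.Z), np.abs(fit.Z))
        reconstructed = np.allclose(out.Z, fit.Z) or np.allclose(out.Z, -fit.Z)
        assert reconstructed


class TestTrendCovariateCorr:
    def test_identical_series(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert dfa.trend_covariate_corr(x, x) == pytest.approx(1.0)

    def test_negation(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert dfa.trend_covariate_corr(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # (1,2,3,4) vs (1,3,2,4): r = 0.8
        assert dfa.trend_covariate_corr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_fatal(self):
        with pytest.raises(ValueError, match="zero-variance"):
            dfa.trend_covariate_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
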