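import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from orgshift import diffloc_test as dt
from orgshift import spatial_data as sp
from orgshift import synthetic_data as sd
from orgshift.exceptions import ConfigError


class TestAlrTransform:
    def test_uniform_maps_to_zero(self):
        np.testing.assert_allclose(dt.alr_transform(np.full(10, 0.1), ref=10), np.zeros(9))

    def test_forced_arithmetic(self):
        comp = np.array([0.2] + [0.1] * 8 + [0.1])
        comp = comp / comp.sum()
        out = dt.alr_transform(comp, ref=10)
        assert out[0] == pytest.approx(np.log(2.0))
        np.testing.assert_allclose(out[1:], 0.0, atol=1e-12)

    def test_round_trip(self, rng):
        for _ in range(100):
            comp = rng.dirichlet(np.full(10, 2.0))
            comp = np.maximum(comp, 1e-6)
            comp /= comp.sum()
            ref = int(rng.integers(1, 11))
            back = dt.inverse_alr(dt.alr_transform(comp, ref=ref), ref=ref)
            assert np.abs(back - comp).max() < 1e-10

    def test_ref_out_of_range(self):
        with pytest.raises(ValueError):
            dt.alr_transform(np.full(10, 0.1), ref=11)
        with pytest.raises(ValueError):
            dt.inverse_alr(np.zeros(9), ref=0)

    def test_zero_floored(self):
        comp = np.array([1.0] + [0.0] * 9)
        out = dt.alr_transform(comp)
        assert np.all(np.isfinite(out))


class TestSeKernel:
    def test_diagonal_is_amplitude(self):
        h = dt.GPHyperparams(2.5, 1.3, 0.1)
        assert dt.se_kernel(3.0, 3.0, h) == pytest.approx(2.5)

    def test_closed_form(self):
        h = dt.GPHyperparams(1.0, 1.0, 0.1)
        assert dt.se_kernel(1.0, 2.0, h) == pytest.approx(np.exp(-0.5))

    def test_symmetry(self, rng):
        h = dt.GPHyperparams(1.7, 0.8, 0.2)
        for _ in range(10):
            x, y = rng.uniform(-5, 5, 2)
            assert dt.se_kernel(x, y, h) == pytest.approx(dt.se_kernel(y, x, h))


class TestGpLogMarginal:
    def test_single_point_closed_form(self):
        # a^2 + sigma^2 = 1, y = 0 -> -0.5 log(2 pi)
        h = dt.GPHyperparams(0.6, 1.0, 0.4)
        value = dt.gp_log_marginal(np.array([1.0]), np.array([0.0]), h)
        assert value == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-10)

    def test_two_point_mvn_oracle(self, rng):
        for _ in range(20):
            xs = rng.uniform(0, 5, 2)
            ys = rng.standard_normal(2)
            h = dt.GPHyperparams(
                float(rng.uniform(0.2, 3)), float(rng.uniform(0.3, 3)), float(rng.uniform(0.1, 1))
            )
            K = dt.se_kernel(xs[:, None], xs[None, :], h) + h.noise * np.eye(2)
            oracle = stats.multivariate_normal(np.zeros(2), K).logpdf(ys)
            assert dt.gp_log_marginal(xs, ys, h) == pytest.approx(oracle, abs=1e-10)

    def test_mvn_oracle_up_to_five(self, rng):
        # direct multivariate-normal density oracle, n <= 5
        for _ in range(100):
            n = int(rng.integers(1, 6))
            xs = rng.uniform(0, 9, n)
            ys = rng.standard_normal(n) * 2
            h = dt.GPHyperparams(
                float(rng.uniform(0.2, 3)), float(rng.uniform(0.3, 4)), float(rng.uniform(0.05, 1))
            )
            K = dt.se_kernel(xs[:, None], xs[None, :], h) + h.noise * np.eye(n)
            oracle = stats.multivariate_normal(np.zeros(n), K, allow_singular=True).logpdf(ys)
            assert abs(dt.gp_log_marginal(xs, ys, h) - oracle) < 1e-10

    def test_short_lengthscale_limit(self, rng):
        # l -> 0 with distinct xs decouples into independent Gaussians
        h = dt.GPHyperparams(1.5, 1e-6, 0.5)
        xs = np.arange(1.0, 6.0)
        ys = rng.standard_normal(5)
        expected = stats.norm(0, np.sqrt(1.5 + 0.5)).logpdf(ys).sum()
        assert dt.gp_log_marginal(xs, ys, h) == pytest.approx(expected, abs=1e-8)

    def test_repeated_x_allowed(self):
        h = dt.GPHyperparams(1.0, 1.0, 0.3)
        value = dt.gp_log_marginal(np.array([1.0, 1.0, 2.0]), np.array([0.1, 0.2, -0.1]), h)
        assert np.isfinite(value)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dt.gp_log_marginal(np.array([]), np.array([]), dt.GPHyperparams(1, 1, 1))


class TestMapHyperparameters:
    def test_deterministic_with_seed(self, rng):
        xs = np.tile(np.arange(1.0, 10.0), 3)
        ys = rng.standard_normal(27)
        a = dt.map_hyperparameters(xs, ys, n_restarts=1, seed=5)
        b = dt.map_hyperparameters(xs, ys, n_restarts=1, seed=5)
        assert a == b

    def test_objective_improves_on_starts(self, rng):
        xs = np.tile(np.arange(1.0, 10.0), 3)
        ys = np.sin(xs) + 0.3 * rng.standard_normal(27)
        priors = dt.GPPriors()
        hyper = dt.map_hyperparameters(xs, ys, priors, n_restarts=4, seed=0)

        def objective(h):
            lp = (
                priors.amplitude.log_pdf(h.amplitude)
                + priors.lengthscale.log_pdf(h.lengthscale)
                + priors.noise.log_pdf(h.noise)
            )
            return dt.gp_log_marginal(xs, ys, h) + lp

        achieved = objective(hyper)
        for trial in (
            dt.GPHyperparams(float(np.var(ys)), 1.0, float(np.var(ys)) / 2),
            dt.GPHyperparams(priors.amplitude.mean, priors.lengthscale.mean, priors.noise.mean),
        ):
            assert achieved >= objective(trial) - 1e-6

    def test_parameter_recovery(self, rng):
        true = dt.GPHyperparams(2.0, 2.0, 0.05)
        xs = np.linspace(0, 20, 200)
        K = dt.se_kernel(xs[:, None], xs[None, :], true) + true.noise * np.eye(200)
        ys = rng.multivariate_normal(np.zeros(200), K)
        est = dt.map_hyperparameters(xs, ys, n_restarts=3, seed=1)
        assert true.lengthscale / 2 <= est.lengthscale <= true.lengthscale * 2

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            dt.map_hyperparameters(np.array([1.0]), np.array([0.0]))


class TestLogBayesFactor:
    def test_identical_data_favors_null(self):
        # byte-identical control/treated replicate sets on realistic profiles
        cfg = sd.GeneratorConfig(n_unknown=40, n_movers=0, markers_per_class=(2,) * 11, seed=9)
        control, _, _ = sd.simulate_dataset(cfg)
        matrix = sp.concatenate_replicates(sp.normalize_experiment(control))
        scan = dt.diffloc_scan(matrix, matrix, config=dt.DiffLocConfig())
        assert (scan["log_bayes_factor"] <= 0).mean() >= 0.95

    def test_separated_conditions_favor_difference(self, rng):
        ctrl = np.zeros((3, 9)) + 0.05 * rng.standard_normal((3, 9))
        trt = np.full((3, 9), 5.0) + 0.05 * rng.standard_normal((3, 9))
        assert dt.log_bayes_factor(ctrl, trt, n_restarts=2, seed=0) > 0

    def test_sign_symmetry(self, rng):
        ctrl = rng.standard_normal((3, 9))
        trt = rng.standard_normal((3, 9)) + 1.0
        a = dt.log_bayes_factor(ctrl, trt, n_restarts=2, seed=0)
        b = dt.log_bayes_factor(-ctrl, -trt, n_restarts=2, seed=0)
        assert a == pytest.approx(b, abs=1e-6)

    def test_replicate_exchangeability(self, rng):
        ctrl = rng.standard_normal((3, 9))
        trt = rng.standard_normal((3, 9))
        a = dt.log_bayes_factor(ctrl, trt, n_restarts=2, seed=0)
        b = dt.log_bayes_factor(ctrl[[2, 0, 1]], trt[[1, 2, 0]], n_restarts=2, seed=0)
        assert a == pytest.approx(b, abs=1e-6)

    def test_empty_condition_errors(self):
        with pytest.raises(ValueError):
            dt.log_bayes_factor(np.empty((0, 9)), np.zeros((3, 9)))


class TestBfToPosterior:
    def test_unit_bayes_factor_returns_prior(self):
        assert dt.bf_to_posterior(0.0, 0.01) == 0.01

    def test_bf_99(self):
        assert dt.bf_to_posterior(np.log(99.0), 0.01) == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        assert dt.bf_to_posterior(np.inf, 0.01) == 1.0
        assert dt.bf_to_posterior(-np.inf, 0.01) == 0.0

    def test_extreme_values_stable(self):
        assert dt.bf_to_posterior(1e4, 0.01) == pytest.approx(1.0)
        assert dt.bf_to_posterior(-1e4, 0.01) == pytest.approx(0.0)

    def test_invalid_prior(self):
        with pytest.raises(ConfigError):
            dt.bf_to_posterior(0.0, 1.0)

    @given(
        st.floats(min_value=-50, max_value=50),
        st.floats(min_value=-50, max_value=50),
        st.floats(min_value=0.001, max_value=0.999),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_log_bf(self, a, b, pi):
        lo, hi = sorted((a, b))
        assert dt.bf_to_posterior(lo, pi) <= dt.bf_to_posterior(hi, pi)


class TestCallMovers:
    def _results(self):
        return pd.DataFrame(
            {
                "protein_id": ["P1", "P2", "P3"],
                "log_bayes_factor": [0.0, 25.0, 10.0],
                "posterior": [0.01, 1.0 - 1e-9, 0.9],
                "mover": [False, False, False],
            }
        )

    def test_prior_only_means_no_movers(self):
        out = dt.call_movers(self._results().assign(posterior=0.01))
        assert not out["mover"].any()

    def test_zero_threshold_flags_all(self):
        out = dt.call_movers(self._results(), mover_threshold=0.0)
        assert out["mover"].all()

    def test_ranking_deterministic(self):
        frame = self._results().assign(posterior=[0.5, 0.5, 0.9], log_bayes_factor=[1.0, 1.0, 2.0])
        out = dt.call_movers(frame, mover_threshold=0.6)
        assert list(out["protein_id"]) == ["P3", "P1", "P2"]


class TestRecoveryProperties:
    def test_mover_recovery_small_scale(self, small_dataset):
        cfg, cm, tm, truth = small_dataset
        scan = dt.diffloc_scan(cm, tm, config=dt.DiffLocConfig())
        scan["true_mover"] = scan["protein_id"].isin(truth.mover_ids)
        recall = scan.loc[scan["true_mover"], "mover"].mean()
        false_rate = scan.loc[~scan["true_mover"], "mover"].mean()
        assert recall >= 0.75
        assert false_rate <= 0.02

    def test_power_monotone_in_lambda(self):
        recalls = {}
        for lam in (0.25, 0.5, 1.0):
            cfg = sd.GeneratorConfig(
                n_unknown=120, n_movers=25, markers_per_class=(5,) * 11,
                mover_completeness=lam, seed=21,
            )
            control, treated, truth = sd.simulate_dataset(cfg)
            cm = sp.concatenate_replicates(sp.normalize_experiment(control))
            tm = sp.concatenate_replicates(sp.normalize_experiment(treated))
            scan = dt.diffloc_scan(cm, tm, sorted(truth.mover_ids), dt.DiffLocConfig())
            recalls[lam] = scan["mover"].mean()
        slack = 1 / 25  # one mover of seeded noise
        assert recalls[0.25] <= recalls[0.5] + slack
        assert recalls[0.5] <= recalls[1.0] + slack

    def test_power_monotone_in_kappa(self):
        recalls = {}
        for kappa in (50.0, 200.0):
            cfg = sd.GeneratorConfig(
                n_unknown=120, n_movers=25, markers_per_class=(5,) * 11,
                concentration=kappa, seed=21,
            )
            control, treated, truth = sd.simulate_dataset(cfg)
            cm = sp.concatenate_replicates(sp.normalize_experiment(control))
            tm = sp.concatenate_replicates(sp.normalize_experiment(treated))
            scan = dt.diffloc_scan(cm, tm, sorted(truth.mover_ids), dt.DiffLocConfig())
            recalls[kappa] = scan["mover"].mean()
        assert recalls[50.0] <= recalls[200.0] + 1 / 25
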