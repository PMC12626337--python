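"""The iterative estimator: warm starts, refinement, restarts, gauge."""

import numpy as np
import pytest

from ilvkit import (
    CompositionSeries,
    GLVParams,
    ILVConfig,
    ILVRegressor,
    fit_ilv,
    optimizer_stability_report,
    subroutine1,
    subroutine2,
    trajectory_rmse,
)
from ilvkit.estimators import gradient_matching_regression


@pytest.fixture(scope="module")
def small_cfg():
    return ILVConfig(restarts=2, seed=3)


class TestSubroutine1:
    def test_single_iteration_is_plain_linear_approximation(self, periodic):
        series, _ = periodic
        cfg = ILVConfig(M=1)
        params, path, it = subroutine1(series, cfg)
        r, B = gradient_matching_regression(
            np.clip(series.X, 1e-6, None) * cfg.nsum_guess,
            series.times,
            include_self=False,
        )
        assert it == 1 and path.shape == (1,)
        assert np.allclose(params.r, r) and np.allclose(params.B, B)

    def test_selected_rmse_never_above_first_iterate(self):
        from ilvkit import generate_dataset, make_scenario

        for name in ("periodic", "stabilizing", "fig2_ablation"):
            series, _ = generate_dataset(make_scenario(name))
            _, path, it = subroutine1(series, ILVConfig())
            assert np.nanmin(path) <= path[0]
            assert path[it - 1] == np.nanmin(path)

    def test_ablation_best_iterate(self, ablation):
        series, _ = ablation
        params, path, it = subroutine1(series, ILVConfig())
        assert it == 13  # refinement peaks early in the 100-iteration budget
        assert min(path) == pytest.approx(0.169, rel=0.02)

    def test_gauge_covariance_of_linear_step(self, periodic):
        # scaling the total-abundance guess by c leaves r and rescales B by 1/c
        series, _ = periodic
        base = subroutine1(series, ILVConfig(M=1))[0]
        for c in (0.1, 10.0):
            scaled = subroutine1(
                series, ILVConfig(M=1, nsum_guess=200.0 * c)
            )[0]
            assert np.allclose(scaled.r, base.r, rtol=0, atol=1e-12)
            assert np.allclose(scaled.B * c, base.B, rtol=1e-9, atol=1e-15)


class TestSubroutine2:
    def test_never_worse_than_start(self, periodic):
        series, _ = periodic
        start, _, _ = subroutine1(series, ILVConfig(M=1))
        start_rmse = trajectory_rmse(series, start, series.X[0], 200.0)
        fit = subroutine2(series, start, series.X[0], 200.0)
        assert fit.rmse <= start_rmse

    def test_perfect_start_returned_unchanged(self):
        # constant composition is exactly reproduced by the zero system
        X = np.tile([0.4, 0.6], (6, 1))
        series = CompositionSeries(np.arange(6.0), X)
        start = GLVParams(np.zeros(2), np.zeros((2, 2)))
        fit = subroutine2(series, start, X[0], 100.0)
        assert fit.rmse <= 1e-9
        assert fit.backend == "subroutine1-only"

    def test_nonzero_diagonal_rejected(self, periodic):
        series, _ = periodic
        bad = GLVParams(np.zeros(3), np.eye(3) * 0.1, self_interactions=True)
        with pytest.raises(ValueError, match="diagonal"):
            subroutine2(series, bad, series.X[0], 200.0)

    def test_warm_start_reaches_machine_level_fit(self, ablation):
        series, _ = ablation
        start, _, _ = subroutine1(series, ILVConfig())
        fit = subroutine2(series, start, series.X[0], 200.0, ("lm-a",))
        assert fit.rmse < 1e-6


class TestFitILV:
    def test_deterministic_given_seed(self, periodic, small_cfg):
        series, _ = periodic
        a = fit_ilv(series, small_cfg)
        b = fit_ilv(series, small_cfg)
        assert a.rmse == b.rmse
        assert np.array_equal(a.params.B, b.params.B)

    def test_restart_metadata_and_path(self, periodic, small_cfg):
        series, _ = periodic
        fit = fit_ilv(series, small_cfg)
        assert fit.rmse >= 0 and fit.best_iteration >= 1
        assert np.all(np.diag(fit.params.B) == 0)
        assert fit.rmse_path.shape == (small_cfg.M,)
        assert fit.x0.sum() == pytest.approx(1.0)

    def test_more_restarts_never_hurt(self, periodic):
        series, _ = periodic
        one = fit_ilv(series, ILVConfig(restarts=1, seed=5))
        many = fit_ilv(series, ILVConfig(restarts=3, seed=5))
        assert many.rmse <= one.rmse
        if one.rmse < 1e-8:
            # already at the solver floor: the winner is the same start
            assert many.restart == one.restart

    def test_noise_free_recovery(self, periodic):
        series, truth = periodic
        fit = fit_ilv(series, ILVConfig(restarts=2, seed=1))
        from ilvkit import cosine_offdiag

        assert cosine_offdiag(fit.params.B, truth.B) > 0.999
        assert np.max(np.abs(fit.params.r - truth.r)) < 1e-3

    def test_guess_scale_does_not_change_fit_quality(self, periodic):
        # the total-abundance gauge: doubling the guess halves B, same fit
        series, truth = periodic
        a = fit_ilv(series, ILVConfig(restarts=1, nsum_guess=200.0))
        b = fit_ilv(series, ILVConfig(restarts=1, nsum_guess=400.0))
        from ilvkit import cosine_offdiag

        assert abs(a.rmse - b.rmse) < 1e-6
        assert cosine_offdiag(a.params.B, b.params.B) == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(a.params.r, b.params.r, atol=1e-5)


class TestStabilityReport:
    def test_summary_order_statistics(self, periodic):
        series, _ = periodic
        cfg = ILVConfig(restarts=1, M=20, backends=("lm-a", "trf"), seed=2)
        rep = optimizer_stability_report(series, cfg, runs=2)
        assert set(rep.index) == {"lm-a", "trf"}
        assert (rep["min"] <= rep["median"]).all()
        assert (rep["median"] <= rep["max"]).all()

    def test_report_reproducible(self, periodic):
        series, _ = periodic
        cfg = ILVConfig(restarts=1, M=10, backends=("lm-a",), seed=2)
        a = optimizer_stability_report(series, cfg, runs=2)
        b = optimizer_stability_report(series, cfg, runs=2)
        assert a.equals(b)

    def test_requires_two_runs(self, periodic):
        series, _ = periodic
        with pytest.raises(ValueError):
            optimizer_stability_report(series, ILVConfig(), runs=1)


class TestILVRegressor:
    def test_sklearn_interface(self, periodic):
        from sklearn.base import clone

        series, truth = periodic
        est = ILVRegressor(restarts=1, random_state=0)
        cloned = clone(est)
        assert cloned.get_params()["restarts"] == 1
        est.fit(series.X, series.times)
        assert est.r_.shape == (3,) and est.B_.shape == (3, 3)
        assert est.rmse_ >= 0 and est.n_features_in_ == 3
        pred = est.predict(series.times)
        assert pred.shape == series.X.shape
        assert np.max(np.abs(pred - series.X)) < 1e-4
        assert est.score(series.X, series.times) == pytest.approx(-est.rmse_)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ILVConfig(nsum_guess=-1)
        with pytest.raises(ValueError):
            ILVConfig(M=0)
        with pytest.raises(ValueError):
            ILVConfig(backends=("bogus",))
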