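"""Trust-region NLS solver: initialization, recovery, budgets, contracts."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from relaxfit.models import MEParams, SEParams, default_bounds, evaluate
from relaxfit.nls import (
    NLSConfig,
    default_initial_guess,
    initial_guess_table,
    nls_fit_map,
    nls_fit_voxel,
)
from relaxfit.synthetic import ParamPrior, make_dataset, sample_parameters


class TestInitialGuess:
    def test_loglinear_recovers_noiseless_T(self, schedule):
        s = evaluate("me", np.array([1.0, 50.0]), schedule)
        init = default_initial_guess("me", s, schedule)
        assert init.T_me == pytest.approx(50.0, rel=0.01)

    def test_constant_signal_clips_to_upper_bound(self, schedule):
        init = default_initial_guess("me", np.ones(6), schedule)
        assert init.T_me == 300.0

    def test_be_uses_stated_defaults(self, schedule):
        s = evaluate("be", np.array([1.0, 0.3, 2.0, 40.0]), schedule)
        init = default_initial_guess("be", s, schedule)
        assert init.phi_f == 0.5
        b = default_bounds("be")
        assert init.T_s == pytest.approx(np.sqrt(b.lower[2] * b.upper[2]))
        assert init.T_l == pytest.approx(np.sqrt(b.lower[3] * b.upper[3]))

    def test_nonpositive_signal_falls_back_to_midpoint(self, schedule):
        with pytest.warns(UserWarning, match="midpoint"):
            init = default_initial_guess("me", -np.ones(6), schedule)
        b = default_bounds("me")
        assert init.T_me == pytest.approx(b.mid[1])


class TestVoxelFit:
    def test_noiseless_me_recovery(self, schedule):
        truth = MEParams(1.0, 30.0)
        s = evaluate("me", truth.array, schedule)
        res = nls_fit_voxel(s, schedule, "me", default_initial_guess("me", s, schedule))
        assert res.params[1] == pytest.approx(30.0, rel=1e-4)
        assert res.converged

    def test_noiseless_se_recovery(self, schedule):
        truth = SEParams(1.0, 80.0, 0.6)
        s = evaluate("se", truth.array, schedule)
        res = nls_fit_voxel(s, schedule, "se", default_initial_guess("se", s, schedule))
        np.testing.assert_allclose(res.params, truth.array, rtol=1e-3)
        assert res.residual_norm < 1e-8

    def test_zero_budget_returns_init(self, schedule):
        s = evaluate("me", np.array([1.0, 30.0]), schedule) + 0.01
        init = MEParams(0.9, 100.0)
        res = nls_fit_voxel(s, schedule, "me", init, NLSConfig(max_iterations=0))
        np.testing.assert_array_equal(res.params, init.array)
        assert res.iterations_used == 0

    def test_residual_trace_is_nonincreasing(self, schedule):
        ds = make_dataset("se", 10, seed=8)
        init = default_initial_guess("se", ds.signals[0], schedule)
        res = nls_fit_voxel(ds.signals[0], schedule, "se", init, NLSConfig(max_iterations=200))
        assert np.all(np.diff(res.residual_trace) <= 1e-12)

    def test_nonfinite_signal_rejected(self, schedule):
        s = np.array([1.0, np.nan, 0.5, 0.4, 0.3, 0.2])
        with pytest.raises(ValueError, match="finite"):
            nls_fit_voxel(s, schedule, "me", MEParams(1.0, 50.0))

    def test_penalty_pulls_toward_range_midpoint(self, schedule):
        """With a huge regularization weight the minimizer sits at the midpoint."""
        s = evaluate("me", np.array([1.0, 30.0]), schedule)
        init = default_initial_guess("me", s, schedule)
        cfg = NLSConfig(max_iterations=500, penalty_weight=1e6)
        res = nls_fit_voxel(s, schedule, "me", init, cfg)
        b = default_bounds("me")
        np.testing.assert_allclose(res.params, b.mid, rtol=1e-3)


class TestMapFit:
    def test_singleton_map_equals_voxel_fit(self, schedule):
        ds = make_dataset("me", 10, seed=1)
        init = initial_guess_table("me", ds.signals, schedule)
        voxel = nls_fit_voxel(ds.signals[0], schedule, "me", init[0], trace=False)
        as_map = nls_fit_map(ds.signals[:1], schedule, "me", init[:1])
        np.testing.assert_allclose(as_map.params[0], voxel.params, rtol=1e-12)

    def test_permutation_equivariance(self, schedule):
        ds = make_dataset("se", 20, seed=2)
        init = initial_guess_table("se", ds.signals, schedule)
        cfg = NLSConfig(max_iterations=50)
        res = nls_fit_map(ds.signals, schedule, "se", init, cfg)
        perm = np.random.default_rng(0).permutation(20)
        res_p = nls_fit_map(ds.signals[perm], schedule, "se", init[perm], cfg)
        np.testing.assert_allclose(res_p.params, res.params[perm], rtol=1e-10)

    def test_mask_yields_sentinel_results(self, schedule):
        ds = make_dataset("me", 10, seed=3)
        init = initial_guess_table("me", ds.signals, schedule)
        mask = np.zeros(10, dtype=bool)
        res = nls_fit_map(ds.signals, schedule, "me", init, mask=mask)
        assert np.all(np.isnan(res.params))
        assert np.all(res.iterations_used == 0)

    def test_shape_mismatch_rejected(self, schedule):
        with pytest.raises(ValueError):
            nls_fit_map(np.ones((5, 6)), schedule, "me", np.ones((4, 2)))


class TestConvergenceQuality:
    @pytest.mark.parametrize("model", ["me", "se", "be"])
    def test_matches_scipy_bounded_reference(self, model, schedule):
        """Final residual norms agree with a generic bounded LS solver."""
        theta = sample_parameters(ParamPrior(model), 20, seed=77)
        s = evaluate(model, theta, schedule)
        b = default_bounds(model)
        init = initial_guess_table(model, s, schedule, b)
        ours = nls_fit_map(s, schedule, model, init)
        t = schedule.array
        for i in range(s.shape[0]):
            ref = least_squares(
                lambda th: evaluate(model, th, t, check=False) - s[i],
                np.clip(init[i], b.lo + 1e-9, b.hi - 1e-9),
                bounds=(b.lo, b.hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            assert abs(ours.residual_norm[i] - np.linalg.norm(ref.fun)) < 1e-6

    def test_mean_residual_monotone_in_budget(self, schedule):
        ds = make_dataset("me", 200, seed=5)
        init = initial_guess_table("me", ds.signals, schedule)
        means = []
        for k in (0, 10, 50, 200):
            res = nls_fit_map(ds.signals, schedule, "me", init, NLSConfig(max_iterations=k))
            means.append(res.residual_norm.mean())
        assert np.all(np.diff(means) <= 1e-12)

    def test_noise_floor_reached_at_full_budget(self, schedule):
        """Mean NRMSR after 2000 iterations stays within 10% of noise-only."""
        ds = make_dataset("me", 400, seed=9)
        init = initial_guess_table("me", ds.signals, schedule)
        res = nls_fit_map(ds.signals, schedule, "me", init)
        norms = np.linalg.norm(ds.signals, axis=1)
        fit_nrmsr = np.mean(res.residual_norm / norms)
        noise_only = np.mean(np.linalg.norm(ds.signals - ds.clean_signals, axis=1) / norms)
        assert fit_nrmsr <= 1.1 * noise_only
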