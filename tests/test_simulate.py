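"""Stochastic integration, order parameters, bout durations, ensemble sweeps."""

import math

import numpy as np
import pytest

import hexacpg as hx
from hexacpg.simulate import _integrate_ensemble_xi


class TestOrderParameters:
    def test_pure_gaits(self):
        assert hx.xi_tripod(hx.TRIPOD) == pytest.approx(1.0)
        assert hx.xi_idle(hx.TRIPOD) == pytest.approx(0.0, abs=1e-15)
        assert hx.xi_idle(hx.IDLE) == pytest.approx(1.0)
        assert hx.xi_tripod(hx.IDLE) == pytest.approx(0.0, abs=1e-15)

    def test_half_split_state(self):
        # legs split by side instead of by trio: no synchrony, partial tripod
        phi = np.array([0.0, 0.0, 0.0, np.pi, np.pi, np.pi])
        assert hx.xi_idle(phi) == pytest.approx(0.0, abs=1e-15)
        assert hx.xi_tripod(phi) == pytest.approx(1.0 / 3.0)

    def test_invariance_to_wraps_and_shifts(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 6)
        shifted = phi + 2 * np.pi * rng.integers(-3, 4, 6) + 0.0
        assert hx.xi_tripod(shifted) == pytest.approx(hx.xi_tripod(phi))
        assert hx.xi_idle(phi + 1.7) == pytest.approx(hx.xi_idle(phi))

    def test_bounded_in_unit_interval(self, rng):
        phi = rng.uniform(-30, 30, (100, 6))
        xi_i, xi_t = hx.order_parameters(phi)
        assert np.all((0 <= xi_i) & (xi_i <= 1))
        assert np.all((0 <= xi_t) & (xi_t <= 1))


class TestIntegrate:
    def test_noiseless_tripod_is_conserved(self, default_params):
        mp = default_params.with_(sigma=0.0, k=1.0)
        traj = hx.integrate(hx.TRIPOD, mp, dt=0.01, t_max=10.0)
        assert np.abs(traj.phi - hx.TRIPOD).max() < 1e-10
        assert np.allclose(traj.xi_tri, 1.0)

    def test_idle_attracts_nearby_states(self, default_params, rng):
        mp = default_params.with_(sigma=0.0)
        phi0 = hx.IDLE + rng.normal(0, 0.1, 6)
        traj = hx.integrate(phi0, mp, dt=0.01, t_max=30.0)
        assert traj.xi_idl[-1] > 0.9999

    def test_shift_equivariance_propagates(self, default_params, rng):
        mp = default_params.with_(sigma=0.0, k=0.7)
        phi0 = rng.uniform(-1, 1, 6)
        c = 1.234
        t1 = hx.integrate(phi0, mp, dt=0.01, t_max=5.0)
        t2 = hx.integrate(phi0 + c, mp, dt=0.01, t_max=5.0)
        assert np.abs(t2.phi - t1.phi - c).max() < 1e-9

    def test_seed_determinism_bit_identical(self, feedback_params):
        a = hx.integrate(hx.TRIPOD, feedback_params, seed=42, t_max=5.0)
        b = hx.integrate(hx.TRIPOD, feedback_params, seed=42, t_max=5.0)
        assert np.array_equal(a.phi, b.phi)
        c = hx.integrate(hx.TRIPOD, feedback_params, seed=43, t_max=5.0)
        assert not np.array_equal(a.phi, c.phi)

    def test_halving_dt_changes_trajectory_at_first_order(self, default_params):
        mp = default_params.with_(sigma=0.0, k=1.0)
        phi0 = hx.TRIPOD + 0.05 * np.array([1, -1, 0.5, 0, -0.5, 0])
        horizon = 2.0
        ref = hx.integrate(phi0, mp, dt=0.0005, t_max=horizon)
        err = {}
        for dt in (0.02, 0.01):
            traj = hx.integrate(phi0, mp, dt=dt, t_max=horizon)
            on_ref_grid = np.interp(traj.t, ref.t, ref.xi_tri)
            err[dt] = np.abs(traj.xi_tri - on_ref_grid).max()
        # Euler error is O(dt): halving dt should roughly halve the error
        assert err[0.01] < 0.75 * err[0.02]

    def test_initial_kick_mode_is_deterministic_after_start(self, default_params):
        mp = default_params.with_(noise_mode="initial_kick", k=1.0)
        a = hx.integrate(hx.TRIPOD, mp, seed=7, t_max=5.0)
        b = hx.integrate(hx.TRIPOD, mp, seed=7, t_max=5.0)
        assert np.array_equal(a.phi, b.phi)
        assert not np.allclose(a.phi[0], hx.TRIPOD)  # kicked start

    def test_bad_grid_rejected(self, default_params):
        with pytest.raises(ValueError):
            hx.integrate(hx.TRIPOD, default_params, dt=0.0, t_max=1.0)
        with pytest.raises(ValueError):
            hx.integrate(hx.TRIPOD, default_params, dt=1.0, t_max=0.5)

    def test_frame_export_columns(self, feedback_params):
        traj = hx.integrate(hx.TRIPOD, feedback_params, t_max=1.0)
        df = traj.to_frame()
        assert list(df.columns) == [
            "t", "phi1", "phi2", "phi3", "phi4", "phi5", "phi6", "xi_idl", "xi_tri"
        ]


class TestBoutDuration:
    def test_step_series(self):
        t = np.linspace(0, 10, 1001)
        y = np.where(t < 5, 1.0, 0.0)
        assert hx.bout_duration(t, y, "last_crossing_015") == pytest.approx(5.0, abs=0.02)
        assert hx.bout_duration(t, y, "half_life_05") == pytest.approx(5.0, abs=0.02)

    def test_linear_ramp(self):
        t = np.linspace(0, 10, 1001)
        y = 1 - t / 10
        assert hx.bout_duration(t, y, "half_life_05") == pytest.approx(5.0, abs=1e-9)
        assert hx.bout_duration(t, y, "last_crossing_015") == pytest.approx(8.5, abs=1e-9)

    def test_last_crossing_convention_with_recovery(self):
        # dip to 0.4 at t=2, recover to 0.9, final decay at t=7: the half-life
        # is the *last* down-crossing, near 7, not the transient dip at 2
        t = np.linspace(0, 10, 2001)
        y = np.interp(t, [0, 2, 4, 6.5, 7, 10], [1.0, 0.4, 0.9, 0.9, 0.0, 0.0])
        hl = hx.bout_duration(t, y, "half_life_05")
        assert 6.6 < hl < 7.0

    def test_never_crossing_returns_nan(self):
        t = np.linspace(0, 10, 101)
        assert math.isnan(hx.bout_duration(t, np.full(101, 0.9), "half_life_05"))

    def test_series_below_threshold_rejected(self):
        t = np.linspace(0, 1, 11)
        with pytest.raises(ValueError):
            hx.bout_duration(t, np.full(11, 0.1), "half_life_05")

    def test_halflife_precedes_full_duration(self, feedback_params):
        recs = hx.run_bouts(feedback_params, 20, seed=5)
        for r in recs:
            if r.decayed:
                assert r.duration_halflife <= r.duration_last015


class TestBoutClassification:
    def test_instantaneous_step_is_sharp(self):
        from hexacpg.simulate import _record_from_series

        t = np.linspace(0, 10, 1001)
        y = np.where(t < 5, 1.0, 0.0)
        rec = _record_from_series(t, y, tau6=0.5, sharp_window=None)
        assert rec.label == "sharp"

    def test_long_plateau_at_half_is_irregular(self):
        from hexacpg.simulate import _record_from_series

        tau6 = 0.5
        t = np.linspace(0, 20, 2001)
        # drop to 0.5, sit there for 10*tau6, then decay
        y = np.interp(t, [0, 1, 1 + 10 * tau6, 1 + 10 * tau6 + 0.2, 20], [1, 0.5, 0.5, 0, 0])
        rec = _record_from_series(t, y, tau6=tau6, sharp_window=None)
        assert rec.label == "irregular"

    def test_censored_bout_from_exact_start_without_noise(self, default_params):
        mp = default_params.with_(sigma=0.0, k=1.0)
        rec = hx.run_bout(mp, t_max=5.0, seed=0)
        assert rec.label == "censored"
        assert not rec.decayed

    def test_classify_rejects_censored(self, default_params):
        mp = default_params.with_(sigma=0.0, k=1.0)
        rec = hx.run_bout(mp, t_max=5.0, seed=0)
        with pytest.raises(ValueError):
            hx.classify_transition(rec, 1.5)

    def test_no_feedback_ensemble_mixes_labels(self, default_params):
        # without feedback roughly half the decays are irregular
        recs = hx.run_bouts(default_params, 100, seed=11)
        labels = {r.label for r in recs}
        n_sharp = sum(r.label == "sharp" for r in recs)
        n_irr = sum(r.label == "irregular" for r in recs)
        assert "sharp" in labels and "irregular" in labels
        assert n_sharp >= 15 and n_irr >= 15


class TestEnsembles:
    def test_vectorized_ensemble_matches_single_runs_statistically(self, feedback_params):
        t, xi = _integrate_ensemble_xi(feedback_params, 50, 0.01, 30.0, seed=3)
        assert xi.shape == (50, 3001)
        assert np.all((0 <= xi) & (xi <= 1 + 1e-12))
        assert np.all(xi[:, 0] == 1.0)

    def test_mean_halflife_matches_linear_theory_within_factor_two(self, feedback_params):
        recs = hx.run_bouts(feedback_params, 100, seed=21)
        hl = np.array([r.duration_halflife for r in recs if r.decayed])
        predicted = hx.predict_tau(1.0, 0.01)  # ln(100)/2 ~ 2.30
        assert predicted / 2 < hl.mean() < predicted * 2

    def test_sweep_rho_monotone_trend(self, default_params):
        res = hx.sweep_rho([0.0, 0.75, 1.5], default_params, n=60, seed=2)
        rho = res.table["rho"].to_numpy()
        # occasional slow irregular decays may outlast the horizon; they are
        # flagged as censored and excluded from rho, never dropped silently
        assert res.table["n_censored"].sum() <= 3
        assert (res.table["n_decayed"] + res.table["n_censored"] == 60).all()
        # non-decreasing within sampling error
        assert rho[1] >= rho[0] - 0.15
        assert rho[2] >= rho[1] - 0.15
        assert rho[2] > rho[0]

    def test_sweep_rho_needs_enough_reps(self, default_params):
        with pytest.raises(ValueError):
            hx.sweep_rho([0.0], default_params, n=10)

    def test_duration_distribution_estimator_consistency(self, rng):
        durations = rng.exponential(0.5, 2000)  # rate 2
        out = hx.duration_distribution(durations, bins=40)
        assert abs(out["tail_rate"] - 2.0) / 2.0 < 0.1
        assert out["semilog_r2"] > 0.95

    def test_duration_distribution_declines_small_samples(self):
        out = hx.duration_distribution(np.ones(10))
        assert "fit_declined" in out

    def test_low_feedback_distribution_is_multimodal(self, default_params):
        recs = hx.run_bouts(default_params, 200, seed=31)
        out = hx.duration_distribution(recs, bins=25)
        density, edges = out["density"], out["edges"]
        # distinct separated peaks beyond the main mode: look for a local
        # maximum after a deep valley past the global mode
        imode = int(np.argmax(density))
        after = density[imode + 1 :]
        valley = after.min()
        assert after.max() > 2.5 * max(valley, 1e-12)

    def test_feedback_distribution_has_exponential_tail(self, feedback_params):
        recs = hx.run_bouts(feedback_params, 200, seed=41)
        out = hx.duration_distribution(recs, bins=25)
        assert out["semilog_r2"] >= 0.9

    def test_sweep_tau_gamma_scaling(self, default_params):
        mp = default_params.with_(k=1.0)
        res = hx.sweep_tau("gamma", [0.5, 1.0, 2.0, 4.0], mp, n=50, seed=0)
        assert res.fit["kind"] == "power_law"
        assert abs(res.fit["slope"] + 1.0) < 0.15

    def test_sweep_tau_sigma_decline(self, default_params):
        mp = default_params.with_(k=1.0)
        res = hx.sweep_tau("sigma", [1e-3, 1e-2, 1e-1], mp, n=30, seed=0)
        tau = res.table["tau_mean"].to_numpy()
        ci = res.table["tau_ci"].to_numpy()
        # monotone decline beyond the confidence bands
        assert tau[1] < tau[0] + ci[0] and tau[2] < tau[1] + ci[1]
        assert res.fit["kind"] == "logarithmic"
        assert res.fit["r2"] > 0.9
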