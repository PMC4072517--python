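"""Drift-velocity theory: run durations, linearized drift, fixed points."""
import numpy as np
import pytest

from chemodrift import (
    Environment,
    MotorParams,
    Phenotype,
    chemotaxis_coefficient,
    drift_curve,
    drift_exact,
    expected_run_duration,
    feedback_drift,
    feedback_line,
    fixed_points,
    motor_adapted_drift,
    operating_point,
    optimal_y0,
    phenotype_map,
    steady_state_drift,
    f0_of_y0,
    switching_rates,
)
from chemodrift.analytic import eps3_quasi_steady


class TestExpectedRunDuration:
    def test_constant_rate_limit(self, shallow, mp):
        # with no drive the survival is a pure exponential
        for y in (2.0, 2.4, 3.0):
            lam_r = float(switching_rates(y, mp)[0])
            expect = 1.0 / (2 * shallow.Dr + lam_r)
            got = expected_run_duration(f0_of_y0(y), +1, 10.0, 0.0,
                                        shallow, mp)
            assert got == pytest.approx(expect, rel=1e-4)

    def test_low_chey_p_run_is_rotational_diffusion_limited(self, shallow, mp):
        # at Y = 2.4 µM the run lasts ~4.2 s, set jointly by lam_R ≈ 0.116
        # and the 2*Dr reorientation rate
        got = expected_run_duration(f0_of_y0(2.4), +1, 10.0, 0.0, shallow, mp)
        assert got == pytest.approx(4.2, abs=0.1)

    @pytest.mark.parametrize("y0", [2.0, 2.4, 3.0])
    @pytest.mark.parametrize("f", [0.024, 0.12])
    def test_up_gradient_runs_outlast_down_gradient_runs(self, y0, f,
                                                         shallow, mp):
        up = expected_run_duration(f0_of_y0(y0), +1, 10.0, f, shallow, mp)
        down = expected_run_duration(f0_of_y0(y0), -1, 10.0, f, shallow, mp)
        assert up > down

    def test_diverging_integral_rejected(self, mp):
        env = Environment(g=0.0, Dr=0.0)
        with pytest.raises(ValueError):
            expected_run_duration(f0_of_y0(0.01), +1, 10.0, 0.0, env, mp)


class TestDriftVelocity:
    def test_no_gradient_no_drift(self, mp):
        env = Environment(g=0.0)
        assert drift_exact(Phenotype(Y0=2.4, tau=10.0), env, mp) == 0.0

    def test_sign_follows_gradient(self, mp):
        up = drift_exact(Phenotype(Y0=2.4, tau=10.0),
                         Environment(g=1 / 5000), mp)
        down = drift_exact(Phenotype(Y0=2.4, tau=10.0),
                           Environment(g=-1 / 5000), mp)
        assert up > 0 > down

    def test_exact_and_linearized_agree_in_shallow_gradient(self, shallow,
                                                            mp):
        # mutual-oracle check; relative agreement is meaningful away from
        # the zero-drift tails, so allow a small absolute floor
        for y0 in np.arange(1.5, 3.51, 0.25):
            de = drift_exact(Phenotype(Y0=float(y0), tau=10.0), shallow, mp)
            dl = float(drift_curve(y0, 10.0, shallow, mp))
            assert abs(de - dl) <= 0.10 * abs(dl) + 0.01

    def test_linear_in_small_adaptation_time(self, shallow, mp):
        v1 = float(drift_curve(2.4, 0.01, shallow, mp))
        v2 = float(drift_curve(2.4, 0.02, shallow, mp))
        assert v2 / v1 == pytest.approx(2.0, rel=0.01)

    def test_saturates_for_large_adaptation_time(self, shallow, mp):
        v1 = float(drift_curve(2.4, 1e4, shallow, mp))
        v2 = float(drift_curve(2.4, 1e6, shallow, mp))
        assert v2 == pytest.approx(v1, rel=1e-3)

    def test_optimum_sits_at_foot_of_cw_response(self, shallow, mp):
        y0 = np.arange(1.0, 4.0, 0.01)
        vd = drift_curve(y0, 10.0, shallow, mp)
        assert 2.3 < y0[np.argmax(vd)] < 2.5

    def test_operating_point_wrapper_matches_vectorized_curve(self, shallow,
                                                              mp):
        from chemodrift import drift_linearized

        op = operating_point(2.4, shallow, mp)
        f = shallow.v * 6.0 * shallow.g
        assert drift_linearized(op, 10.0, f, shallow) == pytest.approx(
            float(drift_curve(2.4, 10.0, shallow, mp)), rel=1e-12)


class TestFeedback:
    def test_zero_drift_keeps_adapted_level(self, steep):
        ph = Phenotype(Y0=2.7, tau=5.0)
        assert float(feedback_line(0.0, ph, steep)) == pytest.approx(2.7)

    def test_operational_offset_arithmetic(self):
        # tau=30 s, N=6, g=1e-3/µm, V_D=4 µm/s -> F_m - F0 = 0.72
        ph = Phenotype(Y0=3.0, tau=30.0)
        env = Environment(g=1e-3)
        ym = float(feedback_line(4.0, ph, env))
        assert np.log(6.0 / ym - 1.0) - ph.F0 == pytest.approx(0.72,
                                                               rel=1e-12)

    def test_slope_halves_when_adaptation_time_doubles(self, steep):
        v1 = float(feedback_drift(2.5, Phenotype(Y0=3.0, tau=10.0), steep))
        v2 = float(feedback_drift(2.5, Phenotype(Y0=3.0, tau=20.0), steep))
        assert v1 / v2 == pytest.approx(2.0, rel=1e-12)


class TestFixedPoints:
    def test_weak_feedback_single_stable_state(self, steep, mp):
        fps = fixed_points(Phenotype(Y0=2.7, tau=5.0), steep, mp)
        assert len(fps) == 1
        assert fps[0].stability == "stable"
        assert 2.3 < fps[0].Y_m < 2.6

    def test_strong_feedback_bistability(self, steep, mp):
        fps = fixed_points(Phenotype(Y0=3.5, tau=30.0), steep, mp)
        assert [fp.stability for fp in fps] == ["stable", "unstable",
                                                "stable"]

    def test_roots_lie_on_both_curves(self, steep, mp):
        ph = Phenotype(Y0=3.5, tau=30.0)
        for fp in fixed_points(ph, steep, mp):
            vd = float(drift_curve(fp.Y_m, ph.tau, steep, mp))
            vfb = float(feedback_drift(fp.Y_m, ph, steep))
            assert abs(vd - vfb) < 1e-6

    def test_stability_labels_match_forward_dynamics(self, steep, mp):
        # iterate the mean-field free-energy relaxation from perturbed
        # starting points and check convergence/divergence
        ph = Phenotype(Y0=3.5, tau=30.0)
        fps = fixed_points(ph, steep, mp)

        def evolve(y_start, T=4000.0, dt=0.05):
            F = np.log(6.0 / y_start - 1.0)
            for _ in range(int(T / dt)):
                y = 6.0 / (1.0 + np.exp(F))
                vd = float(drift_curve(y, ph.tau, steep, mp))
                F += dt * ((ph.F0 - F) / ph.tau + 6.0 * steep.g * vd)
            return 6.0 / (1.0 + np.exp(F))

        for fp in fps:
            if fp.stability == "stable":
                assert evolve(fp.Y_m + 0.05) == pytest.approx(fp.Y_m,
                                                              abs=0.02)
            else:
                far = evolve(fp.Y_m + 0.05)
                assert abs(far - fp.Y_m) > 0.2

    def test_scan_crosses_bifurcation_window(self, steep, mp):
        counts = [len(fixed_points(Phenotype(Y0=float(y0), tau=30.0),
                                   steep, mp))
                  for y0 in (2.5, 3.0, 3.5, 4.0, 4.8)]
        assert counts[0] == 1 and counts[-1] == 1
        assert 3 in counts


class TestMotorAdaptedTheory:
    def test_quasi_steady_eps3_invariant_to_rate_rescaling(self):
        # the joint FliM root depends only on the k_on/k_off ratio
        mp1 = MotorParams(adapt=True)
        mp2 = MotorParams(adapt=True, k_on=0.025e-3, k_off=0.0063e-3)
        y = np.linspace(1.0, 4.0, 30)
        assert np.allclose(eps3_quasi_steady(y, mp1),
                           eps3_quasi_steady(y, mp2), atol=1e-6)

    def test_adaptation_reshapes_high_chey_p_drift(self, steep, mp_adapt,
                                                   mp):
        # remodelling lifts the drift curve at low Y_m (resensitised ring)
        y = np.array([1.6, 1.8])
        ad = motor_adapted_drift(y, 30.0, steep, mp_adapt)
        plain = drift_curve(y, 30.0, steep, mp)
        assert np.all(ad > plain)

    def test_adaptation_moves_optimum_to_lower_chey_p(self, shallow,
                                                      mp_adapt, mp):
        y = np.arange(1.0, 4.0, 0.01)
        y_ad = y[np.argmax(motor_adapted_drift(y, 10.0, shallow, mp_adapt))]
        y_plain = y[np.argmax(drift_curve(y, 10.0, shallow, mp))]
        assert y_ad < y_plain

    def test_trap_phenotype_rescued_to_low_chey_p_state(self, steep,
                                                        mp_adapt):
        vd, ym, _ = steady_state_drift(Phenotype(Y0=3.5, tau=30.0), steep,
                                       mp_adapt, motor_adapt=True)
        assert vd > 3.0
        assert 1.4 < ym < 1.8


class TestOptimaAndMaps:
    def test_shallow_optimum_weakly_depends_on_adaptation_time(self,
                                                               shallow, mp):
        grid = np.arange(2.0, 3.2, 0.02)
        y5, _, _ = optimal_y0(5.0, shallow, mp, y0_grid=grid)
        y30, _, _ = optimal_y0(30.0, shallow, mp, y0_grid=grid)
        assert abs(y5 - y30) < 0.15

    def test_map_normalisation_and_maximin(self, mp_adapt):
        taus = np.linspace(2.0, 20.0, 6)
        tb0s = np.geomspace(0.02, 0.3, 6)
        pm = phenotype_map(taus, tb0s, [1 / 1000, 1 / 5000], mp_adapt)
        assert pm.relative.min() >= 0.0
        assert pm.relative.max() == pytest.approx(1.0)
        for kg in range(2):
            assert pm.relative[kg].max() == pytest.approx(1.0)
        assert 0.0 < pm.maximin_value <= 1.0

    def test_steep_optima_prefer_fast_adaptation_high_bias(self, mp_adapt):
        taus = np.linspace(2.0, 25.0, 8)
        tb0s = np.geomspace(0.02, 0.3, 8)
        pm = phenotype_map(taus, tb0s, [1 / 1000, 1 / 5000], mp_adapt)
        steep_idx = np.unravel_index(pm.vd[0].argmax(), pm.vd[0].shape)
        shallow_idx = np.unravel_index(pm.vd[1].argmax(), pm.vd[1].shape)
        assert taus[steep_idx[0]] <= taus[shallow_idx[0]]
        assert tb0s[steep_idx[1]] >= tb0s[shallow_idx[1]]


class TestChemotaxisCoefficient:
    def test_independent_of_gradient_in_linear_regime(self, mp):
        ph = Phenotype(Y0=2.4, tau=10.0)
        chis = [chemotaxis_coefficient(ph, Environment(g=g), mp)
                for g in (1 / 5000, 1 / 10000)]
        assert chis[0] == pytest.approx(chis[1], rel=1e-9)

    def test_proportional_to_receptor_gain(self, shallow, mp):
        ph = Phenotype(Y0=2.4, tau=10.0)
        assert chemotaxis_coefficient(ph, shallow, mp, N=12.0) == \
            pytest.approx(2 * chemotaxis_coefficient(ph, shallow, mp, N=6.0),
                          rel=1e-12)

    def test_vanishes_without_adaptation_memory(self, shallow, mp):
        chi_fast = chemotaxis_coefficient(Phenotype(Y0=2.4, tau=1e-6),
                                          shallow, mp)
        chi_ref = chemotaxis_coefficient(Phenotype(Y0=2.4, tau=10.0),
                                         shallow, mp)
        assert chi_fast < 1e-3 * chi_ref
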