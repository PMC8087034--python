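"""Core model mechanics: simulation, steady states, Θ maps, oracles."""

import numpy as np
import pytest
from scipy import signal

from bvselect.models import (ConsistencyError, FluidProtocol, ModelParameters,
                             RegressorCoefficients, TrajectoryEvaluator,
                             ValidationError, delta_bv_at, params_to_theta,
                             simulate, state_matrices, steady_state_response,
                             theta_to_params, transfer_function)
from conftest import random_params


def _dlsim_oracle(params, protocol):
    """Independent ZOH discretization via scipy cont2discrete + dlsim."""
    A, B = state_matrices(params)
    A4, B4 = A[:4, :4], B[:4, :]
    C = np.array([[1.0, 0.0, 0.0, 0.0]])
    D = np.zeros((1, 2))
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A4, B4, C, D), protocol.dt,
                                             method="zoh")
    u = np.column_stack([protocol.infusion_rate, protocol.hemorrhage_rate])
    _, y, _ = signal.dlsim((Ad, Bd, Cd, Dd, protocol.dt), u)
    return y.ravel()


def _tf_oracle(params, protocol):
    """Frequency-domain oracle: per-channel rational transfer functions."""
    tf = transfer_function(params)
    out = np.zeros(len(protocol.time))
    for num, series, sign in ((tf.num_u, protocol.infusion_rate, 1.0),
                              (tf.num_v, protocol.hemorrhage_rate, -1.0)):
        ad, bd, cd, dd, _ = signal.cont2discrete(
            signal.tf2ss(num, tf.den), protocol.dt, method="zoh")
        _, y, _ = signal.dlsim((ad, bd, cd, dd, protocol.dt), series)
        out += sign * y.ravel()
    return out


class TestSimulate:
    def test_zero_input_stays_at_rest(self, original_params):
        t = np.arange(0.0, 60.5, 0.5)
        protocol = FluidProtocol(t, np.zeros_like(t), np.zeros_like(t))
        res = simulate(original_params, protocol)
        assert np.allclose(res.delta_bv, 0.0)
        assert np.allclose(res.q, 0.0)
        assert np.allclose(res.r_bv, 0.0)

    @pytest.mark.parametrize("variant", ["original", "refined"])
    def test_conservation_of_volume(self, variant, fixed_protocol):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = random_params(variant, rng)
            res = simulate(p, fixed_protocol)
            balance = (fixed_protocol.cumulative_infused()
                       - fixed_protocol.cumulative_lost())
            err = np.abs(res.delta_bv + res.interstitial_change - balance)
            assert err.max() < 1e-6 * max(np.abs(balance).max(), 1.0)

    def test_refined_with_zero_state_parameters_nests_original(
            self, original_params, fixed_protocol):
        refined = ModelParameters("refined", alpha_u=1.72, alpha_v=1.06,
                                  Kp=0.08, Ki=0.003, A_u=0.0, A_v=0.0)
        a = simulate(original_params, fixed_protocol).delta_bv
        b = simulate(refined, fixed_protocol).delta_bv
        assert np.max(np.abs(a - b)) < 1e-8 * max(np.abs(a).max(), 1.0)

    def test_bolus_reaches_retained_fraction(self):
        # 1000 ml infused over 10 min with alpha_u = 1: half is retained
        # intravascularly at steady state
        t = np.arange(0.0, 2000.5, 0.5)
        u = np.where(t < 10.0, 100.0, 0.0)
        p = ModelParameters("original", alpha_u=1.0, alpha_v=0.5,
                            Kp=0.1, Ki=0.01)
        res = simulate(p, FluidProtocol(t, u, np.zeros_like(t)))
        assert res.delta_bv[-1] == pytest.approx(500.0, rel=1e-3)

    def test_superposition(self, refined_params, fixed_protocol):
        t = fixed_protocol.time
        u1 = fixed_protocol.infusion_rate
        u2 = np.where(t < 40, 10.0, 0.0)
        v = fixed_protocol.hemorrhage_rate
        resp = {}
        for name, (uu, vv) in {"u1": (u1, 0 * v), "u2": (u2, 0 * v),
                               "v": (0 * u1, v),
                               "mix": (2 * u1 + 3 * u2, v)}.items():
            resp[name] = simulate(refined_params,
                                  FluidProtocol(t, uu, vv)).delta_bv
        combo = 2 * resp["u1"] + 3 * resp["u2"] + resp["v"]
        assert np.max(np.abs(combo - resp["mix"])) < 1e-6

    def test_tracking_error_decays_after_inputs_cease(self, original_params):
        t = np.arange(0.0, 3000.0, 1.0)
        v = np.where(t < 15.0, 60.0, 0.0)
        res = simulate(original_params, FluidProtocol(t, np.zeros_like(t), v))
        assert abs(res.e_bv[-1]) < 1e-3
        assert np.allclose(res.e_bv, res.r_bv - res.delta_bv)

    @pytest.mark.parametrize("variant", ["original", "refined"])
    def test_matches_independent_discretization_oracle(self, variant,
                                                       fixed_protocol):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = random_params(variant, rng)
            mine = simulate(p, fixed_protocol).delta_bv
            oracle = _dlsim_oracle(p, fixed_protocol)
            assert np.max(np.abs(mine - oracle)) < 1e-6

    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValidationError, match="uniform"):
            FluidProtocol(np.array([0.0, 1.0, 3.0]), np.zeros(3), np.zeros(3))

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValidationError, match="Kp"):
            ModelParameters("original", alpha_u=1.0, alpha_v=1.0,
                            Kp=-0.1, Ki=0.01)
        with pytest.raises(ValidationError, match="alpha_u"):
            ModelParameters("original", alpha_u=-1.5, alpha_v=1.0,
                            Kp=0.1, Ki=0.01)
        with pytest.raises(ValidationError, match="A_u"):
            ModelParameters("refined", alpha_u=1.0, alpha_v=1.0,
                            Kp=0.1, Ki=0.01, A_u=0.2, A_v=-0.1)

    def test_evaluator_matches_dense_simulation(self, refined_params,
                                                fixed_protocol):
        times = np.array([0.0, 5.0, 17.0, 60.0, 120.0, 180.0])
        fast = delta_bv_at(refined_params, fixed_protocol, times)
        dense = simulate(refined_params, fixed_protocol).delta_bv
        idx = np.rint(times / fixed_protocol.dt).astype(int)
        assert np.max(np.abs(fast - dense[idx])) < 1e-9

    def test_evaluator_rejects_off_grid_times(self, refined_params,
                                              fixed_protocol):
        with pytest.raises(ValidationError, match="grid"):
            TrajectoryEvaluator(fixed_protocol, np.array([0.5 * np.pi]))


class TestSteadyState:
    def test_retained_fraction(self):
        p = ModelParameters("original", alpha_u=1.0, alpha_v=0.5,
                            Kp=0.1, Ki=0.01)
        assert steady_state_response(p, 1000.0, 0.0) == pytest.approx(500.0)
        assert steady_state_response(p, 0.0, 0.0) == 0.0
        assert steady_state_response(p, 300.0, 300.0) == pytest.approx(
            300.0 / 2.0 - 300.0 / 1.5)

    def test_refined_decaying_targets_vanish(self, fixed_protocol):
        p = ModelParameters("refined", alpha_u=0.5, alpha_v=0.5,
                            Kp=0.1, Ki=0.01, A_u=-0.1, A_v=-0.01)
        assert steady_state_response(p, 1234.0, 567.0) == 0.0
        # cross-check against a long-horizon simulation
        t = np.arange(0.0, 5000.0, 1.0)
        u = np.where(t < 10.0, 100.0, 0.0)
        v = np.where((t >= 20) & (t < 30), 50.0, 0.0)
        res = simulate(p, FluidProtocol(t, u, v))
        assert abs(res.delta_bv[-1]) < 1e-3

    def test_mixed_channel_states(self):
        p = ModelParameters("refined", alpha_u=1.0, alpha_v=0.5,
                            Kp=0.1, Ki=0.01, A_u=-0.1, A_v=0.0)
        # decaying infusion target, persistent loss target
        assert steady_state_response(p, 1000.0, 300.0) == pytest.approx(
            -300.0 / 1.5)


class TestThetaMaps:
    def test_hand_worked_original_coefficients(self):
        p = ModelParameters("original", alpha_u=1.0, alpha_v=0.5,
                            Kp=0.1, Ki=0.01)
        theta = params_to_theta(p).theta
        expected = [-0.1, -0.01, 1.0, 0.05, -1.0 / 15.0, 0.005, -1.0 / 150.0]
        np.testing.assert_allclose(theta, expected, rtol=1e-12)
        recovered = theta_to_params(params_to_theta(p))
        np.testing.assert_allclose(recovered.free_values(), p.free_values(),
                                   rtol=1e-8)

    @pytest.mark.parametrize("variant", ["original", "refined"])
    def test_unit_regressor_entry(self, variant):
        rng = np.random.default_rng(2)
        p = random_params(variant, rng)
        theta = params_to_theta(p).theta
        pos = 2 if variant == "original" else 4
        assert theta[pos] == 1.0

    @pytest.mark.parametrize("variant", ["original", "refined"])
    def test_round_trip_identity(self, variant):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = random_params(variant, rng)
            back = theta_to_params(params_to_theta(p))
            rel = np.abs(back.free_values() - p.free_values()) / \
                np.maximum(np.abs(p.free_values()), 1e-6)
            assert rel.max() < 1e-6

    def test_inconsistent_theta_rejected(self):
        p = ModelParameters("original", alpha_u=1.0, alpha_v=0.5,
                            Kp=0.1, Ki=0.01)
        theta = params_to_theta(p).theta.copy()
        theta[3] *= 1.5
        with pytest.raises(ConsistencyError, match="entries"):
            theta_to_params(RegressorCoefficients("original", theta))

    def test_complex_state_parameters_rejected(self):
        # entries 1-4 of an underdamped quartic with no real factor pair
        theta = params_to_theta(ModelParameters(
            "refined", alpha_u=0.2, alpha_v=0.6, Kp=0.28, Ki=0.01,
            A_u=-0.16, A_v=-0.007)).theta.copy()
        # make the (A_u, A_v) quadratic complex: p^2 < 4q
        theta[0] = -0.5   # inconsistent char polynomial
        theta[1] = -0.2
        theta[2] = -0.1
        theta[3] = -0.05
        with pytest.raises(ConsistencyError):
            theta_to_params(RegressorCoefficients("refined", theta))


class TestTransferFunction:
    def test_original_polynomials(self):
        p = ModelParameters("original", alpha_u=1.0, alpha_v=0.5,
                            Kp=0.1, Ki=0.01)
        tf = transfer_function(p)
        np.testing.assert_allclose(tf.den, [1.0, 0.1, 0.01, 0.0])
        np.testing.assert_allclose(tf.num_u, [1.0, 0.05, 0.005])
        np.testing.assert_allclose(tf.num_v, [1.0, 0.1 / 1.5, 0.01 / 1.5])

    @pytest.mark.parametrize("variant", ["original", "refined"])
    def test_denominator_structure(self, variant):
        rng = np.random.default_rng(23)
        p = random_params(variant, rng)
        tf = transfer_function(p)
        assert tf.den[0] == 1.0  # monic
        roots = np.roots(tf.den)
        assert np.all(roots.real <= 1e-12)
        if variant == "original":
            assert len(tf.den) == 4
            assert np.min(np.abs(roots)) < 1e-12  # pure integrator
        else:
            assert len(tf.den) == 5

    @pytest.mark.parametrize("variant", ["original", "refined"])
    def test_step_response_matches_time_domain(self, variant, fixed_protocol):
        rng = np.random.default_rng(29)
        for _ in range(3):
            p = random_params(variant, rng)
            mine = simulate(p, fixed_protocol).delta_bv
            oracle = _tf_oracle(p, fixed_protocol)
            assert np.max(np.abs(mine - oracle)) < 1e-6
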