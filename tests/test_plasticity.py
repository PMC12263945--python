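import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasticlearn import EventTimes, PlasticityParams
from plasticlearn.plasticity import (
    decayed_eta,
    hebbian_drive,
    normalize_weights,
    stdp_delta,
    stdp_pair_drive,
    step_weights,
)

from conftest import make_network


class TestDrives:
    @pytest.mark.parametrize(
        "a_pre,a_post,expected", [(0.0, 0.9, 0.0), (1.0, 1.0, 1.0), (0.5, 0.4, 0.2)]
    )
    def test_hebbian_drive_is_activity_product(self, a_pre, a_post, expected):
        assert hebbian_drive(a_pre, a_post) == pytest.approx(expected, abs=1e-15)

    def test_stdp_potentiation_and_depression_branches(self):
        p = PlasticityParams(A_plus=1.0, A_minus=1.0, tau_plus=2.0, tau_minus=3.0)
        assert stdp_delta(1e-12, p) == pytest.approx(1.0, rel=1e-9)
        assert stdp_delta(2.0, p) == pytest.approx(math.exp(-1), rel=1e-12)
        assert stdp_delta(-3.0, p) == pytest.approx(-math.exp(-1), rel=1e-12)
        assert stdp_delta(0.0, p) == 0.0

    @given(dt=st.floats(min_value=1e-6, max_value=50, allow_nan=False))
    def test_stdp_delta_sign_matches_timing_order(self, dt):
        p = PlasticityParams(A_plus=0.8, A_minus=0.6)
        assert stdp_delta(dt, p) > 0
        assert stdp_delta(-dt, p) < 0

    def test_pair_drive_cancels_for_symmetric_magnitudes(self):
        p = PlasticityParams(A_plus=0.7, A_minus=0.7)
        assert stdp_pair_drive(0.9, 0.8, 1.0, 3.0, p) == 0.0

    @pytest.mark.parametrize(
        "A_plus,A_minus,dt_gap,expected",
        [(1.0, 0.0, 0.0, 1.0), (1.0, 0.5, 1.0, 0.5 * math.exp(-1))],
    )
    def test_pair_drive_closed_form_values(self, A_plus, A_minus, dt_gap, expected):
        p = PlasticityParams(A_plus=A_plus, A_minus=A_minus, tau_pair=1.0)
        assert stdp_pair_drive(1.0, 1.0, 0.0, dt_gap, p) == pytest.approx(
            expected, rel=1e-12
        )

    @given(
        a_pre=st.floats(0, 1),
        a_post=st.floats(0, 1),
        t_pre=st.floats(0, 10),
        t_post=st.floats(0, 10),
        A_plus=st.floats(0, 2),
        A_minus=st.floats(0, 2),
    )
    @settings(max_examples=200)
    def test_pair_drive_matches_algebraic_reduction(
        self, a_pre, a_post, t_pre, t_post, A_plus, A_minus
    ):
        # the two printed terms share |Δt|, so they reduce to a single term
        p = PlasticityParams(A_plus=A_plus, A_minus=A_minus, tau_pair=1.5)
        reduced = (A_plus - A_minus) * a_pre * a_post * math.exp(
            -abs(t_pre - t_post) / 1.5
        )
        assert stdp_pair_drive(a_pre, a_post, t_pre, t_post, p) == pytest.approx(
            reduced, abs=1e-12
        )

    def test_pair_drive_without_events_is_zero(self):
        p = PlasticityParams()
        assert stdp_pair_drive(1.0, 1.0, math.nan, 2.0, p) == 0.0


class TestStepWeights:
    def test_zero_field_leaves_weights_unchanged(self):
        net = make_network([[0, 0.4, 0.3], [0.2, 0, 0], [0, 0.1, 0]])
        p = PlasticityParams(weight_decay=0.0)
        before = net.weights.copy()
        step_weights(net, 0.0, p, dt=0.1)  # eta=0 makes the drive term vanish
        assert np.array_equal(net.weights, before)

    def test_pure_decay_matches_exponential_closed_form(self):
        # dw/dt = -beta w from w0=1 integrated to t=2 -> e^{-1}
        net = make_network([[0, 1.0], [0, 0]], activations=[0.0, 0.0])
        p = PlasticityParams(weight_decay=0.5, w_max=10.0)
        dt = 1e-3
        for _ in range(2000):
            step_weights(net, 0.0, p, dt)
        assert net.weights[0, 1] == pytest.approx(math.exp(-1), abs=1e-3)

    def test_euler_sum_is_exact_without_decay(self):
        # constant drive F=1 (unit activations, hebbian), beta=0:
        # 10 steps of eta*F*dt = 0.1*1*0.1 accumulate to exactly 0.1
        net = make_network([[0, 1e-12], [0, 0]], activations=[1.0, 1.0])
        net.weights[0, 1] = 0.0
        p = PlasticityParams(weight_decay=0.0)
        for _ in range(10):
            step_weights(net, 0.1, p, dt=0.1)
        assert net.weights[0, 1] == pytest.approx(0.1, abs=1e-15)

    def test_constant_drive_matches_affine_ode_solution(self):
        # dw/dt = eta*F0 - beta*w  ->  w0 e^{-bt} + (eta F0/b)(1 - e^{-bt})
        eta, beta, w0, T, dt = 0.2, 0.8, 1.5, 2.0, 0.01
        net = make_network([[0, w0], [0, 0]], activations=[1.0, 1.0])
        p = PlasticityParams(weight_decay=beta, w_max=10.0)
        for _ in range(int(T / dt)):
            step_weights(net, eta, p, dt)
        exact = w0 * math.exp(-beta * T) + (eta / beta) * (1 - math.exp(-beta * T))
        assert abs(net.weights[0, 1] - exact) < 10 * dt

    def test_first_order_convergence_halving_dt_halves_error(self):
        beta, w0, T = 0.5, 1.0, 2.0
        exact = w0 * math.exp(-beta * T)
        errors = []
        for dt in (0.1, 0.05, 0.025):
            net = make_network([[0, w0], [0, 0]], activations=[0.0, 0.0])
            p = PlasticityParams(weight_decay=beta, w_max=10.0)
            for _ in range(round(T / dt)):
                step_weights(net, 0.0, p, dt)
            errors.append(abs(net.weights[0, 1] - exact))
        for coarse, fine in zip(errors, errors[1:]):
            assert coarse / fine == pytest.approx(2.0, rel=0.15)

    def test_weights_clamped_to_bounds(self):
        net = make_network([[0, 4.9, 0.05], [0, 0, 0], [0, 0.06, 0]],
                           activations=[1.0, 1.0, 1.0])
        p = PlasticityParams(weight_decay=5.0, w_min=0.03, w_max=5.0)
        for _ in range(50):
            step_weights(net, 10.0, p, dt=0.5)
            w = net.weights[net.mask]
            assert np.all(w >= 0.03) and np.all(w <= 5.0)

    def test_non_finite_result_names_the_synapse(self):
        net = make_network([[0, 1.0], [0, 0]], activations=[1.0, 1.0])
        net.weights[0, 1] = 1e308
        p = PlasticityParams(weight_decay=1e300, w_max=np.inf)
        with pytest.raises(FloatingPointError, match=r"\(0, 1\)"):
            step_weights(net, 0.0, p, dt=1e8)


class TestEtaScheduleAndNormalization:
    def test_decayed_eta_fixed_points(self):
        p = PlasticityParams(eta0=0.04, lr_time_decay=2.0)
        assert decayed_eta(0.0, p) == 0.04
        assert decayed_eta(0.5, p) == pytest.approx(0.04 * math.exp(-1), rel=1e-12)
        flat = PlasticityParams(eta0=0.04, lr_time_decay=0.0)
        assert decayed_eta(100.0, flat) == 0.04

    def test_zero_gamma_is_identity(self):
        net = make_network([[0, 0.7, 0.2], [0.3, 0, 0], [0, 0, 0]])
        before = net.weights.copy()
        normalize_weights(net, 0.0)
        assert np.array_equal(net.weights, before)

    def test_row_normalization_direct_substitution(self):
        net = make_network([[0, 1.0, 1.0], [0, 0, 0], [0, 0, 0]])
        normalize_weights(net, 0.5)  # denominator 1 + 0.5*2 = 2
        assert net.weights[0, 1] == pytest.approx(0.5)
        assert net.weights[0, 2] == pytest.approx(0.5)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=8),
           st.floats(0.01, 5.0))
    @settings(max_examples=100)
    def test_normalized_row_sum_below_reciprocal_gamma(self, row, gamma):
        n = len(row) + 1
        w = np.zeros((n, n))
        w[0, 1:] = row
        net = make_network(w)
        normalize_weights(net, gamma)
        assert net.weights[0].sum() < 1.0 / gamma
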