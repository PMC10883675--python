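"""Tissue dynamics: rectified current, leaky integrator, thresholds, trace."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortiphos import DynamicsParams
from cortiphos.dynamics import (DutyCycleError, brightness, effective_current,
                                sample_thresholds, update_activation,
                                update_trace)

D = DynamicsParams()
MICRO = 1e-6


# -- effective current ------------------------------------------------------


def test_subrheobase_amplitude_yields_no_effective_current():
    assert effective_current(20e-6, D.I0, 0.0, 170e-6, 300.0) == 0.0


def test_rectification_boundary_at_the_rheobase():
    assert effective_current(D.I0, D.I0, 0.0, 170e-6, 300.0) == 0.0


def test_effective_current_hand_value():
    # (100 - 23.9) uA times duty cycle 170e-6 * 300 = 0.051
    got = effective_current(100e-6, D.I0, 0.0, 170e-6, 300.0)
    assert got == pytest.approx(3.8811e-6, rel=1e-9)


def test_memory_trace_subtracts_from_the_drive():
    with_trace = effective_current(100e-6, D.I0, 10e-6, 170e-6, 300.0)
    without = effective_current(100e-6, D.I0, 0.0, 170e-6, 300.0)
    assert with_trace == pytest.approx(without - 10e-6 * 0.051, rel=1e-9)


def test_duty_cycle_above_one_is_rejected():
    with pytest.raises(DutyCycleError):
        effective_current(100e-6, D.I0, 0.0, 5e-3, 300.0)


def test_smooth_rectifier_approaches_the_hard_one_far_from_zero():
    hard = effective_current(100e-6, D.I0, 0.0, 170e-6, 300.0)
    soft = effective_current(100e-6, D.I0, 0.0, 170e-6, 300.0,
                             mode="smooth", sharpness=1e9)
    assert soft == pytest.approx(hard, rel=1e-3)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(amp=st.floats(0, 30e-6), B=st.floats(0, 50e-6),
       pw=st.floats(10e-6, 500e-6), f=st.floats(1.0, 1000.0))
def test_rectification_property_no_output_at_or_below_leak(amp, B, pw, f):
    if pw * f > 1.0 or amp > D.I0 + B:
        return
    assert effective_current(amp, D.I0, B, pw, f) == 0.0


# -- leaky integrator -------------------------------------------------------


def test_quiescence_is_a_fixed_point():
    assert update_activation(0.0, 0.0, 1e-3, D.tau_act) == 0.0
    assert update_trace(0.0, 0.0, 1e-3, D.tau_trace, D.kappa) == 0.0


def test_activation_converges_to_analytic_steady_state():
    dt = D.tau_act / 100
    I_eff = 3.8811e-6
    A = 0.0
    for _ in range(3000):  # ~3.3 s >> tau_act
        A = update_activation(A, I_eff, dt, D.tau_act, d=1.0)
    assert A == pytest.approx(I_eff * 1.0 * D.tau_act, rel=0.01)


def test_activation_half_life_matches_exponential_decay():
    dt = D.tau_act / 1000
    x = 1e-6
    A = x
    for _ in range(round(np.log(2) * 1000)):
        A = update_activation(A, 0.0, dt, D.tau_act)
    assert A == pytest.approx(x / 2, rel=5e-3)


def test_trace_half_life_matches_printed_time_constant():
    dt = 1.0  # dt << tau_trace = 1970 s
    B = 1e-6
    n = round(D.tau_trace * np.log(2))  # ~1365.5 s of simulated time
    for _ in range(n):
        B = update_trace(B, 0.0, dt, D.tau_trace, D.kappa)
    assert B == pytest.approx(1e-6 / 2, rel=2e-3)


def test_euler_update_converges_at_first_order():
    I_eff, T, tau = 2e-6, 0.2, D.tau_act
    exact = I_eff * tau * (1 - np.exp(-T / tau))

    def final(dt):
        A = 0.0
        for _ in range(round(T / dt)):
            A = update_activation(A, I_eff, dt, tau)
        return A

    e1 = abs(final(1e-3) - exact)
    e2 = abs(final(5e-4) - exact)
    assert 1.5 < e1 / e2 < 3.0  # halving dt ~halves the error


def test_duration_scale_d_scales_the_input():
    a_full = update_activation(0.0, 1e-6, 1e-3, D.tau_act, d=1.0)
    a_half = update_activation(0.0, 1e-6, 1e-3, D.tau_act, d=0.5)
    assert a_half == pytest.approx(a_full / 2)


# -- thresholds -------------------------------------------------------------


def test_degenerate_sigma_gives_identical_thresholds():
    thr = sample_thresholds(100, D.theta50, 0.0, seed=1)
    assert np.all(thr == D.theta50)


def test_threshold_sample_mean_matches_distribution():
    n = 100_000
    thr = sample_thresholds(n, D.theta50, D.sigma_thr, seed=12345)
    assert np.all(thr > 0)
    # redrawing negatives truncates: compare against the truncated-normal mean
    from scipy.stats import truncnorm
    a = (0 - D.theta50) / D.sigma_thr
    expected = truncnorm.mean(a, np.inf, loc=D.theta50, scale=D.sigma_thr)
    se = D.sigma_thr / np.sqrt(n)
    assert abs(thr.mean() - expected) < 3 * se


def test_thresholds_are_deterministic_given_seed():
    a = sample_thresholds(1000, D.theta50, D.sigma_thr, seed=7)
    b = sample_thresholds(1000, D.theta50, D.sigma_thr, seed=7)
    np.testing.assert_array_equal(a, b)


# -- brightness -------------------------------------------------------------


def test_brightness_midpoint_is_exactly_half():
    assert brightness(D.A50, D.A50 / 2, D.lambda_b, D.A50) == 0.5


def test_brightness_is_gated_below_threshold():
    assert brightness(0.0, D.theta50, D.lambda_b, D.A50) == 0.0
    assert brightness(D.theta50 * 0.99, D.theta50, D.lambda_b, D.A50) == 0.0


def test_brightness_sigmoid_hand_value():
    A = D.A50 + 10.0 / D.lambda_b
    got = brightness(A, D.theta50, D.lambda_b, D.A50)
    assert got == pytest.approx(1.0 / (1.0 + np.exp(-10.0)), rel=1e-12)


def test_smooth_gate_tracks_the_hard_gate_away_from_threshold():
    A = np.array([0.0, D.theta50 * 0.5, D.A50, D.A50 * 2])
    hard = brightness(A, D.theta50, D.lambda_b, D.A50, mode="hard")
    soft = brightness(A, D.theta50, D.lambda_b, D.A50, mode="smooth",
                      gate_sharpness=1e12)
    np.testing.assert_allclose(soft, hard, atol=1e-6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(amp=st.floats(30e-6, 500e-6), scale=st.floats(1.01, 2.0))
def test_brightness_after_a_train_is_monotone_in_amplitude(amp, scale):
    def bright_after_train(amplitude):
        A = 0.0
        for _ in range(10):
            I_eff = effective_current(amplitude, D.I0, 0.0, 170e-6, 300.0)
            A = update_activation(A, I_eff, 0.01, D.tau_act)
        return brightness(A, D.theta50 * 1e-6, D.lambda_b, D.A50)

    assert bright_after_train(amp * scale) >= bright_after_train(amp)


def test_repeated_trains_habituate_brightness():
    """The memory trace makes successive identical trains dimmer."""
    A = B = 0.0
    dt = 0.01
    peaks = []
    for _ in range(5):  # trains of 10 frames, 40-frame gaps
        peak = 0.0
        for _ in range(10):
            I_eff = effective_current(200e-6, D.I0, B, 170e-6, 300.0)
            A = update_activation(A, I_eff, dt, D.tau_act)
            B = update_trace(B, I_eff, dt, D.tau_trace, D.kappa)
            peak = max(peak, brightness(A, D.theta50, D.lambda_b, D.A50))
        for _ in range(40):
            A = update_activation(A, 0.0, dt, D.tau_act)
            B = update_trace(B, 0.0, dt, D.tau_trace, D.kappa)
        peaks.append(peak)
    assert np.all(np.diff(peaks) <= 0) and peaks[-1] < peaks[0]
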