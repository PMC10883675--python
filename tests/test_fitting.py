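"""Parameter recovery on synthetic psychometric data."""
import numpy as np
import pytest

from cortiphos import DynamicsParams
from cortiphos import fitting as fit

D = DynamicsParams()


# -- generators -------------------------------------------------------------


def test_subrheobase_conditions_never_detect():
    conds = fit.make_conditions([5.0, 15.0, 23.9])
    data = fit.generate_detection_data(D, conds, n_trials=200, seed=1)
    assert np.all(data["n_detected"] == 0)


def test_detection_rate_is_half_at_the_mean_threshold():
    amp = fit.amplitude_for_activation(D.theta50, 170.0, 300.0, 0.166, D)
    conds = fit.make_conditions([amp])
    data = fit.generate_detection_data(D, conds, n_trials=10_000, seed=2)
    rate = data["n_detected"].iloc[0] / data["n_trials"].iloc[0]
    assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / 10_000)


def test_generators_are_deterministic_given_seed():
    conds = fit.make_conditions(np.linspace(25, 120, 10))
    a = fit.generate_detection_data(D, conds, 100, seed=9)
    b = fit.generate_detection_data(D, conds, 100, seed=9)
    assert a.equals(b)


def test_activation_inversion_round_trips():
    amp = fit.amplitude_for_activation(5e-7, 170.0, 300.0, 0.166, D)
    back = fit.simulate_train_activation(amp, 170.0, 300.0, 0.166, D)
    assert back == pytest.approx(5e-7, rel=1e-6)


# -- threshold distribution fit --------------------------------------------


def test_threshold_distribution_recovery_within_ten_percent():
    conds = fit.make_conditions(np.linspace(25, 120, 20))
    data = fit.generate_detection_data(D, conds, n_trials=500, seed=7)
    res = fit.fit_threshold_distribution(data, D)
    assert res.theta50 == pytest.approx(D.theta50, rel=0.10)
    assert res.sigma == pytest.approx(D.sigma_thr, rel=0.10)
    assert res.r_squared > 0.95


def test_degenerate_sigma_generator_recovers_a_tiny_sigma():
    narrow = DynamicsParams(sigma_thr=D.theta50 * 1e-4)
    conds = fit.make_conditions(np.linspace(25, 120, 20))
    data = fit.generate_detection_data(narrow, conds, n_trials=500, seed=3)
    res = fit.fit_threshold_distribution(data, narrow)
    assert res.sigma < 0.05 * res.theta50


def test_balanced_exact_proportions_recover_exactly():
    conds = fit.make_detection_conditions(D, n=20)
    A = np.array([fit.simulate_train_activation(
        row.amplitude_uA, row.pulse_width_us, row.frequency_hz,
        row.duration_ms * 1e-3, D) for row in conds.itertuples()])
    p = fit.detection_probability(A, D.theta50, D.sigma_thr)
    data = conds.copy()
    data["n_trials"] = 1
    data["n_detected"] = p  # noiseless proportions at the Phi quantiles
    res = fit.fit_threshold_distribution(data, D)
    assert res.theta50 == pytest.approx(D.theta50, rel=1e-5)
    assert res.sigma == pytest.approx(D.sigma_thr, rel=1e-4)


def test_one_sided_data_is_non_identifiable():
    conds = fit.make_conditions([5.0, 10.0, 20.0])
    data = fit.generate_detection_data(D, conds, n_trials=100, seed=1)
    with pytest.raises(fit.NonIdentifiableError):
        fit.fit_threshold_distribution(data, D)


# -- brightness sigmoid fit -------------------------------------------------


def test_noiseless_brightness_recovery_within_one_percent():
    conds = fit.make_brightness_conditions(D, n=15)
    data = fit.generate_brightness_data(D, conds)
    res = fit.fit_brightness_sigmoid(data, D)
    assert res.lambda_b == pytest.approx(D.lambda_b, rel=0.01)
    assert res.A50 == pytest.approx(D.A50, rel=0.01)


def test_half_brightness_condition_pins_the_midpoint():
    conds = fit.make_brightness_conditions(D, n=15)
    data = fit.generate_brightness_data(D, conds)
    res = fit.fit_brightness_sigmoid(data, D)
    mid_amp = fit.amplitude_for_activation(res.A50, 170.0, 300.0, 0.166, D)
    A_mid = fit.simulate_train_activation(mid_amp, 170.0, 300.0, 0.166, D)
    assert res.predict(fit.make_conditions([mid_amp]))[0] == pytest.approx(
        0.5, abs=1e-3)
    assert A_mid == pytest.approx(res.A50, rel=1e-6)


def test_noisy_brightness_recovery_within_ten_percent():
    conds = fit.make_brightness_conditions(D, n=15)
    data = fit.generate_brightness_data(D, conds, noise_sd=0.05,
                                        n_repeats=20, seed=5)
    res = fit.fit_brightness_sigmoid(data, D)
    assert res.lambda_b == pytest.approx(D.lambda_b, rel=0.10)
    assert res.A50 == pytest.approx(D.A50, rel=0.10)


def test_underdetermined_brightness_data_is_rejected():
    conds = fit.make_conditions([100.0])
    data = fit.generate_brightness_data(D, conds)
    with pytest.raises(fit.UnderdeterminedError):
        fit.fit_brightness_sigmoid(data, D)


# -- strength-duration fit --------------------------------------------------


def test_noiseless_strength_duration_recovery_is_exact():
    data = fit.generate_strength_duration_data(
        23.9e-6, 1e-3, np.linspace(1e-4, 2e-3, 10))
    model = fit.fit_strength_duration(data["duration_s"], data["charge_thr"])
    assert model.I0 == pytest.approx(23.9e-6, rel=1e-9)
    assert model.chronaxie == pytest.approx(1e-3, rel=1e-9)
    assert not model.degenerate


def test_constant_charge_flags_a_degenerate_chronaxie():
    t = np.linspace(1e-4, 2e-3, 8)
    model = fit.fit_strength_duration(t, np.full_like(t, 5e-8))
    assert model.degenerate and model.chronaxie == np.inf


def test_noisy_strength_duration_recovers_rheobase_within_ten_percent():
    data = fit.generate_strength_duration_data(
        23.9e-6, 1e-3, np.linspace(1e-4, 2e-3, 10), noise_frac=0.05, seed=21)
    model = fit.fit_strength_duration(data["duration_s"], data["charge_thr"])
    assert model.I0 == pytest.approx(23.9e-6, rel=0.10)


def test_too_few_distinct_durations_raise_a_rank_error():
    with pytest.raises(np.linalg.LinAlgError):
        fit.fit_strength_duration([1e-3, 1e-3, 2e-3], [1e-8, 1e-8, 2e-8])


# -- cross-validation -------------------------------------------------------


@pytest.fixture(scope="module")
def cv_data():
    conds = fit.make_conditions(np.linspace(25, 120, 30))
    return fit.generate_detection_data(D, conds, n_trials=500, seed=11)


def test_threefold_crossvalidation_predicts_held_out_conditions(cv_data):
    cv = fit.crossvalidate(cv_data,
                           lambda d: fit.fit_threshold_distribution(d, D),
                           k_folds=3, seed=5)
    assert len(cv.fold_r_squared) == 3
    assert cv.mean_r_squared > 0.8


def test_fold_assignment_is_deterministic(cv_data):
    fitter = lambda d: fit.fit_threshold_distribution(d, D)
    a = fit.crossvalidate(cv_data, fitter, 3, seed=5)
    b = fit.crossvalidate(cv_data, fitter, 3, seed=5)
    assert a.fold_r_squared == b.fold_r_squared


def test_leave_one_condition_out_runs_without_error():
    conds = fit.make_conditions(np.linspace(30, 120, 8))
    data = fit.generate_detection_data(D, conds, n_trials=500, seed=4)
    cv = fit.crossvalidate(data, lambda d: fit.fit_threshold_distribution(d, D),
                           k_folds=len(data), seed=1)
    assert len(cv.fold_r_squared) == len(data)


def test_more_folds_than_conditions_is_a_partition_error(cv_data):
    with pytest.raises(ValueError, match="partition"):
        fit.crossvalidate(cv_data.head(2),
                          lambda d: fit.fit_threshold_distribution(d, D),
                          k_folds=3)


def test_fit_is_invariant_to_condition_order_and_trial_rescaling():
    conds = fit.make_conditions(np.linspace(25, 120, 20))
    data = fit.generate_detection_data(D, conds, n_trials=500, seed=7)
    res = fit.fit_threshold_distribution(data, D)
    shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
    res_shuffled = fit.fit_threshold_distribution(shuffled, D)
    scaled = data.copy()
    scaled["n_trials"] *= 10
    scaled["n_detected"] *= 10
    res_scaled = fit.fit_threshold_distribution(scaled, D)
    for other in (res_shuffled, res_scaled):
        assert other.theta50 == pytest.approx(res.theta50, rel=1e-6)
        assert other.sigma == pytest.approx(res.sigma, rel=1e-6)
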