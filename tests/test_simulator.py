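"""Session façade: determinism, stepping, decomposition, quantizer."""
import numpy as np
import pytest

from cortiphos import (DynamicsParams, InitializationError, PhospheneMap,
                       RunConfig, SimulatorSession, StimFrame,
                       make_grid_layout, quantize_amplitude, sample_thresholds,
                       smooth_staircase)
from cortiphos.io import stimulation_frames

from conftest import stim_array


def make_session(grid, run, **kwargs):
    return SimulatorSession(grid.copy(), run=run, **kwargs)


def test_empty_map_is_rejected(small_run):
    empty = make_grid_layout(1, 1, 0.4, origin=0j)
    empty_map = PhospheneMap(
        w=empty.w[:0], r=empty.r[:0], theta=empty.theta[:0],
        x_deg=empty.x_deg[:0], y_deg=empty.y_deg[:0],
        magnification=empty.magnification[:0],
        hemisphere=empty.hemisphere[:0], active=empty.active[:0])
    with pytest.raises(InitializationError):
        SimulatorSession(empty_map, run=small_run)


def test_identical_seeds_give_identical_sessions_and_frames(small_grid, small_run):
    stim = stim_array(4, len(small_grid), 300.0)
    frames_a = make_session(small_grid, small_run).run_sequence(
        stimulation_frames(stim))
    frames_b = make_session(small_grid, small_run).run_sequence(
        stimulation_frames(stim))
    for fa, fb in zip(frames_a, frames_b):
        np.testing.assert_array_equal(fa.image, fb.image)


def test_degenerate_sigma_fixes_all_thresholds_at_the_mean(small_grid, small_run):
    s = SimulatorSession(small_grid.copy(), run=small_run,
                         dynamics=DynamicsParams(sigma_thr=0.0))
    assert np.all(s.state.Athr == DynamicsParams().theta50)


def test_large_map_initializes(small_run):
    # ~1000 phosphenes over a 16 deg field of view
    g = make_grid_layout(32, 32, 0.25, origin=16 + 0j)
    s = SimulatorSession(g, run=small_run)
    assert len(s.map) == 1024


def test_zero_stimulation_from_quiescence_stays_black(small_grid, small_run):
    s = make_session(small_grid, small_run)
    frame = s.step(StimFrame.from_user(np.zeros(len(small_grid)), 0.0, 0.0))
    assert not frame.image.any()
    assert not s.state.A.any() and not s.state.B.any()


def test_subrheobase_train_produces_only_black_frames(small_grid, small_run):
    n_frames = int(np.ceil(0.166 / small_run.dt))
    stim = stim_array(n_frames, len(small_grid), 20.0, 170.0, 300.0)
    frames = make_session(small_grid, small_run).run_sequence(
        stimulation_frames(stim))
    assert all(not f.image.any() for f in frames)


def test_brightness_decays_smoothly_after_stimulation_offset(small_grid, small_run):
    s = SimulatorSession(small_grid.copy(), run=small_run,
                         dynamics=DynamicsParams(sigma_thr=0.0))
    n = len(small_grid)
    on = stim_array(10, n, 300.0)
    off = stim_array(6, n, 0.0, 0.0, 0.0)
    _, trace = s.run_sequence(stimulation_frames(np.concatenate([on, off])),
                              render=False, record_trace=True)
    A = trace.as_arrays()["A"][:, 0]
    post = A[10:]
    assert np.all(post > 0)                   # delayed offset, not a cut
    assert np.all(np.diff(post) < 0)          # smooth exponential decay
    ratios = post[1:] / post[:-1]
    np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)


def test_nan_input_is_rejected_with_frame_and_electrode(small_grid, small_run):
    s = make_session(small_grid, small_run)
    amps = np.zeros(len(small_grid))
    amps[4] = np.nan
    with pytest.raises(ValueError, match=r"frame 0.*\[4\]"):
        s.step(StimFrame.from_user(amps, 170.0, 300.0))


def test_empty_sequence_gives_empty_output(small_grid, small_run):
    assert make_session(small_grid, small_run).run_sequence([]) == []


def test_split_and_resumed_run_is_bit_identical(small_grid, small_run):
    stim = stim_array(8, len(small_grid), 250.0)
    full = make_session(small_grid, small_run).run_sequence(
        stimulation_frames(stim))
    s1 = make_session(small_grid, small_run)
    part1 = s1.run_sequence(stimulation_frames(stim[:3]))
    snapshot = s1.export_state()
    s2 = make_session(small_grid, small_run)
    s2.import_state(snapshot)
    part2 = s2.run_sequence(stimulation_frames(stim[3:]))
    for fa, fb in zip(full, part1 + part2):
        np.testing.assert_array_equal(fa.image, fb.image)


def test_dropped_electrodes_contribute_nothing(small_grid, small_run):
    g = small_grid.copy()
    g.active[:] = False
    g.active[0] = True
    stim = stim_array(5, len(g), 300.0)
    s = SimulatorSession(g, run=small_run,
                         dynamics=DynamicsParams(sigma_thr=0.0))
    _, trace = s.run_sequence(stimulation_frames(stim), render=False,
                              record_trace=True)
    bright = trace.as_arrays()["brightness"]
    assert np.all(bright[:, 1:] == 0.0)
    assert np.any(bright[:, 0] > 0)


def test_composed_frame_equals_sum_of_single_electrode_runs(small_grid):
    run = RunConfig(resolution=(64, 64), dt=1 / 30, seed=3, clip_mode="none")
    n = len(small_grid)
    stim = stim_array(6, n, 300.0)
    total = make_session(small_grid, run).run_sequence(
        stimulation_frames(stim))[-1].image
    thresholds = sample_thresholds(n, DynamicsParams().theta50,
                                   DynamicsParams().sigma_thr, seed=run.seed)
    acc = np.zeros_like(total)
    for e in range(n):
        solo = np.zeros_like(stim)
        solo[:, e, :] = stim[:, e, :]
        g = small_grid.copy()
        g.thresholds = thresholds.copy()
        acc += make_session(g, run).run_sequence(
            stimulation_frames(solo))[-1].image
    np.testing.assert_allclose(acc, total, atol=1e-12)


def test_amplitude_increase_raises_both_brightness_and_size(small_grid, small_run):
    def last_state(amplitude):
        s = SimulatorSession(small_grid.copy(), run=small_run,
                             dynamics=DynamicsParams(sigma_thr=0.0))
        stim = stim_array(6, len(small_grid), amplitude)
        _, tr = s.run_sequence(stimulation_frames(stim), render=False,
                               record_trace=True)
        arrays = tr.as_arrays()
        return arrays["brightness"][-1, 0], s._last[2][0]

    b1, size1 = last_state(200.0)
    b2, size2 = last_state(210.0)
    assert b2 > b1 and size2 > size1


def test_threshold_reinitialization_is_explicit_and_seeded(small_grid, small_run):
    s = make_session(small_grid, small_run)
    original = s.state.Athr.copy()
    s.reinitialize_thresholds(seed=small_run.seed)
    np.testing.assert_array_equal(s.state.Athr, original)
    s.reinitialize_thresholds(seed=small_run.seed + 1)
    assert np.any(s.state.Athr != original)


# -- quantizer --------------------------------------------------------------


@pytest.mark.parametrize("x,expected", [
    (0.0, 0.0),
    (128.0, 128.0),
    (20.0, 128.0 / 9),      # nearest of 10 levels spaced ~14.222 uA
    (200.0, 128.0),         # clamped to the top level
])
def test_quantizer_snaps_to_the_discrete_level_set(x, expected):
    assert quantize_amplitude(x) == pytest.approx(expected, rel=1e-12)


def test_quantizer_levels_include_both_endpoints():
    levels = np.unique(quantize_amplitude(np.linspace(0, 128, 1000)))
    assert len(levels) == 10
    assert levels[0] == 0.0 and levels[-1] == 128.0
    np.testing.assert_allclose(np.diff(levels), 128.0 / 9, rtol=1e-12)


def test_quantizer_is_idempotent():
    x = np.linspace(0, 128, 57)
    q = quantize_amplitude(x)
    np.testing.assert_array_equal(quantize_amplitude(q), q)


def test_smooth_staircase_converges_to_the_hard_quantizer():
    x = np.linspace(0, 128, 201)
    hard = quantize_amplitude(x)
    soft = smooth_staircase(x, sharpness=50.0)
    # away from the level boundaries the surrogate matches the staircase
    step = 128.0 / 9
    interior = np.abs((x / step) - np.round(x / step)) < 0.3
    np.testing.assert_allclose(soft[interior], hard[interior], atol=0.05)
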