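"""Stateful frame-based simulator of cortical prosthetic vision.

A :class:`SimulatorSession` binds an electrode/phosphene map to the model
parameters, holds the dynamic per-electrode state (activation, memory
trace, fixed detection thresholds), and advances one stimulation frame at
a time.  Each step performs, per electrode:

1. effective current from amplitude, rheobase, memory trace and duty cycle;
2. leaky-integrator activation update;
3. memory-trace update;
4. threshold-gated sigmoidal brightness;
5. phosphene size from the instantaneous current and local magnification;
6. Gaussian-blob rendering, summed over electrodes.

Sessions are deterministic: identical (map, parameters, seed, stimulation)
produce bit-identical frame sequences, and a session resumed from exported
state reproduces the unsplit run exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from . import dynamics as dyn
from .dynamics import SimState, StimFrame
from .geometry import PhospheneSpec, phosphene_size
from .interactions import InteractionConfig, coactivation_currents, costim_loss
from .params import (DynamicsParams, GeometryParams, RunConfig,
                     WedgeDipoleParams, validate_bundles)
from .renderer import FrameGeometry, PerceptFrame, compose_frame
from .visuotopy import PhospheneMap

__all__ = ["SimulatorSession", "quantize_amplitude", "smooth_staircase"]


class InitializationError(ValueError):
    """Session cannot be initialized (e.g. empty electrode map)."""


@dataclass
class StateTrace:
    """Per-frame record of the dynamic state, for analysis and export."""

    I_eff: list = field(default_factory=list)
    A: list = field(default_factory=list)
    B: list = field(default_factory=list)
    brightness: list = field(default_factory=list)
    costim_loss: list = field(default_factory=list)

    def as_arrays(self) -> dict[str, np.ndarray]:
        out = {k: np.asarray(getattr(self, k))
               for k in ("I_eff", "A", "B", "brightness")}
        out["costim_loss"] = np.asarray(self.costim_loss)
        return out


class SimulatorSession:
    """One simulation run over a fixed electrode map and parameter set.

    Parameters are immutable for the lifetime of the session, with one
    documented exception: detection thresholds may be re-initialized
    explicitly via :meth:`reinitialize_thresholds`.
    """

    def __init__(self, pmap: PhospheneMap,
                 map_params: WedgeDipoleParams = WedgeDipoleParams(),
                 dynamics: DynamicsParams = DynamicsParams(),
                 geometry: GeometryParams = GeometryParams(),
                 run: RunConfig = RunConfig(),
                 interaction: InteractionConfig = InteractionConfig()):
        if len(pmap) == 0:
            raise InitializationError("electrode map is empty")
        validate_bundles(dynamics, run)
        self.map = pmap
        self.map_params = map_params
        self.dynamics = dynamics
        self.geometry = geometry
        self.run = run
        self.interaction = interaction
        self.frame_geometry = FrameGeometry.from_run(run)
        thresholds = (pmap.thresholds if pmap.thresholds is not None else
                      dyn.sample_thresholds(len(pmap), dynamics.theta50,
                                            dynamics.sigma_thr, seed=run.seed))
        self.map.thresholds = np.asarray(thresholds, dtype=float)
        self.state = SimState.zeros(self.map.thresholds)
        self.clock = 0.0
        self.frame_count = 0

    # -- state management --------------------------------------------------

    def reinitialize_thresholds(self, seed: int | None = None) -> None:
        """Redraw the per-electrode detection thresholds.

        Thresholds are otherwise fixed for the session; this explicit call
        supports re-initialization between experiments.
        """
        seed = self.run.seed if seed is None else seed
        thr = dyn.sample_thresholds(len(self.map), self.dynamics.theta50,
                                    self.dynamics.sigma_thr, seed=seed)
        self.map.thresholds = thr
        self.state.Athr = thr.copy()

    def export_state(self) -> dict[str, np.ndarray | float | int]:
        """Plain-array snapshot (A, B, Athr, clock) for resumable runs."""
        return {"A": self.state.A.copy(), "B": self.state.B.copy(),
                "Athr": self.state.Athr.copy(),
                "clock": self.clock, "frame_count": self.frame_count}

    def import_state(self, snapshot: dict) -> None:
        n = len(self.map)
        for key in ("A", "B", "Athr"):
            arr = np.asarray(snapshot[key], dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"state array {key!r} has wrong shape")
        self.state = SimState(A=np.array(snapshot["A"], dtype=float),
                              B=np.array(snapshot["B"], dtype=float),
                              Athr=np.array(snapshot["Athr"], dtype=float))
        self.map.thresholds = self.state.Athr.copy()
        self.clock = float(snapshot["clock"])
        self.frame_count = int(snapshot["frame_count"])

    # -- stepping -----------------------------------------------------------

    def _electrode_currents(self, stim: StimFrame) -> np.ndarray:
        I = stim.amplitude
        if self.interaction.mode == "coactivation":
            positions = np.column_stack([self.map.w.real, self.map.w.imag])
            I = I + coactivation_currents(I, positions,
                                          self.interaction.leak_constant)
        return I

    def step(self, stim: StimFrame, render: bool = True) -> PerceptFrame | None:
        """Advance one frame; returns the rendered percept (or None).

        ``render=False`` updates the dynamics without rasterizing, which is
        orders of magnitude faster for long psychophysics-style sequences
        where only the per-electrode brightness trace is needed.
        """
        n = len(self.map)
        if stim.amplitude.shape != (n,):
            raise ValueError(
                f"stimulation frame has {stim.amplitude.shape} amplitudes "
                f"for {n} electrodes")
        bad = ~(np.isfinite(stim.amplitude) & np.isfinite(stim.pulse_width)
                & np.isfinite(stim.frequency))
        if bad.any():
            raise ValueError(
                f"non-finite stimulation input at frame {self.frame_count}, "
                f"electrodes {np.flatnonzero(bad).tolist()}")

        p = self.dynamics
        I = self._electrode_currents(stim)
        I_eff = dyn.effective_current(I, p.I0, self.state.B,
                                      stim.pulse_width, stim.frequency)
        I_eff = np.where(self.map.active, I_eff, 0.0)
        self.state.A = dyn.update_activation(self.state.A, I_eff, self.run.dt,
                                             p.tau_act, p.d)
        self.state.B = dyn.update_trace(self.state.B, I_eff, self.run.dt,
                                        p.tau_trace, p.kappa)
        bright = dyn.brightness(self.state.A, self.state.Athr, p.lambda_b,
                                p.A50, mode=self.run.gating_mode)
        bright = np.where(self.map.active, bright, 0.0)
        sizes = phosphene_size(np.where(self.map.active, I, 0.0), self.map.r,
                               self.geometry, self.map_params)
        self._last = (I_eff, bright, sizes)

        frame = None
        if render:
            specs = [PhospheneSpec(x, y, s, b)
                     for x, y, s, b in zip(self.map.x_deg, self.map.y_deg,
                                           sizes, np.clip(bright, 0.0, 1.0))
                     if b > 0 and s > 0]
            frame = compose_frame(specs, self.frame_geometry,
                                  clip_mode=self.run.clip_mode)
        self.frame_count += 1
        self.clock = self.frame_count * self.run.dt
        return frame

    def run_sequence(self, stim_sequence: Iterable[StimFrame],
                     render: bool = True, record_trace: bool = False):
        """Run a sequence of stimulation frames in order.

        Returns the list of rendered frames (empty when ``render=False``),
        or ``(frames, trace)`` when ``record_trace`` is set; the trace holds
        per-frame per-electrode I_eff, A, B and brightness arrays plus the
        co-stimulation penalty when that interaction mode is enabled.
        """
        frames: list[PerceptFrame] = []
        trace = StateTrace()
        positions = np.column_stack([self.map.w.real, self.map.w.imag])
        for i, stim in enumerate(stim_sequence):
            try:
                frame = self.step(stim, render=render)
            except ValueError as exc:
                raise ValueError(f"frame {i}: {exc}") from exc
            if render and frame is not None:
                frames.append(frame)
            if record_trace:
                I_eff, bright, _ = self._last
                trace.I_eff.append(I_eff)
                trace.A.append(self.state.A.copy())
                trace.B.append(self.state.B.copy())
                trace.brightness.append(bright)
                if self.interaction.mode == "costim_loss":
                    trace.costim_loss.append(
                        costim_loss(stim.amplitude, positions))
        if record_trace:
            return frames, trace
        return frames


# --------------------------------------------------------------------------
# Discrete-amplitude encoder constraint


def quantize_amplitude(x, n_levels: int = 10, max_uA: float = 128.0) -> np.ndarray:
    """Snap amplitudes (uA) to the nearest of ``n_levels`` uniform levels.

    Levels include both endpoints of [0, max_uA]; values outside the range
    are clamped to the extreme levels.  The default ten levels over
    0-128 uA reflect a hardware-constrained stimulator.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("amplitude must be >= 0")
    step = max_uA / (n_levels - 1)
    return np.clip(np.round(x / step), 0, n_levels - 1) * step


def smooth_staircase(x, n_levels: int = 10, max_uA: float = 128.0,
                     sharpness: float = 1.0) -> np.ndarray:
    """Smooth surrogate of :func:`quantize_amplitude` for gradient use.

    A sum of sigmoids with one riser per level boundary; as ``sharpness``
    (1/uA) grows the surrogate approaches the hard staircase.  Intended as
    the backward-pass slope in straight-through estimation.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    x = np.asarray(x, dtype=float)
    step = max_uA / (n_levels - 1)
    edges = (np.arange(1, n_levels) - 0.5) * step
    return step * expit(sharpness * (x[..., None] - edges)).sum(axis=-1)
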