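"""Per-electrode temporal dynamics of cortical tissue activation.

The stimulation amplitude first loses an ineffective component — the
rheobase current ``I0`` plus the habituation memory trace ``B`` — and the
remainder is scaled by the duty cycle of the biphasic pulse train
(pulse width x frequency):

    Ieff = max(0, (Istim - I0 - B) * Pw * f)

Tissue activation ``A`` integrates the effective current with a leaky
integrator (explicit forward-Euler, one step per frame of duration dt):

    A <- A + (-A / tau_act + Ieff * d) * dt

and the memory trace accumulates stimulation history on a much slower
timescale, modelling brightness accommodation for prolonged or repeated
stimulation:

    B <- B + (-B / tau_trace + Ieff * kappa) * dt

A phosphene is perceived only when ``A`` reaches its electrode's detection
threshold; thresholds are drawn once per electrode from N(theta50, sigma^2)
(redrawn until positive) and stay fixed for a session.  Perceived brightness
follows the sigmoid 1 / (1 + exp(-lambda * (A - A50))).

The forward-Euler update is used deliberately (rather than exact exponential
integration) so one frame corresponds to exactly one update of the printed
difference equations; dt < tau_act is enforced at configuration time.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "StimFrame", "SimState", "effective_current", "update_activation",
    "update_trace", "sample_thresholds", "brightness",
]

MICRO = 1e-6

#: default sharpness (1/activation-unit) of the smooth threshold gate
DEFAULT_GATE_SHARPNESS = 1e9
#: default sharpness (1/A) of the softplus rectifier in smooth mode
DEFAULT_RECT_SHARPNESS = 1e7


class DutyCycleError(ValueError):
    """Pulse width x frequency exceeds one (more on-time than period)."""


from dataclasses import dataclass


@dataclass
class StimFrame:
    """Per-electrode stimulation for one frame, in SI units.

    ``amplitude`` (A), ``pulse_width`` (s), ``frequency`` (Hz).  Use
    :meth:`from_user` for the conventional uA / us / Hz magnitudes.
    """

    amplitude: np.ndarray
    pulse_width: np.ndarray
    frequency: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        self.pulse_width = np.broadcast_to(
            np.asarray(self.pulse_width, dtype=float), self.amplitude.shape).copy()
        self.frequency = np.broadcast_to(
            np.asarray(self.frequency, dtype=float), self.amplitude.shape).copy()

    @classmethod
    def from_user(cls, amplitude_uA, pulse_width_us, frequency_hz) -> "StimFrame":
        return cls(np.asarray(amplitude_uA, dtype=float) * MICRO,
                   np.asarray(pulse_width_us, dtype=float) * MICRO,
                   np.asarray(frequency_hz, dtype=float))

    @property
    def duty_cycle(self) -> np.ndarray:
        return self.pulse_width * self.frequency


@dataclass
class SimState:
    """Dynamic per-electrode state: activation A, memory trace B, thresholds."""

    A: np.ndarray
    B: np.ndarray
    Athr: np.ndarray

    @classmethod
    def zeros(cls, thresholds: np.ndarray) -> "SimState":
        n = len(thresholds)
        return cls(A=np.zeros(n), B=np.zeros(n), Athr=np.asarray(thresholds, float))

    def copy(self) -> "SimState":
        return SimState(self.A.copy(), self.B.copy(), self.Athr.copy())


def _validate_duty(duty: np.ndarray) -> None:
    if np.any(duty < 0) or np.any(duty > 1.0 + 1e-12):
        raise DutyCycleError(
            "duty cycle Pw*f must lie in [0, 1]; got values outside that range")


def effective_current(I_stim, I0: float, B, pulse_width, frequency,
                      mode: str = "hard",
                      sharpness: float = DEFAULT_RECT_SHARPNESS) -> np.ndarray:
    """Effective stimulation current Ieff (A) after leak, trace and duty cycle.

    ``mode="hard"`` applies the exact rectification max(0, .); ``"smooth"``
    substitutes a softplus surrogate of configurable sharpness (1/A) for
    gradient-friendly use.
    """
    I_stim = np.asarray(I_stim, dtype=float)
    B = np.asarray(B, dtype=float)
    duty = np.asarray(pulse_width, dtype=float) * np.asarray(frequency, dtype=float)
    if np.any(I_stim < 0):
        raise ValueError("stimulation amplitude must be >= 0")
    _validate_duty(duty)
    drive = (I_stim - I0 - B) * duty
    if mode == "hard":
        return np.maximum(0.0, drive) + 0.0  # normalize -0.0
    if mode == "smooth":
        # softplus(x) = log(1 + e^{s x}) / s, numerically via logaddexp
        return np.logaddexp(0.0, sharpness * drive) / sharpness
    raise ValueError(f"unknown rectification mode {mode!r}")


def update_activation(A_prev, I_eff, dt: float, tau_act: float,
                      d: float = 1.0) -> np.ndarray:
    """One forward-Euler step of the activation leaky integrator."""
    A_prev = np.asarray(A_prev, dtype=float)
    return A_prev + (-A_prev / tau_act + np.asarray(I_eff, float) * d) * dt


def update_trace(B_prev, I_eff, dt: float, tau_trace: float,
                 kappa: float) -> np.ndarray:
    """One forward-Euler step of the habituation memory trace."""
    B_prev = np.asarray(B_prev, dtype=float)
    return B_prev + (-B_prev / tau_trace + np.asarray(I_eff, float) * kappa) * dt


def sample_thresholds(n: int, theta50: float, sigma_thr: float,
                      seed=None) -> np.ndarray:
    """Draw per-electrode detection thresholds from N(theta50, sigma^2).

    Non-positive draws are redrawn until positive (a non-positive detection
    threshold is physically meaningless).  ``seed`` may be an integer or a
    :class:`numpy.random.Generator`; draws are deterministic given a seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma_thr < 0:
        raise ValueError("sigma_thr must be >= 0")
    if sigma_thr == 0:
        return np.full(n, float(theta50))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = rng.normal(theta50, sigma_thr, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(theta50, sigma_thr, size=int(bad.sum()))
        bad = out <= 0
    return out


def brightness(A, Athr, lambda_b: float, A50: float, mode: str = "hard",
               gate_sharpness: float = DEFAULT_GATE_SHARPNESS) -> np.ndarray:
    """Perceived phosphene brightness in [0, 1].

    Below the detection threshold the phosphene is not perceived (hard mode:
    exactly 0).  At and above threshold, brightness follows the sigmoid
    ``1 / (1 + exp(-lambda * (A - A50)))``.  ``mode="smooth"`` replaces the
    hard step with a steep sigmoid gate so the output stays differentiable
    in ``A``.
    """
    A = np.asarray(A, dtype=float)
    Athr = np.asarray(Athr, dtype=float)
    base = expit(lambda_b * (A - A50))
    if mode == "hard":
        return np.where(A >= Athr, base, 0.0)
    if mode == "smooth":
        return base * expit(gate_sharpness * (A - Athr))
    raise ValueError(f"unknown gating mode {mode!r}")
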