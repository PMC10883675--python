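"""Parameter estimation on synthetic psychometric data.

The simulator's perceptual parameters (detection-threshold distribution,
brightness sigmoid, strength-duration rheobase) were originally estimated
from clinical psychophysics.  This module provides (a) generators of
synthetic trial data under the simulator's own forward model, and (b) the
corresponding fitting routines, so every fit is testable by parameter
recovery without any external dataset.

Detection model: a pulse train drives the tissue activation A through the
leaky integrator; a phosphene is detected when A exceeds the electrode's
threshold, a positive draw from N(theta50, sigma^2).  Averaging over
threshold draws gives the detection probability

    P(detect | A) = Phi((A - theta50) / sigma)   for A > 0,
    P(detect | A = 0) = 0,

where Phi is the standard normal CDF.  The A = 0 branch is exact for the
sampled-threshold mechanism (thresholds are strictly positive, so a train
that produces no effective current is never detected); the plain-Phi form
is kept above zero for continuity with the underlying normal model.

Fits use nonlinear least squares on per-condition proportions
(:func:`scipy.optimize.curve_fit`), reporting the coefficient of
determination R^2 on predicted vs. observed proportions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.special import expit, logit, ndtr
from scipy.stats import norm

from . import dynamics as dyn
from .params import DynamicsParams, MICRO

__all__ = [
    "StrengthDurationModel", "simulate_train_activation",
    "detection_probability", "make_conditions",
    "amplitude_for_activation", "make_brightness_conditions",
    "make_detection_conditions",
    "generate_detection_data", "generate_brightness_data",
    "generate_strength_duration_data",
    "fit_threshold_distribution", "fit_brightness_sigmoid",
    "fit_strength_duration", "crossvalidate",
]

#: integration step (s) for condition-level activation simulation
DEFAULT_FIT_DT = 1e-3

CONDITION_COLS = ["amplitude_uA", "pulse_width_us", "frequency_hz", "duration_ms"]


class NonIdentifiableError(ValueError):
    """The data cannot constrain the requested parameters."""


class UnderdeterminedError(ValueError):
    """Fewer informative conditions than free parameters."""


# --------------------------------------------------------------------------
# Forward model helpers


def simulate_train_activation(amplitude_uA: float, pulse_width_us: float,
                              frequency_hz: float, duration_s: float,
                              dynamics: DynamicsParams = DynamicsParams(),
                              dt: float = DEFAULT_FIT_DT) -> float:
    """Peak tissue activation reached by one pulse train from quiescence.

    Runs the full per-electrode dynamics (effective current, activation,
    memory trace) at time step ``dt`` for ``ceil(duration/dt)`` frames and
    returns the maximum activation along the way.
    """
    n_steps = max(1, math.ceil(duration_s / dt))
    A = 0.0
    B = 0.0
    peak = 0.0
    for _ in range(n_steps):
        I_eff = float(dyn.effective_current(
            amplitude_uA * MICRO, dynamics.I0, B,
            pulse_width_us * MICRO, frequency_hz))
        A = float(dyn.update_activation(A, I_eff, dt, dynamics.tau_act, dynamics.d))
        B = float(dyn.update_trace(B, I_eff, dt, dynamics.tau_trace, dynamics.kappa))
        peak = max(peak, A)
    return peak


def _condition_activations(data: pd.DataFrame, dynamics: DynamicsParams,
                           dt: float) -> np.ndarray:
    return np.array([
        simulate_train_activation(row.amplitude_uA, row.pulse_width_us,
                                  row.frequency_hz, row.duration_ms * 1e-3,
                                  dynamics, dt)
        for row in data.itertuples()])


def detection_probability(A, theta50: float, sigma: float) -> np.ndarray:
    """P(detect | activation A) under the positive-threshold normal model."""
    A = np.asarray(A, dtype=float)
    if sigma == 0:
        p = (A >= theta50).astype(float)
    else:
        p = ndtr((A - theta50) / sigma)
    return np.where(A > 0, p, 0.0)


def make_conditions(amplitudes_uA: Sequence[float], pulse_width_us: float = 170.0,
                    frequency_hz: float = 300.0,
                    duration_ms: float = 166.0) -> pd.DataFrame:
    """Convenience builder: an amplitude sweep at fixed train timing."""
    return pd.DataFrame({
        "amplitude_uA": np.asarray(amplitudes_uA, dtype=float),
        "pulse_width_us": pulse_width_us,
        "frequency_hz": frequency_hz,
        "duration_ms": duration_ms,
    })


def amplitude_for_activation(target_A: float, pulse_width_us: float,
                             frequency_hz: float, duration_s: float,
                             dynamics: DynamicsParams = DynamicsParams(),
                             dt: float = DEFAULT_FIT_DT) -> float:
    """Amplitude (uA) whose train reaches the given peak activation.

    Numerically inverts :func:`simulate_train_activation` (monotone in
    amplitude above rheobase) by bracketing and bisection.
    """
    if target_A <= 0:
        raise ValueError("target activation must be > 0")
    lo = dynamics.I0 / MICRO * (1 + 1e-9)
    hi = max(2 * lo, 100.0)
    f = lambda a: simulate_train_activation(a, pulse_width_us, frequency_hz,
                                            duration_s, dynamics, dt) - target_A
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("could not bracket the target activation")
    return float(brentq(f, lo, hi, xtol=1e-9, rtol=1e-12))


def make_brightness_conditions(dynamics: DynamicsParams = DynamicsParams(),
                               n: int = 15,
                               levels: tuple[float, float] = (0.02, 0.98),
                               pulse_width_us: float = 170.0,
                               frequency_hz: float = 300.0,
                               duration_ms: float = 166.0,
                               dt: float = DEFAULT_FIT_DT) -> pd.DataFrame:
    """Amplitude conditions placed at evenly spaced brightness quantiles.

    The brightness sigmoid is steep relative to a uniform amplitude grid;
    placing conditions at target response levels (as adaptive psychophysics
    procedures do) keeps the slope identifiable.
    """
    b = np.linspace(levels[0], levels[1], n)
    targets = dynamics.A50 + logit(b) / dynamics.lambda_b
    amps = [amplitude_for_activation(t, pulse_width_us, frequency_hz,
                                     duration_ms * 1e-3, dynamics, dt)
            for t in targets]
    return make_conditions(amps, pulse_width_us, frequency_hz, duration_ms)


def make_detection_conditions(dynamics: DynamicsParams = DynamicsParams(),
                              n: int = 20,
                              levels: tuple[float, float] = (0.02, 0.98),
                              pulse_width_us: float = 170.0,
                              frequency_hz: float = 300.0,
                              duration_ms: float = 166.0,
                              dt: float = DEFAULT_FIT_DT) -> pd.DataFrame:
    """Amplitude conditions at evenly spaced detection-probability quantiles."""
    p = np.linspace(levels[0], levels[1], n)
    targets = dynamics.theta50 + dynamics.sigma_thr * norm.ppf(p)
    targets = np.maximum(targets, dynamics.theta50 * 1e-3)
    amps = [amplitude_for_activation(t, pulse_width_us, frequency_hz,
                                     duration_ms * 1e-3, dynamics, dt)
            for t in targets]
    return make_conditions(amps, pulse_width_us, frequency_hz, duration_ms)


# --------------------------------------------------------------------------
# Synthetic data generators


def generate_detection_data(dynamics: DynamicsParams, conditions: pd.DataFrame,
                            n_trials: int, seed: int | None = None,
                            dt: float = DEFAULT_FIT_DT) -> pd.DataFrame:
    """Bernoulli detection outcomes for each stimulation condition.

    For every condition the train's peak activation is simulated, converted
    to a detection probability, and ``n_trials`` Bernoulli outcomes are
    drawn.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    A = _condition_activations(conditions, dynamics, dt)
    p = detection_probability(A, dynamics.theta50, dynamics.sigma_thr)
    detected = rng.binomial(n_trials, p)
    out = conditions.reset_index(drop=True).copy()
    out["n_trials"] = n_trials
    out["n_detected"] = detected
    return out


def generate_brightness_data(dynamics: DynamicsParams, conditions: pd.DataFrame,
                             noise_sd: float = 0.0, n_repeats: int = 1,
                             seed: int | None = None,
                             dt: float = DEFAULT_FIT_DT) -> pd.DataFrame:
    """Graded brightness responses per condition, with optional report noise.

    The noiseless response is the threshold-gated sigmoid of the simulated
    peak activation (gate at theta50); per-trial Gaussian report noise of
    s.d. ``noise_sd`` is averaged over ``n_repeats`` and the mean clipped
    to [0, 1].
    """
    rng = np.random.default_rng(seed)
    A = _condition_activations(conditions, dynamics, dt)
    true = np.asarray(dyn.brightness(A, dynamics.theta50, dynamics.lambda_b,
                                     dynamics.A50))
    if noise_sd > 0:
        responses = true[:, None] + rng.normal(0.0, noise_sd,
                                               size=(len(true), n_repeats))
        mean = np.clip(responses.mean(axis=1), 0.0, 1.0)
    else:
        mean = true
    out = conditions.reset_index(drop=True).copy()
    out["n_trials"] = n_repeats
    out["mean_brightness"] = mean
    return out


def generate_strength_duration_data(I0: float, chronaxie_s: float,
                                    durations_s: Sequence[float],
                                    noise_frac: float = 0.0,
                                    seed: int | None = None) -> pd.DataFrame:
    """Threshold charges Qthr = I0*(c + t), optionally with multiplicative noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(durations_s, dtype=float)
    q = I0 * (chronaxie_s + t)
    if noise_frac > 0:
        q = q * (1.0 + rng.normal(0.0, noise_frac, size=len(t)))
    return pd.DataFrame({"duration_s": t, "charge_thr": q})


# --------------------------------------------------------------------------
# Fit results


@dataclass
class ThresholdFit:
    """Recovered detection-threshold distribution (theta50, sigma) + fit R^2."""

    theta50: float
    sigma: float
    r_squared: float
    dynamics: DynamicsParams
    dt: float = DEFAULT_FIT_DT

    def predict(self, conditions: pd.DataFrame) -> np.ndarray:
        A = _condition_activations(conditions, self.dynamics, self.dt)
        return detection_probability(A, self.theta50, self.sigma)


@dataclass
class BrightnessFit:
    """Recovered brightness sigmoid (slope lambda, midpoint A50) + fit R^2."""

    lambda_b: float
    A50: float
    r_squared: float
    dynamics: DynamicsParams
    dt: float = DEFAULT_FIT_DT

    def predict(self, conditions: pd.DataFrame) -> np.ndarray:
        A = _condition_activations(conditions, self.dynamics, self.dt)
        return expit(self.lambda_b * (A - self.A50))


@dataclass
class StrengthDurationModel:
    """Strength-duration line Qthr = I0*(c + t): rheobase I0 and chronaxie c."""

    I0: float
    chronaxie: float
    r_squared: float = float("nan")
    degenerate: bool = False

    def predict(self, durations_s) -> np.ndarray:
        return self.I0 * (self.chronaxie + np.asarray(durations_s, dtype=float))


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# Fitters


def fit_threshold_distribution(data: pd.DataFrame,
                               dynamics: DynamicsParams = DynamicsParams(),
                               dt: float = DEFAULT_FIT_DT) -> ThresholdFit:
    """Estimate (theta50, sigma) from detection proportions.

    The per-condition activation is recomputed with the supplied dynamics
    (it does not depend on the threshold parameters being estimated) and
    the psychometric curve Phi((A - theta50)/sigma) is fitted to observed
    proportions by nonlinear least squares.
    """
    obs = data["n_detected"].to_numpy() / data["n_trials"].to_numpy()
    if np.all(obs <= 0) or np.all(obs >= 1):
        raise NonIdentifiableError(
            "detection data must span sub- and supra-threshold conditions")
    A = _condition_activations(data, dynamics, dt)

    def model(a, theta50, sigma):
        return detection_probability(a, theta50, sigma)

    mid = A[np.argmin(np.abs(obs - 0.5))]
    span = max(A.max() - A.min(), A.max() * 0.1, 1e-12)
    p0 = (max(mid, 1e-12), span / 4.0)
    popt, _ = curve_fit(model, A, obs, p0=p0,
                        bounds=([1e-15, 1e-15], [np.inf, np.inf]),
                        maxfev=20000)
    theta50, sigma = map(float, popt)
    r2 = _r_squared(obs, model(A, theta50, sigma))
    return ThresholdFit(theta50=theta50, sigma=sigma, r_squared=r2,
                        dynamics=dynamics, dt=dt)


def fit_brightness_sigmoid(data: pd.DataFrame,
                           dynamics: DynamicsParams = DynamicsParams(),
                           dt: float = DEFAULT_FIT_DT) -> BrightnessFit:
    """Estimate the brightness sigmoid (lambda, A50) from graded responses."""
    obs = data["mean_brightness"].to_numpy(dtype=float)
    A = _condition_activations(data, dynamics, dt)
    informative = len(np.unique(A)) >= 2
    if len(data) < 2 or not informative:
        raise UnderdeterminedError(
            "need at least two conditions with distinct activations")

    def model(a, lambda_b, A50):
        return expit(lambda_b * (a - A50))

    a50_0 = A[np.argmin(np.abs(obs - 0.5))]
    span = max(A.max() - A.min(), A.max() * 0.1, 1e-12)
    p0 = (4.0 / span, max(a50_0, 1e-12))
    popt, _ = curve_fit(model, A, obs, p0=p0,
                        bounds=([1e-12, 1e-15], [np.inf, np.inf]),
                        maxfev=20000)
    lambda_b, A50 = map(float, popt)
    r2 = _r_squared(obs, model(A, lambda_b, A50))
    return BrightnessFit(lambda_b=lambda_b, A50=A50, r_squared=r2,
                         dynamics=dynamics, dt=dt)


def fit_strength_duration(durations_s, charges) -> StrengthDurationModel:
    """Linear strength-duration fit: slope = I0, intercept = I0 * chronaxie.

    Constant charge across durations means the line has (near-)zero slope;
    the chronaxie then diverges and the result is flagged ``degenerate``.
    """
    t = np.asarray(durations_s, dtype=float)
    q = np.asarray(charges, dtype=float)
    if len(np.unique(t)) < 3:
        raise np.linalg.LinAlgError(
            "need at least three distinct durations for a strength-duration fit")
    slope, intercept = np.polyfit(t, q, 1)
    pred = slope * t + intercept
    r2 = _r_squared(q, pred)
    scale = max(abs(q).max() / max(t.max(), 1e-30), 1e-300)
    if slope <= 1e-9 * scale:
        return StrengthDurationModel(I0=float(slope), chronaxie=math.inf,
                                     r_squared=r2, degenerate=True)
    return StrengthDurationModel(I0=float(slope),
                                 chronaxie=float(intercept / slope),
                                 r_squared=r2)


# --------------------------------------------------------------------------
# Cross-validation


@dataclass
class CrossValidationResult:
    fold_r_squared: list[float]

    @property
    def mean_r_squared(self) -> float:
        return float(np.nanmean(self.fold_r_squared))


def crossvalidate(data: pd.DataFrame,
                  fitter: Callable[[pd.DataFrame], object],
                  k_folds: int = 3, seed: int | None = None,
                  observed_col: str | None = None) -> CrossValidationResult:
    """Condition-stratified k-fold cross-validation of a psychometric fit.

    Conditions (rows) are shuffled deterministically by ``seed`` and split
    into ``k_folds`` folds; the fitter runs on k-1 folds and the held-out
    proportions are scored by R^2.  Folds with a single condition score
    NaN (R^2 is undefined for one observation) and are skipped in the mean.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = len(data)
    if n < k_folds:
        raise ValueError(
            f"cannot partition {n} conditions into {k_folds} folds")
    if observed_col is None:
        observed_col = ("n_detected" if "n_detected" in data.columns
                        else "mean_brightness")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    data = data.reset_index(drop=True)
    scores: list[float] = []
    for fold in folds:
        test = data.iloc[fold]
        train = data.drop(index=fold)
        model = fitter(train)
        pred = model.predict(test)
        if observed_col == "n_detected":
            obs = test["n_detected"].to_numpy() / test["n_trials"].to_numpy()
        else:
            obs = test[observed_col].to_numpy(dtype=float)
        scores.append(_r_squared(obs, pred))
    return CrossValidationResult(fold_r_squared=scores)
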