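"""Central registry of model parameters, defaults, units and validation.

Internally everything is stored in SI units: currents in amperes, times in
seconds, frequencies in hertz, cortical distances in millimetres and visual
angles in degrees (azimuths in radians).  User-facing configuration files and
the CLI accept the conventional microampere / microsecond magnitudes because
all published parameter values are quoted in those units; conversion happens
exactly once, at load time.

The default values are the fitted estimates for intracortical stimulation of
human V1:

==============  =========================  ===========================
symbol          default                    meaning
==============  =========================  ===========================
a, b            0.75, 120 (deg)            dipole singularity offsets
k               17.3 (mm)                  cortical scaling
alpha           0.95                       wedge shear
K               675 (uA mm^-2)             cortical excitability
I0              23.9 uA                    rheobase (leak) current
tau_act         0.111 (s)                  activation decay constant
d               1.0                        within-frame duration scale
lambda          19.2e7 (1/A)               brightness sigmoid slope
A50             1.06e-6 (A)                half-brightness activation
theta50         9.14e-8 (A)                mean detection threshold
sigma           6.72e-8 (A)                detection threshold s.d.
tau_trace       1.97e3 (s)                 memory-trace decay constant
kappa           14.0                       memory-trace input gain
==============  =========================  ===========================
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

logger = logging.getLogger(__name__)

MICRO = 1e-6


class ConfigError(ValueError):
    """Malformed configuration input (unknown key, unparseable value)."""


class ValidationError(ConfigError):
    """A parameter violates its documented bound."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValidationError(message)


# --------------------------------------------------------------------------
# Unit-suffix parsing for user-facing quantities such as "23.9 uA".

_UNIT_SCALES = {
    "ua": 1e-6, "µa": 1e-6, "ma": 1e-3, "a": 1.0,
    "us": 1e-6, "µs": 1e-6, "ms": 1e-3, "s": 1.0,
    "hz": 1.0, "khz": 1e3,
}


def parse_quantity(value: Any, default_scale: float = 1.0) -> float:
    """Parse a numeric value or a ``"number unit"`` string into SI units.

    Bare numbers are interpreted with ``default_scale`` (e.g. 1e-6 for a
    microampere-denominated config key).
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value) * default_scale
    if isinstance(value, str):
        m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([a-zA-Zµ]*)\s*", value)
        if m is None:
            raise ConfigError(f"cannot parse quantity {value!r}")
        number, unit = m.groups()
        try:
            x = float(number)
        except ValueError as exc:
            raise ConfigError(f"cannot parse quantity {value!r}") from exc
        if not unit:
            return x * default_scale
        scale = _UNIT_SCALES.get(unit.lower())
        if scale is None:
            raise ConfigError(f"unknown unit {unit!r} in quantity {value!r}")
        return x * scale
    raise ConfigError(f"cannot parse quantity {value!r}")


# --------------------------------------------------------------------------
# Parameter bundles


@dataclass(frozen=True)
class WedgeDipoleParams:
    """Constants of the wedge-dipole visuotopic map of flattened V1.

    ``a`` and ``b`` (deg) place the two singularities of the dipole, ``k``
    (mm) scales the map to cortical millimetres and ``alpha`` is the shear
    of the wedge transform.  ``hemisphere`` labels which cortical hemisphere
    the map describes; a right-hemisphere map represents the left visual
    hemifield and vice versa.
    """

    a: float = 0.75
    b: float = 120.0
    k: float = 17.3
    alpha: float = 0.95
    hemisphere: str = "right"

    def __post_init__(self) -> None:
        _require(self.a > 0, f"a must be > 0, got {self.a}")
        _require(self.b > self.a, f"b must be > a ({self.a}), got {self.b}")
        _require(self.k > 0, f"k must be > 0, got {self.k}")
        _require(0 < self.alpha <= 1, f"alpha must be in (0, 1], got {self.alpha}")
        _require(self.hemisphere in ("left", "right"),
                 f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the tissue-activation, brightness and habituation model.

    Activation-like quantities (``A50``, ``theta50``, ``sigma_thr``) share
    the unit of the effective current integrated by the leaky integrator;
    with currents in amperes they are ampere-denominated.
    """

    I0: float = 2.39e-5          # rheobase current (A)
    tau_act: float = 0.111       # activation decay constant (s)
    d: float = 1.0               # within-frame duration scale, (0, 1]
    lambda_b: float = 19.2e7     # brightness sigmoid slope (1/activation)
    A50: float = 1.06e-6         # half-brightness activation
    theta50: float = 9.14e-8     # mean detection threshold
    sigma_thr: float = 6.72e-8   # detection threshold s.d. (>= 0)
    tau_trace: float = 1.97e3    # memory-trace decay constant (s)
    kappa: float = 14.0          # memory-trace input gain

    def __post_init__(self) -> None:
        for name in ("I0", "tau_act", "lambda_b", "A50", "theta50",
                     "tau_trace", "kappa"):
            _require(getattr(self, name) > 0,
                     f"{name} must be > 0, got {getattr(self, name)}")
        _require(self.sigma_thr >= 0,
                 f"sigma_thr must be >= 0, got {self.sigma_thr}")
        _require(0 < self.d <= 1, f"d must be in (0, 1], got {self.d}")


@dataclass(frozen=True)
class GeometryParams:
    """Current-spread geometry: cortical excitability constant K (uA mm^-2)."""

    K: float = 675.0

    def __post_init__(self) -> None:
        _require(self.K > 0, f"K must be > 0, got {self.K}")


@dataclass(frozen=True)
class RunConfig:
    """Run-level settings: rendered window, frame clock, seed and modes.

    ``dt`` is the frame duration; it must stay below ``tau_act`` so the
    explicit-Euler state updates remain stable (checked where both bundles
    are in scope, see :func:`validate_bundles`).
    """

    resolution: tuple[int, int] = (256, 256)
    fov: float = 16.0            # angular width of the rendered window (deg)
    dt: float = 1.0 / 30.0       # frame duration (s)
    seed: int = 42
    gating_mode: str = "hard"    # {"hard", "smooth"}
    clip_mode: str = "clip"      # {"clip", "none"}

    def __post_init__(self) -> None:
        rows, cols = self.resolution
        _require(int(rows) >= 8 and int(cols) >= 8,
                 f"resolution components must be >= 8, got {self.resolution}")
        object.__setattr__(self, "resolution", (int(rows), int(cols)))
        _require(self.fov > 0, f"fov must be > 0, got {self.fov}")
        _require(self.dt > 0, f"dt must be > 0, got {self.dt}")
        _require(self.gating_mode in ("hard", "smooth"),
                 f"gating_mode must be 'hard' or 'smooth', got {self.gating_mode!r}")
        _require(self.clip_mode in ("clip", "none"),
                 f"clip_mode must be 'clip' or 'none', got {self.clip_mode!r}")


ParamBundles = tuple[WedgeDipoleParams, DynamicsParams, GeometryParams, RunConfig]


def validate_bundles(dynamics: DynamicsParams, run: RunConfig) -> None:
    """Cross-bundle invariants: dt < tau_act (Euler stability guard)."""
    _require(run.dt < dynamics.tau_act,
             f"dt ({run.dt} s) must be < tau_act ({dynamics.tau_act} s) "
             "for a stable explicit-Euler update")


# --------------------------------------------------------------------------
# Configuration file handling.
#
# Config keys are named after the conventional symbols.  Current-like keys
# carry an explicit unit suffix where the conventional magnitude is not SI.

_KEY_MAP = {
    # key: (bundle, field, SI scale for bare numbers)
    "a": ("map", "a", 1.0),
    "b": ("map", "b", 1.0),
    "k": ("map", "k", 1.0),
    "alpha": ("map", "alpha", 1.0),
    "hemisphere": ("map", "hemisphere", None),
    "K": ("geometry", "K", 1.0),
    "I0_uA": ("dynamics", "I0", MICRO),
    "tau_act": ("dynamics", "tau_act", 1.0),
    "d": ("dynamics", "d", 1.0),
    "lambda": ("dynamics", "lambda_b", 1.0),
    "A50": ("dynamics", "A50", 1.0),
    "theta50": ("dynamics", "theta50", 1.0),
    "sigma": ("dynamics", "sigma_thr", 1.0),
    "tau_trace": ("dynamics", "tau_trace", 1.0),
    "kappa": ("dynamics", "kappa", 1.0),
    "dt": ("run", "dt", 1.0),
    "fov_deg": ("run", "fov", 1.0),
    "resolution": ("run", "resolution", None),
    "seed": ("run", "seed", None),
    "gating_mode": ("run", "gating_mode", None),
    "clip_mode": ("run", "clip_mode", None),
}


def resolve_config(mapping: Mapping[str, Any] | None) -> ParamBundles:
    """Resolve a key-value document into validated parameter bundles.

    Missing keys fall back to the defaults above; unknown keys raise a
    :class:`ConfigError` naming the key.
    """
    mapping = dict(mapping or {})
    collected: dict[str, dict[str, Any]] = {"map": {}, "dynamics": {},
                                            "geometry": {}, "run": {}}
    for key, value in mapping.items():
        if key not in _KEY_MAP:
            raise ConfigError(f"unknown configuration key {key!r}")
        bundle, fname, scale = _KEY_MAP[key]
        if scale is not None:
            value = parse_quantity(value, default_scale=scale)
        elif key == "resolution":
            value = tuple(int(v) for v in value)
        elif key == "seed":
            value = int(value)
        collected[bundle][fname] = value

    map_params = WedgeDipoleParams(**collected["map"])
    dynamics = DynamicsParams(**collected["dynamics"])
    geometry = GeometryParams(**collected["geometry"])
    run = RunConfig(**collected["run"])
    validate_bundles(dynamics, run)
    return map_params, dynamics, geometry, run


def load_config(path: str | Path) -> ParamBundles:
    """Load a YAML configuration file and return the resolved bundles.

    The fully resolved parameter set is echoed to the module logger so a
    run's provenance is always recorded.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed configuration file {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"configuration file {path} must be a key-value document")
    bundles = resolve_config(raw)
    logger.info("resolved configuration from %s: %s", path, config_to_dict(*bundles))
    return bundles


def config_to_dict(map_params: WedgeDipoleParams, dynamics: DynamicsParams,
                   geometry: GeometryParams, run: RunConfig) -> dict[str, Any]:
    """Serialize resolved bundles back to the user-facing key-value form."""
    return {
        "a": map_params.a, "b": map_params.b, "k": map_params.k,
        "alpha": map_params.alpha, "hemisphere": map_params.hemisphere,
        "K": geometry.K,
        "I0_uA": dynamics.I0 / MICRO,
        "tau_act": dynamics.tau_act, "d": dynamics.d,
        "lambda": dynamics.lambda_b, "A50": dynamics.A50,
        "theta50": dynamics.theta50, "sigma": dynamics.sigma_thr,
        "tau_trace": dynamics.tau_trace, "kappa": dynamics.kappa,
        "dt": run.dt, "fov_deg": run.fov,
        "resolution": list(run.resolution), "seed": run.seed,
        "gating_mode": run.gating_mode, "clip_mode": run.clip_mode,
    }


def save_config(path: str | Path, map_params: WedgeDipoleParams,
                dynamics: DynamicsParams, geometry: GeometryParams,
                run: RunConfig) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(map_params, dynamics, geometry, run),
                       sort_keys=False))


# --------------------------------------------------------------------------
# Symbol registry: every model symbol resolves to exactly one bundle field.

PARAMETER_SYMBOLS: dict[str, tuple[str, str]] = {
    "a": ("map", "a"), "b": ("map", "b"), "k": ("map", "k"),
    "alpha": ("map", "alpha"),
    "K": ("geometry", "K"),
    "I0": ("dynamics", "I0"), "tau_act": ("dynamics", "tau_act"),
    "d": ("dynamics", "d"), "lambda": ("dynamics", "lambda_b"),
    "A50": ("dynamics", "A50"), "theta50": ("dynamics", "theta50"),
    "sigma": ("dynamics", "sigma_thr"), "tau_trace": ("dynamics", "tau_trace"),
    "kappa": ("dynamics", "kappa"),
}


def get_parameter(symbol: str, map_params: WedgeDipoleParams,
                  dynamics: DynamicsParams, geometry: GeometryParams) -> float:
    """Look up a model symbol (e.g. ``"lambda"``) in the parameter bundles."""
    try:
        bundle, fname = PARAMETER_SYMBOLS[symbol]
    except KeyError as exc:
        raise KeyError(f"unknown parameter symbol {symbol!r}") from exc
    source = {"map": map_params, "dynamics": dynamics, "geometry": geometry}[bundle]
    return getattr(source, fname)
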