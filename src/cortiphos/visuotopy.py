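"""Wedge-dipole visuotopic mapping between visual field and flattened V1.

A visual-field point is written as the complex number ``z = r * exp(i*theta)``
with eccentricity ``r`` (deg) and azimuth ``theta`` (rad, ``|theta| <= pi/2``
within one hemifield; theta=0 is the horizontal meridian, positive theta up).
The sheared ("wedge") point is ``z' = r * exp(i*alpha*theta)`` and the
cortical position in millimetres is the normalized complex-log dipole map

    w = k * log( b * (z' + a) / (a * (z' + b)) )

which fixes the foveal origin at w = 0.  The analytic inverse is

    z' = a * b * (e^{w/k} - 1) / (b - a * e^{w/k}),    z = |z'| e^{i arg(z')/alpha}

and the cortical magnification along the horizontal meridian is

    M(r) = k * (b - a) / ((r + a) * (r + b))       [mm / deg].

Hemisphere handedness: the map itself is written in a canonical hemifield
frame; a *right*-hemisphere electrode represents the *left* visual hemifield,
so canonical azimuths are mirrored about the vertical meridian when
converting to visual-field Cartesian coordinates (see
:meth:`PhospheneMap.field_xy`).

Alternative retinotopies (monopole/dipole variants, LGN or extrastriate
maps) can be substituted by passing any object implementing
:class:`VisuotopicModel`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np

from .params import WedgeDipoleParams

HALF_PI = np.pi / 2.0
#: reject cortical points this close (in e^{w/k} units) to the map singularity
SINGULARITY_TOL = 1e-9


class MapDomainError(ValueError):
    """Input outside the admissible domain of the visuotopic map."""


class MapSingularityError(MapDomainError):
    """Cortical point at (or numerically at) the dipole singularity."""


class PlacementError(ValueError):
    """Electrode layout contains points outside the admissible cortical range."""


class VisuotopicModel(Protocol):
    """Interface hook for substituting alternative retinotopic maps."""

    def to_cortex(self, r, theta): ...

    def to_field(self, w): ...

    def magnification(self, r): ...


def visual_to_cortical(r, theta, params: WedgeDipoleParams) -> np.ndarray:
    """Map visual-field polar coordinates to cortical position w (mm, complex).

    Scalar or array input; the foveal origin maps exactly to ``0+0j``.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(theta))):
        raise MapDomainError("non-finite visual-field coordinates")
    if np.any(r < 0):
        raise MapDomainError("eccentricity must be >= 0")
    if np.any(np.abs(theta) > HALF_PI + 1e-12):
        raise MapDomainError("azimuth must satisfy |theta| <= pi/2 "
                             "within one hemifield")
    zp = r * np.exp(1j * params.alpha * theta)
    w = params.k * np.log(params.b * (zp + params.a)
                          / (params.a * (zp + params.b)))
    return w


def cortical_to_visual(w, params: WedgeDipoleParams) -> tuple[np.ndarray, np.ndarray]:
    """Invert the map: cortical position w (mm) -> (eccentricity, azimuth).

    Raises :class:`MapSingularityError` for points at the dipole singularity
    (``e^{w/k} = b/a``) and :class:`MapDomainError` for points whose inverse
    falls outside the hemifield ``|theta| <= pi/2``.
    """
    w = np.asarray(w, dtype=complex)
    if not np.all(np.isfinite(w)):
        raise MapDomainError("non-finite cortical coordinates")
    ratio = np.exp(w / params.k)
    denom = params.b - params.a * ratio
    if np.any(np.abs(ratio - params.b / params.a) < SINGULARITY_TOL):
        raise MapSingularityError(
            "cortical point at the dipole singularity e^{w/k} = b/a")
    zp = params.a * params.b * (ratio - 1.0) / denom
    r = np.abs(zp)
    theta = np.where(r > 0, np.angle(zp) / params.alpha, 0.0)
    if np.any(np.abs(theta) > HALF_PI + 1e-9):
        raise MapDomainError(
            "cortical point maps outside the hemifield |theta| <= pi/2")
    return r, theta


def cortical_magnification(r, params: WedgeDipoleParams) -> np.ndarray:
    """Cortical magnification M(r) in mm of cortex per degree of visual angle."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise MapDomainError("eccentricity must be >= 0")
    return params.k * (params.b - params.a) / ((r + params.a) * (r + params.b))


# --------------------------------------------------------------------------


@dataclass
class PhospheneMap:
    """Per-electrode geometry record.

    Arrays are aligned per electrode: canonical cortical position ``w`` (mm,
    complex), canonical hemifield polars ``(r, theta)``, visual-field
    Cartesian position ``(x_deg, y_deg)`` with hemisphere mirroring applied,
    magnification ``magnification`` (mm/deg), hemisphere labels, aliveness
    flags, and (once a simulator session is initialized) detection
    thresholds ``thresholds``.
    """

    w: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    magnification: np.ndarray
    hemisphere: np.ndarray          # per-electrode, '<U5' of {'left','right'}
    active: np.ndarray              # bool
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.w)
        for name in ("r", "theta", "x_deg", "y_deg", "magnification",
                     "hemisphere", "active"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if np.any(self.magnification <= 0):
            raise ValueError("magnification must be positive everywhere")
        if self.thresholds is not None and np.any(self.thresholds <= 0):
            raise ValueError("detection thresholds must be positive")

    def __len__(self) -> int:
        return len(self.w)

    @property
    def n_electrodes(self) -> int:
        return len(self.w)

    @classmethod
    def from_cortical(cls, w, hemisphere, params: WedgeDipoleParams,
                      active=None) -> "PhospheneMap":
        """Build a map from canonical cortical positions (mm, complex)."""
        w = np.atleast_1d(np.asarray(w, dtype=complex))
        hemi = np.broadcast_to(np.asarray(hemisphere, dtype="<U5"), w.shape).copy()
        r, theta = cortical_to_visual(w, params)
        mag = cortical_magnification(r, params)
        x, y = _field_xy(r, theta, hemi)
        act = (np.ones(len(w), dtype=bool) if active is None
               else np.asarray(active, dtype=bool).copy())
        return cls(w=w, r=np.atleast_1d(r), theta=np.atleast_1d(theta),
                   x_deg=x, y_deg=y, magnification=np.atleast_1d(mag),
                   hemisphere=hemi, active=act)

    @classmethod
    def from_visual(cls, eccentricity, azimuth, params: WedgeDipoleParams,
                    active=None) -> "PhospheneMap":
        """Build a map from visual-field polars with full-circle azimuth.

        Points in the right hemifield (``|azimuth| <= pi/2``) are assigned to
        the left cortical hemisphere; the rest are mirrored into the
        canonical frame and assigned to the right hemisphere.
        """
        r = np.atleast_1d(np.asarray(eccentricity, dtype=float))
        az = np.atleast_1d(np.asarray(azimuth, dtype=float))
        az = np.angle(np.exp(1j * az))  # wrap to (-pi, pi]
        right_field = np.abs(az) <= HALF_PI + 1e-12
        theta = np.where(right_field, az, np.sign(az) * np.pi - az)
        hemi = np.where(right_field, "left", "right").astype("<U5")
        w = visual_to_cortical(r, theta, params)
        mag = cortical_magnification(r, params)
        x, y = _field_xy(r, theta, hemi)
        act = (np.ones(len(r), dtype=bool) if active is None
               else np.asarray(active, dtype=bool).copy())
        return cls(w=np.atleast_1d(w), r=r, theta=theta, x_deg=x, y_deg=y,
                   magnification=mag, hemisphere=hemi, active=act)

    def field_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Visual-field Cartesian coordinates (deg), hemifield mirror applied."""
        return self.x_deg, self.y_deg

    def copy(self) -> "PhospheneMap":
        return PhospheneMap(
            w=self.w.copy(), r=self.r.copy(), theta=self.theta.copy(),
            x_deg=self.x_deg.copy(), y_deg=self.y_deg.copy(),
            magnification=self.magnification.copy(),
            hemisphere=self.hemisphere.copy(), active=self.active.copy(),
            thresholds=None if self.thresholds is None else self.thresholds.copy())


def _field_xy(r, theta, hemisphere) -> tuple[np.ndarray, np.ndarray]:
    # canonical frame covers the right hemifield; right-hemisphere electrodes
    # live in the left hemifield -> mirror x
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    mirror = np.where(np.asarray(hemisphere) == "right", -1.0, 1.0)
    return np.atleast_1d(x * mirror), np.atleast_1d(y)


def make_grid_layout(n_rows: int, n_cols: int, spacing_mm: float,
                     origin: complex = 0j,
                     params: WedgeDipoleParams = WedgeDipoleParams(),
                     hemisphere: str = "right") -> PhospheneMap:
    """Equally spaced electrode grid on the flattened cortical map.

    The grid is centred on ``origin`` (mm, complex; real axis runs
    fovea -> periphery).  Grid points whose inverse mapping falls outside
    the admissible range raise :class:`PlacementError` listing the offending
    electrode indices.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    cols = (np.arange(n_cols) - (n_cols - 1) / 2.0) * spacing_mm
    rows = (np.arange(n_rows) - (n_rows - 1) / 2.0) * spacing_mm
    xx, yy = np.meshgrid(cols, rows)
    w = (complex(origin) + xx + 1j * yy).ravel()

    bad: list[int] = []
    r = np.zeros(len(w))
    theta = np.zeros(len(w))
    for i, wi in enumerate(w):
        try:
            ri, ti = cortical_to_visual(wi, params)
        except MapDomainError:
            bad.append(i)
            continue
        r[i], theta[i] = ri, ti
    if bad:
        raise PlacementError(
            f"grid points outside the admissible cortical range: electrodes {bad}")
    hemi = np.full(len(w), hemisphere, dtype="<U5")
    mag = cortical_magnification(r, params)
    x, y = _field_xy(r, theta, hemi)
    return PhospheneMap(w=w, r=r, theta=theta, x_deg=x, y_deg=y,
                        magnification=mag, hemisphere=hemi,
                        active=np.ones(len(w), dtype=bool))


def perturb_layout(pmap: PhospheneMap, pos_noise_mm: float = 0.0,
                   dropout_p: float = 0.0, seed: int | None = None,
                   params: WedgeDipoleParams = WedgeDipoleParams()) -> PhospheneMap:
    """Jitter cortical positions and randomly deactivate electrodes.

    Positions receive zero-mean isotropic Gaussian noise of scale
    ``pos_noise_mm``; each electrode is independently deactivated with
    probability ``dropout_p``.  Visual-field coordinates and magnification
    are recomputed from the perturbed cortical positions.  Deterministic
    given ``seed``.
    """
    if not 0.0 <= dropout_p <= 1.0:
        raise ValueError("dropout_p must be in [0, 1]")
    if pos_noise_mm < 0:
        raise ValueError("pos_noise_mm must be >= 0")
    rng = np.random.default_rng(seed)
    w = pmap.w.copy()
    if pos_noise_mm > 0:
        jitter = rng.normal(0.0, pos_noise_mm, size=(len(w), 2))
        w = w + jitter[:, 0] + 1j * jitter[:, 1]
    active = pmap.active.copy()
    if dropout_p > 0:
        active &= rng.random(len(w)) >= dropout_p
    out = PhospheneMap.from_cortical(w, pmap.hemisphere, params, active=active)
    out.thresholds = None if pmap.thresholds is None else pmap.thresholds.copy()
    return out
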