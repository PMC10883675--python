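"""Phosphene size from current spread and cortical magnification.

Intracortical stimulation at current I (uA) activates a roughly circular
patch of cortex whose diameter follows the current-spread relation

    D = 2 * sqrt(I / K)        [mm],  K in uA mm^-2

and the perceived phosphene size in visual degrees divides the activated
cortical extent by the local cortical magnification:

    P = D / M(r)               [deg].

Only the instantaneous stimulation current enters the size computation —
never the memory trace or the pulse timing; there is no experimental basis
for a history dependence of phosphene size.  Whether the raw amplitude or
the rheobase-rectified amplitude drives the spread is configurable
(``subtract_rheobase``); the default uses the raw instantaneous current.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import GeometryParams, WedgeDipoleParams, MICRO
from .visuotopy import cortical_magnification

__all__ = ["PhospheneSpec", "activation_diameter", "phosphene_size"]


@dataclass
class PhospheneSpec:
    """One renderable phosphene: field position (deg), size (deg), brightness."""

    x_deg: float
    y_deg: float
    size_deg: float
    brightness: float

    def __post_init__(self) -> None:
        if self.size_deg < 0:
            raise ValueError("size_deg must be >= 0")
        if not 0.0 <= self.brightness <= 1.0:
            raise ValueError("brightness must lie in [0, 1]")


def activation_diameter(current, geometry: GeometryParams = GeometryParams()) -> np.ndarray:
    """Diameter (mm) of activated cortical tissue for current (A)."""
    current = np.asarray(current, dtype=float)
    if np.any(current < 0):
        raise ValueError("current must be >= 0")
    return 2.0 * np.sqrt((current / MICRO) / geometry.K)


def phosphene_size(current, eccentricity,
                   geometry: GeometryParams = GeometryParams(),
                   map_params: WedgeDipoleParams = WedgeDipoleParams(),
                   *, I0: float = 0.0,
                   subtract_rheobase: bool = False) -> np.ndarray:
    """Phosphene size (deg) at the given current (A) and eccentricity (deg)."""
    current = np.asarray(current, dtype=float)
    if subtract_rheobase:
        current = np.maximum(0.0, current - I0)
    D = activation_diameter(current, geometry)
    M = cortical_magnification(eccentricity, map_params)
    return D / M
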