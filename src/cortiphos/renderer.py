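"""Rasterize phosphenes into a simulated percept image.

Each phosphene is drawn as an isotropic, peak-normalized Gaussian blob at
its visual-field position: sigma = P/2 in degrees (two standard deviations
span the phosphene size, so ~95% of the 1-D profile falls within +/-P/2)
and the peak pixel value equals the phosphene's brightness.  Contributions
are summed across phosphenes and, by default, clipped to [0, 1].

Pixel grid conventions: square pixels; the field of view is the angular
width of the window; fixation sits at the exact image centre; azimuth 0
points right, positive angles up; row 0 is the top of the image.

All pixel values are continuous, piecewise-differentiable functions of
brightness, centre and size — no lookups or resampling — so the renderer
composes cleanly with gradient-based pipelines.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

import numpy as np

from .geometry import PhospheneSpec
from .params import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["FrameGeometry", "PerceptFrame", "render_phosphene",
           "render_gabor", "compose_frame"]

_warned_offscreen = False


@dataclass(frozen=True)
class FrameGeometry:
    """Pixel grid of the rendered window: resolution (rows, cols), fov (deg)."""

    resolution: tuple[int, int] = (256, 256)
    fov: float = 16.0

    @classmethod
    def from_run(cls, run: RunConfig) -> "FrameGeometry":
        return cls(resolution=run.resolution, fov=run.fov)

    @property
    def pixel_size(self) -> float:
        """Angular extent of one (square) pixel, deg."""
        return self.fov / self.resolution[1]

    @cached_property
    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinate grids (x right, y up), deg."""
        rows, cols = self.resolution
        px = self.pixel_size
        x = (np.arange(cols) + 0.5) * px - cols * px / 2.0
        y = rows * px / 2.0 - (np.arange(rows) + 0.5) * px
        return np.meshgrid(x, y)


@dataclass
class PerceptFrame:
    """Rendered 2-D brightness image with its angular extent."""

    image: np.ndarray
    fov: float

    @property
    def resolution(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]


def _envelope(spec: PhospheneSpec, geom: FrameGeometry) -> np.ndarray | None:
    """Peak-normalized Gaussian envelope, or None for a zero contribution."""
    global _warned_offscreen
    if spec.brightness <= 0 or spec.size_deg <= 0:
        return None
    half = geom.fov / 2.0
    rows, cols = geom.resolution
    half_v = rows * geom.pixel_size / 2.0
    if not (-half <= spec.x_deg <= half and -half_v <= spec.y_deg <= half_v):
        if not _warned_offscreen:
            logger.info("phosphene centre outside the rendered window; "
                        "contribution clipped to the window")
            _warned_offscreen = True
    sigma = spec.size_deg / 2.0
    X, Y = geom.grids
    d2 = (X - spec.x_deg) ** 2 + (Y - spec.y_deg) ** 2
    return np.exp(-d2 / (2.0 * sigma * sigma))


def render_phosphene(spec: PhospheneSpec, geom: FrameGeometry) -> np.ndarray:
    """Render one phosphene as a Gaussian blob; peak value = brightness."""
    env = _envelope(spec, geom)
    if env is None:
        return np.zeros(geom.resolution)
    return spec.brightness * env


def render_gabor(spec: PhospheneSpec, frequency: float, orientation: float,
                 geom: FrameGeometry) -> np.ndarray:
    """Render a Gabor patch: the Gaussian envelope times a cosine carrier.

    ``frequency`` in cycles/deg, ``orientation`` in rad.  The carrier is
    zero-phase at the patch centre and mapped to [0, 1] under the envelope
    as 0.5 + 0.5*cos, so the zero-frequency limit reproduces the plain
    Gaussian blob.
    """
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    env = _envelope(spec, geom)
    if env is None:
        return np.zeros(geom.resolution)
    X, Y = geom.grids
    u = ((X - spec.x_deg) * np.cos(orientation)
         + (Y - spec.y_deg) * np.sin(orientation))
    carrier = 0.5 + 0.5 * np.cos(2.0 * np.pi * frequency * u)
    return spec.brightness * env * carrier


def compose_frame(specs: Iterable[PhospheneSpec], geom: FrameGeometry,
                  clip_mode: str = "clip") -> PerceptFrame:
    """Sum phosphene renderings into one percept frame.

    Rendering is linear before clipping; with ``clip_mode="clip"`` the
    summed image is clipped to [0, 1] (overlapping bright phosphenes
    saturate), with ``"none"`` it is returned raw.
    """
    if clip_mode not in ("clip", "none"):
        raise ValueError(f"unknown clip_mode {clip_mode!r}")
    image = np.zeros(geom.resolution)
    for spec in specs:
        env = _envelope(spec, geom)
        if env is not None:
            image += spec.brightness * env
    if clip_mode == "clip":
        np.clip(image, 0.0, 1.0, out=image)
    return PerceptFrame(image=image, fov=geom.fov)
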