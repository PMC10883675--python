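"""Readers/writers for on-disk formats, fixture scenarios and frame output.

Formats (all plain text, comma-separated, mandatory header, '.' decimal,
UTF-8):

* electrode map CSV — either cortical columns
  (``electrode_id, x_cortex_mm, y_cortex_mm, hemisphere``) or visual-field
  columns (``electrode_id, eccentricity_deg, azimuth_rad``); the reader
  auto-detects which triple is present and the writer always emits both
  coordinate systems plus ``magnification_mm_per_deg`` and ``active``;
* stimulation CSV — sparse long format
  (``frame, electrode_id, amplitude_uA, pulse_width_us, frequency_hz``);
  frames/electrodes absent from the file receive zero stimulation;
* psychometric CSV — ``amplitude_uA, pulse_width_us, frequency_hz,
  duration_ms, n_trials`` plus ``n_detected`` (detection) or
  ``mean_brightness`` (brightness).

Rendered frames are written as 8-bit grayscale PNGs (linear [0,1] -> [0,255])
with zero-padded indices and a JSON sidecar manifest; a container video is
optional sugar on top when an encoder is available.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .dynamics import StimFrame
from .params import (DynamicsParams, GeometryParams, RunConfig,
                     WedgeDipoleParams, config_to_dict, resolve_config)
from .renderer import PerceptFrame
from .visuotopy import PhospheneMap, make_grid_layout

logger = logging.getLogger(__name__)

__all__ = [
    "read_electrode_csv", "write_electrode_csv",
    "read_stimulation_csv", "write_stimulation_csv",
    "stimulation_frames", "read_psychometric_csv", "write_psychometric_csv",
    "FixtureSpec", "SCENARIOS", "build_scenario", "make_fixture",
    "write_frames", "read_frames", "write_video",
]

CORTICAL_COLS = ["x_cortex_mm", "y_cortex_mm", "hemisphere"]
VISUAL_COLS = ["eccentricity_deg", "azimuth_rad"]
STIM_COLS = ["frame", "electrode_id", "amplitude_uA", "pulse_width_us",
             "frequency_hz"]


class FormatError(ValueError):
    """A file is missing required columns or has inconsistent content."""


def _require_cols(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# --------------------------------------------------------------------------
# Electrode map CSV


def read_electrode_csv(path, params: WedgeDipoleParams = WedgeDipoleParams()
                       ) -> PhospheneMap:
    """Read an electrode map, auto-detecting the coordinate system."""
    df = pd.read_csv(path)
    _require_cols(df, ["electrode_id"], path)
    if all(c in df.columns for c in CORTICAL_COLS):
        w = df["x_cortex_mm"].to_numpy() + 1j * df["y_cortex_mm"].to_numpy()
        pmap = PhospheneMap.from_cortical(w, df["hemisphere"].to_numpy("<U5"),
                                          params)
    elif all(c in df.columns for c in VISUAL_COLS):
        pmap = PhospheneMap.from_visual(df["eccentricity_deg"].to_numpy(),
                                        df["azimuth_rad"].to_numpy(), params)
    else:
        raise FormatError(
            f"{path}: need either columns {CORTICAL_COLS} or {VISUAL_COLS}")
    if "active" in df.columns:
        pmap.active = df["active"].to_numpy(dtype=bool)
    return pmap


def write_electrode_csv(pmap: PhospheneMap, path) -> None:
    """Write an electrode map with both coordinate systems."""
    az = np.arctan2(pmap.y_deg, pmap.x_deg)
    df = pd.DataFrame({
        "electrode_id": np.arange(len(pmap)),
        "x_cortex_mm": pmap.w.real,
        "y_cortex_mm": pmap.w.imag,
        "hemisphere": pmap.hemisphere,
        "eccentricity_deg": pmap.r,
        "azimuth_rad": az,
        "magnification_mm_per_deg": pmap.magnification,
        "active": pmap.active.astype(int),
    })
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Stimulation sequences


def write_stimulation_csv(stim: np.ndarray, path) -> None:
    """Write a dense (frames, electrodes, 3) user-unit array as sparse long CSV.

    The last axis holds (amplitude_uA, pulse_width_us, frequency_hz); rows
    with zero amplitude are omitted.
    """
    stim = np.asarray(stim, dtype=float)
    if stim.ndim != 3 or stim.shape[2] != 3:
        raise ValueError("stimulation array must have shape (frames, electrodes, 3)")
    frames, elecs = np.nonzero(stim[:, :, 0])
    df = pd.DataFrame({
        "frame": frames,
        "electrode_id": elecs,
        "amplitude_uA": stim[frames, elecs, 0],
        "pulse_width_us": stim[frames, elecs, 1],
        "frequency_hz": stim[frames, elecs, 2],
    })
    df.to_csv(path, index=False)


def read_stimulation_csv(path, n_frames: int | None = None,
                         n_electrodes: int | None = None) -> np.ndarray:
    """Read a sparse long-format stimulation CSV into a dense array.

    Returns shape (n_frames, n_electrodes, 3) in user units; absent
    (frame, electrode) pairs are zero stimulation.
    """
    df = pd.read_csv(path)
    _require_cols(df, STIM_COLS, path)
    nf = n_frames if n_frames is not None else (int(df["frame"].max()) + 1
                                                if len(df) else 0)
    ne = n_electrodes if n_electrodes is not None else (
        int(df["electrode_id"].max()) + 1 if len(df) else 0)
    out = np.zeros((nf, ne, 3))
    f = df["frame"].to_numpy(dtype=int)
    e = df["electrode_id"].to_numpy(dtype=int)
    out[f, e, 0] = df["amplitude_uA"].to_numpy()
    out[f, e, 1] = df["pulse_width_us"].to_numpy()
    out[f, e, 2] = df["frequency_hz"].to_numpy()
    return out


def stimulation_frames(stim: np.ndarray) -> list[StimFrame]:
    """Convert a dense user-unit stimulation array into per-frame StimFrames."""
    stim = np.asarray(stim, dtype=float)
    return [StimFrame.from_user(stim[i, :, 0], stim[i, :, 1], stim[i, :, 2])
            for i in range(stim.shape[0])]


# --------------------------------------------------------------------------
# Psychometric CSV


def read_psychometric_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    base = ["amplitude_uA", "pulse_width_us", "frequency_hz", "duration_ms",
            "n_trials"]
    _require_cols(df, base, path)
    if "n_detected" not in df.columns and "mean_brightness" not in df.columns:
        raise FormatError(
            f"{path}: missing required column(s) "
            "['n_detected' or 'mean_brightness']")
    return df


def write_psychometric_csv(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Fixture scenarios
#
# Bundled worked scenarios mirror the standard demonstration protocols:
# `four_arrays`   — four 10x10 grids (0.4 mm spacing, Utah-array-like) in the
#                   right hemisphere, 166 ms trains (170 us, 300 Hz) at
#                   40 / 80 / 120 uA;
# `brightness_sweep` — one electrode, 166 ms / 170 us / 300 Hz trains over an
#                   amplitude sweep 0-120 uA;
# `habituation`   — one electrode, 125 ms / 100 us / 200 Hz trains at 90 uA:
#                   50 trains at 4 s start-to-start intervals, then 5 trains
#                   at 200 s intervals to test recovery.


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible run-input recipe: grid + stimulation train schedule."""

    name: str
    n_rows: int = 10
    n_cols: int = 10
    spacing_mm: float = 0.4
    origins: tuple[tuple[float, float], ...] = ((12.0, 0.0),)
    hemisphere: str = "right"
    train_ms: float = 166.0
    pulse_width_us: float = 170.0
    frequency_hz: float = 300.0
    amplitudes_uA: tuple[float, ...] = (100.0,)
    intervals_s: tuple[float, ...] = ()   # start-to-start gaps between trains
    dt: float = 1.0 / 30.0
    fov_deg: float = 16.0
    resolution: tuple[int, int] = (256, 256)
    seed: int = 42


SCENARIOS: dict[str, FixtureSpec] = {
    "four_arrays": FixtureSpec(
        name="four_arrays",
        origins=((12.0, 0.0), (24.0, 6.0), (24.0, -6.0), (36.0, 0.0)),
        amplitudes_uA=(40.0, 80.0, 120.0),
        intervals_s=(1.0, 1.0),
    ),
    "brightness_sweep": FixtureSpec(
        name="brightness_sweep",
        n_rows=1, n_cols=1, origins=((20.0, 0.0),),
        amplitudes_uA=tuple(float(a) for a in range(0, 130, 10)),
        intervals_s=(2.0,) * 12,
    ),
    "habituation": FixtureSpec(
        name="habituation",
        n_rows=1, n_cols=1, origins=((20.0, 0.0),),
        train_ms=125.0, pulse_width_us=100.0, frequency_hz=200.0,
        amplitudes_uA=(90.0,) * 55,
        intervals_s=(4.0,) * 49 + (200.0,) * 5,
        dt=0.025,
    ),
}


def build_scenario(spec: FixtureSpec | str,
                   params: WedgeDipoleParams = WedgeDipoleParams()
                   ) -> tuple[PhospheneMap, np.ndarray, dict]:
    """Materialize a fixture: (electrode map, dense stimulation array, config).

    The stimulation array is (frames, electrodes, 3) in user units; every
    train stimulates all electrodes.  Train i starts at the cumulative sum
    of the start-to-start intervals and lasts ceil(train_ms / dt) frames.
    """
    if isinstance(spec, str):
        try:
            spec = SCENARIOS[spec]
        except KeyError:
            raise KeyError(
                f"unknown scenario {spec!r}; available: {sorted(SCENARIOS)}")
    maps = [make_grid_layout(spec.n_rows, spec.n_cols, spec.spacing_mm,
                             origin=complex(x, y), params=params,
                             hemisphere=spec.hemisphere)
            for x, y in spec.origins]
    pmap = _concat_maps(maps)

    n_trains = len(spec.amplitudes_uA)
    starts_s = np.concatenate([[0.0], np.cumsum(spec.intervals_s)])[:n_trains]
    if len(starts_s) < n_trains:
        raise ValueError("fewer intervals than trains")
    train_frames = max(1, int(np.ceil(spec.train_ms * 1e-3 / spec.dt)))
    start_frames = np.round(starts_s / spec.dt).astype(int)
    n_frames = int(start_frames[-1]) + train_frames if n_trains else 0
    stim = np.zeros((n_frames, len(pmap), 3))
    for amp, f0 in zip(spec.amplitudes_uA, start_frames):
        stim[f0:f0 + train_frames, :, 0] = amp
        stim[f0:f0 + train_frames, :, 1] = spec.pulse_width_us
        stim[f0:f0 + train_frames, :, 2] = spec.frequency_hz
    config = {"dt": spec.dt, "fov_deg": spec.fov_deg,
              "resolution": list(spec.resolution), "seed": spec.seed}
    return pmap, stim, config


def _concat_maps(maps: list[PhospheneMap]) -> PhospheneMap:
    return PhospheneMap(
        w=np.concatenate([m.w for m in maps]),
        r=np.concatenate([m.r for m in maps]),
        theta=np.concatenate([m.theta for m in maps]),
        x_deg=np.concatenate([m.x_deg for m in maps]),
        y_deg=np.concatenate([m.y_deg for m in maps]),
        magnification=np.concatenate([m.magnification for m in maps]),
        hemisphere=np.concatenate([m.hemisphere for m in maps]),
        active=np.concatenate([m.active for m in maps]))


def make_fixture(spec: FixtureSpec | str, out_dir) -> dict[str, Path]:
    """Write a scenario's three run inputs (electrodes, stimulation, config).

    Byte-identical outputs for identical spec + seed.
    """
    pmap, stim, config = build_scenario(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"electrodes": out / "electrodes.csv",
             "stimulation": out / "stimulation.csv",
             "config": out / "config.yaml"}
    write_electrode_csv(pmap, paths["electrodes"])
    write_stimulation_csv(stim, paths["stimulation"])
    import yaml
    config = dict(config, n_frames=int(stim.shape[0]),
                  n_electrodes=len(pmap))
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths


# --------------------------------------------------------------------------
# Frame output


def write_frames(frames: Sequence[PerceptFrame], out_dir, fps: float
                 ) -> list[Path]:
    """Write frames as zero-padded 8-bit grayscale PNGs plus a manifest."""
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames) - 1)))
    paths = []
    for i, frame in enumerate(frames):
        img = np.clip(frame.image, 0.0, 1.0)
        img8 = np.round(img * 255.0).astype(np.uint8)
        p = out / f"frame_{i:0{width}d}.png"
        iio.imwrite(p, img8)
        paths.append(p)
    manifest = {"n_frames": len(frames), "fps": fps,
                "fov_deg": frames[0].fov,
                "resolution": list(frames[0].image.shape)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths


def read_frames(frame_dir) -> np.ndarray:
    """Read a PNG frame directory back into a float array stack in [0, 1]."""
    paths = sorted(Path(frame_dir).glob("frame_*.png"))
    return np.stack([iio.imread(p).astype(float) / 255.0 for p in paths])


def write_video(frames: Sequence[PerceptFrame], path, fps: float) -> Path | None:
    """Assemble a container video when an encoder is available.

    PNG frames (see :func:`write_frames`) remain the canonical output; this
    returns None, with a logged warning, if no encoder backend exists.
    """
    try:
        import imageio.v2 as iio2
        writer = iio2.get_writer(str(path), fps=fps)
    except Exception as exc:  # encoder backend missing
        logger.warning("video encoder unavailable (%s); PNG frames only", exc)
        return None
    with writer:
        for frame in frames:
            img8 = np.round(np.clip(frame.image, 0, 1) * 255).astype(np.uint8)
            writer.append_data(img8)
    return Path(path)
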