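"""Synthetic particle-tracking data: the stand-in for high-speed video.

The experimental record this emulates is a manual-tracking export (one row
per cell per frame).  The generator advects tracer particles through the
computed flow field, samples their positions at the camera frame interval,
quantizes to the pixel grid, adds isotropic Gaussian localization noise, and
restricts to the axial field of view.  Everything is deterministic given the
acquisition seed.

Canonical CSV schema (bit-exact): header ``track_id,frame,t_s,x_um,y_um``,
one row per particle per frame, UTF-8, '.' decimal separator.  The reader
also accepts an MTrackJ-export dialect (``TID`` -> track_id, point index
``PID`` -> frame).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import FlowField2D, FluidProperties
from .particles import ParticleProperties, advect_through_channel

__all__ = [
    "AcquisitionModel",
    "generate_track_table",
    "write_track_csv",
    "read_track_csv",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]

#: plausible high-speed-camera range for this kind of microfluidic imaging
FRAME_RATE_RANGE = (100.0, 50_000.0)


@dataclass(frozen=True)
class AcquisitionModel:
    """Camera/tracking emulation parameters.

    frame_rate : fps (within :data:`FRAME_RATE_RANGE`)
    pixel_size : um/px quantization of reported positions (0 disables)
    localization_sigma : um, isotropic Gaussian localization noise sd
    field_of_view : axial window (x_lo_um, x_hi_um) retained in the table
    seed : RNG seed; identical seed implies identical output
    """

    frame_rate: float
    pixel_size: float = 0.5
    localization_sigma: float = 0.25
    field_of_view: tuple = (-100.0, 550.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = FRAME_RATE_RANGE
        if not (lo <= self.frame_rate <= hi):
            raise ValueError(f"frame_rate outside plausible range {FRAME_RATE_RANGE}")
        if self.pixel_size < 0.0 or self.localization_sigma < 0.0:
            raise ValueError("pixel_size and localization_sigma must be >= 0")
        if not self.field_of_view[0] < self.field_of_view[1]:
            raise ValueError("field_of_view must be an increasing (lo, hi) pair")


def generate_track_table(field: FlowField2D, fluid: FluidProperties,
                         particle: ParticleProperties, releases,
                         acq: AcquisitionModel, *,
                         max_time: float = 60.0) -> pd.DataFrame:
    """Advect each release point and emit the frame-sampled noisy track table.

    ``releases`` is a sequence of ``(x0, y0)`` in meters.  Track ids are
    1-based in release order; frames count from the release instant.
    """
    releases = list(releases)
    if not releases:
        warnings.warn("empty release list: returning an empty track table",
                      stacklevel=2)
        return pd.DataFrame(columns=TRACK_COLUMNS)

    rng = np.random.default_rng(acq.seed)
    dt_frame = 1.0 / acq.frame_rate
    x_lo, x_hi = acq.field_of_view
    rows = []
    for tid, (x0, y0) in enumerate(releases, start=1):
        traj = advect_through_channel(field, fluid, particle, (x0, y0),
                                      x_stop=x_hi * 1e-6, max_time=max_time,
                                      particle_id=tid)
        n_frames = int(traj.t[-1] / dt_frame) + 1
        frames = np.arange(n_frames)
        ts = frames * dt_frame
        xs = np.interp(ts, traj.t, traj.x) * 1e6
        ys = np.interp(ts, traj.t, traj.y) * 1e6
        # noise is drawn for every frame so the FOV crop cannot change the
        # random stream alignment between configurations
        nx = rng.normal(0.0, 1.0, n_frames)
        nyz = rng.normal(0.0, 1.0, n_frames)
        if acq.pixel_size > 0.0:
            xs = np.round(xs / acq.pixel_size) * acq.pixel_size
            ys = np.round(ys / acq.pixel_size) * acq.pixel_size
        xs = xs + acq.localization_sigma * nx
        ys = ys + acq.localization_sigma * nyz
        keep = (xs >= x_lo) & (xs <= x_hi)
        rows.append(pd.DataFrame({
            "track_id": tid,
            "frame": frames[keep],
            "t_s": ts[keep],
            "x_um": xs[keep],
            "y_um": ys[keep],
        }))
    return pd.concat(rows, ignore_index=True)


def write_track_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=TRACK_COLUMNS)


_MTRACKJ_MAP = {"tid": "track_id", "pid": "frame"}


def read_track_csv(path, frame_rate: float | None = None) -> pd.DataFrame:
    """Read a track table; canonical schema or an MTrackJ-style export.

    MTrackJ columns are mapped as TID -> track_id, PID (point index) ->
    frame; position columns are matched on their leading letter (``x [um]``,
    ``y [um]``, ``t [s]``).  If the dialect lacks a time column,
    ``frame_rate`` must be given and ``t_s = frame / frame_rate``.
    """
    df = pd.read_csv(path)
    if set(TRACK_COLUMNS).issubset(df.columns):
        return df[TRACK_COLUMNS].copy()
    ren = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _MTRACKJ_MAP:
            ren[col] = _MTRACKJ_MAP[key]
        elif key.split()[0] in ("x", "y", "t"):
            ren[col] = {"x": "x_um", "y": "y_um", "t": "t_s"}[key.split()[0]]
    df = df.rename(columns=ren)
    if "frame" not in df.columns:
        raise ValueError("track file lacks a frame/PID column")
    df["frame"] = df["frame"].astype(int)
    if "t_s" not in df.columns:
        if frame_rate is None:
            raise ValueError("no time column: pass frame_rate to derive t_s")
        df["t_s"] = df["frame"] / frame_rate
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"unrecognized track table; missing {missing}")
    return df[TRACK_COLUMNS].copy()
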