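"""Trajectory tables, velocity directors and the polarization time series.

The polarization of a shoal at frame t is

    P(t) = | (1/n_eff) Σ_i u_i(t) | ,   u_i = v_i / |v_i| ,

where the sum runs over fish with a valid, fast-enough velocity at that
frame and n_eff counts them.  Velocities come from forward differences of
the tracked positions, so a table of T frames yields T − 1 director
frames.  The recording protocol trims the first and last minute of each
trial before statistics are computed.

Input dialects (CSV, NaN or empty cell = missing):

wide
    ``frame,x1,y1,...,xN,yN`` — one row per frame.
long
    ``frame,fish_id,x,y`` — one row per (frame, fish).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = [
    "TrajectoryTable",
    "DirectorSeries",
    "PolarizationSeries",
    "read_trajectories",
    "compute_directors",
    "polarization_series",
    "write_polarization",
]

DEFAULT_MIN_SPEED = 0.1  # cm/s; below this the heading is undefined


@dataclass(frozen=True)
class TrajectoryTable:
    positions: np.ndarray  # (T, N, 2) in cm, NaN where missing
    dt: float
    valid: np.ndarray  # (T, N)
    meta: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return self.positions.shape[0]

    @property
    def N(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class DirectorSeries:
    directors: np.ndarray  # (T-1, N, 2) unit vectors, NaN where invalid
    valid: np.ndarray
    dt: float
    min_speed: float
    n_positions: int  # frame count of the source table, for trimming
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PolarizationSeries:
    time: np.ndarray  # seconds
    P: np.ndarray
    P2: np.ndarray
    n_effective: np.ndarray
    valid: np.ndarray  # frames with n_effective >= 2
    meta: dict = field(default_factory=dict)


def _table_from_frame(frame_idx: np.ndarray, xy: np.ndarray, dt: float, meta: dict):
    if len(frame_idx) != len(set(frame_idx.tolist())):
        dup = pd.Series(frame_idx).duplicated()
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(f"duplicated frame index at row {row}")
    if np.any(np.diff(frame_idx) <= 0):
        row = int(np.flatnonzero(np.diff(frame_idx) <= 0)[0]) + 1
        raise FormatError(f"non-monotone frame index at row {row}")
    valid = np.isfinite(xy).all(axis=2)
    return TrajectoryTable(positions=xy, dt=dt, valid=valid, meta=meta)


def read_trajectories(
    path: str | Path,
    dialect: Literal["wide", "long"] = "wide",
    dt: float | None = None,
) -> TrajectoryTable:
    """Read a trajectory CSV; ``dt`` comes from the sidecar metadata if present.

    A ``<path>.meta.json`` sidecar (as written by the synthesizer) supplies
    dt and provenance; an explicit ``dt`` argument overrides it.  Missing
    or non-numeric cells yield masked (frame, fish) entries.
    """
    path = Path(path)
    meta: dict = {"source": str(path), "dialect": dialect}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if dt is not None:
        meta["dt"] = dt
    if meta.get("dt") is None:
        raise FormatError(
            f"{path}: no dt available; pass dt= or provide a metadata sidecar"
        )
    dt = float(meta["dt"])
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegated parsing
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    cols = list(df.columns)
    if dialect == "wide":
        if not cols or cols[0] != "frame":
            raise FormatError(f"{path}: wide dialect requires a leading 'frame' column")
        pair_cols = cols[1:]
        n = len(pair_cols) // 2
        expected = [c for i in range(1, n + 1) for c in (f"x{i}", f"y{i}")]
        if n == 0 or pair_cols != expected:
            raise FormatError(
                f"{path}: wide dialect requires columns x1,y1,...,xN,yN, got {pair_cols}"
            )
        frame_idx = df["frame"].to_numpy()
        xy = np.empty((len(df), n, 2))
        for i in range(n):
            xy[:, i, 0] = pd.to_numeric(df[f"x{i + 1}"], errors="coerce")
            xy[:, i, 1] = pd.to_numeric(df[f"y{i + 1}"], errors="coerce")
    elif dialect == "long":
        required = ["frame", "fish_id", "x", "y"]
        if cols[: len(required)] != required:
            raise FormatError(f"{path}: long dialect requires columns {required}")
        dup = df.duplicated(subset=["frame", "fish_id"])
        if dup.any():
            raise FormatError(
                f"{path}: duplicate (frame, fish_id) at row {int(dup.idxmax())}"
            )
        fish = sorted(df["fish_id"].unique().tolist())
        frames = sorted(df["frame"].unique().tolist())
        xp = df.pivot(index="frame", columns="fish_id", values="x").reindex(
            index=frames, columns=fish
        )
        yp = df.pivot(index="frame", columns="fish_id", values="y").reindex(
            index=frames, columns=fish
        )
        frame_idx = np.asarray(frames)
        xy = np.stack(
            [
                xp.apply(pd.to_numeric, errors="coerce").to_numpy(),
                yp.apply(pd.to_numeric, errors="coerce").to_numpy(),
            ],
            axis=2,
        )
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return _table_from_frame(np.asarray(frame_idx), xy, dt, meta)


def compute_directors(
    traj: TrajectoryTable, min_speed: float = DEFAULT_MIN_SPEED
) -> DirectorSeries:
    """Unit velocity directors by forward difference.

    v_i(t) = (x_i(t+1) − x_i(t)) / dt; the director at t is valid only if
    both position frames are valid and |v| >= min_speed.
    """
    if traj.T < 2:
        raise ValueError("need at least 2 frames to differentiate")
    if not traj.dt > 0:
        raise ValueError("dt must be positive")
    disp = np.diff(traj.positions, axis=0)
    speed = np.hypot(disp[:, :, 0], disp[:, :, 1]) / traj.dt
    valid = traj.valid[:-1] & traj.valid[1:] & (speed >= min_speed)
    with np.errstate(invalid="ignore", divide="ignore"):
        directors = disp / np.linalg.norm(disp, axis=2, keepdims=True)
    directors[~valid] = np.nan
    return DirectorSeries(
        directors=directors,
        valid=valid,
        dt=traj.dt,
        min_speed=min_speed,
        n_positions=traj.T,
        meta=dict(traj.meta),
    )


def polarization_series(
    directors: DirectorSeries,
    trim_start: float = 0.0,
    trim_end: float = 0.0,
) -> PolarizationSeries:
    """Per-frame polarization over the valid directors, with protocol trimming.

    Frames average over the valid subset of fish and record n_effective;
    frames with fewer than 2 valid fish are marked invalid rather than
    dropped silently.  Trimming removes director frames whose underlying
    position frames fall in the first ``trim_start`` or last ``trim_end``
    seconds of the recording (a director needs both endpoints inside the
    kept window).
    """
    dt = directors.dt
    T_dir = directors.directors.shape[0]
    k0 = int(math.ceil(trim_start / dt - 1e-9))
    k1 = directors.n_positions - int(math.ceil(trim_end / dt - 1e-9))
    lo, hi = max(k0, 0), min(k1 - 1, T_dir)
    if hi <= lo:
        raise ValueError("trim window leaves no frames")
    d = directors.directors[lo:hi]
    v = directors.valid[lo:hi]
    n_eff = v.sum(axis=1)
    sx = np.nansum(d[:, :, 0], axis=1)
    sy = np.nansum(d[:, :, 1], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.hypot(sx, sy) / n_eff
    frame_valid = n_eff >= 2
    P = np.where(frame_valid, P, np.nan)
    np.minimum(P, 1.0, out=P, where=frame_valid)
    if not frame_valid.any():
        raise ValueError("no frames with at least 2 valid fish after trimming")
    time = (np.arange(lo, hi)) * dt
    return PolarizationSeries(
        time=time,
        P=P,
        P2=P * P,
        n_effective=n_eff,
        valid=frame_valid,
        meta={**directors.meta, "trim_start": trim_start, "trim_end": trim_end},
    )


def write_polarization(series: PolarizationSeries, tsv_path, json_path=None) -> None:
    """Per-trial polarization table (TSV) and metadata JSON."""
    pd.DataFrame(
        {
            "time": series.time,
            "P": series.P,
            "P2": series.P2,
            "n_effective": series.n_effective,
        }
    ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        meta = {k: v for k, v in series.meta.items()}
        Path(json_path).write_text(json.dumps(meta, indent=1, default=str))
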