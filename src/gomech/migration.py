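"""Single-cell migration statistics from microfluidic track tables.

Cells transit straight channels along a known axis (default +x), so the
natural observable is the *net axial velocity*: net displacement projected
on the channel axis between the first and last sample of a track, divided
by elapsed time, in µm/h.  Net motion against the axis gives a negative
velocity and is retained, not clipped.  A path-length speed is available
behind ``path_length=True`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gomech.errors import InvalidParameterError

TRACK_COLUMNS = ["cell_id", "t_min", "x_um", "y_um"]


@dataclass
class TrackSet:
    """A cohort of single-cell tracks.

    ``data`` holds one row per (cell, time) sample with columns
    ``cell_id, t_min, x_um, y_um``; per-cell times must be strictly
    increasing with at least two samples per cell.
    """

    data: pd.DataFrame
    channel_axis: tuple = (1.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"track table missing columns {missing}")
        axis = np.asarray(self.channel_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise InvalidParameterError("channel axis must be non-zero")
        self.channel_axis = tuple(axis / norm)
        for cid, grp in self.data.groupby("cell_id"):
            t = grp["t_min"].to_numpy()
            if t.size < 2:
                raise InvalidParameterError(f"cell {cid!r} has < 2 samples")
            if np.any(np.diff(t) <= 0):
                raise InvalidParameterError(
                    f"cell {cid!r} has non-increasing timestamps"
                )

    @property
    def cell_ids(self):
        return list(dict.fromkeys(self.data["cell_id"]))

    def track(self, cell_id) -> pd.DataFrame:
        return self.data[self.data["cell_id"] == cell_id]


@dataclass
class MigrationStats:
    """Cohort velocity summary: per-cell velocities plus moments, µm/h."""

    velocities: np.ndarray
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n_cells: int


def per_cell_velocity(
    track: pd.DataFrame,
    axis=(1.0, 0.0),
    path_length: bool = False,
) -> float:
    """Velocity of one track in µm/h.

    Net displacement projected on ``axis`` between first and last sample,
    over elapsed time.  With ``path_length=True``, the summed step length
    over elapsed time instead (always non-negative).
    """
    t = track["t_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) == 0):
        raise InvalidParameterError("duplicate timestamps in track")
    if np.any(np.diff(t) < 0):
        raise InvalidParameterError("timestamps must be increasing")
    elapsed_h = (t[-1] - t[0]) / 60.0
    if elapsed_h <= 0:
        raise InvalidParameterError("track duration must be positive")
    xy = track[["x_um", "y_um"]].to_numpy(dtype=float)
    if path_length:
        dist = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
        return dist / elapsed_h
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return float((xy[-1] - xy[0]) @ axis) / elapsed_h


def cohort_stats(tracks: TrackSet, path_length: bool = False) -> MigrationStats:
    """Per-cell velocities and their mean, SD (sample), median and quartiles."""
    vels = np.array(
        [
            per_cell_velocity(tracks.track(cid), tracks.channel_axis, path_length)
            for cid in tracks.cell_ids
        ]
    )
    if vels.size == 0:
        raise InvalidParameterError("empty track set")
    sd = float(vels.std(ddof=1)) if vels.size > 1 else 0.0
    return MigrationStats(
        velocities=vels,
        mean=float(vels.mean()),
        sd=sd,
        median=float(np.median(vels)),
        q1=float(np.percentile(vels, 25)),
        q3=float(np.percentile(vels, 75)),
        n_cells=int(vels.size),
    )


def inhibition_percent(mean_control: float, mean_treated: float) -> float:
    """Migration inhibition, %: ``100 * (v_ctrl - v_treated) / v_ctrl``."""
    if mean_control <= 0:
        raise InvalidParameterError("control mean velocity must be positive")
    return 100.0 * (mean_control - mean_treated) / mean_control
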