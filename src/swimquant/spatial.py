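"""Vertical spatial preference and dwell-time maps.

The water body is split at the mid-level depth — 50% of the way from the
water surface to the tank bottom.  A frame counts as "upper" when the
centroid is strictly above the mid line (smaller y, since image y grows
downward); a centroid exactly on the line counts as lower.  Dwell heatmaps
are 2-D position histograms normalized to fractions of total time, and the
projection views reshape the centroid series for trajectory (x–y over
time) and vertical-movement (y over time) plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinematics import CentroidTrack


@dataclass
class OccupancySummary:
    subject_id: str
    group: str
    upper_s: float
    lower_s: float
    total_s: float

    @property
    def upper_fraction(self) -> float:
        return self.upper_s / self.total_s if self.total_s else float("nan")


@dataclass
class DwellHeatmap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    dwell: np.ndarray  # (nx, ny), fractions summing to 1


def occupancy(ct: CentroidTrack, tol_px: float = 1.0) -> OccupancySummary:
    """Time in the upper vs lower half of the water body.

    Durations are frame counts divided by fps, so upper_s + lower_s equals
    the total track time exactly.  Frames outside the configured water
    column by more than ``tol_px`` trigger a geometry-mismatch warning.
    """
    geom = ct.geometry
    outside = (ct.y < geom.surface_y - tol_px) | (ct.y > geom.bottom_y + tol_px)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} of {ct.n_frames} frames lie outside the "
            f"configured water column by more than {tol_px} px; check the "
            "tank geometry",
            stacklevel=2,
        )
    upper = int((ct.y < geom.mid_y).sum())  # strict: y == mid_y is lower
    total = ct.n_frames
    upper_s = upper / ct.fps
    lower_s = (total - upper) / ct.fps
    return OccupancySummary(
        subject_id=ct.subject_id,
        group=ct.group,
        upper_s=upper_s,
        lower_s=lower_s,
        # total time is reported as the sum so conservation is exact in
        # floating point (upper_s + lower_s == total_s bit-for-bit)
        total_s=upper_s + lower_s,
    )


def dwell_heatmap(ct: CentroidTrack, nx: int = 50, ny: int = 50) -> DwellHeatmap:
    """Fraction of time spent in each cell of an nx×ny grid over the tank.

    Positions are clipped into the tank extent first so the fractions sum
    to 1 even when a few frames fall marginally outside the configured
    geometry.
    """
    if nx < 1 or ny < 1:
        raise ValidationError("nx and ny must be >= 1")
    if ct.n_frames == 0:
        raise ValidationError("cannot build a heatmap from an empty track")
    geom = ct.geometry
    x = np.clip(ct.x, 0.0, geom.width_px)
    y = np.clip(ct.y, geom.surface_y, geom.bottom_y)
    counts, x_edges, y_edges = np.histogram2d(
        x, y, bins=[nx, ny],
        range=[[0.0, geom.width_px], [geom.surface_y, geom.bottom_y]],
    )
    return DwellHeatmap(x_edges=x_edges, y_edges=y_edges,
                        dwell=counts / ct.n_frames)


def projection_series(ct: CentroidTrack, view: str) -> pd.DataFrame:
    """Reshape the centroid series for the two plotting projections.

    ``"xy_over_time"`` returns (t, x, y) triples for trajectory plots;
    ``"yz_over_time"`` returns (t, y) pairs for vertical movement over
    time.  Data are only reshaped, never altered.
    """
    if view == "xy_over_time":
        return pd.DataFrame({"t": ct.times, "x": ct.x, "y": ct.y})
    if view == "yz_over_time":
        return pd.DataFrame({"t": ct.times, "y": ct.y})
    raise ValidationError(
        f"unknown view {view!r}; expected 'xy_over_time' or 'yz_over_time'"
    )
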