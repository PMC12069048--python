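"""Whole-body centroid trajectory and motility metrics.

The centroid ("average coordinates") is the unweighted per-frame mean of
all tracked body-part positions.  From it the pipeline computes

* total path distance (sum of Euclidean inter-frame step lengths),
* mean velocity per non-overlapping window of fixed length ("average
  velocity at regular intervals"; the window defaults to 1 s),
* rapid-swimming duration: time spent in windows whose velocity meets or
  exceeds a control-referenced threshold, control mean + k·SEM with k = 3
  by default.  The SEM is taken across control fish — each control fish's
  mean windowed velocity is one replicate — with an across-windows variant
  available for sensitivity analysis.

All quantities are in pixels / seconds; centimetre conversions are applied
only at reporting time when a pixel scale is configured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DesignError, ValidationError
from .pose_io import PoseTrack, TankGeometry


@dataclass
class CentroidTrack:
    """QC'd whole-body (x, y) time series at a fixed frame rate."""

    fps: float
    x: np.ndarray
    y: np.ndarray
    geometry: TankGeometry
    subject_id: str = "subject"
    group: str = "none"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def duration_s(self) -> float:
        return max(self.n_frames - 1, 0) / self.fps


@dataclass
class VelocitySeries:
    """Mean speed (px/s) per non-overlapping window of length window_s."""

    window_s: float
    v: np.ndarray
    fps: float

    @property
    def n_windows(self) -> int:
        return len(self.v)

    @property
    def mean_v(self) -> float:
        return float(np.mean(self.v)) if len(self.v) else float("nan")


@dataclass(frozen=True)
class RapidThreshold:
    """Control-referenced rapid-swimming cutoff: mean + k·SEM (px/s)."""

    control_mean_v: float
    control_sem_v: float
    k: float = 3.0
    n_controls: int = 0

    @property
    def threshold(self) -> float:
        return self.control_mean_v + self.k * self.control_sem_v


@dataclass
class KinematicsSummary:
    subject_id: str
    group: str
    total_distance_px: float
    mean_velocity_px_s: float
    rapid_duration_s: float
    window_s: float
    threshold_px_s: float
    total_distance_cm: float | None = None


def centroid(track: PoseTrack) -> CentroidTrack:
    """Per-frame unweighted mean of all body-part positions."""
    if not track.bodyparts:
        raise ValidationError("track has no body parts")
    x = track.data.loc[:, (slice(None), "x")].to_numpy().mean(axis=1)
    y = track.data.loc[:, (slice(None), "y")].to_numpy().mean(axis=1)
    return CentroidTrack(
        fps=track.fps, x=x, y=y, geometry=track.geometry,
        subject_id=track.subject_id, group=track.group,
    )


def step_lengths(ct: CentroidTrack) -> np.ndarray:
    return np.hypot(np.diff(ct.x), np.diff(ct.y))


def path_distance(ct: CentroidTrack) -> float:
    """Total distance traveled: sum of Euclidean inter-frame steps (px)."""
    if ct.n_frames < 2:
        warnings.warn("track has fewer than 2 frames; distance is 0", stacklevel=2)
        return 0.0
    return float(step_lengths(ct).sum())


def interval_velocity(ct: CentroidTrack, window_s: float = 1.0) -> VelocitySeries:
    """Mean speed per non-overlapping window.

    Window k covers the steps between frames ``k·w`` and ``(k+1)·w`` where
    ``w = window_s·fps`` frames, so whole windows partition the step
    sequence and their distances sum to the path distance over the covered
    span.  A trailing partial window is discarded.
    """
    w = int(round(window_s * ct.fps))
    if w < 1:
        raise ValidationError("window_s must span at least one frame")
    steps = step_lengths(ct) if ct.n_frames >= 2 else np.empty(0)
    n_windows = len(steps) // w
    if n_windows == 0:
        warnings.warn("window longer than track; empty velocity series",
                      stacklevel=2)
        return VelocitySeries(window_s=window_s, v=np.empty(0), fps=ct.fps)
    per_window = steps[: n_windows * w].reshape(n_windows, w).sum(axis=1)
    return VelocitySeries(window_s=window_s, v=per_window / window_s, fps=ct.fps)


def rapid_threshold(
    controls: list[VelocitySeries], k: float = 3.0, sem_over: str = "fish"
) -> RapidThreshold:
    """Rapid-swimming cutoff from the control group's windowed velocities.

    ``sem_over="fish"`` (default): each control fish's mean windowed
    velocity is one replicate; SEM = sd(per-fish means)/√n_fish.
    ``sem_over="windows"``: all control windows pooled, SEM over windows
    (sensitivity variant).
    """
    if len(controls) < 2:
        raise DesignError("rapid_threshold needs >= 2 control subjects for a SEM")
    per_fish = np.array([vs.mean_v for vs in controls])
    if sem_over == "fish":
        sem = float(np.std(per_fish, ddof=1) / np.sqrt(len(per_fish)))
    elif sem_over == "windows":
        pooled = np.concatenate([vs.v for vs in controls])
        sem = float(np.std(pooled, ddof=1) / np.sqrt(len(pooled)))
    else:
        raise ValidationError(f"unknown sem_over mode {sem_over!r}")
    return RapidThreshold(
        control_mean_v=float(per_fish.mean()),
        control_sem_v=sem,
        k=k,
        n_controls=len(controls),
    )


def rapid_duration(vs: VelocitySeries, thr: RapidThreshold) -> float:
    """Seconds spent in windows at or above the threshold (inclusive)."""
    return float((vs.v >= thr.threshold).sum() * vs.window_s)


def summarize(
    ct: CentroidTrack,
    thr: RapidThreshold,
    window_s: float = 1.0,
) -> KinematicsSummary:
    """Per-fish motility summary at the configured window and threshold."""
    vs = interval_velocity(ct, window_s)
    dist = path_distance(ct)
    scale = ct.geometry.px_per_cm
    return KinematicsSummary(
        subject_id=ct.subject_id,
        group=ct.group,
        total_distance_px=dist,
        mean_velocity_px_s=vs.mean_v,
        rapid_duration_s=rapid_duration(vs, thr),
        window_s=window_s,
        threshold_px_s=thr.threshold,
        total_distance_cm=None if scale is None else dist / scale,
    )
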