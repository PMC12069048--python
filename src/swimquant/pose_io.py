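"""Pose-table I/O, tank geometry and run configuration.

Coordinate convention used throughout the package: image pixel coordinates
with the origin at the top-left of the video frame, x increasing rightward
and y increasing *downward*.  The water surface therefore has a smaller y
than the tank bottom, and "upper half of the water" means ``y < mid_y``.

Pose tables follow the three-header-row CSV dialect emitted by markerless
pose-estimation tools: a ``scorer`` row, a ``bodyparts`` row and a
``coords`` row (``x`` / ``y`` / ``likelihood`` per body part), with the
first column holding the frame index.  Frame rate and tank geometry are not
carried by the dialect and are supplied via configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, PoseDialectError, ValidationError

COORDS = ("x", "y", "likelihood")
HEADER_LEVELS = ("scorer", "bodyparts", "coords")
DEFAULT_SCORER = "swimquant"


@dataclass(frozen=True)
class TankGeometry:
    """Vertical and horizontal extent of the imaged water body, in pixels.

    Parameters
    ----------
    surface_y : float
        Pixel row of the water surface (smaller y = higher in the tank).
    bottom_y : float
        Pixel row of the tank bottom; must exceed ``surface_y``.
    width_px : float
        Horizontal extent of the tank in pixels.
    px_per_cm : float, optional
        Pixel-to-centimetre scale; when present, report-level distances are
        also expressed in cm.  Analysis itself stays in pixels.
    """

    surface_y: float
    bottom_y: float
    width_px: float
    px_per_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.surface_y < self.bottom_y:
            raise ValidationError(
                f"surface_y ({self.surface_y}) must be above bottom_y "
                f"({self.bottom_y}); image y grows downward"
            )
        if not self.width_px > 0:
            raise ValidationError(f"width_px must be positive, got {self.width_px}")
        if self.px_per_cm is not None and not self.px_per_cm > 0:
            raise ValidationError(f"px_per_cm must be positive, got {self.px_per_cm}")

    @property
    def height_px(self) -> float:
        return self.bottom_y - self.surface_y

    @property
    def mid_y(self) -> float:
        """Mid-level water depth: 50% of the way from surface to bottom."""
        return self.surface_y + 0.5 * (self.bottom_y - self.surface_y)


@dataclass(eq=False)
class PoseTrack:
    """Per-frame body-part coordinates for one fish.

    ``data`` has a two-level column index (body part, coordinate) with
    coordinates ``x``/``y`` in pixels and ``likelihood`` in [0, 1]; the row
    index is the contiguous frame index starting at 0.
    """

    data: pd.DataFrame
    fps: float
    geometry: TankGeometry
    subject_id: str = "subject"
    group: str = "none"
    latent: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.data.columns.nlevels != 2:
            raise ValidationError("PoseTrack.data needs (bodypart, coord) columns")
        for bp in self.bodyparts:
            cols = tuple(self.data[bp].columns)
            if cols != COORDS:
                raise ValidationError(
                    f"body part {bp!r} has columns {cols}, expected {COORDS}"
                )
        n = len(self.data)
        if n and not np.array_equal(self.data.index.to_numpy(), np.arange(n)):
            raise ValidationError("frame index must be contiguous from 0")
        if n and len(self.data.columns):
            lik = self.data.loc[:, (slice(None), "likelihood")].to_numpy()
            if np.isnan(lik).any() or (lik < 0).any() or (lik > 1).any():
                raise ValidationError("likelihoods must lie in [0, 1]")

    @property
    def bodyparts(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        """Time spanned by the frames (n − 1 inter-frame intervals)."""
        return max(self.n_frames - 1, 0) / self.fps

    def equals(self, other: "PoseTrack") -> bool:
        return (
            self.fps == other.fps
            and self.geometry == other.geometry
            and self.subject_id == other.subject_id
            and self.group == other.group
            and self.data.equals(other.data)
        )


def frames_from_arrays(
    bodyparts: Iterable[str],
    x: np.ndarray,
    y: np.ndarray,
    likelihood: np.ndarray,
) -> pd.DataFrame:
    """Assemble a PoseTrack data frame from (n_frames, n_bodyparts) arrays."""
    bodyparts = list(bodyparts)
    x, y, likelihood = (np.asarray(a, dtype=float) for a in (x, y, likelihood))
    if not (x.shape == y.shape == likelihood.shape):
        raise ValidationError("x, y and likelihood arrays must share a shape")
    if x.ndim != 2 or x.shape[1] != len(bodyparts):
        raise ValidationError("arrays must be (n_frames, n_bodyparts)")
    cols = pd.MultiIndex.from_product(
        [bodyparts, COORDS], names=HEADER_LEVELS[1:]
    )
    out = pd.DataFrame(index=pd.RangeIndex(x.shape[0]), columns=cols, dtype=float)
    for j, bp in enumerate(bodyparts):
        out[(bp, "x")] = x[:, j]
        out[(bp, "y")] = y[:, j]
        out[(bp, "likelihood")] = likelihood[:, j]
    return out


def read_pose_csv(
    path: str | Path,
    geometry: TankGeometry,
    fps: float = 15.0,
    subject_id: str | None = None,
    group: str = "none",
) -> PoseTrack:
    """Read a three-header-row pose CSV into a :class:`PoseTrack`.

    Body parts keep file order; malformed numeric cells raise rather than
    being dropped.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
        )
    except (pd.errors.EmptyDataError, FileNotFoundError):
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise PoseDialectError(f"{path}: cannot parse pose CSV dialect: {exc}") from exc
    if tuple(raw.columns.names) != HEADER_LEVELS:
        raise PoseDialectError(
            f"{path}: expected header rows {HEADER_LEVELS}, "
            f"got {tuple(raw.columns.names)}"
        )
    if raw.shape[0] == 0:
        raise EmptyInputError(f"{path}: pose CSV has no data rows")
    # Drop the scorer level; validate per-bodypart coords below via PoseTrack.
    data = raw.droplevel(0, axis=1)
    data.columns = data.columns.set_names(HEADER_LEVELS[1:])
    try:
        data = data.astype(float)
    except (TypeError, ValueError) as exc:
        raise PoseDialectError(f"{path}: malformed numeric cell: {exc}") from exc
    idx = pd.to_numeric(data.index, errors="coerce")
    if idx.isna().any():
        raise PoseDialectError(f"{path}: non-integer frame index")
    data.index = idx.astype(int)
    if not np.array_equal(data.index.to_numpy(), np.arange(len(data))):
        raise ValidationError(f"{path}: frame index must be contiguous from 0")
    data.index = pd.RangeIndex(len(data))
    return PoseTrack(
        data=data,
        fps=fps,
        geometry=geometry,
        subject_id=subject_id if subject_id is not None else path.stem,
        group=group,
    )


def write_pose_csv(
    track: PoseTrack, path: str | Path, scorer: str = DEFAULT_SCORER
) -> Path:
    """Write a :class:`PoseTrack` in the three-header-row CSV dialect.

    The emitted file round-trips through :func:`read_pose_csv` with full
    float precision.
    """
    path = Path(path)
    bps = track.bodyparts
    header = [
        "scorer," + ",".join([scorer] * (3 * len(bps))),
        "bodyparts," + ",".join(bp for bp in bps for _ in COORDS),
        "coords," + ",".join(COORDS * len(bps)),
    ]
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        track.data.to_csv(fh, header=False)
    return path


# --- run configuration -----------------------------------------------------

DEFAULT_CONFIG: dict = {
    "fps": 15.0,
    "geometry": {
        "surface_y": 20.0,
        "bottom_y": 420.0,
        "width_px": 600.0,
        "px_per_cm": None,
    },
    "qc": {"likelihood_threshold": 0.9, "max_gap_frames": None},
    "kinematics": {"window_s": 1.0, "k_sem": 3.0},
    "spatial": {"heatmap_nx": 50, "heatmap_ny": 50},
    "stats": {"alpha": 0.05},
    "groups": {"control": "control", "treated": "treated"},
}


def load_config(path: str | Path) -> dict:
    """Load a YAML or TOML run configuration, merged over defaults."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    else:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: Mapping) -> dict:
    """Deep-merge a user mapping over :data:`DEFAULT_CONFIG`."""

    def _merge(base: dict, over: Mapping) -> dict:
        out = dict(base)
        for key, val in over.items():
            if isinstance(val, Mapping) and isinstance(out.get(key), dict):
                out[key] = _merge(out[key], val)
            else:
                out[key] = val
        return out

    return _merge(DEFAULT_CONFIG, user)


def geometry_from_config(cfg: Mapping) -> TankGeometry:
    g = cfg["geometry"]
    return TankGeometry(
        surface_y=float(g["surface_y"]),
        bottom_y=float(g["bottom_y"]),
        width_px=float(g["width_px"]),
        px_per_cm=None if g.get("px_per_cm") is None else float(g["px_per_cm"]),
    )


def replace(obj, **changes):
    """dataclasses.replace re-export (used when deriving per-subject params)."""
    return dataclasses.replace(obj, **changes)
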