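"""Likelihood gating and gap imputation for pose tracks.

Frames whose pose-estimation likelihood falls below the threshold (default
0.9; a likelihood of exactly 0.9 is retained) are treated as missing and
their x/y replaced by linear interpolation between the nearest retained
frames on each side, with time-proportional weights.  Leading and trailing
gaps, where two-sided interpolation is undefined, are filled by extending
the nearest retained value; they are flagged in the QC report.  Likelihood
values themselves are never altered, which makes the operation idempotent.
No smoothing beyond this interpolation is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import UnrecoverableTrackError, ValidationError
from .pose_io import PoseTrack


@dataclass(frozen=True)
class QcConfig:
    """likelihood_threshold in [0, 1]; max_gap_frames caps interior gap
    length (None = unlimited; a longer gap is an unrecoverable-track error)."""

    likelihood_threshold: float = 0.9
    max_gap_frames: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.likelihood_threshold <= 1.0:
            raise ValidationError("likelihood_threshold must lie in [0, 1]")
        if self.max_gap_frames is not None and self.max_gap_frames < 1:
            raise ValidationError("max_gap_frames must be >= 1 or None")


@dataclass
class QcReport:
    """Per-bodypart gating summary, serializable to JSON for the run log."""

    n_frames: int
    threshold: float
    gated: dict[str, int] = field(default_factory=dict)
    longest_gap: dict[str, int] = field(default_factory=dict)
    leading_gap: dict[str, int] = field(default_factory=dict)
    trailing_gap: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_imputed(self) -> float:
        total = self.n_frames * max(len(self.gated), 1)
        return sum(self.gated.values()) / total if total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "threshold": self.threshold,
            "fraction_imputed": self.fraction_imputed,
            "gated": self.gated,
            "longest_gap": self.longest_gap,
            "leading_gap": self.leading_gap,
            "trailing_gap": self.trailing_gap,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _interior_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each run of True values in mask."""
    runs = []
    n = len(mask)
    t = 0
    while t < n:
        if mask[t]:
            start = t
            while t < n and mask[t]:
                t += 1
            runs.append((start, t - start))
        else:
            t += 1
    return runs


def gate_and_impute(
    track: PoseTrack, cfg: QcConfig = QcConfig()
) -> tuple[PoseTrack, QcReport]:
    """Apply the likelihood gate and linear gap imputation, per body part.

    Returns a new track (retained frames bit-identical to the input) and a
    :class:`QcReport`.  A body part with zero retained frames, or with an
    interior gap longer than ``cfg.max_gap_frames``, raises
    :class:`UnrecoverableTrackError` naming the body part.
    """
    n = track.n_frames
    data = track.data.copy()
    report = QcReport(n_frames=n, threshold=cfg.likelihood_threshold)
    idx = np.arange(n)

    for bp in track.bodyparts:
        lik = data[(bp, "likelihood")].to_numpy()
        gated = lik < cfg.likelihood_threshold  # strict: exactly 0.9 retained
        report.gated[bp] = int(gated.sum())
        retained = idx[~gated]
        if retained.size == 0:
            raise UnrecoverableTrackError(
                f"body part {bp!r} has no frames at or above the likelihood "
                f"threshold {cfg.likelihood_threshold}"
            )
        runs = _interior_runs(gated)
        report.longest_gap[bp] = max((length for _, length in runs), default=0)
        report.leading_gap[bp] = int(retained[0])
        report.trailing_gap[bp] = int(n - 1 - retained[-1])
        if cfg.max_gap_frames is not None:
            for start, length in runs:
                interior = start > 0 and start + length < n
                if interior and length > cfg.max_gap_frames:
                    raise UnrecoverableTrackError(
                        f"body part {bp!r}: interior gap of {length} frames at "
                        f"frame {start} exceeds max_gap_frames={cfg.max_gap_frames}"
                    )
        if gated.any():
            for axis in ("x", "y"):
                vals = data[(bp, axis)].to_numpy().copy()
                # np.interp: linear between anchors, nearest-value extension
                # at the edges; retained frames are left untouched.
                filled = np.interp(idx[gated], retained, vals[retained])
                vals[gated] = filled
                data[(bp, axis)] = vals

    out = PoseTrack(
        data=data,
        fps=track.fps,
        geometry=track.geometry,
        subject_id=track.subject_id,
        group=track.group,
        latent=track.latent,
    )
    return out, report
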