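"""Synthetic swim tracks and qPCR datasets.

The swim generator emulates the statistical structure the downstream
analysis assumes, so every stage is testable without a recording:

* a two-state (cruise / rapid) Markov speed process — each frame the fish
  moves exactly ``speed × dt`` pixels along its path;
* a correlated horizontal walk (persistent direction sign) with reflecting
  side walls;
* vertical depth preference as an exact AR(1) (discrete Ornstein–Uhlenbeck)
  pull toward a preferred depth.  The preferred depth is placed at
  ``mid_y − σ_st · Φ⁻¹(p_upper)`` where ``σ_st`` is the stationary depth
  spread, so the stationary probability of being in the upper half equals
  ``p_upper`` in closed form; the initial depth is drawn from the
  stationary law, which keeps short-track occupancy time-averages unbiased;
* body parts as fixed offsets around the latent centroid plus Gaussian
  jitter, with likelihood dropouts whose coordinates are corrupted
  (uniform over the tank) and whose likelihood falls below the QC gate.

The qPCR generator draws standard-series and sample Ct values from a
log-linear standard curve ``Ct = intercept + slope·log10(copies)`` with
Gaussian Ct noise, a per-fish global scale (lognormal, cancelled by
reference normalization) and a treated-group fold change on the target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .pose_io import PoseTrack, TankGeometry, frames_from_arrays

DEFAULT_BODYPART_OFFSETS: dict[str, tuple[float, float]] = {
    "eye": (18.0, 0.0),
    "operculum": (10.0, -2.0),
    "dorsal_fin": (0.0, -8.0),
    "pelvic_fin": (-2.0, 8.0),
    "caudal_fin": (-20.0, 0.0),
    "torso": (0.0, 0.0),
}

# Dropout likelihoods land in [0, 0.9); retained ones in [0.95, 1], so the
# >= 0.9 QC gate is unambiguous.
DROPOUT_LIK_HIGH = 0.9
RETAINED_LIK_LOW = 0.95


@dataclass(frozen=True)
class SwimParams:
    """Parameters of the regime-switching bounded swim model.

    ``regime_switch_prob`` may be a single per-frame switch probability
    (symmetric chain, 50% rapid occupancy at stationarity) or a pair
    ``(p_cruise_to_rapid, p_rapid_to_cruise)``.
    """

    fps: float = 15.0
    duration_s: float = 300.0
    regime_speeds: tuple[float, float] = (40.0, 140.0)  # (cruise, rapid) px/s
    regime_switch_prob: float | tuple[float, float] = (0.02, 0.10)
    p_upper: float = 0.5
    heading_persistence: float = 0.95
    bodypart_offsets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BODYPART_OFFSETS)
    )
    jitter_sd_px: float = 1.0
    p_drop: float = 0.02
    depth_sd_px: float = 35.0       # stationary spread of the depth process
    vertical_step_px: float = 0.8   # per-frame vertical innovation SD
    speed_cv: float = 0.1           # within-regime speed variability
    seed: int = 0

    def __post_init__(self) -> None:
        p_cr, p_rc = self.switch_probs
        for name, p in [
            ("p_upper", self.p_upper),
            ("p_drop", self.p_drop),
            ("cruise→rapid switch prob", p_cr),
            ("rapid→cruise switch prob", p_rc),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        if not 0.0 <= self.heading_persistence < 1.0:
            raise ValidationError("heading_persistence must lie in [0, 1)")
        if min(self.regime_speeds) < 0:
            raise ValidationError("regime speeds must be non-negative")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValidationError("duration_s and fps must be positive")
        if self.jitter_sd_px < 0 or self.speed_cv < 0:
            raise ValidationError("jitter_sd_px and speed_cv must be >= 0")
        if not 0 < self.vertical_step_px <= self.depth_sd_px:
            raise ValidationError(
                "need 0 < vertical_step_px <= depth_sd_px for a stable depth process"
            )

    @property
    def switch_probs(self) -> tuple[float, float]:
        p = self.regime_switch_prob
        if np.isscalar(p):
            return float(p), float(p)
        return float(p[0]), float(p[1])

    @property
    def rapid_occupancy(self) -> float:
        """Stationary fraction of time in the rapid regime (closed form)."""
        p_cr, p_rc = self.switch_probs
        if p_cr + p_rc == 0:
            return 0.0
        return p_cr / (p_cr + p_rc)

    @property
    def n_frames(self) -> int:
        """Frames per track: duration_s spans exactly duration·fps steps."""
        return int(round(self.duration_s * self.fps)) + 1


def preferred_depth(params: SwimParams, geometry: TankGeometry) -> float:
    """Depth whose AR(1) stationary law puts mass ``p_upper`` above mid_y."""
    p = min(max(params.p_upper, 1e-12), 1 - 1e-12)
    return geometry.mid_y - params.depth_sd_px * norm.ppf(p)


def _validate_offsets(params: SwimParams, geometry: TankGeometry) -> None:
    if not params.bodypart_offsets:
        raise ValidationError("at least one body part is required")
    for bp, (dx, dy) in params.bodypart_offsets.items():
        if abs(dx) >= geometry.width_px / 2 or abs(dy) >= geometry.height_px / 2:
            raise ValidationError(
                f"body part {bp!r} offset ({dx}, {dy}) exceeds half the tank extent"
            )


def simulate_centroid(
    params: SwimParams, geometry: TankGeometry, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent centroid path; columns x, y, regime (0 cruise / 1 rapid), speed."""
    n = params.n_frames
    dt = 1.0 / params.fps
    p_cr, p_rc = params.switch_probs
    v_cruise, v_rapid = params.regime_speeds

    # Regime chain, started from its stationary distribution.
    regime = np.empty(n, dtype=np.int8)
    regime[0] = rng.random() < params.rapid_occupancy
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        p_switch = p_rc if regime[t - 1] else p_cr
        regime[t] = regime[t - 1] ^ (u[t - 1] < p_switch)

    speed = np.where(regime == 1, v_rapid, v_cruise).astype(float)
    if params.speed_cv > 0:
        k = 1.0 / params.speed_cv**2
        speed *= rng.gamma(shape=k, scale=1.0 / k, size=n)

    # Depth AR(1): y_{t+1} = y_t + kappa (y* - y_t) + sigma_v eps, clipped so
    # the per-frame vertical move never exceeds the planned step length.
    sigma_st = params.depth_sd_px
    sigma_v = params.vertical_step_px
    kappa = 1.0 - np.sqrt(1.0 - (sigma_v / sigma_st) ** 2)
    y_star = preferred_depth(params, geometry)

    y0 = y_star + sigma_st * rng.standard_normal()
    y0 = float(np.clip(y0, geometry.surface_y, geometry.bottom_y))
    x0 = float(rng.uniform(0.1 * geometry.width_px, 0.9 * geometry.width_px))

    eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    flip = rng.random(n - 1) < (1.0 - params.heading_persistence) / 2.0
    sign = 1.0 if rng.random() < 0.5 else -1.0

    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = x0, y0
    surf, bot, width = geometry.surface_y, geometry.bottom_y, geometry.width_px
    for t in range(1, n):
        step = speed[t] * dt
        dy = kappa * (y_star - y[t - 1]) + sigma_v * eps[t - 1]
        dy = min(max(dy, -step), step)
        dx = sign * np.sqrt(max(step * step - dy * dy, 0.0))
        if flip[t - 1]:
            sign = -sign
        xn = x[t - 1] + dx
        yn = y[t - 1] + dy
        if xn < 0.0:
            xn = -xn
            sign = -sign
        elif xn > width:
            xn = 2.0 * width - xn
            sign = -sign
        if yn < surf:
            yn = 2.0 * surf - yn
        elif yn > bot:
            yn = 2.0 * bot - yn
        x[t], y[t] = xn, yn
    return pd.DataFrame({"x": x, "y": y, "regime": regime, "speed": speed})


def simulate_track(
    params: SwimParams,
    geometry: TankGeometry,
    subject_id: str = "fish",
    group: str = "control",
) -> PoseTrack:
    """Simulate one fish: latent centroid plus per-bodypart observations.

    The returned track carries the latent centroid path in ``track.latent``
    (in-memory only; not serialized by ``write_pose_csv``).
    """
    _validate_offsets(params, geometry)
    rng = np.random.default_rng(params.seed)
    latent = simulate_centroid(params, geometry, rng)
    n = len(latent)
    bps = list(params.bodypart_offsets)
    nb = len(bps)

    offsets = np.array([params.bodypart_offsets[bp] for bp in bps])
    x = latent["x"].to_numpy()[:, None] + offsets[:, 0][None, :]
    y = latent["y"].to_numpy()[:, None] + offsets[:, 1][None, :]
    if params.jitter_sd_px > 0:
        x = x + rng.normal(0.0, params.jitter_sd_px, size=(n, nb))
        y = y + rng.normal(0.0, params.jitter_sd_px, size=(n, nb))

    drop = rng.random((n, nb)) < params.p_drop
    lik = rng.uniform(RETAINED_LIK_LOW, 1.0, size=(n, nb))
    if drop.any():
        lik[drop] = rng.uniform(0.0, DROPOUT_LIK_HIGH, size=int(drop.sum()))
        # Dropped detections are garbage: uniform over the tank extent.
        x[drop] = rng.uniform(0.0, geometry.width_px, size=int(drop.sum()))
        y[drop] = rng.uniform(
            geometry.surface_y, geometry.bottom_y, size=int(drop.sum())
        )

    data = frames_from_arrays(bps, x, y, lik)
    return PoseTrack(
        data=data,
        fps=params.fps,
        geometry=geometry,
        subject_id=subject_id,
        group=group,
        latent=latent,
    )


def subject_seed(master_seed: int, group_index: int, subject_index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), group_index, subject_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(
    params_control: SwimParams,
    params_treated: SwimParams,
    n_per_group: int,
    geometry: TankGeometry,
    seed: int = 0,
    group_labels: tuple[str, str] = ("control", "treated"),
) -> list[PoseTrack]:
    """Simulate n control + n treated tracks with independent subject seeds."""
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    tracks: list[PoseTrack] = []
    for g_idx, (label, base) in enumerate(
        zip(group_labels, (params_control, params_treated))
    ):
        for i in range(n_per_group):
            p = dataclasses.replace(base, seed=subject_seed(seed, g_idx, i))
            tracks.append(
                simulate_track(p, geometry, subject_id=f"{label}_{i:02d}", group=label)
            )
    return tracks


# --- qPCR simulation -------------------------------------------------------


@dataclass(frozen=True)
class QpcrSimParams:
    """Log-linear standard curve and sample-generation parameters.

    ``effect_multiplier`` may be a scalar (single time point) or a sequence
    of per-time-point fold changes of the target transcript in the treated
    group relative to control.
    """

    slope: float = -3.3219280948873623  # Ct per log10(copies); perfect doubling
    intercept: float = 40.0             # Ct at one copy
    dilution_points: int = 6
    dilution_factor: float = 10.0
    ct_noise_sd: float = 0.15
    n_fish_per_group: int = 12
    effect_multiplier: float | tuple[float, ...] = 2.0
    base_copies: float = 100.0          # lowest standard
    target_base_copies: float = 1.0e5   # control-group target abundance
    ref_base_copies: float = 1.0e8      # 18S abundance
    fish_scale_sd: float = 0.2          # lognormal per-fish global scale (log SD)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError("standard-curve slope must be negative")
        if self.dilution_points < 2:
            raise ValidationError("need at least 2 dilution points")
        if self.ct_noise_sd < 0 or self.fish_scale_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if min(self.base_copies, self.target_base_copies, self.ref_base_copies) <= 0:
            raise ValidationError("copy numbers must be positive")

    @property
    def effect_multipliers(self) -> tuple[float, ...]:
        m = self.effect_multiplier
        if np.isscalar(m):
            return (float(m),)
        return tuple(float(v) for v in m)

    def ct_of(self, copies: float) -> float:
        return self.intercept + self.slope * np.log10(copies)


def simulate_qpcr(params: QpcrSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (standards, samples) Ct tables.

    Standards cover both the target and the 18S reference with known copy
    numbers spanning ``dilution_factor**(dilution_points - 1)``.  Samples
    hold one target and one 18S Ct per fish per group per time point.
    """
    rng = np.random.default_rng(params.seed)
    copies = params.base_copies * params.dilution_factor ** np.arange(
        params.dilution_points
    )

    rows = []
    for target in ("target", "18S"):
        for c in copies:
            ct = params.ct_of(c) + rng.normal(0.0, params.ct_noise_sd)
            rows.append(
                dict(role="standard", target=target, copies=c, Ct=ct,
                     group=pd.NA, fish_id=pd.NA, time_point=pd.NA)
            )
    standards = pd.DataFrame(rows)

    rows = []
    for tp, mult in enumerate(params.effect_multipliers):
        for group, fold in (("control", 1.0), ("treated", mult)):
            for i in range(params.n_fish_per_group):
                scale = float(
                    np.exp(rng.normal(0.0, params.fish_scale_sd))
                ) if params.fish_scale_sd > 0 else 1.0
                fish = f"{group}_{i:02d}"
                for target, base in (
                    ("target", params.target_base_copies * fold),
                    ("18S", params.ref_base_copies),
                ):
                    ct = params.ct_of(base * scale) + rng.normal(
                        0.0, params.ct_noise_sd
                    )
                    rows.append(
                        dict(role="sample", target=target, copies=pd.NA, Ct=ct,
                             group=group, fish_id=fish, time_point=tp)
                    )
    samples = pd.DataFrame(rows)
    return standards, samples
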