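"""qPCR absolute quantification and %Ctrl normalization.

Calibration follows the universal log-linear model

    Ct = intercept + slope · log10(copies),        slope < 0,

fitted by ordinary least squares on a plasmid-standard dilution series.
Amplification efficiency is ``10^(−1/slope) − 1`` (1.0 = perfect doubling
per cycle) and curve quality is gated on |r| ≥ 0.95 and on the dynamic
range of the standards; failing curves are flagged, never silently used.

Sample Ct values invert the curve to absolute quantities, are normalized
by the 18S reference measured in the same sample, and are expressed as a
percentage of the mean normalized value of the time-matched control group
("%Ctrl") — the transformation that lets fish with different basal
expression be pooled without inflating variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, ValidationError

DEFAULT_MIN_R = 0.95
DEFAULT_MIN_DYNAMIC_RANGE = 1.0e5


@dataclass
class StandardCurve:
    slope: float                  # Ct per log10(copies)
    intercept: float              # Ct at one copy
    r: float                      # Pearson r of Ct vs log10(copies)
    dynamic_range: float          # max/min standard quantity
    n_points: int
    copies_range: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 10^(−1/slope) − 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def passes_qc(self) -> bool:
        return not self.flags


def fit_standard_curve(
    copies,
    ct,
    min_r: float = DEFAULT_MIN_R,
    min_dynamic_range: float | None = DEFAULT_MIN_DYNAMIC_RANGE,
) -> StandardCurve:
    """OLS fit of Ct on log10(copies) with curve-quality flags."""
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.shape != ct.shape or copies.ndim != 1:
        raise ValidationError("copies and Ct must be 1-D arrays of equal length")
    if (copies <= 0).any():
        raise ValidationError("standard copy numbers must be positive")
    if len(np.unique(copies)) < 3:
        raise ValidationError("need >= 3 distinct dilution points")
    logq = np.log10(copies)
    fit = stats.linregress(logq, ct)
    curve = StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        dynamic_range=float(copies.max() / copies.min()),
        n_points=len(copies),
        copies_range=(float(copies.min()), float(copies.max())),
    )
    if curve.slope >= 0:
        curve.flags.append("nonnegative_slope")
    if abs(curve.r) < min_r:
        curve.flags.append("low_r")
    if min_dynamic_range is not None and curve.dynamic_range < min_dynamic_range:
        curve.flags.append("narrow_dynamic_range")
    return curve


def quantify(ct, curve: StandardCurve, warn_extrapolation: bool = True):
    """Invert the standard curve: copies = 10^((Ct − intercept)/slope).

    Accepts a scalar or array of Ct values.  Quantities outside the
    standards' range are flagged with a warning (extrapolation).
    """
    if curve.slope == 0:
        raise ValidationError("cannot invert a standard curve with slope 0")
    ct_arr = np.asarray(ct, dtype=float)
    copies = 10.0 ** ((ct_arr - curve.intercept) / curve.slope)
    if warn_extrapolation:
        lo, hi = curve.copies_range
        # small relative margin so quantities at the range ends do not warn
        out = (copies < lo * (1 - 1e-9)) | (copies > hi * (1 + 1e-9))
        if out.any():
            warnings.warn(
                f"{int(np.sum(out))} quantit(ies) fall outside the standards' "
                f"range [{lo:g}, {hi:g}]; extrapolating",
                stacklevel=2,
            )
    return copies if ct_arr.shape else float(copies)


def fit_curves(standards: pd.DataFrame, **qc_kwargs) -> dict[str, StandardCurve]:
    """One standard curve per target from a tidy standards table
    (columns: target, copies, Ct)."""
    return {
        target: fit_standard_curve(sub["copies"], sub["Ct"], **qc_kwargs)
        for target, sub in standards.groupby("target", sort=False)
    }


def quantify_samples(
    samples: pd.DataFrame,
    curves: dict[str, StandardCurve],
    reference: str = "18S",
) -> pd.DataFrame:
    """Absolute quantities and reference-normalized expression per fish.

    ``samples`` is tidy (columns: target, Ct, group, fish_id, time_point)
    with one target row and one reference row per fish per time point.
    Returns one record per fish per non-reference target with columns
    target_quantity, reference_quantity, normalized.
    """
    if reference not in curves:
        raise ValidationError(f"no standard curve for reference {reference!r}")
    sub = samples.copy()
    sub["quantity"] = [
        quantify(row.Ct, curves[row.target], warn_extrapolation=False)
        for row in sub.itertuples()
    ]
    keys = ["fish_id", "group", "time_point"]
    ref = (
        sub[sub["target"] == reference]
        .set_index(keys)["quantity"]
        .rename("reference_quantity")
    )
    out = sub[sub["target"] != reference].rename(
        columns={"quantity": "target_quantity"}
    )
    out = out.merge(ref, left_on=keys, right_index=True, how="left")
    if out["reference_quantity"].isna().any():
        missing = out.loc[out["reference_quantity"].isna(), "fish_id"].tolist()
        raise PairingError(f"no {reference} measurement for fish {missing}")
    out["normalized"] = out["target_quantity"] / out["reference_quantity"]
    return out[keys + ["target", "target_quantity", "reference_quantity",
                       "normalized"]].reset_index(drop=True)


def to_pct_ctrl(
    records: pd.DataFrame, control_group: str = "control"
) -> pd.DataFrame:
    """Express normalized values as % of the time-matched control mean.

    Adds a ``pct_ctrl`` column: 100 × normalized / mean(normalized of the
    control group at the same target and time point).  By construction the
    control group's pct_ctrl averages to 100 at every time point.
    """
    out = records.copy()
    out["pct_ctrl"] = np.nan
    for (target, tp), idx in out.groupby(["target", "time_point"]).groups.items():
        block = out.loc[idx]
        ctrl = block.loc[block["group"] == control_group, "normalized"]
        if ctrl.empty:
            raise PairingError(
                f"no control ({control_group!r}) records for target {target!r} "
                f"at time point {tp!r}"
            )
        out.loc[idx, "pct_ctrl"] = 100.0 * block["normalized"] / ctrl.mean()
    return out
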