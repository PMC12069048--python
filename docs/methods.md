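# Methods

## Coordinate convention and inputs

All analysis happens in image pixel coordinates: origin top-left, x
rightward, y **downward**. The water surface is the smallest y of the
water column and "upper half" means y below (numerically smaller than)
the mid-level depth `mid_y = surface_y + 0.5·(bottom_y − surface_y)`.
Pose tables use the three-header-row CSV dialect (scorer / bodyparts /
coords rows, frame index in the first column) with `(x, y, likelihood)`
per body part. The dialect carries neither frame rate nor tank geometry,
so both are supplied by configuration; the default frame rate is 15
frames/s. Distances stay in pixels; a `px_per_cm` scale, when configured,
is applied only in per-fish report rows.

## QC: likelihood gate and imputation

Per body part and axis, frames with likelihood < 0.9 (configurable) are
marked missing; likelihood exactly at the threshold is retained. Missing
interior frames are linearly interpolated between the nearest retained
frames with time-proportional weights; leading/trailing gaps, where a
second anchor does not exist, extend the nearest retained value and are
flagged in the QC report. Likelihood values are never altered — only
coordinates are imputed — which makes the operation idempotent and keeps
retained frames bit-identical. An optional `max_gap_frames` cap turns
overlong interior gaps into a hard error rather than silently bridging
them; a body part with no retained frame at all is likewise a hard error.
No smoothing (Kalman, Savitzky–Golay, …) is applied beyond this
interpolation.

## Motility metrics

The whole-body centroid is the unweighted mean of all body-part
positions per frame. Total distance is the sum of Euclidean inter-frame
step lengths. "Average velocity at regular intervals" uses
non-overlapping windows of `window_s` seconds (default 1 s = 15 frames);
window *k* covers the steps between frames `k·w` and `(k+1)·w`, so whole
windows partition the step sequence and window distances sum exactly to
the path distance over the covered span; a trailing partial window is
discarded rather than rescaled, keeping windows identically distributed.

Rapid swimming is defined against the control group: threshold =
control mean windowed velocity + *k*·SEM with *k* = 3 by default, and a
window counts as rapid when its velocity is ≥ the threshold (inclusive).
Two interpretations were open and are resolved as follows. (i) The SEM's
unit of replication is the control **fish** (SD of per-fish mean
velocities / √n); an across-windows variant is available
(`sem_over="windows"`) for sensitivity analysis. A threshold of 3·SEM
*alone* (without the control mean) was rejected: it would classify
essentially every window as rapid. (ii) Rapid classification operates on
windowed velocities, not per-frame speeds, so the statistic and its
threshold live on the same scale; per-frame granularity is recovered by
setting `window_s` to one frame. The threshold definition used is
recorded in every run manifest.

## Spatial preference

A frame is "upper" when the centroid is strictly above `mid_y`; a
centroid exactly on the line counts as lower (documented tie-break,
covered by a boundary test). Durations are frame counts / fps and the
reported total is the sum of the two, so conservation holds exactly in
floating point. Dwell heatmaps are 2-D histograms over a 50×50 grid
(configurable; resolution is cosmetic) spanning the configured tank,
normalized to fractions; positions are clipped into the tank first so
the map always sums to 1. The X–Y and Y–Z projection views are pure
reshapes of the centroid series for plotting.

## Synthetic swim model

The generator produces the statistical structure the analysis assumes,
not hydrodynamic realism:

* **Speed**: a two-state Markov chain (cruise/rapid) with per-frame
  switch probabilities `(p_cruise→rapid, p_rapid→cruise)`; stationary
  rapid occupancy `p_cr/(p_cr+p_rc)` in closed form, and the chain starts
  from it. Within a regime the speed is the regime mean times gamma
  noise (CV 0.1 by default). Each frame the centroid moves exactly
  `speed·dt` along its path, so regime speeds are recoverable from
  windowed velocities.
* **Depth preference**: the vertical component follows an exact AR(1)
  (discrete Ornstein–Uhlenbeck) pull toward a preferred depth, with
  innovation SD `vertical_step_px` (0.8 px/frame) and stationary SD
  `depth_sd_px` (35 px; the demo uses 20 px for faster vertical mixing).
  The preferred depth is `mid_y − depth_sd_px·Φ⁻¹(p_upper)`, so the
  stationary probability of being above mid-level equals `p_upper`
  exactly, and the initial depth is drawn from the stationary law, which
  keeps short-track occupancy time-averages unbiased. The vertical move
  is clipped to the frame's planned step length (rare under defaults);
  the horizontal component takes up the remaining step length with a
  persistent direction sign (flip probability `(1−heading_persistence)/2`
  per frame) — a 1-D correlated walk standing in for a full heading
  process. Walls, surface and bottom reflect.
* **Observation model**: each body part is the centroid plus a fixed
  offset plus Gaussian jitter (1 px). With probability `p_drop` a
  detection "drops out": its likelihood is drawn uniformly on [0, 0.9)
  and its coordinates are replaced by garbage uniform over the tank;
  retained detections get likelihood on [0.95, 1]. The gap between 0.9
  and 0.95 makes the ≥ 0.9 gate unambiguous in tests.
* **Cohorts**: per-subject seeds derive deterministically from the
  master seed via `SeedSequence([master, group_index, subject_index])`,
  so cohorts are reproducible and subjects independent.

What the generator does **not** emulate: burst-glide microstructure,
wall-following and thigmotaxis, feeding events, occlusion-correlated
dropout (dropout here is independent across frames and body parts), or
any interaction between speed and depth preference. Tests passing on
this generator therefore validate the *estimators* (that the pipeline
recovers known generating parameters), not the biological realism of any
particular recording.

Default study conditions mirror the experimental design the pipeline
targets: 12 fish per group, 5-min tracks at 15 frames/s, six body parts.
The demo's treated group (`p_upper` 0.8 vs 0.2, rapid-state occupancy
25% vs ≈5%, shared regime speeds 40/140 px/s) encodes a surface-biased,
high-activity phenotype; speeds in pixels are free parameters of the
simulator — no published distribution of real swim speeds was available
to fit — and are documented, not fitted.

## qPCR quantification

Calibration uses the universal log-linear model
`Ct = intercept + slope·log10(copies)` fitted by OLS to a plasmid
dilution series (default 6 points, 10-fold steps, 10⁵ dynamic range).
Efficiency is `10^(−1/slope) − 1`; curves with |r| < 0.95 or a dynamic
range below the configured minimum are flagged and never silently used.
Quantities invert the curve; values outside the standards' range are
flagged as extrapolation. Normalization divides the target quantity by
the 18S quantity from the same sample (18S is the sole reference; the
β-actin/GAPDH alternatives are out of scope), and %Ctrl is
`100 × normalized / arithmetic mean of the time-matched control group's
normalized values`, so control means are 100 by construction and any
per-fish global scale cancels. The qPCR simulator draws Ct values from
the same model with Gaussian Ct noise, a lognormal per-fish scale
applied to target and reference alike (cancelled by normalization —
this is why the noiseless 2-fold induction recovers exactly 200%), and a
per-time-point fold change in the treated group.

## Statistics

One-way fixed-effects ANOVA (F = MS_between/MS_within via
`scipy.stats.f_oneway`) feeds the Newman–Keuls step-down procedure:
group means sorted, the widest range tested first against the
studentized-range distribution (range parameter = number of means
spanned, `scipy.stats.studentized_range`), and a sub-range tested only
when every enclosing range was rejected. Unbalanced pairs use the
harmonic mean of the two group sizes (Tukey–Kramer-style); MS_within of
zero is a degenerate-input error. Because sub-ranges use smaller range
parameters, Newman–Keuls rejects a superset of Tukey-HSD rejections on
balanced data — a property used as an independent cross-check in the
tests.

Time courses use two-way ANOVA (time × treatment with interaction) via
statsmodels OLS on complete **balanced** designs only; unbalanced data
are rejected rather than silently approximated (with equal cell counts
the Type I/II/III distinction vanishes). Post-hoc contrasts compare each
treated cell with its time-matched control using the pooled within-cell
mean square, with Bonferroni adjustment (raw p × number of comparisons,
capped at 1); only treated-vs-control contrasts are made, not all cell
pairs. Significance is α = 0.05 throughout, rendered as an asterisk in
report tables.

## Problem sizes and numerical choices

The shipped test and demo sizes — 12 fish/group, 5-min tracks, 10⁴
replicates for the ANOVA null-calibration check, 10⁵ frames for the
multinomial heatmap check — are the package's chosen validation
conditions; Monte-Carlo checks use 3-SE (or 3 binomial-SE) tolerances
with fixed seeds. CSV round trips preserve full float precision
(`float_precision="round_trip"` on read). Occupancy reports the total as
`upper_s + lower_s` so conservation is exact in floating point.
Reported velocities and thresholds are in px/s; all tie-breaks
(likelihood = 0.9 retained, window velocity = threshold rapid,
y = mid_y lower) are inclusive in the documented direction.

## Known limitations

* The generator's vertical process mixes slowly relative to a 5-min
  track (by design, depth preference persists for minutes), so
  single-fish upper-fraction estimates are noisy; cohort means are
  unbiased because initial depths are drawn from the stationary law.
* Newman–Keuls controls the familywise error only weakly for k > 3
  groups (a known property of the procedure, inherited deliberately).
* The pose dialect reader handles the CSV variant only, not HDF5.
* Heatmap "clustering" is visual; no partitioning algorithm is applied.
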