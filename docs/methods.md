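# Methods

This note documents the models, conventions and numerical choices behind
`irtbat`, and what the synthetic phantoms do and do not establish about
real data.

## Radiometric conversion

Thermal cameras report raw counts; temperature is recovered by the
standard Planck-law inversion for microbolometer sensors,

    T(K) = B / ln( R1 / (R2 · (S_obj + O)) + F ),

with the object signal corrected for reflected ambient radiation,
`S_obj = (S_raw − (1−ε)·S_refl)/ε`, where `S_refl` is the signal a
blackbody at the reflected temperature would produce. The five constants
(R1, R2, B, F, O), emissivity and reflected temperature travel in a JSON
sidecar next to each 16-bit PNG frame, so data remain vendor-file-free and
bit-exact on disk. The inverse map (temperature → counts) is exact before
integer quantization; one count is worth ≈ 0.018 °C near skin temperature
for the default constants (R1 = 17000, R2 = 0.045, B = 1430 K, F = 1,
O = −300, ε = 0.98, T_refl = 295.15 K — representative magnitudes, not a
specific camera's calibration). Atmospheric transmission is not modelled:
over an indoor path of a few metres the correction is far below sensor
noise. This is a known limitation for long-path or outdoor use.

## ROI construction

Coordinates are 0-based, x = column, y = row, origin top-left;
"left/right" are image sides. The supraclavicular ROI is a closed polygon:
superolateral apex → neck contour → acromioclavicular apex → sternal apex
→ back. The neck contour is found per row as the maximum of the horizontal
temperature-gradient magnitude within ±30 px of a straight-line prior
between the two lateral apices, with parabolic sub-pixel refinement;
endpoint rows are pinned to the apices. Rows whose search band spans less
than 3 °C raise an error naming the row — the method presumes a background
several degrees cooler than skin. Detection is invariant to adding a
constant to the frame (gradient-based).

Rasterization uses a pixel-cell half-coverage rule: a pixel belongs to the
mask when the polygon covers at least half of the unit cell centred on it
(ties included). This rule was chosen over center-in rules because it is
area-faithful (the mask area tracks the polygon's geometric area) and
symmetric under reflection, so mirror-image apex sets produce mirror-image
masks; its one quirk is that polygon edges lying exactly on cell-center
lines are half-covered ties and are then included as a whole row/column,
which only matters for polygons aligned to the pixel grid exactly.

The sternal reference is a circle of 10 px diameter placed one diameter
(10 px, configurable) below the sternal apex — "immediately below" is not
quantified in the field, so one diameter is adopted as the convention —
with pixel-center distance ≤ radius, ties included (81 px at an integer
center).

## Time series and outcomes

Per frame, T_SCR is the median of the hottest k = ceil(0.1·N) ROI pixels
(stable descending sort, so value ties at the cutoff are broken by scan
order; median of the k values, mean of the two middle ones for even k).
The reference statistic is the mean over the reference circle (median
available as an option; the mean is the default because the 81-px circle
sits on homogeneous skin where the two are indistinguishable and the mean
has lower variance). The relative series is hotspot − reference computed
per frame *before* smoothing; both absolute and relative series are then
smoothed with a centred period-5 moving average (valid mode, output length
n−4, centre timestamps). All windows are half-open [start, end): base =
mean over [onset, onset+60 s) of the smoothed series, peak = max over
[onset, onset+600 s) ("initial") or [onset, ∞) ("initial+final"), delta =
peak − base. Peaks are taken on the smoothed series. The primary reported
outcome is the right ROI relative to the reference; both sides and kinds
are always computed.

## Frame registration and difference video

Sequential frames are registered to a baseline with a similarity transform
(tx, ty, rotation about the image centre, scale), found by Powell
minimization of the mean-squared temperature difference on a two-level
pyramid, seeded by phase correlation. Bilinear interpolation; pixels
mapped outside the frame are excluded from the metric. The recovery
envelope verified by test is |t| ≤ 10 px, |θ| ≤ 5°, s ∈ [0.95, 1.05] to
within 0.5 px / 0.5° / 0.01. Difference frames map Δ = frame − baseline
onto a fixed piecewise-linear colormap with breakpoints at 0 (white),
±range/2 (red/blue) and ±range (yellow/black), range 2 °C by default,
clamping beyond. Averaging follows registration (register-then-average).

## MIP and hotspot

`MIP(x, y) = max_z V(x, y, z)` exactly, on the native grid (no resampling
before projection); the projection axis defaults to the third array axis
and is configurable because the anatomical "coronal" axis depends on
acquisition orientation. The MIP hotspot uses the identical selection rule
as the thermal hotspot. The regional kinetic estimate MR(gluc)_BAT is an
external per-subject scalar input, not computed here.

## Locally weighted mean transformation

At each control point a full bivariate quadratic (1, x, y, x², xy, y²) per
output coordinate is least-squares fitted to its 16 nearest control points
(self included, Euclidean distance in source space), in locally centred
coordinates scaled by the neighbourhood radius R_i (distance to the most
distant neighbour) for conditioning. Evaluation blends local polynomials
with Goshtasby's taper W(t) = 1 − 3t² + 2t³ for t = d_i/R_i ∈ [0, 1].
Points outside every radius fall back to the nearest control point's
polynomial (counted, never an error). Because the map is not analytically
invertible, forward (thermal→MIP: polygons, points) and inverse
(MIP→thermal: image resampling) transforms are fitted independently with
roles swapped. Central correctness property: pairs drawn from any global
polynomial of degree ≤ 2 are reproduced exactly (to 1e-6) everywhere
covered — each local fit recovers the global polynomial and the blend of
identical values is that value. Rank-deficient (collinear) neighbourhoods
raise an error naming the control point. Warped polygon edges are
re-densified so no mapped segment exceeds 1 px before rasterization.

## Overlap and statistics

Overlap = 100 · |TI ∩ MIP hotspot| / |MIP hotspot|. The two hotspots
select the same fraction of the same (warped) ROI, so their counts agree
up to warping discretization; the MIP-hotspot count is used as the fixed
denominator, with a symmetric mean-count option. SEM uses the n−1 sample
SD over √n. Pearson r² carries a two-sided p from the t distribution with
n−2 df. Paired session comparisons default to the two-sided paired t-test
(Wilcoxon available); report tables round half-up to 1 decimal.

## Synthetic phantoms and ground truth

The generator's defaults define the study conditions: 5-s frame interval;
acclimatization 120 s, initial period 600 s (cooling onset at its start),
final period 180 s beginning 3000 s after onset; 120×160 frames; 22 °C
background vs 33.5 °C skin; a neck/torso silhouette with a gently bowed,
widening neck edge (closed form, so the true contour is known); one
Gaussian blob (σ = 6 px) per supraclavicular fossa sitting A0 = 2 °C above
skin at baseline — which puts the relative baseline near the ~1.9 °C seen
in adult cohorts — rising by ΔT_max·(1−e^{−t/τ}) with τ = 120 s after
onset (saturating-exponential activation: fast early rise, continued small
rise under prolonged cooling). ΔT_max defaults to 0.3 °C (cohorts draw it
per subject from N(0.3, 0.12²) truncated at 0.05, landing in the 0.1–0.3 °C
range typical of published Δ₁₀T_SCR values); vehicle sessions use 0.05 °C
of drift. Sensor noise is i.i.d. N(0, 0.05 °C); frames are encoded to
counts and back so quantization is always exercised. PET volumes
(100×128×32) carry 3-D Gaussian uptake blobs placed where the true warp
sends the thermal blob centres (±1.5 px colocalization jitter), amplitude
coupled to ΔT_max via `pet_gain` = 20 uptake-units/°C in cohorts (vehicle
amplitude 0), over a 0.5-unit background with smoothed noise; CT is a
crude soft-tissue ellipsoid with clavicle-like bars, used only for
composites. The true warp is a global degree-2 polynomial (scale ≈ 0.8,
small rotation/translation, quadratic terms ~1e-4), which makes LWM
exactness provable; 70 control points are a jittered 10×7 grid over the
supraclavicular neighbourhood with N(0, 0.5 px) placement error.

Ground truth recorded per session includes the noiseless-pipeline outcome
values (computed from the analytic field with the *true* geometry — note
this oracle shares the hotspot selection rule with the pipeline, which is
itself verified against independent sort oracles; what the recovery tests
add is robustness to noise, quantization and detected-rather-than-true
contours), the true hotspot masks, and the true overlap obtained by
forward-mapping TI hotspot pixels through the closed-form warp.

What the phantoms do **not** emulate: anatomical torso rendering, motion
(cohort frames are registered by construction), physiological drift and
vasoconstriction dynamics, PET counting statistics and reconstruction
artifacts, and breathing-related deformation — so passing recovery tests
demonstrates algorithmic correctness under the stated noise model, not
clinical performance.

## Problem sizes and determinism

The end-to-end recovery study uses 20 cohorts × 8 subjects × 2 sessions
(180 frames each) — chosen so the whole suite completes in a few minutes
on one core while still giving stable win-rate and correlation estimates.
All randomness derives from a single integer seed through numpy
`SeedSequence`; identical spec + seed give byte-identical frames and
hash-identical result CSVs.

## Known limitations

- The vendor's exact conversion formula variant (window/atmosphere terms)
  is not modelled; agreement is by construction of the sidecar contract.
- The half-coverage rasterization includes tied (exactly half-covered)
  cells, which slightly over-counts polygons aligned to the pixel grid.
- Automatic apex detection is out of scope; apices come from annotation
  CSVs (or the generator).
- No multiple-testing correction is applied in the results tables.
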