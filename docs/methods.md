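# Methods

## Problem and model

Dynamic CTA records the transit of an iodinated contrast bolus through
the cerebral vasculature as a 4D HU volume (typical clinical acquisition:
512·512·113 voxels at 0.44·0.44·1 mm, 30 frames at Δt = 2 s). In an
artery, the bolus front travels with the blood, so the arrival time of
contrast at a voxel increases linearly with distance along the vessel at
rate 1/v, where v is the average transport velocity. flowtrace estimates
v per vessel segment as the inverse slope of an ordinary-least-squares
regression of per-voxel time delay on centerline arc-length. The sign of
the slope is the flow direction relative to the path orientation
(proximal → distal): positive = anterograde, negative = retrograde
(collateral supply entering from the distal end).

The method quantifies *contrast* transport. Contrast molecules are
nanometer-sized and follow the plasma; red-cell flux, pulsatility and
dispersion of the bolus front are not modelled.

## Pipeline stages and parameters

**Registration** (off by default) aligns each frame to a reference frame
by maximizing FFT cross-correlation over integer voxel shifts
(`max_shift` = 5 voxels, optional quadratic sub-voxel refinement).
Translation captures the dominant inter-frame head motion; data already
registered (or motion-free phantoms) should skip it. A constant frame —
including a pre-contrast reference frame — yields zero shift with a
warning.

**Bilateral denoising** (spatial σ = 1 mm, range σ = 30 HU, kernel
truncated at 2σ) smooths each frame while preserving vessel edges. The
filter is an anisotropic 3-D implementation whose range-weight → ∞ limit
is exactly truncated-kernel Gaussian smoothing; this limit is tested
against `scipy.ndimage.gaussian_filter`. Temporal smoothing is deferred
to TAC conditioning.

**t-MIP and segmentation.** The temporal maximum intensity projection
shows every vessel at peak enhancement. Vessels are segmented by an HU
threshold (absolute or percentile) with components below 27 voxels
removed; an externally produced mask is accepted unchanged, which is the
intended route when a dedicated segmentation model is available. An ROI
mask restricts the analysis to the territory of interest.

**Skeleton and paths.** 3-D morphological thinning
(`skimage.morphology.skeletonize`) preserves topology; the skeleton
becomes a 26-connected voxel graph with anisotropic mm edge lengths.
Spurs shorter than 3 mm ending at a branch node are pruned as thinning
artifacts. Markers snap to the nearest skeleton node within 3 voxels
(mm metric, lexicographic tie-break). Paths minimize
`Σ ℓ_uv · (I_max − (I_u + I_v)/2 + ε)` with ε = 1 HU and I_max the t-MIP
maximum over skeleton nodes (a constant per-unit-length offset relative
to taking it over the full mask); Dijkstra ties resolve toward the
lexicographically smallest predecessor, making paths deterministic. The
distal portions of all marker paths share a prefix up to the node where
they diverge: that prefix is the *mother* segment, the remainders are
*daughter* segments.

**TAC conditioning.** Raw TACs are baseline-subtracted (mean of the
pre-arrival samples, detected as the samples before the curve first
exceeds 10% of its dynamic range), upsampled ×10 by polyphase
band-limited interpolation (2 s → 0.2 s grid) and filtered with a
4th-order Butterworth low-pass at 0.1 Hz applied forward–backward.
Zero-phase filtering is mandatory: the measurand is a time shift, and a
causal filter's group delay would masquerade as flow. The conditioning
chain perturbs the relative delay of two exact shifted copies by well
under 0.1 s (tested).

**Quality control.** TACs whose conditioned maximum is strictly below
5% of the proximal reference maximum carry too little contrast and are
excluded (the comparison is strict: exactly 5% is kept). The threshold
is applied to conditioned maxima for noise robustness; the choice is
recorded in the run manifest.

**Delay estimation.** The delay of a TAC against the proximal marker's
TAC is the lag maximizing the Pearson correlation over the overlapping
support, searched within ± half the record duration, with ties going to
the smaller |lag| and an optional quadratic sub-sample refinement of the
peak. On the 0.2 s conditioned grid the estimator agrees with a dense
(0.01 s) cross-correlation oracle to < 0.2 s.

**Velocity fit and pattern.** Per segment with ≥ 3 valid delay points,
OLS of delay on arc-length (Theil–Sen available via `estimator:
"theilsen"` for outlier-heavy profiles). Slopes within ±0.005 s/mm are
reported *unresolved*: over a ≤ 100 mm path at Δt = 2 s such slopes are
below the temporal quantization floor and their sign is noise (this
reproduces the zero-delay plateaus seen in fast-flow segments). The
case-level pattern is decided by the resolved daughter directions —
I all anterograde, II all retrograde, III mixed; with a single unbranched
distal path the mother segment itself votes. No resolved segment at all
gives "indeterminate".

## The phantom

The generator emulates the study conditions: trees of straight
cylindrical segments (default grid 64·64·16 at 1 mm for the bundled
demos, 30 frames at Δt = 2 s — the clinical frame interval with a
desk-scale spatial grid), a gamma-variate bolus
`C(τ) = A (τ/t_p)^α e^{α(1−τ/t_p)}` with A = 400 HU, t_p = 6 s, α = 3,
background 40 HU, and additive i.i.d. Gaussian noise of σ = 10 HU.
Segment velocities are signed; retrograde segments receive the bolus at
their distal end with a configurable arrival offset, mimicking
collateral supply. A thrombus is a sub-interval of one segment whose
enhancement is scaled by a permeability factor in [0, 1]. Because the
published TACs are not parameterized, the bolus amplitude and timing are
plausible perfusion-literature values, not fitted ones; the bolus
amplitude doubles as the peak vessel enhancement, so a single parameter
(`BolusSpec.amplitude_hu`) controls it.

What the phantom does **not** emulate: partial-volume averaging (voxel
membership is binary, keeping the ground truth exact; optional edge
feathering was considered and rejected for that reason), beam hardening
and photon statistics, cardiac pulsatility, bolus dispersion along the
vessel, curved or tapering vessels, and surrounding anatomy (the
background is flat, which is why the demo configurations skip
registration — there is no static structure for the correlation to lock
onto). Passing phantom tests therefore validates the geometry and the
delay/velocity estimators under ideal tube geometry and additive noise;
they do not establish segmentation performance on real angiograms.

## Numerical choices and edge cases

- Frame k samples time k·Δt; voxel indices are 0-based; world
  coordinates are origin + index·spacing; all distances use anisotropic
  spacing in mm.
- Delay-estimation quantization: at native lag resolution the worst-case
  error for continuous delays is half the frame interval, i.e. ~1 s at
  Δt = 2 s. Strictly, the decision boundary between adjacent lags sits a
  few milliseconds off the exact midpoint because the sampled bolus is
  not band-limited (the sharp onset aliases), so the supremum is 1 s
  plus that millisecond-scale asymmetry rather than 1 s exactly. The
  ×10 upsampling plus quadratic refinement used in the pipeline makes
  this irrelevant for velocity estimates.
- Zero-variance TACs yield invalid delay points with a recorded reason;
  segments with < 3 valid points, or a degenerate arc-length range, are
  unresolved, never an exception; a case with no resolved segment
  classifies as "indeterminate".
- Equal-cost path ties, marker-snap ties and correlation-peak ties all
  have deterministic lexicographic / smaller-|lag| rules, so repeated
  runs are byte-identical.
- `velocity_mm_s` is null in the JSON output when a segment is
  unresolved (its inverse slope may be arbitrarily large).

## Limitations

- Velocities beyond ~200 mm/s (slope dead band 0.005 s/mm) are not
  resolvable at Δt = 2 s and are reported as unresolved, not as a
  direction.
- The linear delay–distance model assumes constant velocity per segment;
  genuinely varying flow within a segment biases the fit (the residual
  SD and R² in `segments.json` flag this).
- Thresholding is a stand-in for learned vessel segmentation; on real
  scans a supplied mask from a dedicated tool is preferred.
- Marker placement remains manual by design: automatic occlusion
  detection and branch selection are out of scope.
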