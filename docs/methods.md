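# Methods

## Measurement model

The observable is a color video of a mesentery in which one collecting
lymphatic vessel is filled with blue dye and recorded from above under
reflected light.  The dye absorbs the wavelengths a camera's red channel
detects, so the vessel is a dark band on a brighter background in that
channel, and its edge can be found with a single intensity threshold.
The quantity of interest is the vessel's luminal width as a function of
time and of position along the vessel axis; every contractile parameter is
a functional of that width surface.

Assumptions: the vessel is roughly straight within the analyzed region of
interest (so a rotated rectangle can orient it vertically and "width" is
the horizontal pixel count per row); the dye fills the lumen so the optical
width tracks the luminal diameter; the cross-section is circular when the
ejection fraction is interpreted as an area fraction; illumination is
stable enough that one threshold serves the whole video.  No image
registration is performed — the threshold-based segmentation tolerates the
small residual motion of a stabilized preparation.

## Pipeline and parameters

**Calibration.** `mm_per_px` converts pixel widths to mm.  It is supplied
directly or derived from two points a known distance apart on a ruler
image.  It is a per-analysis input, never a built-in constant (13.7 µm/px
is the documented example value of the reference acquisition setup).

**ROI.** `cx,cy,length,width,angle` defines a rotated rectangle; the
sub-video is resampled with bilinear interpolation (identity slicing when
the angle is 0 and the grid aligns).  Angle is measured from the image
vertical, positive toward increasing column.  The interactive selection of
a GUI workflow is replaced by this serializable spec plus a green-tinted
preview image; any selection can be reproduced exactly from the logged
string.

**Segmentation.** Vessel = red channel strictly below the threshold.  The
automatic default is the arithmetic mean of per-frame two-class splits
(Otsu between-class-variance criterion on the 256-bin histogram, smallest
maximizing split) over `n_sample_frames` = 6 equally spaced frames; the
split is computed in-package so its convention and tie-breaking are exact
and testable against a brute-force oracle.  Components smaller than
`min_component_px` = 10 (8-connectivity, strictly smaller removed) are
imaging artifacts.  Saturation = all three channels ≥
ceil(0.99 × intensity range); every pixel within euclidean distance
`exclusion_radius_px` = 5 (inclusive) of a saturated pixel is excluded,
computed by an exact distance transform.  One threshold serves the whole
video; a `REPRO` log line records every parameter of the run.

**Width profile.** Width at position *y* = number of vessel pixels in row
*y* (pixel count, not edge-to-edge span; the two differ only for vessels
with interior holes, and small-component removal already deletes stray
specks).  A row is *missing* in a frame when any of its vessel pixels
intersects the exclusion zone — glare would otherwise make the vessel look
narrower.  An empty row is width 0, not missing.  A frame of a mean-width
series is missing when more than half of its positions are missing
(majority rule; the exclusion granularity is the whole pixel row, since
width is a per-row scalar).

**Smoothing.** Sliding centered 20-frame window (clamped, full-length, at
the series ends; missing values bridged by linear interpolation and
re-flagged afterwards).  Two smoothers are provided:

* *moving average* (default for detection) — preserves the monototonicity
  of contraction limbs, which the trough rule below depends on;
* *2-means window smoother* — each window is split into two clusters by
  exact 1-D 2-means (optimal split of sorted values, smallest-split
  tie-break) and the center value is replaced by the centroid of its
  cluster, snapping singleton clusters to the opposite centroid.  This
  removes single-frame aberrations outright but renders slopes as
  staircases whose flat treads can outlast the 10-frame confirmation runs
  of the trough rule; on coarsely averaged (per-section) series this can
  leave genuine troughs undetectable.  It therefore remains an explicit
  option (`--smoother kmeans`) rather than the default.

The window is specified in frames; at 22 FPS, 20 frames ≈ 0.91 s.

**Trough detection.** Frame *t* is a contraction trough when the 10
(`minima_run_frames`) differences before it are all decreasing and the 10
after all increasing.  Comparisons are plateau-tolerant: steps within
`flat_tol_px` = 0.05 px of zero count as flat, and each run must contain at
least one step beyond the tolerance.  The tolerance is 5% of the minimum
event amplitude (1 px) — above the residual wobble of window smoothing on
a quantized-width series, far below any real contraction slope.  A strict
mode (`--strict-monotone`) restores exact monotonicity.  Qualifying frames
within 10 frames of each other are one trough, reported at the lowest
smoothed value (ties toward the earliest frame, so an exactly flat plateau
reports its earliest frame).

**Event expansion.** From each trough the event extends forward until the
curve flattens or begins to decrease, and backward likewise; the backward
endpoint carries the EDD, the trough the ESD.  "Flattened" is confirmed
over the same 10-frame run as detection: the walk continues as long as a
value more than `flat_tol_px` higher lies within the next 10 frames
(jumping straight to it, so it rides over smoothing wobble), and stops at
a sustained plateau.  A literal "first non-increasing difference" stop was
rejected because it terminates inside the trough plateau of any
realistically smoothed trace.  Walks that reach the series boundary while
still rising flag the event truncated.

**Filtering.** Events with amplitude < 1 px (`min_amp_px`) are within
quantization noise; events spanning more than 110 frames
(`max_dur_frames`; 5 s at 22 FPS) are too slow to be a lymphatic
contraction.  Both bounds are inclusive on the keep side; each rejection
is logged with its reason.

**Parameters.** Per event: EDD, ESD, CA = EDD − ESD, EF = (EDD² −
ESD²)/EDD² × 100, contraction duration (start→trough), shortening speed =
CA/duration; with a predecessor: relaxation duration (previous trough →
this start), filling speed = (EDD − previous ESD)/relaxation duration,
percent re-filling = (EDD − previous ESD)/previous CA × 100.  Aggregate:
CF = 60 s / mean trough-to-trough interval; FPF = mean(per-event EF) × CF
(an `aggregate` mode using the EF of mean diameters is available — the two
differ slightly for irregular traces); peak and nadir are the extremes of
the smoothed trace over the whole recording, contraction-associated or
not.  With a single event, CF and predecessor-dependent quantities are
absent (NaN), not zero.  Values are stored at full precision; rounding is
a display concern.

**Sectioning.** The vessel axis is tiled into 30-px sections
(`section_len_px`; ≈ 0.41 mm at 13.7 µm/px) from the image top; a trailing
remainder is kept but flagged short.  Each section runs the identical
series → smooth → detect → filter → summarize pipeline independently; a
section with no usable signal is flagged absent.  Section length trades
noise averaging (a single row fluctuates by whole pixels) against spatial
resolution of the amplitude heterogeneity.

## Synthetic data: what it emulates, and what it does not

`VesselScene` renders a vertical vessel of analytic width
`w(y, t) = baseline(y) − amplitude(y) · pulse(t)` with half-pixel
anti-aliased edges (so threshold placement has a realistic ±1 px effect),
a dark red channel inside the vessel, saturated white glare discs, and
seeded truncated-Gaussian sensor noise on the red channel (optionally all
channels).  The same seed renders a bit-identical video.  Ground truth —
the analytic width matrix and the pulse's event timings — is returned
alongside, so recovery can be asserted exactly.

`preset_paper_like()` is the reference scene, built to the documented
acquisition conditions: 22 FPS, 30 s (660 frames), 13.7 µm/px, four
contractions at a uniform 140-frame period (CF = 9.43 min⁻¹), diastolic
width 15 px and mean amplitude 9 px (mean diameter swinging ≈ 205–82 µm),
each cycle a 60-frame (≈ 2.7 s) contraction limb, a 22-frame (≈ 1 s) rapid
re-filling limb and a diastasis until the next onset — so the trough-to-
next-EDD relaxation interval is ≈ 3.6 s and full event spans stay inside
the 110-frame physiological filter.  Amplitude varies sinusoidally
(±1.5 px) along the 240-px vessel while timing is global; the baseline
carries a gentle taper (mean exactly 15 px) plus static ±0.5 px per-row
edge roughness, because a perfectly smooth profile would give all rows of
a section the same sub-pixel edge phase and hence a shared, non-averaging
quantization bias that real (irregular) vessel walls do not exhibit.  One
glare disc sits on the vessel at mid-length; red-channel noise SD is 6
intensity levels.

The generator does **not** emulate: vessel curvature or branching, motion
from breathing or arterial pulsation, focus drift, dye washout or
extravasation, valve shadows, or non-uniform illumination.  Passing tests
therefore demonstrate that the measurement chain is correct and robust to
edge quantization, sensor noise, and glare — not that segmentation will
survive arbitrary real-world contrast degradation, which is what the
montage/overlay confirmation outputs are for.

## Numerical choices and degenerate inputs

* Coordinates are 0-based (row, column), row 0 at the image top,
  everywhere including CSV output; the ROI string uses `cx,cy` = (column,
  row) order for its first two fields.
* The Otsu split is computed on the integer histogram; ties take the
  smallest split.  Constant sampled frames contribute nothing; if all are
  constant the threshold is an error ("no contrast"), not a guess.
* Saturation cutoff = ceil(fraction × (2^bit_depth − 1)); exclusion
  distance is inclusive at exactly the radius.
* A still image is a one-frame clip (`fps` absent): all spatial operations
  work unchanged; time-domain operations refuse it with a clear error.
* Widths at excluded cells are NaN, never zero; CSV round-trips preserve
  the distinction (empty width field + `excluded_flag`).
* Window smoothing at the series ends clamps the window inside the series
  (it keeps full length by shifting) rather than shrinking it.
* Event boundary cases: a trough with an exactly flat approach starts at
  `trough − 1`; amplitude/duration filters keep `amplitude = 1 px` and
  `span = 110` frames exactly.
* CF uses trough-to-trough (ESD-to-ESD) intervals; EDD-to-EDD differs for
  irregular traces and was not chosen because the trough is the sharpest
  landmark on a smoothed trace.
* CSV floats are written with a fixed `%.10g` format so repeated runs are
  byte-identical.

## Known limitations

* Width is a pixel count per row; a vessel with interior holes (e.g. an
  air bubble) would undercount relative to an edge-to-edge span.
* The threshold's sub-pixel placement biases widths by up to ~1 px
  systematically (the automatic split does not sit exactly at the
  half-coverage intensity); comparisons between groups analyzed with the
  same settings are unaffected.
* The moving-average smoother biases ESD upward by a few tenths of a pixel
  at sharp troughs (curvature averaging), and the expansion walk can place
  the event start a few frames after the true onset when contraction
  begins gradually; both effects are bounded by the smoothing window.
* Sections heavily covered by glare report from few valid rows and can
  yield unreliable peak−nadir values; positions missing in all frames are
  NaN, and the per-section `absent` flag marks unusable sections.
* FPF assumes competent valves; with valvular reflux it overestimates
  net pumping.
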