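# Methods

This note documents the models, conventions and numerical choices behind
`gazeqc`, the defaults of its synthetic-session generator, and what the test
suite does and does not establish about real recordings.

## Viewing geometry and angle conventions

All metric computation happens on gaze expressed as angular orientations of
the eye. The geometry model is deliberately minimal: a single eye fixed on
the perpendicular through the centre of a flat screen, at
`viewing_distance_mm` from it. There is no head tracking, no per-sample eye
position, and no vergence model; for seated, chinrest-or-near-chinrest
desktop recordings the error this introduces is far below typical tracker
inaccuracy, but for free head movement or very close screens the pixel→degree
conversion will be correspondingly off.

Angles follow the Fick rotation order: azimuth about the vertical axis
first, then elevation about the interim horizontal axis, with right and up
positive. Concretely,

```
azimuth   = atan2(x_mm, d)
elevation = atan2(y_mm, hypot(x_mm, d))
```

and the inverse direction vector is
`(cos e·sin a, sin e, cos e·cos a)`, so `(0°, 0°)` is straight ahead
`(0, 0, 1)`. Helmholtz order (elevation first) and direction-cosine
conventions exist in the oculomotor literature and differ in the second
decimal place at 10–20° eccentricity; the Fick choice here is a pinned
convention, not a fact about any particular tracker, and users comparing
against vendor output at large eccentricities should check which convention
the vendor uses.

Pixels are continuous (trackers report sub-pixel gaze), with origin at the
top-left and +y downward — the common display convention — while the
physical frame is centred with +y up. The pixel→mm map is affine; no
half-pixel centre offset is applied.

## Inaccuracy

A fixation segment's samples are converted to unit gaze vectors; the
component-wise mean (default) or median of those vectors is the
representative gaze direction, and the inaccuracy is the arccos of its
normalised inner product with the target direction, in degrees. The mean
vector is renormalised implicitly by the inner-product normalisation, so
whether one renormalises explicitly first is mathematically irrelevant. The
component-wise median is a pragmatic robust variant — it is not the
geometric (spatial) median on the sphere, which would add an iterative solve
for no practical gain at fixation scales.

Sample selection is entirely delegated to the recording's target-assignment
column: every contiguous run of one target id is a measurement interval.
Alternative selection strategies (fixation classification, minimum-dispersion
windows) are intentionally out of scope.

## Precision measures

RMS-S2S and STD are computed as Euclidean quantities in (azimuth, elevation)
degree space, exactly as their component formulas are conventionally
written, not as great-circle distances; at fixation scale (well under 1°)
the difference is far below measurement noise. Sample pairs spanning an
invalid sample are dropped, never bridged: interpolating across a blink
would fabricate a large displacement. STD uses population (1/n)
normalisation — the segment is the complete object of description, not a
sample from a larger population.

The sliding-window RMS-S2S uses a window of
`round(window_ms/1000 × fs)` samples (half-up), slid one sample at a time;
only windows whose every sample is valid contribute, and the median across
windows is returned. Requiring full validity (rather than per-window NaN
dropping) is a pinned choice: it keeps each window's estimate an honest
fixed-length RMS and lets the median reject windows contaminated by
saccades or spikes, which is the measure's whole purpose.

BCEA uses `k = −ln(1−P)` with the natural logarithm — the only base for
which the "ellipse contains a fraction P" property holds, since the squared
Mahalanobis radius of a bivariate Gaussian is exponential with mean 2 and
`P(d² ≤ 2k) = 1 − e^(−k) = P`. Ellipse orientation and axis radii come from
the eigen-decomposition of the 2×2 population covariance scaled by `2k`;
`area = π·major·minor` then holds identically. Degenerate clouds (zero
variance on an axis, or perfectly collinear samples) produce zero area, with
the undefined correlation reported as 0 plus a warning.

## Data loss and durations

A sample is invalid when either coordinate is NaN; vendor sentinel encodings
((0,0) pairs, negative-resolution values) are normalised to NaN at the I/O
layer so the arithmetic stays pure. Loss against the expected count uses
`duration × nominal_frequency` as a real number, and a surplus of samples
yields a negative loss, returned as-is with a warning rather than clipped —
clipping would hide a symptom of timestamping or frequency problems.

Two duration conventions are used, both on the view that n samples span n
sampling periods, not n−1: a recording's duration is its timestamp span plus
one nominal period when the nominal rate is known (bare span otherwise), and
a segment's effective frequency divides its valid-sample count by the
timestamp span plus one *median* inter-sample interval, so a gap-free
regularly sampled segment recovers its sampling rate exactly.

## Validation-file dialect

The field convention fixes the column roles but not names; this package pins
`timestamp, left_x, left_y, right_x, right_y, target_id, tar_x, tar_y`, tab
separation, seconds for timestamps (a `timestamp_unit="ms"` flag rescales),
and −1 or an empty cell as the "not in a measurement interval" sentinel.
Either pixel or degree units are accepted; pixels require a screen-geometry
config (TOML/YAML/JSON) before metrics can be computed. NaN round-trips as
an empty cell and finite doubles round-trip bit-exactly
(`float_precision="round_trip"` on read).

Each eye is processed independently; an optional "average eye" (per-sample
mean of the two eyes where both are valid) can be enabled and is off by
default, since averaging policy is a study-level decision.

## Reporting conventions

Across-recording summaries first reduce each recording to one value per
measure (NaN-ignoring mean over its eye × target rows), then take mean,
sample (n−1) standard deviation and range across recordings. Note the
deliberate asymmetry: n−1 across recordings (describing a sample of
recordings), 1/n inside the STD precision measure (describing a complete
segment). Report text prints inaccuracy to 2 decimals, RMS-S2S/STD precision
to 3, data-loss percentages to 1 decimal with a trailing ".0" dropped, and
frequencies as integer Hz, all rounded half-even for reproducible golden
files. These decimal rules are a formatting convention inferred from common
reporting practice, not a statistical claim.

## Synthetic sessions: what they emulate and what they do not

The generator emulates a screen-based validation protocol: a 3×3 target
grid spanning ±10° (the customary 9-point layout), visited in seed-shuffled
random order, 1-s measurement intervals at 600 Hz, 0.5-s inter-target
"flight" intervals emitted with the sentinel target id, gaze at
target + constant offset + i.i.d. isotropic Gaussian noise per axis
(default σ = 0.05°, a typical good desktop-tracker noise level), and blinks
at 20 per minute lasting 300 ms — the upper end of normal spontaneous
blinking, which alone produces about 10% data loss. Blinks NaN both eyes
simultaneously. A deterministic blink mode (evenly spaced gaps) exists
alongside the Poisson mode so injected loss fractions are exact integers of
samples. The offset is applied additively in angle space, which is what a
calibration offset looks like in tracker output; note that an azimuth offset
at elevation e corresponds to an angular offset of ≈ cos(e) times its
nominal size, a ≤1.5% foreshortening within the ±10° grid that
parameter-recovery tolerances account for.

Not modelled, deliberately: drift of the offset within a session, pupil-size
artifacts, saccade dynamics in the flight intervals (they are linear
interpolation plus noise), heavy-tailed or temporally correlated noise, and
per-eye blink asymmetry. Consequently, passing recovery tests establish that
the estimators are correct and unbiased under the stated model — constant
offset, white Gaussian noise, NaN-encoded loss — not that real recordings
satisfy that model. Real signals have coloured noise (RMS-S2S/STD ratios
deviate from √2), drifting offsets, and loss that correlates with gaze
position.

## Problem sizes and numerical checks

Monte-Carlo identity checks use 10⁵ samples, where the white-noise
identities (RMS-S2S = 2σ, STD = σ√2, BCEA = 2kπσ²) hold to well within the
3–5% tolerances asserted. Offset-recovery regression uses 200 sessions with
offsets drawn uniformly in [0.2°, 2°] at σ = 0.05° and 500 samples per
target. BCEA containment is checked at 10⁵ samples against 68% ± 1
percentage point. Angle round-trips are asserted to 1e-9 degrees over
|azimuth|, |elevation| ≤ 80°; beyond ~89° the fixed-eye model has no
on-screen meaning. Arccos arguments are clipped to [−1, 1] and `1 − ρ²` is
floored at 0 before square roots; ties in the sliding-window median follow
numpy's even-sample interpolation.

## Known limitations

- Fixed-eye geometry only; no head pose, eye-position, or vergence input.
- The recording-level expected-sample loss assumes the timestamp span plus
  one period is the true recording duration; trackers that pause their
  clock during track loss will bias it.
- The segment effective frequency is undefined (NaN) for single-sample
  segments.
- Vendor-native formats (EyeLink ASC/EDF, Tobii exports) are not parsed;
  data must be exported to the TSV dialect first.
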