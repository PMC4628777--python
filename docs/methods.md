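# Methods

## Problem and signal model

Anterior-segment OCT acquired in a fixed meridional plane yields a temporal
sequence of B-scans of the iridocorneal region. Cardiac blood pulsation and
respiration displace the ocular structures axially by small amounts; these
displacements, and the depth *D* of the gap between the posterior corneal
surface and the anterior iris surface, are the signals of interest. All
positions are expressed in pixels of the (possibly rotated/cropped) image:
no optical-distortion correction or conversion to micrometres or to
iridocorneal-angle degrees is attempted, as the images analysed are not
distortion-corrected.

The axial motion is modelled as a common signal shared by both surfaces,

    s(t) = A_b sin(2π f_b t + φ_b) + Σ_k A_k sin(2π k f_c t + φ_c),

a respiratory sinusoid (default f_b = 0.25 Hz) plus a cardiac fundamental
(default f_c = 1.25 Hz) with harmonic amplitudes A_k at integer multiples,
scaled per structure by gains g_cornea and g_iris. When the gains are equal
the depth D = iris − cornea is invariant under s(t); a gain difference
leaks a scaled copy of s(t) into D.

## Synthetic sequence generator

The generator is the ground-truth oracle for every pipeline stage. It
renders, per frame:

- a **corneal band** of thickness 12 px whose posterior boundary is the
  quadratic profile `apex + curvature·(x − x_c)²` (apex row 40, curvature
  0.002 px⁻¹ → ~12.6 px sag over the default 160-column field);
- an **iris region** from the sloped boundary `base + 0.15·x` (base row
  120) to the bottom of the frame, with an optional step (a 6 px ledge) to
  emulate step-like iris surface relief;
- intensities background 0.05, cornea 0.25, iris 0.55 — the cornea is
  deliberately the dimmer band so that it has the lower SNR, as in real
  anterior-segment OCT;
- **anti-aliasing** by linear partial-pixel coverage with pixel r centred
  at integer row r, so a boundary at row b leaves pixel ⌊b⌉ partially
  covered and sub-pixel ground truth lives on the sample grid;
- **speckle** as per-pixel multiplicative gamma noise with shape
  `speckle_looks` (default 4, std/mean = 0.5) applied to the tissue
  contribution, plus additive Gaussian noise (σ = 0.01) — the standard
  multi-look approximation of coherent-imaging speckle;
- **lateral drift** by evaluating the boundary profiles at shifted column
  coordinates x − d_lat(t); this is analytically equivalent to a sub-pixel
  whole-image shift for the rendered content (profiles extend smoothly past
  the edge, acting as replicate padding) and keeps ground truth exact.

Defaults are one acquisition condition: 90 frames at 22.7 Hz (duration
3.96 s), frame size 200 × 160 px. The 200 × 160 desk scale keeps tests and
simulations fast; the full clinical 900 × 1009 px size is available through
the geometry configuration. Motion amplitudes are not reported by clinical
studies in pixel units; breathing 2 px and cardiac 1 px were fixed once as
plausible magnitudes for this geometry. The `motion_subject3` fixture adds
the harmonic comb (amplitudes 1.0, 0.5, 0.35, 0, 0.25 px at multiples of
1.25 Hz — orders 1, 2, 3, 5), whose highest component, 6.25 Hz, stays below
the 11.35 Hz Nyquist; the generator refuses motion specs whose highest
harmonic would alias.

What the generator does **not** emulate: physical OCT image formation
(interferometric artefacts, depth-dependent roll-off), pupil or
accommodation dynamics, dicrotic pulse shapes, non-sinusoidal breathing,
and frame-to-frame eye rotation. Passing recovery tests on these phantoms
therefore demonstrates correctness of the measurement chain under the
stated motion/noise model, not robustness to every property of clinical
recordings.

## Segmentation

The edge operator is the vertical (axial) derivative of a Gaussian
(default σ = 1.5 px, 2-D smoothing), gated by polarity: the posterior
cornea is a bright→dark transition going down the A-scan, the anterior
iris dark→bright. Per column, the surface is the argmax of the
zone-restricted response (ties toward the smaller row, biasing to the
anterior-most transition), refined by 3-point parabolic interpolation of
the response; the refinement offset is clipped to ±0.5 px. Confidence is
the peak response over the zone's 95th-percentile response (clipped to
[0, 1]); columns below `min_confidence` (default 0.3) are invalid and
carry no position claim.

Search zones (row intervals bounding each surface) either come from the
run configuration or are initialized automatically from frame 0: the
dominant dark→bright row per column seeds the iris zone (2nd–98th
percentile of per-column argmax rows, robust to speckle outliers), the
strongest bright→dark response above it seeds the cornea zone, and both
are dilated by 12 rows — which must exceed the maximum expected axial
displacement (≈4 px under the default motion).

The horizontal analysis range — chosen subjectively by a human operator in
the original semiautomatic workflow — is selected deterministically as the
longest contiguous run of columns valid for both surfaces in **all**
frames (leftmost run on ties, minimum width 16 columns); an absent run
raises a "no reliable range" error carrying the best run's width.

Measured on the phantoms, tracing accuracy is RMS ≈ 0.03 px noiseless and
≈ 0.3 px under default speckle, against test thresholds of 0.25 and 1.5 px.

## Dynamics and spectra

Within the selected range, traced rows are stacked into (column, frame)
matrices without interpolation (the acquisition protocol delivers evenly
spaced B-scans). D is the elementwise difference iris − cornea; any
non-positive value is an ordering-violation error. Before the FFT each
column is detrended; the default mode removes only the temporal mean (the
minimal reading of "FFT of the temporal changes"), a linear mode is
available for drifty data, and the spectrum operation rejects non-detrended
input (|mean| > 10⁻⁶ × RMS, with a 10⁻⁹ px absolute floor so constant
columns pass).

Power is one-sided, `|F_k|²/n²`, with window choices `rect` (default —
plain FFT of the signal) and `hann`, both normalized for coherent gain so
an exact-bin sinusoid of amplitude a reads a²/4 in either. Parseval holds
per column for the rect window to 10⁻⁹ relative, with folding weights 2 on
interior bins. The 90-sample, 22.7 Hz grid has bin spacing 0.2522 Hz, so
the first non-DC bin coincides (at two decimals) with the 0.25 Hz
respiratory rhythm.

Peaks are strict local maxima of the column-averaged spectrum within
frequency bands (defaults: respiratory [0.1, 0.6) Hz, cardiac [0.75, 2.0)
Hz, harmonic [2.0, 7.0) Hz — band edges bracket the physiological
locations, which are the observable, not the bands). The respiratory and
cardiac bands report only their highest maximum; the harmonic band keeps
every maximum above 5% of its top peak. The DC bin is never eligible.
Reported frequencies are refined by 3-point parabolic interpolation in
log-power; the refinement falls back to the bin centre when a neighbour
bin is negligible (< 10⁻⁹ of the peak, e.g. the DC bin next to the
respiratory peak), where the log-parabola is degenerate. With the rect
window the refinement is conservative (the Dirichlet kernel is nearly
flat-topped in log space); recovered cardiac frequencies land within
~0.01 Hz of the injected 1.25 Hz.

The cardiac fundamental is estimated from the peak comb: candidates are
every peak frequency divided by an integer such that the quotient falls in
the cardiac band, and the winner maximizes the number of peaks within a
tolerance (default 0.15 Hz) of an integer multiple (lowest candidate on
ties). If no candidate explains at least two peaks, the cardiac-band peak
is returned alone with no harmonic flags. The search is restricted to
cardiac-band candidates by design: the 3.75–4.5 Hz features are treated as
possible harmonics, never as fundamentals — the estimator reports evidence
for a comb, it does not decide physiology.

## Design choices and numerical notes

- **Model/results API.** The pipeline is exposed statsmodels-style:
  `OcularPulseModel(sequence, **settings).fit()` returns an
  `OcularPulseResults` holding series, spectra, peaks, fundamentals and a
  `summary()`; the stage functions remain importable individually.
- **One ROI/rotation per sequence**, bilinear interpolation: keeps column
  identity stable across frames, which per-column temporal analysis
  requires.
- **16-bit TIFF + JSON sidecar** as the on-disk form: preserves sub-8-bit
  quanta, metadata bit-exact and human-readable; frame order is page order
  or lexicographic file order.
- **Determinism.** All simulator randomness flows from one integer seed
  through a single `numpy` generator; phases default to 0; analysis is
  deterministic given its input, so repeated runs are byte-identical.
- **Degenerate inputs.** Zero frames trace as all-invalid (confidence 0);
  empty or misordered search zones, unknown method/window/polarity names,
  and out-of-bounds ROIs raise configuration errors; boundary-crossing
  motion reports the offending frame.

## Verification scales

The test suite and the acceptance script run entirely on generated
phantoms at the 200 × 160 default frame size: single sequences of 90
frames for accuracy and spectrum checks, a 20-seed batch (with cornea gain
0.8 vs iris 1.0) for peak-recovery rates, and 50 random signals against a
direct O(n²) DFT oracle. Common-mode rejection (equal gains ⇒ cardiac
power absent from the depth spectrum, ≥ 100× below the cornea's) is
verified on noiseless renders, where the depth residual reflects only the
tracking chain rather than the speckle noise floor.

## Known limitations

- No lateral image stabilization: lateral eye movement is simulated (and
  shows up, correctly, as depth modulation where the iris has relief) but
  not corrected.
- The 3.96 s record gives only ~0.25 Hz spectral resolution; respiratory
  and cardiac peaks occupy a handful of bins, and sub-bin refinement with
  the rect window is approximate.
- Segmentation is confidence-gated argmax tracing, not a global
  graph-search or learned layer segmentation; heavily speckled columns are
  dropped rather than bridged.
- Peak significance is not tested statistically; detection is geometric
  (strict local maxima within bands).
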