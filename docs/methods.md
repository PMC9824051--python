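# Methods

This note documents the measurement model, the synthetic data the package
is validated against, the numerical choices, and the limits of what the
tests demonstrate.

## The measurement model

A growing pollen tube is imaged as a single fluorescence channel in which
essentially only the cell wall is bright. Geometrically the tube is a
cylinder of radius R ≈ 4 µm capped by a hemisphere; in a medial optical
section its wall appears as two bright lines joined at the apex, each with
an approximately Gaussian transverse intensity profile whose standard
deviation σ is the wall-thickness measure. Along the growth axis the
apical wall therefore produces a Gaussian intensity bump centered on the
tip: fitting `I(s) = b + a·exp(−(s−µ)²/2σ²)` to the intensity profile
sampled along the trajectory gives the tip midpoint µ and thickness σ per
frame in one step. Velocity is the time derivative of µ.

Oscillatory growth is quantified on the fluctuations: both series are
smoothed with an 11-point centered running average (shorter symmetric
windows at the edges) and the overall baseline — interpreted as the series
mean — is subtracted. "Overall baseline = mean" is a deliberate reading:
it makes correlations of fluctuations well defined and is the weakest
detrend that does so; a linear detrend is selectable (`detrend: linear`)
for drifting tubes. Correlations use the biased (full-denominator)
normalization, which keeps values in [−1, 1] and is standard for
oscillation-lag detection. The cross-correlation sign convention is fixed
so that a peak at positive lag k means thickness changes precede velocity
changes by k seconds. The reported peak is the first positive-lag local
maximum of the cohort-averaged curve (anti-phase lobes can exceed it in
magnitude, so the global maximum is not used), refined by 3-point parabolic
interpolation; its uncertainty is the SEM of per-tube refined peaks —
a definition chosen because averaging first and refining once does not
propagate between-tube variability.

## Segmentation and trajectory

Per-frame segmentation: Gaussian pre-smooth (1 px) → global Otsu →
half-maximum refinement → morphological closing (disk radius 5 µm,
implemented with Euclidean distance transforms and edge-replicating
padding so structures running out of the field of view are not eroded) →
largest connected component → hole filling. The half-maximum refinement
re-thresholds at `background + 0.5·(peak − background)` (robust estimates
from the Otsu split): Otsu's level depends on the foreground/background
pixel proportions, whereas the half-max level delineates a Gaussian-walled
tube reproducibly — this is the "finer" segmentation applied per frame.
The closing radius must exceed the tube radius minus the wall half-width
so the two wall lines merge into a filled tube; 5 µm covers tubes up to
~10 µm diameter.

The growth trajectory is the morphological skeleton of the segmented time
projection: spurs shorter than 5 px are pruned, the longest geodesic path
between skeleton endpoints is taken (8-connected graph, diagonal steps
√2), and the path is oriented base→tip using the first frame's mask
centroid. Two corrections matter in practice:

- **Tip extension.** The medial axis of a round-capped tube ends one tube
  radius short of the apex; the path is therefore extended along its
  terminal tangent until it exits the mask (both ends for tube-length
  measurement, where the base may also be interior after rotation).
- **Arc-length metric.** The raw 8-connected chain overestimates oblique
  lengths by up to ~8% (a 30° line costs cos30° + (√2−1)·sin30° ≈ 1.073
  per unit run). The polyline is smoothed with a Gaussian (σ = 2 vertices,
  ends linearly extrapolated before filtering so straight segments and
  endpoints are preserved exactly) and arc length is the Euclidean sum
  over the smoothed vertices. This keeps axis-aligned lengths exact and
  brings 30–60° rotations within ~2%; the computation is deterministic,
  so outputs remain bit-reproducible.

The mask-based tip (last trajectory point inside the per-frame mask) sits
at the outer half-max boundary, i.e. ~σ√(2 ln 2) beyond the wall midline;
it is used only to center the Gaussian-fit window (±3 µm by default —
wide enough to include baseline on both sides of a σ ≤ 0.7 µm bump, short
enough to stay inside the cap region), and the fitted µ is the tip
position used for velocity. Frames whose fit fails are flagged; gaps of at
most 2 frames are filled by linear interpolation, longer gaps reject the
tube.

## ROI quantification

Images are aligned with the tube vertical (tip up) by a rigid rotation;
the terminal tangent is estimated by a total-least-squares line fit over
the trajectory's last 20 µm excluding the final 7 µm, where the discrete
medial axis bends into the cap — short-window tangents are biased by 2–3°.
Tip (≤ 5 µm from the tip) and shank (5–65 µm) ROIs are built by projecting
each tube-mask pixel onto its nearest trajectory point and binning the
arc-length distance from the tip; this is robust to curvature, unlike
Euclidean distance from the apex point.

Staining inside an ROI is segmented by Otsu's threshold on the ROI
histogram, kept only if the threshold clears the sub-threshold median by
3× the scaled MAD of the sub-threshold pixels (so constant or noise-only
ROIs yield fraction 0), followed by removal of objects under 4 px. A
median + k·MAD background threshold is available (`method="mad"`) but is
not the default: once staining covers more than half the ROI the median
sits inside the stained class and the rule collapses, whereas the study's
densest structures (clear-zone vesicle markers) reach ~60% coverage.

## Wall-deposition profiles

Wall-component gradients are measured along the wall itself: the tube-mask
boundary is split at the apex (boundary point nearest the trajectory tip)
into two arms, each boundary vertex is snapped inward to the local
wall-intensity ridge (the segmentation boundary sits roughly a half-width
outside the bright wall line), the snapped polyline is smoothed as above,
and intensity is sampled bilinearly at pixel spacing with x = arc length
from the apex. Sides can be analyzed separately or averaged (default).

Three models are fitted per tube by least squares: a Gaussian for
apical-dome peaks (pectin methylesterase), and four-/three-parameter
logistics `I(x) = A + (B−A)/(1+exp((x_mid−x)/s))` for components rising
toward the shank (crystalline cellulose, callose; the 3PL fixes A = 0).
The logistic is canonicalized to s > 0 (the pair (A,B,s) and (B,A,−s)
describe the same curve). Group structure is handled in two stages:
per-tube fits, then means, SEMs, and Welch tests on the fitted parameters
with tube as the unit of replication. This replaces nonlinear mixed-model
(random tube effect) estimation: group-mean parameters agree in
expectation, but standard errors are not the mixed-model ones, and no
shrinkage of extreme tubes occurs. Dunnett-style multiplicity control is
out of scope. The apical window for the Gaussian defaults to 15 µm
(configurable; the appropriate window depends on how far the dome signal
extends in a given marker).

## The synthetic data

The generator renders what the analysis assumes, with closed-form truth:

- **Kinematics**: `v(t) = v0 + Av·sin(2πt/T)`,
  `σ(t) = w0 + Aw·sin(2π(t+δ)/T)`; tip position is the cumulative
  trapezoidal integral of v. The sinusoid (rather than a sawtooth or
  relaxation oscillation) is chosen because it makes the phase lead δ
  analytically well defined. Defaults: v0 = 0.3, Av = 0.2 µm/s (peak
  velocity 0.5 µm/s, within the range reported for growing tobacco pollen
  tubes), w0 = 0.5, Aw = 0.15 µm, T = 40 s, dt = 1 s, duration 240 s —
  six oscillation cycles, enough for a stable correlation peak.
- **Geometry/optics**: straight tube, radius 4 µm (8 µm diameter),
  wall-only fluorescence with Gaussian cross-section, optical blur
  σ_psf = 0.1 µm (confocal lateral PSF at NA ≈ 1.25, ~510 nm emission),
  Gaussian read noise (SNR = wall peak / noise sd = 10 in the benchmark
  conditions) with optional Poisson shot noise; intensities are floats,
  clipped at 0 after noise.
- **ROI images**: non-overlapping bright disks dropped until the covered
  fraction is within 0.5 points of target; because random sequential
  adsorption of hard disks jams near ~55% coverage, placement falls back
  to permitting overlap for denser targets. The returned truth is always
  the exact fraction of the realized union mask.
- **Profile cohorts**: per-tube parameters = population values plus
  Gaussian between-tube jitter; i.i.d. Gaussian residual noise.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: curved or reorienting tubes, cytoplasmic
background and organelle autofluorescence, photobleaching, focus drift,
multi-tube scenes, non-sinusoidal pulse shapes, and growth arrest. The
benchmarks demonstrate that the estimators are calibrated and unbiased
under the stated noise model, not that segmentation will succeed on
arbitrary micrographs.

## Benchmark problem sizes and tolerances

The validation module fixes the study conditions (T = 40 s, dt = 1 s,
240 s, SNR 10) and uses: 10 tubes per condition for lag recovery
(thickness leads 23 s and 17 s, recovered within 2 s with the ordering
preserved); 100 frames for thickness calibration (σ = 0.5 µm at
0.1 µm/px, median relative error < 10%; the measured median is ~2%,
dominated by the ~2% PSF-broadening bias √(σ² + σ_psf²)/σ); 50 random
series against the O(n²) correlation oracle (agreement to 1e-10); the
closed-form Dirichlet attenuation of the 11-point running average
(within 2%); ROI targets {5, 15, 30, 60}% × 10 seeds (mean absolute error
< 1 point); 20 tubes/group for 4PL recovery (x_mid = 8 µm, s = 2 µm,
noise sd 5, 10% between-tube jitter; group means within 5%, a 3 µm
inflection shift detected at p < 0.01); and rotation fixtures at 90° and
30° for length invariance (< 0.5% and < 3%).

Numerical details: Gaussian and logistic fits use bounded/unbounded
Levenberg–Marquardt/trust-region least squares with data-driven
initialization (baseline = min, amplitude = range, center = argmax,
σ from the half-width; logistic x_mid from the half-range crossing,
s = span/10). Peakless profiles are rejected before fitting by a
prominence check against a difference-based noise estimate. Ties in the
parabolic peak refinement (flat triangular peaks) return the grid lag.
All randomness flows from explicit integer seeds; repeated runs are
byte-identical.
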