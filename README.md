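# tipkinetics

Quantitative analysis of oscillatory tip growth in pollen tubes from
single-channel fluorescence time lapses — and a synthetic-data generator
with exact ground truth so every stage of the analysis can be verified
without microscopy data.

Pollen tubes elongate exclusively at the apex in a pulsed rhythm:
wall-material secretion thickens the apical cell wall, then turgor-driven
extension follows, with thickening leading elongation by a phase lag of
tens of seconds. `tipkinetics` measures that rhythm. Given a calibrated
time lapse of a wall-labelled tube it:

1. **segments** the tube in every frame and in the time projection
   (Gaussian smoothing → Otsu threshold → half-maximum boundary refinement
   → morphological closing → largest component → hole filling);
2. extracts the **growth trajectory** as the centerline (pruned
   morphological skeleton) of the time-projection mask, with arc-length
   parameterization in µm;
3. tracks the **tip** per frame: the mask/trajectory intersection centers a
   ±3 µm intensity-profile window (averaged over a 3-px transverse width),
   and a Gaussian fit `I(s) = b + a·exp(−(s−µ)²/2σ²)` yields the tip
   midpoint `µ` and the apical wall thickness `σ`;
4. derives **velocity** by central differences of `µ(t)`, cleans both
   series with an 11-point running average, and subtracts the overall
   baseline;
5. computes per-tube **velocity autocorrelation** and
   **thickness → velocity cross-correlation**
   `ρ_wv(k) = Σ_t w_t v_{t+k} / √(Σw²·Σv²)`, averages the curves across
   tubes, and reports the first positive-lag peak with parabolic
   refinement (a peak at lag `k > 0` means thickening precedes elongation
   by `k` seconds; uncertainty is the SEM of per-tube peaks).

Two companion analyses handle single-frame images: ROI quantification
(vertical alignment, 5 µm tip ROI and 60 µm shank ROI along the
trajectory, robust staining segmentation, percent-area and mean-intensity
tables) and wall-deposition profiles (wall-ridge intensity vs distance
from the tip over 0–30 µm, fitted per tube by a Gaussian, a three-parameter
logistic, or a four-parameter logistic
`I(x) = A + (B−A)/(1+exp((x_mid−x)/s))`, with two-stage group statistics).

The `synthetic` module renders movies of a straight tube with sinusoidally
pulsed velocity `v(t) = v0 + Av·sin(2πt/T)` and wall thickness
`σ(t) = w0 + Aw·sin(2π(t+δ)/T)` (`δ` = the phase lead of thickening), plus
punctate ROI images with exactly known covered-area fractions and 1-D
profile cohorts with known parameters — the ground truth every test is
checked against.

## Worked example

Simulate a noisy movie (240 s, 1 frame/s, SNR 10) whose wall thickening
leads elongation by δ = 20 s, then run the measurement chain:

```sh
tipkinetics simulate stack --params params.yaml --seed 11 --out sim
tipkinetics track sim/stack.tif --out tracked
tipkinetics correlate tracked/tip_trace.csv --out corr
```

with `params.yaml`:

```yaml
kinematics: {v0: 0.3, Av: 0.2, T: 40.0, delta: 20.0, duration: 240.0, dt: 1.0}
geometry: {noise_gaussian_sd: 10.0}
```

`corr/peaks.json` then contains

```json
{
  "autocorrelation":    {"lag_s": 40.06, "n_tubes": 1, "sem_s": 0.0},
  "cross_correlation":  {"lag_s": 19.92, "n_tubes": 1, "sem_s": 0.0}
}
```

The velocity autocorrelation peaks at 40.06 s — the oscillation period T —
and the thickness→velocity cross-correlation peaks at +19.92 s, recovering
the simulated 20 s phase lead of wall thickening over elongation to within
a tenth of a second. `tracked/tip_trace.csv` holds the per-frame tip
position, thickness, velocity and their smoothed/detrended versions.

The same entry points work on real data: a multi-page TIFF plus a sidecar
YAML giving `pixel_size_um` and `frame_interval_s`.

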