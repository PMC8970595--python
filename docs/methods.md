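# Methods

## Scope and model

`omkit` processes high-speed voltage-dye fluorescence movies of paced
rodent hearts and validates every stage against a built-in synthetic
simulator. The processing chain assumes a regular paced rhythm (all
conditioning is stimulus-aligned), a fractional inverted-polarity dye
signal riding on a static baseline, and approximately stationary white
sensor noise. It does not model motion (real preparations are
electromechanically uncoupled), arrhythmic or alternating rhythms, or
photobleaching beyond a linear drift.

## Synthetic recordings

The simulator renders

F(x, y, t) = B(x, y) · (1 − a · V(x, y, t)) + drift · t + N(0, σ²),

rounded to the camera's integer range.

* **Wave geometry.** Activation time is the analytic elliptical field
  T(x, y) = sqrt((u/v_L)² + (w/v_T)²) where (u, w) are mm offsets from the
  pacing site rotated into the fiber frame. v_L/v_T are the longitudinal
  and transversal conduction velocities in m/s (= mm/ms). The ground-truth
  field is returned exactly; the simulator never discretizes the truth.
* **AP waveform.** Each pixel plays the same normalized template delayed by
  T: a 2 ms smoothstep upstroke to 1, then exponential repolarization with
  τ = (APD80 − up/2)/ln 5, so the time from the maximum upstroke derivative
  (mid-upstroke) to the 20%-of-amplitude crossing equals APD80 exactly —
  the template's APD80 is true by construction, not by calibration.
  The train is periodic in the pacing cycle length (PCL); the residual tail
  at wrap-around is ≤ ~10⁻³ of the peak for the packaged scenarios.
* **Restitution.** APD80(PCL) = APD80_ref − s·(150 − PCL), with the mouse
  slope anchored so APD80 shortens 19 ms from PCL 150 to 80 ms. Velocities
  shorten analogously (51 → 47 cm/s longitudinal and 29 → 25 cm/s
  transversal between PCL 150 and 90 ms). The drug preset adds a fixed
  +19 ms APD80 increment, emulating a transient-outward K⁺-current blocker.
* **Noise calibration.** σ is solved in closed form from the target raw
  SNR: σ = mean(B over the intensity mask) · a · RMS(V) / SNR_target
  (mouse 0.5, rat 1.4). Baseline 600 counts of a 10-bit range with a radial
  cosine vignette (strength 0.3, reaching 0.7 at the frame margin) and
  2 counts/s drift. The absolute APD80 defaults (mouse 40 ms, rat 60 ms at
  PCL 150) and the rat velocities are declared defaults — the validation
  data this emulates prints anchors and accuracies, not those absolutes.
* **Determinism.** One integer seed drives a single PRNG; identical seeds
  give bit-identical recordings. The pipeline fans a global seed out to
  stages via `stage_seed(seed, k) = (seed·100003 + k) mod 2³¹−1`.

## Conditioning

1. **Spatial binning**: each frame is convolved with a normalized gaussian
   truncated to the window (default 5×5). The window sizes are prescribed;
   the corresponding σ is not, so σ = (window−1)/4 (truncation at 2σ),
   reflect padding to avoid edge dimming. For white noise the 5×5/σ=1
   kernel reduces the noise SD by 1/Σw² per axis ≈ 3.48× in 2-D.
2. **Beat segmentation**: onsets come from the global (frame-mean) signal —
   the largest-magnitude first derivative fixes the upstroke phase, beats
   follow at strides of one PCL with ±2-frame refinement by the local
   derivative extremum. Each window opens before the onset by a lead-in
   measured from the global derivative's own left edge (its 10%-of-peak
   crossing) plus 5% of the PCL: the global upstroke peaks at the *mean*
   activation time, and without the measured lead the earliest-activating
   pixels (near the pacing site) would fall outside their window — at short
   PCLs this produced catastrophic per-pixel activation errors.
3. **Ensemble averaging**: all complete beats inside the window (default
   2 s → 13 beats at PCL 150) are averaged per pixel, shrinking
   uncorrelated noise by ~√N.
4. **Normalization**: polarity is flipped (depolarization darkens a
   voltage dye) and each pixel rescaled to resting 0 / peak 1; zero-range
   pixels are flagged dead, never raised.

## SNR

SNR = RMS signal amplitude / RMS noise, the noise evaluated at resting
potential: the pooled diastolic windows, defined as the last 20% of each
cycle (the most repolarized interval before the next upstroke). Two
estimator details matter at raw SNR ≈ 0.5:

* The beat-window mean-square deviation contains the noise power itself,
  so the naive ratio can never fall below ~1. The amplitude is therefore
  estimated as sqrt(max(P_beat − P_noise, 0)); with that subtraction the
  estimator is unbiased and sub-unity SNR is measurable. The literal
  RMS-ratio is available via `correct_noise_bias=False`.
* The resting level is the per-window diastolic mean (robust to drift),
  and both the noise power (dof correction for the estimated means) and
  the beat power (variance of the estimated resting level) are
  bias-corrected; without these the measured raw SNR runs ~13% high at
  the mouse noise level.

The conditioned SNR of the mouse scenario is the raw calibration times the
conditioning gain, 3.48 × √13 ≈ 12.5 — about 6.3, inside the published
16 ± 10 band for conditioned rodent recordings. A gain much beyond this is
not achievable from stationary white noise with this chain; the packaged
conditions are not tuned to inflate it.

## Masking

Pixels are kept when conditioned SNR ≥ cutoff (default 2) and the mean
intensity lies between the intensity cutoff (default 0.8× the center
baseline, which selects the analytic vignette disc) and a saturation bound
(top 1% of the sample range). Dead pixels are removed. Masks carry their
provenance (the cutoffs that produced them).

## Mapping

* **Activation**: time of the maximum first difference, parabolically
  refined (strict local maxima only; plateaus keep the earliest sample —
  the tie-break is part of the contract). At ~1 kHz a 2 ms upstroke spans
  only two frames and the refined estimate scallops by ~0.1 ms with the
  sampling phase; that ripple has a spatial wavelength of one isochrone
  spacing and corrupts local velocity fits even without noise. The
  pipeline therefore band-limits the trace with a 2 ms temporal gaussian
  (the upstroke timescale) before differencing; the symmetric upstroke's
  derivative peak does not shift.
* **Resting level** (for APD): the trace filtered with a 1-D gaussian,
  σ = 7 ms truncated at 4σ, averaged over the diastolic window — noise
  otherwise distorts the apparent resting potential and hence the
  repolarization threshold.
* **APD80**: from activation to the first sustained (2-sample) crossing
  below resting + 0.2·amplitude after the peak, linearly interpolated.
  The sustained requirement suppresses the first-passage early bias on
  shallow repolarization tails; a single below-threshold final sample also
  terminates, so clean traces behave identically. Unrepolarized pixels
  return NaN. Population statistics exclude outliers with single-pass
  Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR; quartiles by linear
  interpolation between order statistics).
* **Conduction velocity**: per masked pixel, a least-squares polynomial
  surface (default order 2 over a 7×7 window, in mm units) is fit to the
  activation map; v = ∇T/|∇T|² at the center, in cm/s. Fits with RMS
  residual above 2 ms, underdetermined windows and near-zero gradients are
  undefined. The estimator is exact on polynomial surfaces up to the fit
  order. Axis CV averages the speeds of vectors within ±15° of the axis
  (or its opposite — waves leave a central pacing site both ways); since
  speed is a reciprocal gradient magnitude, its noise distribution has a
  heavy right tail, so the same Tukey-fence exclusion used for APD is
  applied to the cone speeds before averaging (the plain mean is available
  via `robust=False`).
* **Restitution**: per-PCL summaries aggregate into a table sorted from
  slow to fast pacing; duplicate PCLs are rejected.

## Numerical and interface choices

* Time is ms everywhere; velocities cm/s (pixel size in mm/px lives in the
  movie header — CV is meaningless without spatial calibration, default
  0.035 mm/px).
* All filtering runs in floating point; quantization happens only at
  file I/O. The OMR1 container stores uint16 samples little-endian,
  frame-major, after a fixed 44-byte header.
* Full-size problem sizes: the packaged scenarios are 200×200 px × 1954
  frames; the validation script runs five seeded mouse replicates plus rat
  and PCL-80 runs, a few minutes total on one CPU. Tests use down-scaled
  grids (40–100 px) for unit-level checks and the full-size scenarios for
  end-to-end recovery.

## What passing tests show — and what they do not

The simulator shares the pipeline's signal model (identical AP templates
per pixel, white stationary noise, no motion). Parameter recovery under
these conditions demonstrates the correctness and calibration of the
estimators, not their robustness to waveform heterogeneity, motion
artifact, or non-stationary illumination. Known limitations observed on
the synthetic data itself:

* With strongly prolonged APD at fast pacing (drug preset at PCL 150,
  APD80 = 59 ms), repolarization is incomplete before the next stimulus;
  the residual tail raises the estimated resting level and biases APD80
  low by ~5 ms. This mirrors the real measurement problem rather than a
  code defect; the bias shrinks with slower pacing.
* Conditioned SNR estimates for a single averaged beat rest on ~30
  diastolic samples and are individually noisy; only masked means are
  reported.
* The CV fit window (7×7 ≈ 0.25 mm) is smaller than the spatial
  correlation length of conditioned noise, so per-vector speeds scatter
  ±20%; the robust cone average absorbs this, but single-vector values
  should not be over-interpreted.
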