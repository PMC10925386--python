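# Methods

## Data model and conventions

A hypercube is `data[band, row, col]` with strictly ascending band centers
in cm⁻¹ and pixel pitches `dx`, `dy` in µm. Images are 0-based, row-major,
origin top-left. The default band set is the 27 discrete-frequency bands of
the 902–1898 cm⁻¹ sweep plus the Amide I reference at 1660 cm⁻¹ (28 bands;
1662 and 1668 cm⁻¹ are separate members of the sweep). Sparse acquisition
keeps rows {0, s, 2s, …} of every non-reference band, where
`s = dy_lo / dy_hi` must be an integer; the last partial stride is retained
(`rows_lo = ceil(rows_hi / s)`), and sparse row *i* corresponds to dense
row *i·s* with row 0 aligned — the interleave phase is a convention, and
anchoring at row 0 is the reproducible choice. Absorbance is stored as
float; small negative values (noise) are legal, and validation flags
|A| > 5 as suspicious rather than rejecting it.

## Fourier interpolation

Upsampling is per column along y: FFT, fftshift, symmetric zero-padding to
the target row count, Gaussian windowing, inverse FFT, rescale by
`rows_hi / rows_lo`. Numerical details that matter:

- **Nyquist splitting.** For even `rows_lo` the single Nyquist bin is split
  half/half into the ±Nyquist positions of the padded spectrum, so real
  inputs map to real outputs; the residual imaginary part is asserted
  < 1e-8 of the signal norm before being dropped.
- **Window.** `w(k) = exp(−k²/2σ²)` over the centered y-frequency index,
  with σ set so the gain is 0.5 at
  `window_half_gain_fraction × rows_lo/2`. The default fraction 1.0 anchors
  the smoothing to the actual low-resolution Nyquist; `None` disables the
  window (pure trigonometric interpolation). Only the y axis is windowed —
  x was fully sampled, and smoothing it would discard measured detail.
- **Grid alignment.** When `s` does not divide `rows_hi`, bands are
  upsampled to `s·rows_lo` rows and cropped, so output row *r* always sits
  at sparse coordinate *r/s* exactly instead of being stretched by the
  ceil-rule excess.
- DC gain is exactly 1 (window = 1 at k = 0 and the amplitude
  normalization), so mean absorbance — the quantitative content of the
  band — is preserved.

## Curvelet transform

The transform is a frequency-domain tight frame built from separable
radial × angular windows on the fftshift-centered spectrum:

- **Radial:** Meyer-type bands with the C³ polynomial ramp
  `ν(t) = t⁴(35 − 84t + 70t² − 20t³)`; boundaries at `2^(j−J+1)` of the
  per-axis Nyquist, an isotropic lowpass at the coarsest scale, and a
  finest band extending to the grid corners.
- **Angular:** raised-cosine wedges through the same ramp; every frequency
  sample contributes `cos` to its wedge and `sin` to the next, so squared
  contributions sum to one exactly. Wedge counts start at
  `n_angles_coarse` (default 16) at the second-coarsest scale and double
  every second scale toward finer (parabolic scaling). The finest scale is
  isotropic by default ("wavelet" mode, avoiding oriented boundary
  artifacts at the highest frequencies); "curvelet" mode splits it too.

Because Σ|U|² = 1 at every frequency sample, analysis followed by synthesis
is the exact identity and coefficient energy equals image energy (both hold
to ~1e-15 in tests, against a 1e-6 contract). Each wedge is cropped
("wrapped") to the bounding rectangle of its frequency support before its
per-wedge inverse FFT, so coefficient arrays shrink with the wedge; the
inverse re-embeds each wedge spectrum at its recorded offset. This
construction differs from the classical wrapping implementation in using
bounding-box cropping rather than modular wrapping of sheared
parallelograms — simpler index arithmetic, the same tight-frame guarantees,
and native support for non-square, non-power-of-two images.
`n_scales` defaults to `max(2, ceil(log2(min(rows, cols))) − 3)`; images
must have `min side ≥ 2^(n_scales+2)` (and ≥ 32 always).

## Fusion

Per band: equalize the reference to the interpolated band by least squares
(`a, b` minimizing Σ(a·ref + b − band)²; a constant reference degenerates
to `a = 0, b = mean`), transform both, take coarse scales from the
interpolated band and the `fusion_depth` finest scales from the equalized
reference, invert. The per-band `(a, b)` are logged in the reconstruction
result.

`fusion_depth = None` (default) resolves to `n_scales − 1`: one fixed
low/high split in which everything except the coarsest scale comes from
the reference. Two design points here were genuinely open:

- **Depth schedule.** A decimation-matched depth `ceil(log2(s))`
  (`default_fusion_depth`) is the natural information-theoretic choice —
  substitute only the octaves destroyed by decimation. Measured on
  phantoms, however, the fixed `n_scales − 1` split is uniformly better in
  both MSE and SSIM at every factor s ∈ {2, 4, 10, 20, 40}: the equalized
  reference is a better estimate of mid-frequency structure than the
  noise-bearing interpolation even where the interpolation retains signal.
  The adaptive schedule also made quality non-monotone across a spacing
  sweep (deeper substitution at s = 4 beat s = 2). The fixed split is
  therefore the default; the adaptive depth remains available by passing
  `fusion_depth` explicitly.
- **Coarsest scale.** The coarsest scale is never substituted (depth is
  clamped to `n_scales − 1`): it carries the band's mean and broad
  chemistry, which is the spectral information the method must preserve.
  Per-band means consequently shift by < 5 % through fusion, and the
  reference band itself passes through the pipeline bit-identical.

All orientations at a substituted scale come from the reference, including
wedges not degraded by y-decimation — scale-level substitution is the
simple reading of "low frequencies from the interpolated image, high
frequencies from the reference"; orientation-selective fusion is a
possible extension.

## Phantoms: what they emulate and what they do not

`PhantomSpec` defaults define the study conditions: 120 × 120 px at
0.5 µm pitch, 3 classes (epithelium-, stroma-, necrosis-like), blob
regions from Gaussian-smoothed white noise thresholded at equal quantiles
(correlation length `boundary_smoothness` = 8 µm; every class ≥ 2 % of
pixels, degenerate draws retried deterministically), spatial blur
σ = 1 px, additive i.i.d. Gaussian noise σ = 0.01 absorbance. Class
spectra are a class-specific broad baseline (offset 0.05–0.2 plus a gentle
slope — real tissue bands are chosen for chemical significance, so every
band carries some class contrast) plus 3–6 Gaussian peaks at plausible
positions (carbohydrate ~1036, nucleic acid ~1080, amide III ~1240, CH₂
~1456, amide II ~1545, amide I ~1660, ester ~1740 cm⁻¹). Every class gets
an amide I peak with heights spread over [0.5, 1.2] across classes:
protein content separates tissue classes strongly in practice, which is
precisely why amide I serves as the morphology reference — without this,
a randomly weak reference band drives equalization gains to ~6 and
amplifies reference noise into the fused bands. Classes are redrawn until
all pairwise spectral angles are ≥ 5°. Generation is a pure function of
the spec (seed included).

Phantoms do **not** model scattering or baseline artifacts, stage-motion
distortion, spatially correlated noise, instrument response, or the
within-class texture of real tissue. Passing tests demonstrate that the
algorithms behave as specified under known ground truth — not that real
tissue reaches any particular accuracy. In particular the ≥ 90 %
segmentation accuracy on reconstructed phantoms is a preservation check
(reconstruction does not destroy class-discriminative spectra), not a
claim about clinical performance.

## Evaluation

MSE is the plain pixel mean of squared differences. SSIM uses the standard
11 × 11 Gaussian window (σ 1.5), k₁ = 0.01, k₂ = 0.03, with the dynamic
range taken from the truth band so a candidate cannot inflate its score;
a bare two-image call uses the joint range, keeping the score symmetric.
Scores are computed per band against the noiseless truth and averaged
unweighted (scoring against noisy truth is available via a flag; per-cube
joint scoring was the other defensible reading and is not the default).
The spacing sweep regenerates one phantom per replicate
(seed = base_seed + i), reconstructs at each spacing and reports
mean ± sd across replicates (n − 1 denominator); the replicate count is a
parameter (4 in the shipped analyses and examples).

The segmentation harness mirrors a held-out-half protocol: class-balanced
pixels (default 1000/class in the pipeline; sizes are configurable) are
sampled without replacement from the right half of the core, a
100-tree random forest (unlimited depth, √-feature subsampling, seeded)
is trained on the 27 non-reference bands, and the left half is scored.
Overall accuracy is the support-weighted mean of per-class recalls, which
equals the raw pixel-match fraction; both are reported. One-vs-rest AUC
uses trapezoidal ROC integration and is reported as missing (not 0) for a
class absent from the truth.

## Determinism and problem sizes

A single pipeline seed expands into per-stage seeds by hashing the stage
name (`stage_seed`), so identical configs yield byte-identical artifacts
(verified by manifest checksums) and any stage can be rerun in isolation.
Shipped analyses use 120 × 120 px phantoms, 28 bands, 4 sweep replicates
and 1000 training pixels per class — sizes at which every documented
property is stable across seeds while a full pipeline run completes in
seconds; all of them scale up linearly through the same configs.

## Known limitations

- Integer decimation factors only; no 2-D (x and y) sparse patterns and no
  compressed-sensing-style reconstruction.
- Equalization is a global affine fit per band; bands whose relationship
  to the reference is strongly non-affine receive imperfect high-frequency
  scaling (mitigated, not eliminated, by the amide-anchored phantom
  design; on real data, band-to-reference correlation is high).
- The curvelet implementation favors exactness and clarity over speed; it
  is O(n² log n) per band with modest constants, comfortable for desk-
  scale images and TMA cores, but makes no attempt at parallelism.
- The CNN-style patch classifier used in related work is out of scope;
  the prediction interface accepts any classifier exposing
  `predict_proba` over per-pixel spectra.
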