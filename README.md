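# optir-recon

Sparse-sampling reconstruction and evaluation for optical photothermal
infrared (O-PTIR) hyperspectral imaging.

O-PTIR delivers sub-micron mid-infrared chemical images, but raster
acquisition time is proportional to the number of scanned y rows, so a
28-band hypercube of a tissue-microarray core can take well over a day.
This package implements an acquisition/reconstruction scheme that collects
only one band — Amide I at 1660 cm⁻¹, the strongest and most
morphologically informative protein band — at the full 0.5 × 0.5 µm pitch,
acquires the remaining 27 bands at a coarser y pitch (e.g. 0.5 × 5 µm,
i.e. 10 % of the pixels), and computationally restores the missing
resolution. It is aimed at spectroscopic-imaging practitioners who want to
trade acquisition time against reconstruction fidelity in a controlled,
measurable way.

## Method

For a band image sampled every *s*-th row (decimation factor
*s = dy_lo / dy_hi*):

1. **Fourier zero-pad interpolation.** Per column, the y-spectrum of the
   low-resolution band is centered and zero-padded to the full row count, a
   Gaussian window with half gain at the low-resolution Nyquist suppresses
   replication ringing, and the inverse FFT (rescaled by
   `rows_hi / rows_lo` so the mean absorbance is preserved) yields the
   interpolated band.
2. **Curvelet-domain fusion.** The reference band is affinely equalized to
   each interpolated band, `b ≈ a·ref + c`, by least squares. Both images
   are decomposed with a fast discrete curvelet transform — a tight frame
   of Meyer-type polar frequency wedges (squared partition of unity;
   wedges double in orientation count every second scale) with each wedge
   wrapped onto the bounding rectangle of its frequency support. The
   coefficient pyramid is then recombined: coarse scales from the
   interpolated band (preserving the band's own radiometry and
   chemistry), all finer scales from the equalized reference (restoring
   edges lost to decimation), and inverted.

Evaluation utilities cover per-band MSE and SSIM against ground truth, a
spacing sweep over replicate phantoms, and a pixel-wise random-forest
tissue classifier (class-balanced sampling, overall accuracy, one-vs-rest
ROC/AUC) that checks whether reconstruction preserves class-discriminative
chemistry. Because no public O-PTIR dataset exists, the `phantom` module
generates synthetic tissue cores — blob-shaped epithelium/stroma/necrosis
regions, per-class absorbance spectra over the 28-band set, optical blur
and detector noise — with exact ground truth.

## Worked example

```sh
python examples/reconstruct_phantom.py
```

```
sampling 10.0% of the pixels in 27 of 28 bands
interpolated: mean MSE 0.00368, mean SSIM 0.620
fused:        mean MSE 0.00320, mean SSIM 0.693
```

A 120 × 120 px phantom is decimated 10× in y (only the reference band
stays dense), reconstructed both ways, and scored per band against the
noiseless truth. Interpolation alone leaves y-blur (SSIM 0.620); fusing
reference high frequencies sharpens boundaries, cutting mean squared error
by ~13 % and raising SSIM to 0.693. The other examples print the
data-fraction/scan-time budget (`acquisition_budget.py`), the
spacing-quality trade-off that motivates the 0.5 × 5 µm operating point
(`spacing_sweep.py`), and the held-out tissue-classification check
(`segmentation_check.py`, overall accuracy 93.2 % on a reconstructed
cube).

The same operations are scriptable from the shell:

```sh
optir-recon phantom --outdir ph --seed 1
optir-recon subsample ph/truth_noisy.hdr --dy-lo 5 --outdir sparse
optir-recon reconstruct sparse recon.hdr
optir-recon run-all --outdir run --seed 42
```

Cubes are stored as ENVI BSQ float32 pairs or multi-page TIFFs with a JSON
sidecar; label maps as integer TIFFs with a class/RGB sidecar.

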