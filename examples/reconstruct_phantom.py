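"""Reconstruct a sparsely sampled phantom and score it against ground truth.

Generates a synthetic tissue core, simulates the sparse acquisition
(every band y-decimated 10x except the full-resolution 1660 cm^-1
reference), then compares plain Fourier interpolation with curvelet-domain
fusion against the noiseless truth.
"""

from optir_recon import (
    PhantomSpec,
    SamplingScheme,
    evaluate_reconstruction,
    interpolate_cube,
    make_phantom,
    reconstruct_cube,
    sampling_fraction,
    subsample_y,
)

spec = PhantomSpec(rows=120, cols=120, spatial_blur_sigma=0.5, noise_sd=0.005, seed=11)
truth = make_phantom(spec)

scheme = SamplingScheme(dx_hi=0.5, dy_hi=0.5, dy_lo=5.0)  # 0.5 x 5 um sampling
print(f"sampling {sampling_fraction(scheme):.1f}% of the pixels in 27 of 28 bands")

sparse = subsample_y(truth.noisy_cube, scheme)
interp = interpolate_cube(sparse)
result = reconstruct_cube(sparse)

_, agg_i = evaluate_reconstruction(truth.clean_cube, interp, "interpolated")
_, agg_f = evaluate_reconstruction(truth.clean_cube, result.cube, "fused")
print(f"interpolated: mean MSE {agg_i['mse']:.5f}, mean SSIM {agg_i['ssim']:.3f}")
print(f"fused:        mean MSE {agg_f['mse']:.5f}, mean SSIM {agg_f['ssim']:.3f}")
print(
    "-> fusing high-frequency curvelet scales from the Amide I reference "
    "lowers the per-band error and raises structural similarity."
)
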