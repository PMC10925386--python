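import math

import numpy as np
import pytest

from optir_recon import (
    PhantomSpec,
    SamplingScheme,
    acquisition_time_estimate,
    generate_class_map,
    generate_spectral_library,
    make_phantom,
    render_hypercube,
    sampling_fraction,
    subsample_y,
)


class TestClassMap:
    def test_deterministic_under_seed(self):
        spec = PhantomSpec(rows=64, cols=64, seed=7)
        assert np.array_equal(generate_class_map(spec), generate_class_map(spec))

    def test_two_classes_both_present(self):
        labels = generate_class_map(PhantomSpec(rows=64, cols=64, n_classes=2, seed=1))
        assert set(np.unique(labels)) == {0, 1}

    def test_every_class_occupies_at_least_two_percent(self):
        labels = generate_class_map(PhantomSpec(rows=64, cols=64, seed=3))
        counts = np.bincount(labels.ravel(), minlength=3)
        assert counts.min() >= 0.02 * labels.size
        assert counts.max() <= 0.96 * labels.size


class TestSpectralLibrary:
    def test_deterministic_and_shaped(self):
        spec = PhantomSpec(seed=2)
        lib = generate_spectral_library(spec)
        assert lib.shape == (3, len(spec.wavenumbers))
        assert np.array_equal(lib, generate_spectral_library(spec))

    def test_all_spectra_nonnegative(self):
        for seed in range(5):
            lib = generate_spectral_library(PhantomSpec(seed=seed))
            assert (lib >= 0).all()

    def test_classes_separable_by_spectral_angle(self):
        lib = generate_spectral_library(PhantomSpec(seed=0), min_angle_deg=5.0)
        for i in range(3):
            for j in range(i + 1, 3):
                cos = np.dot(lib[i], lib[j]) / (
                    np.linalg.norm(lib[i]) * np.linalg.norm(lib[j])
                )
                assert math.degrees(math.acos(cos)) >= 5.0


class TestRenderHypercube:
    def test_zero_noise_gives_identical_cubes(self):
        spec = PhantomSpec(rows=32, cols=32, noise_sd=0.0, seed=4)
        truth = make_phantom(spec)
        assert np.array_equal(truth.noisy_cube.data, truth.clean_cube.data)

    def test_unblurred_single_class_planes_are_constant(self):
        spec = PhantomSpec(rows=32, cols=32, spatial_blur_sigma=0.0, seed=0)
        lib = generate_spectral_library(spec)
        truth = render_hypercube(np.zeros((32, 32), dtype=int), lib, spec)
        for b in range(truth.clean_cube.n_bands):
            assert np.ptp(truth.clean_cube.data[b]) == 0.0

    def test_noise_variance_matches_noise_sd(self):
        """Sample variance of (noisy - clean) within 30% of noise_sd^2."""
        spec = PhantomSpec(rows=64, cols=64, noise_sd=0.01, seed=9)
        truth = make_phantom(spec)
        resid = truth.noisy_cube.data - truth.clean_cube.data
        per_band_var = resid.reshape(resid.shape[0], -1).var(axis=1)
        assert np.all(np.abs(per_band_var - 1e-4) < 0.3e-4)

    def test_pure_function_of_spec(self):
        spec = PhantomSpec(rows=48, cols=48, seed=13)
        a, b = make_phantom(spec), make_phantom(spec)
        assert np.array_equal(a.noisy_cube.data, b.noisy_cube.data)
        assert np.array_equal(a.label_map, b.label_map)


class TestSamplingFraction:
    @pytest.mark.parametrize(
        "dy_lo, expected",
        [(1.0, 50.0), (2.0, 25.0), (5.0, 10.0), (10.0, 5.0), (20.0, 2.5)],
    )
    def test_printed_percentages(self, dy_lo, expected):
        assert sampling_fraction(SamplingScheme(dy_lo=dy_lo)) == expected

    def test_identity_at_full_resolution(self):
        assert sampling_fraction(SamplingScheme(dy_lo=0.5)) == 100.0

    def test_strictly_decreasing_in_dy_lo(self):
        values = [sampling_fraction(SamplingScheme(dy_lo=d)) for d in (0.5, 1, 2, 5, 10, 20)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestAcquisitionTime:
    def test_dense_limit(self):
        scheme = SamplingScheme(dy_lo=0.5)
        assert acquisition_time_estimate(scheme, 28, 100, 0.1) == pytest.approx(
            0.1 * 100 * 28
        )

    def test_single_band_halved_at_factor_two(self):
        scheme = SamplingScheme(dy_lo=1.0)
        assert acquisition_time_estimate(scheme, 1, 100, 1.0) == pytest.approx(100.0)

    def test_sparse_28_band_fraction(self):
        """28 bands at s=10: time ~= 13.2% of dense (1 full + 27 decimated rows)."""
        scheme = SamplingScheme(dy_lo=5.0)
        sparse = acquisition_time_estimate(scheme, 28, 1000, 1.0)
        dense = acquisition_time_estimate(SamplingScheme(dy_lo=0.5), 28, 1000, 1.0)
        assert sparse / dense == pytest.approx((1000 + 27 * 100) / (28 * 1000))
        assert sparse / dense == pytest.approx(0.132, abs=0.002)


class TestSubsample:
    def test_factor_one_is_identity(self, default_truth):
        sparse = subsample_y(default_truth.noisy_cube, SamplingScheme(dy_lo=0.5))
        mask = default_truth.noisy_cube.wavenumbers != 1660.0
        assert np.array_equal(sparse.sparse_bands, default_truth.noisy_cube.data[mask])

    def test_reference_band_kept_full(self, default_truth):
        sparse = subsample_y(default_truth.noisy_cube, SamplingScheme(dy_lo=5.0))
        assert np.array_equal(
            sparse.reference_band, default_truth.noisy_cube.band(1660.0)
        )

    def test_missing_reference_band_rejected(self, default_truth):
        scheme = SamplingScheme(dy_lo=5.0, reference_wavenumber=1234.0)
        with pytest.raises(KeyError):
            subsample_y(default_truth.noisy_cube, scheme)
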