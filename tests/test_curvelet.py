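import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optir_recon.curvelet import (
    CurveletParams,
    coefficient_energy,
    fdct_forward,
    fdct_inverse,
    orientation_energies,
    split_by_scale,
)
from optir_recon.curvelet import _check_partition


SIZES = [(32, 32), (64, 64), (100, 60)]


@pytest.fixture(params=SIZES, ids=["32x32", "64x64", "100x60"])
def random_image(request):
    rows, cols = request.param
    return np.random.default_rng(42).standard_normal((rows, cols))


class TestTightFrame:
    def test_windows_form_squared_partition_of_unity(self, random_image):
        rows, cols = random_image.shape
        p = CurveletParams().resolve((rows, cols))
        total = _check_partition(rows, cols, p.n_scales, p.n_angles_coarse, p.finest_scale_type)
        assert np.abs(total - 1.0).max() < 1e-12

    def test_round_trip_identity(self, random_image):
        rec = fdct_inverse(fdct_forward(random_image))
        rel = np.linalg.norm(rec - random_image) / np.linalg.norm(random_image)
        assert rel < 1e-6

    def test_parseval_energy_match(self, random_image):
        coeffs = fdct_forward(random_image)
        img_energy = float(np.sum(random_image**2))
        assert coefficient_energy(coeffs) == pytest.approx(img_energy, rel=1e-6)

    def test_round_trip_with_curvelet_finest_scale(self, random_image):
        params = CurveletParams(finest_scale_type="curvelet")
        rec = fdct_inverse(fdct_forward(random_image, params))
        rel = np.linalg.norm(rec - random_image) / np.linalg.norm(random_image)
        assert rel < 1e-6


class TestForward:
    def test_zero_image_gives_zero_coefficients(self):
        coeffs = fdct_forward(np.zeros((32, 32)))
        assert all(
            np.all(a == 0) for scale in coeffs.pyramid for a in scale
        )

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal((2, 32, 32))
        cx, cy, cxy = fdct_forward(x), fdct_forward(y), fdct_forward(x + y)
        for j in range(cxy.n_scales):
            for s, a, b in zip(cxy.pyramid[j], cx.pyramid[j], cy.pyramid[j]):
                assert np.abs(s - (a + b)).max() < 1e-9

    def test_constant_image_round_trips(self):
        x = np.full((48, 48), 3.25)
        rec = fdct_inverse(fdct_forward(x))
        assert np.abs(rec - 3.25).max() < 1e-6

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="minimum side"):
            fdct_forward(np.zeros((16, 16)))

    def test_too_many_scales_rejected(self):
        with pytest.raises(ValueError, match="minimum side"):
            fdct_forward(np.zeros((32, 32)), CurveletParams(n_scales=4))

    def test_orientation_count_doubles_every_second_scale(self):
        p = CurveletParams(n_angles_coarse=16)
        assert [p.n_angles(j) for j in (1, 2, 3, 4, 5)] == [16, 16, 32, 32, 64]
        img = np.random.default_rng(0).standard_normal((128, 128))
        coeffs = fdct_forward(img, CurveletParams(n_scales=4))
        assert [len(s) for s in coeffs.pyramid] == [1, 16, 16, 1]


class TestOrientationSelectivity:
    def test_horizontal_edge_concentrates_in_one_orientation(self):
        """A horizontal edge (variation along y) puts most finest-scale
        energy into the orientation band on the vertical frequency axis."""
        img = np.zeros((64, 64))
        img[32:] = 1.0
        coeffs = fdct_forward(img, CurveletParams(finest_scale_type="curvelet"))
        energies = orientation_energies(coeffs, coeffs.n_scales - 1)
        top = int(np.argmax(energies))
        assert energies[top] > 0.5 * energies.sum()
        # wedge centers sit at l * 2*pi/n from the +kx axis: the vertical
        # frequency axis is orientation index n/4 (antipodal-pooled)
        n = len(coeffs.pyramid[-1])
        assert top == n // 4


class TestSplitByScale:
    @pytest.fixture
    def coeffs(self):
        img = np.random.default_rng(7).standard_normal((64, 64))
        return fdct_forward(img)

    def test_depth_zero_keeps_everything_low(self, coeffs):
        low, high = split_by_scale(coeffs, 0)
        assert all(np.all(a == 0) for s in high.pyramid for a in s)
        for j in range(coeffs.n_scales):
            for a, b in zip(low.pyramid[j], coeffs.pyramid[j]):
                assert np.array_equal(a, b)

    def test_full_depth_moves_everything_high(self, coeffs):
        low, high = split_by_scale(coeffs, coeffs.n_scales)
        assert all(np.all(a == 0) for s in low.pyramid for a in s)

    def test_reassembly_is_exact_partition(self, coeffs):
        low, high = split_by_scale(coeffs, 1)
        for j in range(coeffs.n_scales):
            for lo, hi, orig in zip(low.pyramid[j], high.pyramid[j], coeffs.pyramid[j]):
                assert np.array_equal(lo + hi, orig)

    def test_out_of_range_depth_rejected(self, coeffs):
        with pytest.raises(ValueError, match="depth"):
            split_by_scale(coeffs, coeffs.n_scales + 1)


class TestInverseValidation:
    def test_structural_mismatch_rejected(self):
        coeffs = fdct_forward(np.random.default_rng(0).standard_normal((32, 32)))
        coeffs.pyramid[0][0] = coeffs.pyramid[0][0][:-1]
        with pytest.raises(ValueError, match="shape"):
            fdct_inverse(coeffs)

    def test_zero_coefficients_give_zero_image(self):
        coeffs = fdct_forward(np.random.default_rng(0).standard_normal((32, 32)))
        zero = coeffs.copy_structure(fill=0)
        assert np.abs(fdct_inverse(zero)).max() == 0.0
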