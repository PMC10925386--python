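"""Fast discrete curvelet transform as a tight frame of polar wedge windows.

The transform is built entirely in the frequency domain. The fftshift-
centered 2-D spectrum is multiplied by a family of smooth windows
``U_{j,l} = W_j(r) * V_{j,l}(theta)`` — Meyer-type radial bands crossed with
raised-cosine angular wedges — whose squared magnitudes sum to one at every
frequency sample (a squared partition of unity, hence a Parseval tight
frame). Each windowed wedge is then cropped to the bounding rectangle of
its frequency support ("wrapped" onto a rectangular grid) and inverse-
transformed, so coefficient arrays shrink with the wedge. The inverse
transform re-embeds each wedge spectrum at its recorded offset, multiplies
by the same (real) window, sums, and inverse-transforms once; because of
the squared partition of unity this analysis/synthesis pair is the exact
identity up to floating-point rounding.

Orientation counts follow the parabolic-scaling convention: the second-
coarsest scale carries ``n_angles_coarse`` wedges and the count doubles
every second scale toward finer. The finest scale is isotropic by default
("wavelet" mode); "curvelet" mode splits it into wedges too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "CurveletParams",
    "CurveletCoefficients",
    "fdct_forward",
    "fdct_inverse",
    "split_by_scale",
    "coefficient_energy",
    "orientation_energies",
]

_MIN_IMAGE_SIDE = 32


@dataclass(frozen=True)
class CurveletParams:
    """Transform configuration.

    ``n_scales = None`` resolves to ``max(2, ceil(log2(min(shape))) - 3)``
    for the image at hand. ``n_angles_coarse`` (multiple of 4) is the wedge
    count at the second-coarsest scale.
    """

    n_scales: int | None = None
    n_angles_coarse: int = 16
    finest_scale_type: str = "wavelet"

    def __post_init__(self) -> None:
        if self.n_scales is not None and self.n_scales < 2:
            raise ValueError(f"n_scales must be >= 2, got {self.n_scales}")
        if self.n_angles_coarse < 4 or self.n_angles_coarse % 4:
            raise ValueError(
                f"n_angles_coarse must be a positive multiple of 4, got {self.n_angles_coarse}"
            )
        if self.finest_scale_type not in ("wavelet", "curvelet"):
            raise ValueError(
                f"finest_scale_type must be wavelet|curvelet, got {self.finest_scale_type!r}"
            )

    def resolve(self, shape: tuple[int, int]) -> "CurveletParams":
        """Fill in ``n_scales`` for a concrete image shape and check size."""
        side = min(shape)
        if side < _MIN_IMAGE_SIDE:
            raise ValueError(
                f"image {shape} too small: minimum side is {_MIN_IMAGE_SIDE}"
            )
        n = self.n_scales
        if n is None:
            n = max(2, math.ceil(math.log2(side)) - 3)
        min_side = 2 ** (n + 2)
        if side < min_side:
            raise ValueError(
                f"image {shape} too small for {n} scales: minimum side is {min_side}"
            )
        return replace(self, n_scales=n)

    def n_angles(self, scale: int) -> int:
        """Wedge count at an oriented scale (scale >= 1)."""
        return self.n_angles_coarse * 2 ** ((scale - 1) // 2)


@dataclass
class CurveletCoefficients:
    """Coefficient pyramid of one image.

    ``pyramid[j]`` is the list of orientation-indexed complex arrays at
    scale ``j`` (coarsest first); isotropic scales hold a single array.
    """

    pyramid: list[list[np.ndarray]]
    shape: tuple[int, int]
    params: CurveletParams

    @property
    def n_scales(self) -> int:
        return len(self.pyramid)

    def copy_structure(self, fill: float | None = None) -> "CurveletCoefficients":
        """Same structure; arrays copied, or zero-filled if ``fill`` is 0."""
        pyr = [
            [np.zeros_like(a) if fill == 0 else a.copy() for a in scale]
            for scale in self.pyramid
        ]
        return CurveletCoefficients(pyramid=pyr, shape=self.shape, params=self.params)


# ---------------------------------------------------------------------------
# window construction


def _meyer_ramp(t: np.ndarray) -> np.ndarray:
    """Smooth C^3 ramp nu: 0 -> 1 on [0, 1] (Meyer auxiliary polynomial)."""
    t = np.clip(t, 0.0, 1.0)
    return t**4 * (35.0 - 84.0 * t + 70.0 * t**2 - 20.0 * t**3)


def _radial_windows(r: np.ndarray, n_scales: int) -> list[np.ndarray]:
    """Meyer-type radial bands on normalized radius; squared sum == 1.

    Boundaries sit at ``b_j = 2**(j - (J-1))`` for ``j = 1..J-1`` (so the
    finest boundary is the per-axis Nyquist, r = 1); band j ramps up over
    ``[b_j/2, b_j]`` and down over ``[b_j, 2 b_j]``. The lowpass covers DC
    and the finest band extends to the grid corners (r up to sqrt(2)).
    """
    J = n_scales
    bounds = [2.0 ** (j - (J - 1)) for j in range(1, J)]
    windows = []
    # lowpass: 1 below b_1/2, cosine ramp down across [b_1/2, b_1]
    b1 = bounds[0]
    t = (r - b1 / 2.0) / (b1 / 2.0)
    windows.append(np.cos(0.5 * np.pi * _meyer_ramp(t)))
    for j in range(1, J - 1):
        bj = bounds[j - 1]
        up = np.sin(0.5 * np.pi * _meyer_ramp((r - bj / 2.0) / (bj / 2.0)))
        down = np.cos(0.5 * np.pi * _meyer_ramp((r - bj) / bj))
        w = np.where(r < bj, up, down)
        w[r >= 2.0 * bj] = 0.0
        w[r <= bj / 2.0] = 0.0
        windows.append(w)
    # finest: ramp up over [1/2, 1], flat 1 out to the corners
    bJ = bounds[-1]
    up = np.sin(0.5 * np.pi * _meyer_ramp((r - bJ / 2.0) / (bJ / 2.0)))
    w = np.where(r < bJ, up, 1.0)
    w[r <= bJ / 2.0] = 0.0
    windows.append(w)
    return windows


def _angular_windows(theta: np.ndarray, n_wedges: int) -> list[np.ndarray]:
    """Raised-cosine wedges around centers ``l * 2 pi / n``; squared sum == 1.

    Every frequency sample contributes ``cos`` to its wedge and ``sin`` to
    the next, through the Meyer ramp, so exactly two wedges overlap anywhere
    and the squared contributions sum to one.
    """
    delta = 2.0 * np.pi / n_wedges
    p = np.mod(theta, 2.0 * np.pi) / delta
    cell = np.floor(p).astype(int) % n_wedges
    frac = p - np.floor(p)
    ang = 0.5 * np.pi * _meyer_ramp(frac)
    cosw, sinw = np.cos(ang), np.sin(ang)
    windows = []
    for l in range(n_wedges):
        w = np.zeros_like(theta)
        sel = cell == l
        w[sel] = cosw[sel]
        prev = cell == (l - 1) % n_wedges
        w[prev] = sinw[prev]
        windows.append(w)
    return windows


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1)


@lru_cache(maxsize=16)
def _window_bank(
    rows: int, cols: int, n_scales: int, n_angles_coarse: int, finest: str
) -> list[list[tuple[np.ndarray, tuple[int, int, int, int]]]]:
    """Per-(shape, params) cache of cropped windows and their offsets.

    Returns ``bank[scale][wedge] = (window_cropped, (r0, c0, h, w))`` where
    the window is restricted to the bounding box of its support in the
    fftshift-centered frequency plane.
    """
    ky = (np.arange(rows) - rows // 2) / (rows / 2.0)
    kx = (np.arange(cols) - cols // 2) / (cols / 2.0)
    KY, KX = np.meshgrid(ky, kx, indexing="ij")
    r = np.hypot(KY, KX)
    theta = np.arctan2(KY, KX)

    radial = _radial_windows(r, n_scales)
    bank: list[list[tuple[np.ndarray, tuple[int, int, int, int]]]] = []
    for j, w_rad in enumerate(radial):
        oriented = 1 <= j < n_scales - 1 or (j == n_scales - 1 and finest == "curvelet")
        if not oriented:
            wedges = [w_rad]
        else:
            n_w = n_angles_coarse * 2 ** ((j - 1) // 2)
            wedges = [w_rad * v for v in _angular_windows(theta, n_w)]
        scale_entries = []
        for w in wedges:
            mask = w != 0.0
            if not mask.any():  # degenerate (cannot happen for valid sizes)
                scale_entries.append((np.zeros((1, 1)), (0, 0, 1, 1)))
                continue
            r0, c0, h, wd = _bbox(mask)
            scale_entries.append((w[r0 : r0 + h, c0 : c0 + wd].copy(), (r0, c0, h, wd)))
        bank.append(scale_entries)
    return bank


def _check_partition(rows: int, cols: int, n_scales: int, n_angles_coarse: int, finest: str):
    """Diagnostic: squared sum of all windows over the frequency plane."""
    total = np.zeros((rows, cols))
    for scale in _window_bank(rows, cols, n_scales, n_angles_coarse, finest):
        for w, (r0, c0, h, wd) in scale:
            total[r0 : r0 + h, c0 : c0 + wd] += w**2
    return total


# ---------------------------------------------------------------------------
# transform


def fdct_forward(image: np.ndarray, params: CurveletParams = CurveletParams()) -> CurveletCoefficients:
    """Forward curvelet transform of a 2-D image.

    Coefficients are complex; under the tight-frame normalization their
    total squared magnitude equals the image energy (Parseval).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    resolved = params.resolve(image.shape)
    rows, cols = image.shape
    bank = _window_bank(
        rows, cols, resolved.n_scales, resolved.n_angles_coarse, resolved.finest_scale_type
    )
    spectrum = np.fft.fftshift(np.fft.fft2(image, norm="ortho"))
    pyramid = []
    for scale in bank:
        arrays = []
        for w, (r0, c0, h, wd) in scale:
            block = spectrum[r0 : r0 + h, c0 : c0 + wd] * w
            arrays.append(np.fft.ifft2(block, norm="ortho"))
        pyramid.append(arrays)
    return CurveletCoefficients(pyramid=pyramid, shape=(rows, cols), params=resolved)


def fdct_inverse(coeffs: CurveletCoefficients) -> np.ndarray:
    """Inverse transform back to the recorded image shape (exact)."""
    rows, cols = coeffs.shape
    p = coeffs.params
    bank = _window_bank(rows, cols, p.n_scales, p.n_angles_coarse, p.finest_scale_type)
    if len(bank) != len(coeffs.pyramid) or any(
        len(b) != len(s) for b, s in zip(bank, coeffs.pyramid)
    ):
        raise ValueError("coefficient structure does not match the recorded shape/params")
    acc = np.zeros((rows, cols), dtype=complex)
    for scale_bank, scale_coeffs in zip(bank, coeffs.pyramid):
        for (w, (r0, c0, h, wd)), c in zip(scale_bank, scale_coeffs):
            if c.shape != (h, wd):
                raise ValueError(
                    f"coefficient array shape {c.shape} does not match wedge {(h, wd)}"
                )
            acc[r0 : r0 + h, c0 : c0 + wd] += np.fft.fft2(c, norm="ortho") * w
    return np.fft.ifft2(np.fft.ifftshift(acc), norm="ortho").real


def split_by_scale(
    coeffs: CurveletCoefficients, depth: int
) -> tuple[CurveletCoefficients, CurveletCoefficients]:
    """Split into (low, high): ``depth`` finest scales go to ``high``.

    Both halves keep the full structure (zero-filled placeholders), so
    summing their pyramids reassembles the input exactly.
    """
    if not 0 <= depth <= coeffs.n_scales:
        raise ValueError(f"depth must be in [0, {coeffs.n_scales}], got {depth}")
    low = coeffs.copy_structure()
    high = coeffs.copy_structure(fill=0)
    for j in range(coeffs.n_scales - depth, coeffs.n_scales):
        low.pyramid[j], high.pyramid[j] = high.pyramid[j], low.pyramid[j]
    return low, high


def coefficient_energy(coeffs: CurveletCoefficients) -> float:
    """Total squared coefficient magnitude (equals image energy; Parseval)."""
    return float(
        sum(np.sum(np.abs(a) ** 2) for scale in coeffs.pyramid for a in scale)
    )


def orientation_energies(coeffs: CurveletCoefficients, scale: int) -> np.ndarray:
    """Energy per orientation at an oriented scale, antipodal wedges pooled.

    A real image has a Hermitian spectrum, so wedges at theta and
    theta + pi carry the same structure; they are summed into one
    orientation band (length ``n_wedges / 2``).
    """
    arrays = coeffs.pyramid[scale]
    if len(arrays) < 2:
        raise ValueError(f"scale {scale} is isotropic; no orientations")
    e = np.array([np.sum(np.abs(a) ** 2) for a in arrays])
    half = len(arrays) // 2
    return e[:half] + e[half:]
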