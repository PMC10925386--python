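"""Fourier zero-padding interpolation of y-decimated band images.

Each low-resolution band is upsampled per column: FFT along y, center the
spectrum, zero-pad symmetrically to the full-resolution row count, apply a
Gaussian frequency window (smoothing anchored to the low-resolution Nyquist),
inverse FFT, and rescale by ``rows_hi / rows_lo`` so the mean absorbance
(DC) is preserved. The full-resolution reference band fixes the target row
count and is passed through untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import HyperCube, SparseCube

__all__ = ["InterpParams", "gaussian_freq_window", "fft_upsample_y", "interpolate_cube"]

_IMAG_TOL = 1e-8


@dataclass(frozen=True)
class InterpParams:
    """Interpolation parameters.

    ``window_half_gain_fraction`` places the Gaussian window's half-gain
    point at that fraction of the low-resolution Nyquist frequency
    (default 1.0, i.e. gain 0.5 exactly at the low-res Nyquist). ``None``
    or ``inf`` disables the window (pure zero-pad / trigonometric
    interpolation).
    """

    window_half_gain_fraction: float | None = 1.0

    def __post_init__(self) -> None:
        f = self.window_half_gain_fraction
        if f is not None and not f > 0:
            raise ValueError(f"window_half_gain_fraction must be > 0, got {f}")

    @property
    def window_enabled(self) -> bool:
        f = self.window_half_gain_fraction
        return f is not None and math.isfinite(f)


def gaussian_freq_window(
    rows_hi: int, rows_lo: int, params: InterpParams = InterpParams()
) -> np.ndarray:
    """1-D Gaussian gain over centered y-frequency index k (length rows_hi).

    ``w(k) = exp(-k^2 / (2 sigma^2))`` with sigma chosen so the gain is 0.5
    at ``f_c = window_half_gain_fraction * rows_lo / 2``; unit gain at DC.
    Index 0 of the returned array is the most negative frequency of the
    fftshift-centered spectrum.
    """
    if rows_lo < 2 or rows_hi < rows_lo:
        raise ValueError(f"require rows_hi >= rows_lo >= 2, got {rows_hi}, {rows_lo}")
    k = np.arange(rows_hi) - rows_hi // 2
    if not params.window_enabled:
        return np.ones(rows_hi)
    f_c = params.window_half_gain_fraction * rows_lo / 2.0
    sigma = f_c / math.sqrt(2.0 * math.log(2.0))
    return np.exp(-0.5 * (k / sigma) ** 2)


def fft_upsample_y(
    band_lo: np.ndarray, rows_hi: int, params: InterpParams = InterpParams()
) -> np.ndarray:
    """Upsample a ``(rows_lo, cols)`` image to ``(rows_hi, cols)`` along y.

    For even ``rows_lo`` the Nyquist bin is split half/half into the
    +/-Nyquist positions of the padded spectrum, so real inputs map to real
    outputs. Amplitude is rescaled by ``rows_hi / rows_lo`` (DC preserved).
    """
    band_lo = np.asarray(band_lo, dtype=float)
    if band_lo.ndim == 1:
        band_lo = band_lo[:, None]
    rows_lo = band_lo.shape[0]
    if rows_hi < rows_lo:
        raise ValueError(f"rows_hi={rows_hi} < rows_lo={rows_lo}: cannot downsample")

    spectrum = np.fft.fftshift(np.fft.fft(band_lo, axis=0), axes=0)
    padded = np.zeros((rows_hi, band_lo.shape[1]), dtype=complex)
    lo0 = rows_hi // 2 - rows_lo // 2  # centered placement: index = rows_hi//2 + k
    padded[lo0 : lo0 + rows_lo] = spectrum
    if rows_lo % 2 == 0 and rows_hi > rows_lo:
        # shifted index 0 holds the -Nyquist bin (k = -rows_lo/2)
        half = spectrum[0] / 2.0
        padded[lo0] = half
        padded[lo0 + rows_lo] = half

    padded *= gaussian_freq_window(rows_hi, rows_lo, params)[:, None]
    out = np.fft.ifft(np.fft.ifftshift(padded, axes=0), axis=0) * (rows_hi / rows_lo)
    scale = np.linalg.norm(out)
    if scale > 0 and np.linalg.norm(out.imag) > _IMAG_TOL * scale:
        raise AssertionError("inverse FFT produced non-negligible imaginary part")
    return out.real


def interpolate_cube(sparse: SparseCube, params: InterpParams = InterpParams()) -> HyperCube:
    """Upsample every sparse band to the reference band's grid.

    The reference band is copied through unchanged; the result is a dense
    cube with bands in ascending wavenumber order on the full-resolution
    pitch.
    """
    rows_hi = sparse.rows_hi
    cols = sparse.reference_band.shape[1]
    s = sparse.scheme.decimation_factor
    rows_lo = sparse.sparse_bands.shape[1]
    wavenumbers = sparse.all_wavenumbers
    data = np.empty((wavenumbers.size, rows_hi, cols))
    ref_wn = sparse.scheme.reference_wavenumber
    for b, wn in enumerate(wavenumbers):
        if wn == ref_wn:
            data[b] = sparse.reference_band
        else:
            src = sparse.sparse_bands[np.flatnonzero(sparse.sparse_wavenumbers == wn)[0]]
            # Upsample to s * rows_lo so output row r sits at sparse
            # coordinate r / s exactly, then crop the ceil-rule excess.
            data[b] = fft_upsample_y(src, s * rows_lo, params)[:rows_hi]
    return HyperCube(
        wavenumbers=wavenumbers, data=data, dx=sparse.dx, dy=sparse.scheme.dy_hi
    )
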