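"""Shared data model for hyperspectral cubes and sparse sampling schemes.

Conventions used throughout the package:

* images are addressed ``[row, col]``, 0-based, row-major, origin top-left;
* cubes are addressed ``[band, row, col]`` with bands in strictly ascending
  wavenumber order;
* the sparse (y-decimated) row ``i`` of a band corresponds to full-resolution
  row ``i * s`` where ``s = dy_lo / dy_hi`` is the decimation factor, with
  row 0 retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_WAVENUMBERS",
    "REFERENCE_WAVENUMBER",
    "HyperCube",
    "SamplingScheme",
    "SparseCube",
    "validate_cube",
    "extract_band",
]

#: Default acquisition band set: the 27 discrete-frequency bands in the
#: 902-1898 cm^-1 sweep plus the full-resolution Amide I reference at
#: 1660 cm^-1, for 28 bands total.
DEFAULT_WAVENUMBERS: tuple[float, ...] = (
    908.0, 974.0, 984.0, 1036.0, 1070.0, 1102.0, 1136.0, 1178.0, 1238.0,
    1280.0, 1300.0, 1325.0, 1358.0, 1396.0, 1420.0, 1456.0, 1482.0, 1500.0,
    1536.0, 1556.0, 1596.0, 1610.0, 1660.0, 1662.0, 1668.0, 1682.0, 1746.0,
    1786.0,
)

#: Amide I band (protein backbone absorbance); the full-resolution reference.
REFERENCE_WAVENUMBER: float = 1660.0

#: |absorbance| above this is reported as suspicious by validation.
_SUSPICIOUS_ABSORBANCE = 5.0


@dataclass
class HyperCube:
    """A dense hyperspectral band stack.

    Parameters
    ----------
    wavenumbers
        Band centers in cm^-1, strictly ascending; one per band plane.
    data
        Absorbance, indexed ``[band, row, col]``. Dimensionless; small
        negative values are permitted (noise).
    dx, dy
        Pixel pitch in micrometres along columns (x) and rows (y).
    """

    wavenumbers: np.ndarray
    data: np.ndarray
    dx: float = 0.5
    dy: float = 0.5

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        try:
            self.data = np.asarray(self.data, dtype=float)
        except (ValueError, TypeError):
            # Ragged band planes: keep as a list so validate_cube can report
            # the shape mismatch instead of raising here.
            self.data = [np.asarray(p, dtype=float) for p in self.data]

    @property
    def n_bands(self) -> int:
        return len(self.data)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of every band plane."""
        return self.data.shape[1], self.data.shape[2]

    def band_index(self, wavenumber: float) -> int:
        idx = np.flatnonzero(self.wavenumbers == wavenumber)
        if idx.size == 0:
            lo, hi = self.wavenumbers.min(), self.wavenumbers.max()
            raise KeyError(
                f"wavenumber {wavenumber} cm^-1 not in cube "
                f"(available: {self.n_bands} bands in [{lo}, {hi}] cm^-1)"
            )
        return int(idx[0])

    def band(self, wavenumber: float) -> np.ndarray:
        return self.data[self.band_index(wavenumber)]


@dataclass(frozen=True)
class SamplingScheme:
    """Sparse y-sampling scheme.

    ``dx_hi``/``dy_hi`` are the target full-resolution pitches; ``dy_lo`` is
    the sparse y pitch used for every band except the reference, which is
    acquired at full resolution.
    """

    dx_hi: float = 0.5
    dy_hi: float = 0.5
    dy_lo: float = 5.0
    reference_wavenumber: float = REFERENCE_WAVENUMBER

    def __post_init__(self) -> None:
        if not (self.dy_lo >= self.dy_hi > 0):
            raise ValueError(
                f"require dy_lo >= dy_hi > 0, got dy_lo={self.dy_lo}, dy_hi={self.dy_hi}"
            )
        ratio = self.dy_lo / self.dy_hi
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"dy_lo/dy_hi = {ratio} is not an integer decimation factor"
            )

    @property
    def decimation_factor(self) -> int:
        """s = dy_lo / dy_hi, the y-undersampling rate."""
        return int(round(self.dy_lo / self.dy_hi))


@dataclass
class SparseCube:
    """One full-resolution reference band plus y-decimated remaining bands.

    ``sparse_bands`` has shape ``[band, rows_lo, cols]`` with
    ``rows_lo = ceil(rows_hi / s)``; sparse row ``i`` is full-resolution row
    ``i * s``.
    """

    reference_band: np.ndarray
    sparse_bands: np.ndarray
    sparse_wavenumbers: np.ndarray
    scheme: SamplingScheme
    dx: float = 0.5

    def __post_init__(self) -> None:
        self.reference_band = np.asarray(self.reference_band, dtype=float)
        self.sparse_bands = np.asarray(self.sparse_bands, dtype=float)
        self.sparse_wavenumbers = np.asarray(self.sparse_wavenumbers, dtype=float)
        s = self.scheme.decimation_factor
        rows_hi = self.reference_band.shape[0]
        rows_lo = self.sparse_bands.shape[1]
        expected = math.ceil(rows_hi / s)
        if rows_lo != expected:
            raise ValueError(
                f"sparse bands have {rows_lo} rows; expected ceil({rows_hi}/{s}) = {expected}"
            )
        if self.sparse_bands.shape[2] != self.reference_band.shape[1]:
            raise ValueError("sparse bands and reference band disagree on column count")

    @property
    def rows_hi(self) -> int:
        return self.reference_band.shape[0]

    @property
    def all_wavenumbers(self) -> np.ndarray:
        """Sparse wavenumbers plus the reference, ascending."""
        return np.sort(
            np.append(self.sparse_wavenumbers, self.scheme.reference_wavenumber)
        )


def validate_cube(cube: HyperCube) -> list[str]:
    """Check every :class:`HyperCube` invariant; return one message per violation.

    Validation reports rather than raises: an empty list means the cube is
    well formed.
    """
    violations: list[str] = []
    wn = np.asarray(cube.wavenumbers, dtype=float)

    if isinstance(cube.data, list):
        # Ragged planes could not be stacked; report the offending bands and
        # check what else we can.
        planes = cube.data
        violations.extend(_validate_band_planes(planes, wn))
        if wn.size != len(planes):
            violations.append(
                f"wavenumber count {wn.size} does not match band count {len(planes)}"
            )
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            violations.append("wavenumbers are not strictly increasing")
        return violations

    data = np.asarray(cube.data)
    if data.ndim != 3:
        violations.append(f"data must be 3-D [band, row, col]; got ndim={data.ndim}")
        return violations
    if wn.ndim != 1 or wn.size != data.shape[0]:
        violations.append(
            f"wavenumber count {wn.size} does not match band count {data.shape[0]}"
        )
    if wn.size >= 2 and not np.all(np.diff(wn) > 0):
        violations.append(
            "wavenumbers are not strictly increasing: "
            + np.array2string(wn, max_line_width=200)
        )
    if not cube.dx > 0:
        violations.append(f"dx must be > 0, got {cube.dx}")
    if not cube.dy > 0:
        violations.append(f"dy must be > 0, got {cube.dy}")
    if not np.all(np.isfinite(data)):
        violations.append("data contains non-finite values")
    elif np.abs(data).max(initial=0.0) > _SUSPICIOUS_ABSORBANCE:
        violations.append(
            f"suspicious absorbance magnitude > {_SUSPICIOUS_ABSORBANCE}: "
            f"max |A| = {np.abs(data).max():.3g}"
        )
    return violations


def _validate_band_planes(planes: list[np.ndarray], wavenumbers) -> list[str]:
    """Validate a list of per-band planes that may disagree in shape.

    Used by readers before stacking into a cube array.
    """
    violations = []
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        for i, p in enumerate(planes):
            if p.shape != planes[0].shape:
                violations.append(
                    f"band {i} plane has shape {p.shape}, expected {planes[0].shape}"
                )
    return violations


def extract_band(cube: HyperCube, wavenumber: float) -> np.ndarray:
    """Return the 2-D plane of ``cube`` at ``wavenumber`` (exact match)."""
    return cube.band(wavenumber)
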