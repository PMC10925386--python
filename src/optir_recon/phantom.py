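"""Synthetic tissue-core phantoms and sparse-acquisition simulation.

A phantom emulates a tissue-microarray core imaged by discrete-frequency
mid-IR: piecewise-constant class regions (epithelium-, stroma- and
necrosis-like) with organic blob boundaries, a nonnegative absorbance
spectrum per class built from Gaussian peaks at biologically plausible
band positions, optical blur, and additive Gaussian noise. The same module
simulates the sparse interleaved acquisition: every band y-decimated except
one full-resolution reference band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DEFAULT_WAVENUMBERS, HyperCube, SamplingScheme, SparseCube

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_class_map",
    "generate_spectral_library",
    "render_hypercube",
    "make_phantom",
    "subsample_y",
    "sampling_fraction",
    "acquisition_time_estimate",
]

_MIN_CLASS_FRACTION = 0.02
_MAX_REGENERATION_ATTEMPTS = 10

#: Candidate absorbance peak centers (cm^-1): carbohydrate ~1036, nucleic
#: acid ~1080, amide III ~1240, COO-/CH ~1396, CH2 ~1456, amide II ~1545,
#: amide I ~1660, ester carbonyl ~1740.
_PEAK_POOL = (1036.0, 1080.0, 1240.0, 1396.0, 1456.0, 1545.0, 1660.0, 1740.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic core.

    ``boundary_smoothness`` is the correlation length (um) of the class
    regions; larger values give fewer, larger blobs. ``spatial_blur_sigma``
    (pixels) emulates optical blur, ``noise_sd`` additive detector noise in
    absorbance units. Generation is a pure function of the spec, seed
    included.
    """

    rows: int = 120
    cols: int = 120
    n_classes: int = 3
    wavenumbers: tuple[float, ...] = DEFAULT_WAVENUMBERS
    boundary_smoothness: float = 8.0
    spatial_blur_sigma: float = 1.0
    noise_sd: float = 0.01
    dx: float = 0.5
    dy: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 32 or self.cols < 32:
            raise ValueError(f"rows, cols must be >= 32, got {self.rows}x{self.cols}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: labels plus clean and noisy cubes."""

    label_map: np.ndarray
    clean_cube: HyperCube
    noisy_cube: HyperCube
    library: np.ndarray  # [class, band] spectra
    spec: PhantomSpec


def generate_class_map(spec: PhantomSpec) -> np.ndarray:
    """Blob-structured class labels via quantile-thresholded smoothed noise.

    Gaussian white noise is smoothed to the requested correlation length and
    cut at equally spaced quantiles, so each class occupies roughly 1/n of
    the area (never below 2%; degenerate draws are retried with a shifted
    seed, which keeps the map a pure function of the spec).
    """
    sigma_px = spec.boundary_smoothness / spec.dy
    for attempt in range(_MAX_REGENERATION_ATTEMPTS):
        rng = np.random.default_rng(spec.seed + 7919 * attempt)
        noise = rng.standard_normal((spec.rows, spec.cols))
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
        qs = np.quantile(smooth, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
        labels = np.digitize(smooth, qs)
        counts = np.bincount(labels.ravel(), minlength=spec.n_classes)
        if counts.min() >= _MIN_CLASS_FRACTION * labels.size:
            return labels
    raise RuntimeError(
        f"could not draw a class map with every class above "
        f"{_MIN_CLASS_FRACTION:.0%} in {_MAX_REGENERATION_ATTEMPTS} attempts"
    )


def _spectral_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosang = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def generate_spectral_library(
    spec: PhantomSpec, min_angle_deg: float = 5.0
) -> np.ndarray:
    """Per-class nonnegative spectra, shape ``[n_classes, n_bands]``.

    Each spectrum is a class-specific broad baseline (offset plus gentle
    slope, emulating the broad absorbance and scattering background that
    gives every chemically informative band some contrast between tissue
    types) plus 3-6 Gaussian peaks with class-specific centers, heights and
    widths; classes are redrawn until every pairwise spectral angle is at
    least ``min_angle_deg`` (separable classes). Deterministic under the
    spec seed.
    """
    wn = np.asarray(spec.wavenumbers, dtype=float)
    wn_span = max(wn.max() - wn.min(), 1.0)
    for attempt in range(_MAX_REGENERATION_ATTEMPTS):
        rng = np.random.default_rng(spec.seed + 104729 + 7919 * attempt)
        library = np.empty((spec.n_classes, wn.size))
        # Amide I (the reference band) separates tissue classes strongly in
        # practice — protein-dense epithelium, collagen stroma, degraded
        # necrosis — so its per-class heights are spread across a wide range
        # rather than drawn independently.
        amide_heights = rng.permutation(
            np.linspace(0.5, 1.2, spec.n_classes)
        ) + rng.uniform(-0.05, 0.05, size=spec.n_classes)
        for c in range(spec.n_classes):
            offset = rng.uniform(0.05, 0.2)
            slope = rng.uniform(-0.08, 0.08)
            baseline = offset + slope * (wn - wn.mean()) / wn_span
            # every tissue class absorbs strongly at amide I (the reference
            # band must carry the morphology); remaining peaks vary by class
            n_peaks = int(rng.integers(3, 7))
            others = rng.choice(
                [p for p in _PEAK_POOL if p != 1660.0], size=n_peaks - 1, replace=False
            )
            centers = np.concatenate([[1660.0], others]) + rng.uniform(
                -8.0, 8.0, size=n_peaks
            )
            heights = np.concatenate(
                [[amide_heights[c]], rng.uniform(0.2, 1.0, size=n_peaks - 1)]
            )
            widths = rng.uniform(15.0, 40.0, size=n_peaks)
            spectrum = np.maximum(baseline, 0.01) + np.sum(
                heights[:, None]
                * np.exp(-0.5 * ((wn[None, :] - centers[:, None]) / widths[:, None]) ** 2),
                axis=0,
            )
            library[c] = spectrum
        ok = all(
            _spectral_angle_deg(library[i], library[j]) >= min_angle_deg
            for i in range(spec.n_classes)
            for j in range(i + 1, spec.n_classes)
        )
        if ok:
            return library
    raise RuntimeError(
        f"could not draw {spec.n_classes} spectra with pairwise angle >= "
        f"{min_angle_deg} deg in {_MAX_REGENERATION_ATTEMPTS} attempts"
    )


def render_hypercube(
    label_map: np.ndarray, library: np.ndarray, spec: PhantomSpec
) -> PhantomTruth:
    """Render clean and noisy cubes from a label map and spectral library.

    The clean cube assigns each pixel its class spectrum, blurred in-plane by
    ``spatial_blur_sigma``; the noisy cube adds i.i.d. Gaussian noise of sd
    ``noise_sd`` (seeded).
    """
    if label_map.max() >= library.shape[0]:
        raise ValueError(
            f"label map has class {label_map.max()} but library covers "
            f"{library.shape[0]} classes"
        )
    wn = np.asarray(spec.wavenumbers, dtype=float)
    clean = library[label_map].transpose(2, 0, 1).astype(float)  # [band, row, col]
    if spec.spatial_blur_sigma > 0:
        clean = np.stack(
            [ndimage.gaussian_filter(p, spec.spatial_blur_sigma, mode="reflect") for p in clean]
        )
    rng = np.random.default_rng(spec.seed + 224737)
    if spec.noise_sd > 0:
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    else:
        noisy = clean.copy()
    clean_cube = HyperCube(wavenumbers=wn, data=clean, dx=spec.dx, dy=spec.dy)
    noisy_cube = HyperCube(wavenumbers=wn, data=noisy, dx=spec.dx, dy=spec.dy)
    return PhantomTruth(
        label_map=label_map, clean_cube=clean_cube, noisy_cube=noisy_cube,
        library=library, spec=spec,
    )


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Convenience: class map + spectral library + rendered cubes."""
    labels = generate_class_map(spec)
    library = generate_spectral_library(spec)
    return render_hypercube(labels, library, spec)


# ---------------------------------------------------------------------------
# sparse acquisition simulation


def subsample_y(cube: HyperCube, scheme: SamplingScheme) -> SparseCube:
    """Simulate sparse acquisition: keep rows {0, s, 2s, ...} of every band
    except the reference band, which stays at full resolution."""
    s = scheme.decimation_factor
    ref_idx = cube.band_index(scheme.reference_wavenumber)
    mask = np.ones(cube.n_bands, dtype=bool)
    mask[ref_idx] = False
    return SparseCube(
        reference_band=cube.data[ref_idx].copy(),
        sparse_bands=cube.data[mask, ::s, :].copy(),
        sparse_wavenumbers=cube.wavenumbers[mask].copy(),
        scheme=scheme,
        dx=cube.dx,
    )


def sampling_fraction(scheme: SamplingScheme) -> float:
    """Percent of pixels acquired relative to full resolution (x unchanged):
    ``100 * dy_hi / dy_lo``."""
    return 100.0 * scheme.dy_hi / scheme.dy_lo


def acquisition_time_estimate(
    scheme: SamplingScheme, n_bands: int, rows_hi: int, row_time: float
) -> float:
    """Linear acquisition-time model, in the units of ``row_time`` per
    full-resolution row: one band at full resolution plus ``n_bands - 1``
    decimated bands. Raster time scales with the number of y rows scanned;
    overheads (stage moves, laser tuning) are outside the model."""
    if row_time <= 0:
        raise ValueError(f"row_time must be > 0, got {row_time}")
    s = scheme.decimation_factor
    return row_time * (rows_hi + (n_bands - 1) * math.ceil(rows_hi / s))
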