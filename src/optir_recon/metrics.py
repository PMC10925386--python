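"""MSE/SSIM quality metrics and the pixel-spacing sweep experiment.

Per-band mean square error and structural similarity are computed between a
candidate cube (interpolated or fused) and the noiseless ground truth; the
sweep harness regenerates phantoms across replicates, reconstructs at each
y spacing and reports mean +/- sd of both metrics per method, mirroring the
spacing-vs-quality trade-off analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .core import HyperCube, SamplingScheme
from .fusion import FusionParams, reconstruct_cube
from .interp import InterpParams, interpolate_cube
from .io import ReportRow
from .phantom import PhantomSpec, make_phantom, subsample_y

__all__ = [
    "SSIMParams",
    "SweepResult",
    "mse",
    "ssim",
    "evaluate_reconstruction",
    "spacing_sweep",
]


@dataclass(frozen=True)
class SSIMParams:
    """Structural-similarity constants (Wang et al. defaults).

    ``dynamic_range = None`` means: take ``max - min`` of the truth band in
    :func:`evaluate_reconstruction`, or the joint range of both images in a
    bare :func:`ssim` call (which keeps the score symmetric).
    """

    window_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over pixels of the squared difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def ssim(a: np.ndarray, b: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Mean local SSIM with an 11x11 Gaussian window (sigma 1.5).

    Uses the standard stabilizers ``c1 = (k1 L)^2``, ``c2 = (k2 L)^2`` with
    ``L`` the dynamic range.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < params.window_size:
        raise ValueError(
            f"image {a.shape} smaller than the {params.window_size}-pixel window"
        )
    L = params.dynamic_range
    if L is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        L = float(hi - lo)
    if L == 0:
        # both images constant; identical iff equal
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(
        structural_similarity(
            a,
            b,
            win_size=params.window_size,
            gaussian_weights=True,
            sigma=params.sigma,
            K1=params.k1,
            K2=params.k2,
            use_sample_covariance=False,
            data_range=L,
        )
    )


def evaluate_reconstruction(
    truth: HyperCube, candidate: HyperCube, method: str = "fused",
    ssim_params: SSIMParams = SSIMParams(),
) -> tuple[list[ReportRow], dict]:
    """Per-band MSE/SSIM of ``candidate`` against ``truth``.

    The SSIM dynamic range is taken from the truth band (range inflation in
    the candidate cannot improve the score). Returns the band-level rows and
    a dict of unweighted band means.
    """
    if not np.array_equal(truth.wavenumbers, candidate.wavenumbers):
        raise ValueError("truth and candidate cubes list different wavenumbers")
    if truth.shape != candidate.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {candidate.shape}")
    rows = []
    for b, wn in enumerate(truth.wavenumbers):
        t = truth.data[b]
        c = candidate.data[b]
        p = replace(ssim_params, dynamic_range=float(t.max() - t.min()) or None)
        rows.append(ReportRow(float(wn), method, mse(t, c), ssim(t, c, p)))
    aggregate = {
        "mse": float(np.mean([r.mse for r in rows])),
        "ssim": float(np.mean([r.ssim for r in rows])),
    }
    return rows, aggregate


@dataclass
class SweepResult:
    """Long-format per-cell metrics and the mean +/- sd summary.

    ``table`` columns: replicate, spacing_um, wavenumber, method, mse, ssim.
    ``summary`` columns: spacing_um, method, mse_mean, mse_sd, ssim_mean,
    ssim_sd (sd across replicates of the per-replicate band means, n - 1
    denominator).
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    spacings: tuple[float, ...]
    n_replicates: int
    base_seed: int


def spacing_sweep(
    spec: PhantomSpec,
    spacings: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0),
    n_replicates: int = 4,
    base_seed: int = 0,
    interp_params: InterpParams = InterpParams(),
    fusion_params: FusionParams = FusionParams(),
    against: str = "clean",
) -> SweepResult:
    """MSE/SSIM versus y pixel spacing over replicate phantoms.

    For each replicate (seed ``base_seed + i``) and each spacing, a phantom
    is generated, y-decimated, interpolated and fused, and both
    reconstructions are scored per band against the clean (default) or
    noisy ground truth.
    """
    for sp in spacings:
        ratio = sp / spec.dy
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"spacing {sp} um is not an integer multiple of dy_hi = {spec.dy} um"
            )
    if against not in ("clean", "noisy"):
        raise ValueError(f"against must be clean|noisy, got {against!r}")
    records = []
    for i in range(n_replicates):
        truth = make_phantom(replace(spec, seed=base_seed + i))
        target = truth.clean_cube if against == "clean" else truth.noisy_cube
        for sp in spacings:
            scheme = SamplingScheme(dx_hi=spec.dx, dy_hi=spec.dy, dy_lo=sp)
            sparse = subsample_y(truth.noisy_cube, scheme)
            interp = interpolate_cube(sparse, interp_params)
            fused = reconstruct_cube(sparse, fusion_params, interp_params).cube
            for method, cand in (("interpolated", interp), ("fused", fused)):
                rows, _ = evaluate_reconstruction(target, cand, method)
                for r in rows:
                    records.append(
                        {
                            "replicate": i,
                            "spacing_um": sp,
                            "wavenumber": r.wavenumber,
                            "method": method,
                            "mse": r.mse,
                            "ssim": r.ssim,
                        }
                    )
    table = pd.DataFrame.from_records(records)
    per_rep = (
        table.groupby(["spacing_um", "method", "replicate"])[["mse", "ssim"]]
        .mean()
        .reset_index()
    )
    summary = (
        per_rep.groupby(["spacing_um", "method"])
        .agg(
            mse_mean=("mse", "mean"),
            mse_sd=("mse", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            ssim_mean=("ssim", "mean"),
            ssim_sd=("ssim", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
        )
        .reset_index()
    )
    return SweepResult(
        table=table, summary=summary, spacings=tuple(spacings),
        n_replicates=n_replicates, base_seed=base_seed,
    )
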