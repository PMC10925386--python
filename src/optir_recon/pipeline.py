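"""End-to-end pipeline: phantom -> subsample -> reconstruct -> evaluate -> segment.

A single JSON-serializable :class:`RunConfig` drives the whole chain. One
global seed expands deterministically into per-stage seeds (stable stage-name
hashing), so an identical config always reproduces byte-identical artifacts
and any stage can be rerun in isolation with its own seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from . import io as io_formats
from .core import SamplingScheme
from .curvelet import CurveletParams
from .fusion import FusionParams, reconstruct_cube
from .interp import InterpParams, interpolate_cube
from .metrics import SSIMParams, evaluate_reconstruction, spacing_sweep
from .phantom import PhantomSpec, make_phantom, subsample_y
from .segmentation import (
    ClassifierParams,
    column_split_masks,
    evaluate_segmentation,
    predict_map,
    render_rgb,
    sample_training_pixels,
    train_pixel_classifier,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("optir_recon")


@dataclass(frozen=True)
class SegmentationConfig:
    per_class: int = 1000
    classifier: ClassifierParams = field(default_factory=ClassifierParams)


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    scheme: SamplingScheme = field(default_factory=SamplingScheme)
    interp: InterpParams = field(default_factory=InterpParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    ssim: SSIMParams = field(default_factory=SSIMParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    sweep_spacings: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0)
    sweep_replicates: int = 2
    run_sweep: bool = True
    format: str = "envi"
    seed: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        text = str(source)
        if isinstance(source, Path) or not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        return _from_dict(cls, payload)


def _jsonify(obj):
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _from_dict(cls, payload: dict):
    """Rebuild nested (frozen) dataclasses from a plain dict; unknown keys
    are rejected so typos in config files fail loudly."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in payload.items():
        ftype = fields[name].type
        nested = {
            "PhantomSpec": PhantomSpec,
            "SamplingScheme": SamplingScheme,
            "InterpParams": InterpParams,
            "FusionParams": FusionParams,
            "SSIMParams": SSIMParams,
            "SegmentationConfig": SegmentationConfig,
            "ClassifierParams": ClassifierParams,
            "CurveletParams": CurveletParams,
        }
        base = str(ftype).split(".")[-1].strip("'\" ]")
        if isinstance(value, dict) and base in nested:
            kwargs[name] = _from_dict(nested[base], value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full chain and write all artifacts under ``outdir``.

    Returns the manifest: config, stage log, and a file -> sha256 map.
    Identical configs produce identical checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = config.format
    ext = ".hdr" if fmt == "envi" else ".tiff"
    stages: list[dict] = []

    def stage(name: str, **params):
        t0 = time.perf_counter()
        stages.append({"stage": name, "params": params, "start": len(stages)})
        log.info("stage %s %s", name, params)
        return t0

    def done(t0):
        stages[-1]["seconds"] = round(time.perf_counter() - t0, 3)

    # --- phantom -----------------------------------------------------------
    phantom_spec = replace(config.phantom, seed=stage_seed(config.seed, "phantom"))
    t0 = stage("phantom", spec=asdict(phantom_spec))
    truth = make_phantom(phantom_spec)
    io_formats.write_cube(truth.clean_cube, outdir / f"truth_clean{ext}", fmt)
    io_formats.write_cube(truth.noisy_cube, outdir / f"truth_noisy{ext}", fmt)
    io_formats.write_label_map(truth.label_map, outdir / "labels.tiff")
    done(t0)

    # --- subsample ---------------------------------------------------------
    t0 = stage("subsample", scheme=asdict(config.scheme))
    sparse = subsample_y(truth.noisy_cube, config.scheme)
    done(t0)

    # --- interpolate + reconstruct ----------------------------------------
    t0 = stage("interpolate", params=asdict(config.interp))
    interp = interpolate_cube(sparse, config.interp)
    io_formats.write_cube(interp, outdir / f"interpolated{ext}", fmt)
    done(t0)

    t0 = stage("reconstruct", params=asdict(config.fusion))
    result = reconstruct_cube(sparse, config.fusion, config.interp)
    io_formats.write_cube(result.cube, outdir / f"reconstructed{ext}", fmt)
    result.equalization.to_csv(outdir / "equalization.csv", index=False, float_format="%.9g")
    done(t0)

    # --- evaluate ----------------------------------------------------------
    t0 = stage("evaluate")
    rows_i, agg_i = evaluate_reconstruction(truth.clean_cube, interp, "interpolated", config.ssim)
    rows_f, agg_f = evaluate_reconstruction(truth.clean_cube, result.cube, "fused", config.ssim)
    io_formats.write_report(rows_i + rows_f, outdir / "report.csv")
    done(t0)

    # --- sweep -------------------------------------------------------------
    if config.run_sweep:
        t0 = stage(
            "sweep", spacings=list(config.sweep_spacings), replicates=config.sweep_replicates
        )
        sweep = spacing_sweep(
            config.phantom,
            spacings=config.sweep_spacings,
            n_replicates=config.sweep_replicates,
            base_seed=stage_seed(config.seed, "sweep"),
            interp_params=config.interp,
            fusion_params=config.fusion,
        )
        sweep.table.to_csv(outdir / "sweep_long.csv", index=False, float_format="%.9g")
        sweep.summary.to_csv(outdir / "sweep_summary.csv", index=False, float_format="%.9g")
        done(t0)

    # --- segmentation ------------------------------------------------------
    t0 = stage("segment", per_class=config.segmentation.per_class)
    train_mask, test_mask = column_split_masks(result.cube.shape)
    ref_wn = config.scheme.reference_wavenumber
    train = sample_training_pixels(
        result.cube,
        truth.label_map,
        per_class=config.segmentation.per_class,
        seed=stage_seed(config.seed, "segment"),
        mask=train_mask,
        reference_wavenumber=ref_wn,
    )
    clf_params = replace(
        config.segmentation.classifier, seed=stage_seed(config.seed, "classifier")
    )
    model = train_pixel_classifier(train, clf_params)
    pred_map, proba = predict_map(model, result.cube, ref_wn)
    report = evaluate_segmentation(
        pred_map[test_mask], truth.label_map[test_mask],
        probabilities=proba[:, test_mask].T,  # [n_pixels, n_classes]
    )
    seg_payload = {
        "per_class_accuracy": report.per_class_accuracy,
        "overall_accuracy": report.overall_accuracy,
        "pixel_accuracy": report.pixel_accuracy,
        "per_class_auc": report.per_class_auc,
        "confusion": report.confusion.tolist(),
        "support": report.support.tolist(),
    }
    (outdir / "segmentation.json").write_text(json.dumps(seg_payload, indent=1))
    import tifffile

    tifffile.imwrite(outdir / "prediction_rgb.tiff", render_rgb(pred_map))
    done(t0)

    # --- manifest ----------------------------------------------------------
    files = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": json.loads(config.to_json()),
        "stages": stages,
        "checksums": {p.name: _checksum(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
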