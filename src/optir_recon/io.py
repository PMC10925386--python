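"""Read/write hyperspectral cubes, label maps, and quality reports.

Cubes are stored either as an ENVI pair (plain-text ``.hdr`` plus a BSQ
32-bit little-endian float binary) or as a multi-page TIFF with one page per
band and a JSON sidecar carrying the wavenumbers and pixel pitch. Label maps
are single-page integer TIFFs with a JSON sidecar mapping class index to
name and RGB color. Reports are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import HyperCube, validate_cube

__all__ = [
    "ReportRow",
    "read_cube",
    "write_cube",
    "read_label_map",
    "write_label_map",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class ReportRow:
    """One band-level quality measurement."""

    wavenumber: float
    method: str  # "interpolated" | "fused"
    mse: float
    ssim: float

    def __post_init__(self) -> None:
        if self.method not in ("interpolated", "fused"):
            raise ValueError(f"method must be interpolated|fused, got {self.method!r}")
        if self.mse < 0:
            raise ValueError(f"mse must be >= 0, got {self.mse}")
        if not -1.0 - 1e-9 <= self.ssim <= 1.0 + 1e-9:
            raise ValueError(f"ssim must be in [-1, 1], got {self.ssim}")


# ---------------------------------------------------------------------------
# cubes


def _sort_bands(wavenumbers: np.ndarray, data: np.ndarray):
    order = np.argsort(wavenumbers)
    return wavenumbers[order], data[order]


def write_cube(cube: HyperCube, path, format: str = "envi") -> None:
    """Write ``cube`` to ``path`` as ENVI (``.hdr`` + binary) or multi-page TIFF.

    Values are stored as 32-bit floats; ``read_cube`` round-trips them
    exactly at that precision, including wavenumbers and pixel pitch.
    """
    problems = validate_cube(cube)
    if problems:
        raise ValueError("refusing to write invalid cube: " + "; ".join(problems))
    path = Path(path)
    if format == "envi":
        _write_envi(cube, path)
    elif format == "tiff":
        _write_tiff_cube(cube, path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'envi' or 'tiff'")


def read_cube(path, format: str | None = None) -> HyperCube:
    """Read a cube written by :func:`write_cube`.

    ``format`` is inferred from the suffix when omitted. Bands are reordered
    to ascending wavenumber if the file stores them otherwise.
    """
    path = Path(path)
    if format is None:
        format = "envi" if path.suffix.lower() in (".hdr", ".dat", "") else "tiff"
    if format == "envi":
        cube = _read_envi(path)
    elif format == "tiff":
        cube = _read_tiff_cube(path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'envi' or 'tiff'")
    problems = validate_cube(cube)
    if problems:
        raise ValueError(f"file {path} does not contain a valid cube: " + "; ".join(problems))
    return cube


def _envi_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix.lower() == ".hdr":
        return path, path.with_suffix(".dat")
    if path.suffix.lower() == ".dat":
        return path.with_suffix(".hdr"), path
    return path.with_suffix(".hdr"), path.with_suffix(".dat")


def _write_envi(cube: HyperCube, path: Path) -> None:
    hdr_path, dat_path = _envi_paths(path)
    rows, cols = cube.shape
    wn = ", ".join(repr(float(w)) for w in cube.wavenumbers)
    hdr = (
        "ENVI\n"
        "description = {optir-recon hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = cm-1\n"
        f"pixel size = {{{cube.dx!r}, {cube.dy!r}}}\n"
        f"wavelength = {{{wn}}}\n"
    )
    hdr_path.write_text(hdr)
    np.asarray(cube.data, dtype="<f4").tofile(dat_path)


def _parse_envi_header(text: str) -> dict:
    """Parse 'key = value' ENVI header lines; brace lists become lists."""
    fields: dict[str, object] = {}
    # join continuation lines of brace lists
    body = text.replace("\n", " \n")
    tokens = body.split("\n")
    buf = ""
    for tok in tokens:
        buf += tok
        if buf.count("{") == buf.count("}"):
            line = buf.strip()
            buf = ""
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if value.startswith("{") and value.endswith("}"):
                items = [v.strip() for v in value[1:-1].split(",") if v.strip()]
                fields[key] = items
            else:
                fields[key] = value
    return fields


def _read_envi(path: Path) -> HyperCube:
    hdr_path, dat_path = _envi_paths(path)
    fields = _parse_envi_header(hdr_path.read_text())
    if "wavelength" not in fields:
        raise ValueError(f"{hdr_path}: missing 'wavelength' metadata")
    wavenumbers = np.array([float(v) for v in fields["wavelength"]])
    rows = int(str(fields["lines"]))
    cols = int(str(fields["samples"]))
    n_bands = int(str(fields["bands"]))
    if str(fields.get("interleave", "bsq")).lower() != "bsq":
        raise ValueError(f"{hdr_path}: only BSQ interleave is supported")
    if int(str(fields.get("data type", 4))) != 4:
        raise ValueError(f"{hdr_path}: only data type 4 (float32) is supported")
    dx = dy = 0.5
    if "pixel size" in fields:
        dx, dy = (float(v) for v in fields["pixel size"])
    data = np.fromfile(dat_path, dtype="<f4")
    if data.size != n_bands * rows * cols:
        raise ValueError(
            f"{dat_path}: expected {n_bands * rows * cols} float32 values, got {data.size}"
        )
    data = data.reshape(n_bands, rows, cols).astype(float)
    wavenumbers, data = _sort_bands(wavenumbers, data)
    return HyperCube(wavenumbers=wavenumbers, data=data, dx=dx, dy=dy)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_tiff_cube(cube: HyperCube, path: Path) -> None:
    tifffile.imwrite(
        path, np.asarray(cube.data, dtype=np.float32), photometric="minisblack"
    )
    meta = {
        "wavenumbers": [float(w) for w in cube.wavenumbers],
        "dx": float(cube.dx),
        "dy": float(cube.dy),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def _read_tiff_cube(path: Path) -> HyperCube:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ValueError(f"missing wavenumber sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    wavenumbers = np.asarray(meta["wavenumbers"], dtype=float)
    if wavenumbers.size != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} pages but {wavenumbers.size} listed wavenumbers"
        )
    wavenumbers, data = _sort_bands(wavenumbers, data)
    return HyperCube(
        wavenumbers=wavenumbers, data=data,
        dx=float(meta.get("dx", 0.5)), dy=float(meta.get("dy", 0.5)),
    )


# ---------------------------------------------------------------------------
# label maps

#: Fig-style channel convention: red=epithelium, green=stroma, blue=necrosis.
DEFAULT_CLASS_META = {
    0: {"name": "epithelium", "rgb": [255, 0, 0]},
    1: {"name": "stroma", "rgb": [0, 255, 0]},
    2: {"name": "necrosis", "rgb": [0, 0, 255]},
}


def write_label_map(label_map: np.ndarray, path, class_meta: dict | None = None) -> None:
    """Single-page integer TIFF plus JSON sidecar (index -> name -> RGB)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(label_map, dtype=np.int32), photometric="minisblack")
    meta = class_meta or {
        int(k): DEFAULT_CLASS_META.get(int(k), {"name": f"class{k}", "rgb": [128, 128, 128]})
        for k in np.unique(label_map)
    }
    _sidecar(path).write_text(json.dumps({str(k): v for k, v in meta.items()}, indent=1))


def read_label_map(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    labels = tifffile.imread(path).astype(int)
    meta = {}
    if _sidecar(path).exists():
        meta = {int(k): v for k, v in json.loads(_sidecar(path).read_text()).items()}
    return labels, meta


# ---------------------------------------------------------------------------
# reports


def write_report(rows, path) -> None:
    """CSV with header ``wavenumber,method,mse,ssim``; >= 6 significant digits."""
    records = [
        (r.wavenumber, r.method, r.mse, r.ssim) if isinstance(r, ReportRow) else tuple(r)
        for r in rows
    ]
    df = pd.DataFrame(records, columns=["wavenumber", "method", "mse", "ssim"])
    df.to_csv(path, index=False, float_format="%.9g")


def read_report(path) -> list[ReportRow]:
    df = pd.read_csv(path)
    return [
        ReportRow(float(r.wavenumber), str(r.method), float(r.mse), float(r.ssim))
        for r in df.itertuples()
    ]
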