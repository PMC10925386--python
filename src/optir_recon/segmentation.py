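"""Pixel-wise tissue-subtype classification harness.

Checks that reconstruction preserves class-discriminative chemistry: pixels
are sampled class-balanced from a labeled cube, a random-forest classifier
is trained on their band spectra (all non-reference bands), and performance
is reported as per-class accuracy, overall accuracy, one-vs-rest ROC/AUC
and a confusion matrix. A red/green/blue rendering maps the three tissue
classes (epithelium/stroma/necrosis) for visual inspection.

Any external patch classifier exposing ``predict_proba`` over per-pixel
spectra can be plugged into :func:`predict_map` in place of the built-in
forest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .core import REFERENCE_WAVENUMBER, HyperCube

__all__ = [
    "PixelDataset",
    "EvalReport",
    "ClassifierParams",
    "sample_training_pixels",
    "train_pixel_classifier",
    "predict_map",
    "evaluate_segmentation",
    "render_rgb",
    "rgb_to_labels",
    "column_split_masks",
]

#: Channel convention: red=epithelium (0), green=stroma (1), blue=necrosis (2).
DEFAULT_PALETTE = ((255, 0, 0), (0, 255, 0), (0, 0, 255))


@dataclass
class PixelDataset:
    """Per-pixel spectra with labels and (row, col) provenance."""

    spectra: np.ndarray  # [n_pixels, n_bands]
    labels: np.ndarray  # [n_pixels]
    provenance: np.ndarray  # [n_pixels, 2] (row, col)

    def __post_init__(self) -> None:
        if self.spectra.shape[0] != self.labels.shape[0]:
            raise ValueError("spectra and labels disagree on pixel count")


@dataclass
class EvalReport:
    """Segmentation performance summary.

    ``per_class_accuracy`` is the per-class recall in percent;
    ``overall_accuracy`` the support-weighted mean of those recalls (which
    equals the raw pixel-match fraction); ``per_class_auc`` the one-vs-rest
    ROC area (``None`` where a class is absent from the truth).
    """

    per_class_accuracy: dict[int, float]
    overall_accuracy: float
    pixel_accuracy: float
    per_class_auc: dict[int, float | None]
    confusion: np.ndarray
    support: np.ndarray


@dataclass(frozen=True)
class ClassifierParams:
    """Random-forest defaults: 100 trees, unlimited depth, sqrt features."""

    n_estimators: int = 100
    max_depth: int | None = None
    max_features: str = "sqrt"
    seed: int = 0


def _feature_bands(cube: HyperCube, reference_wavenumber: float | None) -> np.ndarray:
    """Indices of the bands used as features (reference band excluded)."""
    idx = np.arange(cube.n_bands)
    if reference_wavenumber is not None and np.any(
        cube.wavenumbers == reference_wavenumber
    ):
        idx = idx[cube.wavenumbers != reference_wavenumber]
    return idx


def sample_training_pixels(
    cube: HyperCube,
    label_map: np.ndarray,
    per_class: int,
    seed: int = 0,
    mask: np.ndarray | None = None,
    reference_wavenumber: float | None = REFERENCE_WAVENUMBER,
) -> PixelDataset:
    """Class-balanced pixel sampling without replacement.

    Exactly ``per_class`` pixels are drawn from each class (preventing class
    bias in training); the feature vector is the spectrum over all
    non-reference bands. ``mask`` restricts the candidate pixels (e.g. to
    one half of the core).
    """
    label_map = np.asarray(label_map)
    if label_map.shape != cube.shape:
        raise ValueError(f"label map {label_map.shape} does not match cube {cube.shape}")
    if mask is None:
        mask = np.ones_like(label_map, dtype=bool)
    rng = np.random.default_rng(seed)
    bands = _feature_bands(cube, reference_wavenumber)
    classes = np.unique(label_map[mask])
    rows_all, cols_all, labels_all = [], [], []
    for c in classes:
        r, cc = np.nonzero((label_map == c) & mask)
        if r.size < per_class:
            raise ValueError(
                f"class {c} has only {r.size} pixels available; requested {per_class}"
            )
        pick = rng.choice(r.size, size=per_class, replace=False)
        rows_all.append(r[pick])
        cols_all.append(cc[pick])
        labels_all.append(np.full(per_class, c))
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    labels = np.concatenate(labels_all)
    spectra = cube.data[bands][:, rows, cols].T
    return PixelDataset(
        spectra=spectra, labels=labels, provenance=np.column_stack([rows, cols])
    )


def train_pixel_classifier(
    train: PixelDataset, params: ClassifierParams = ClassifierParams()
) -> RandomForestClassifier:
    """Fit the decision-tree ensemble on per-pixel spectra (seeded)."""
    if np.unique(train.labels).size < 2:
        raise ValueError("training data contains a single class; need >= 2")
    model = RandomForestClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        max_features=params.max_features,
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(train.spectra, train.labels)
    return model


def predict_map(
    model,
    cube: HyperCube,
    reference_wavenumber: float | None = REFERENCE_WAVENUMBER,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel class map and probability planes for a whole cube.

    ``model`` is any classifier with ``predict_proba`` over the same feature
    bands used in training. Returns ``(label_map, probabilities)`` with
    probabilities shaped ``[class, row, col]``; the argmax tie-breaks toward
    the lower class index.
    """
    bands = _feature_bands(cube, reference_wavenumber)
    rows, cols = cube.shape
    X = cube.data[bands].reshape(bands.size, -1).T
    n_features = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_features:
        raise ValueError(
            f"cube provides {X.shape[1]} feature bands but the model expects {n_features}"
        )
    proba = model.predict_proba(X)  # [pixel, class]
    labels = np.argmax(proba, axis=1)  # argmax ties -> lower index
    class_ids = getattr(model, "classes_", np.arange(proba.shape[1]))
    label_map = np.asarray(class_ids)[labels].reshape(rows, cols)
    planes = proba.T.reshape(proba.shape[1], rows, cols)
    return label_map, planes


def evaluate_segmentation(
    pred: np.ndarray,
    truth: np.ndarray,
    probabilities: np.ndarray | None = None,
    n_classes: int | None = None,
) -> EvalReport:
    """Accuracy, one-vs-rest AUC and confusion matrix of a predicted map.

    Per-class accuracy is the recall of that class (percent); overall
    accuracy is the support-weighted mean of per-class accuracies, which
    coincides with the raw pixel-match fraction (both reported). AUC uses
    trapezoidal integration of the one-vs-rest ROC and is ``None`` for a
    class absent from the truth.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth differ in size")
    if n_classes is None:
        n_classes = int(max(pred.max(), truth.max())) + 1
    labels = np.arange(n_classes)
    confusion = _sk_confusion(truth, pred, labels=labels)
    support = confusion.sum(axis=1)
    per_class = {
        int(c): (100.0 * confusion[c, c] / support[c]) if support[c] else float("nan")
        for c in labels
    }
    present = support > 0
    overall = float(
        np.sum([per_class[int(c)] * support[c] for c in labels[present]])
        / support[present].sum()
    )
    pixel_accuracy = 100.0 * float(np.mean(pred == truth))
    auc: dict[int, float | None] = {}
    for c in labels:
        if probabilities is None or support[c] == 0 or support[c] == truth.size:
            auc[int(c)] = None
            continue
        p = np.asarray(probabilities)
        scores = p[c].ravel() if p.ndim == 3 else p[:, c]
        auc[int(c)] = float(roc_auc_score((truth == c).astype(int), scores))
    return EvalReport(
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        pixel_accuracy=pixel_accuracy,
        per_class_auc=auc,
        confusion=confusion,
        support=support,
    )


def render_rgb(label_map: np.ndarray, palette=DEFAULT_PALETTE) -> np.ndarray:
    """Map class indices to pure channel colors (uint8 RGB image)."""
    label_map = np.asarray(label_map)
    n = int(label_map.max()) + 1
    if n > len(palette):
        raise ValueError(
            f"label map has {n} classes but the palette covers {len(palette)}"
        )
    lut = np.asarray(palette, dtype=np.uint8)
    return lut[label_map]


def rgb_to_labels(rgb: np.ndarray, palette=DEFAULT_PALETTE) -> np.ndarray:
    """Inverse of :func:`render_rgb` for images made of exact palette colors."""
    rgb = np.asarray(rgb)
    lut = np.asarray(palette, dtype=np.uint8)
    out = np.full(rgb.shape[:2], -1, dtype=int)
    for i, color in enumerate(lut):
        out[np.all(rgb == color, axis=-1)] = i
    if (out < 0).any():
        raise ValueError("image contains colors outside the palette")
    return out


def column_split_masks(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(train, test) boolean masks splitting an image at the column midline:
    right half for training, left half held out for testing."""
    rows, cols = shape
    train = np.zeros((rows, cols), dtype=bool)
    train[:, cols // 2 :] = True
    return train, ~train
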