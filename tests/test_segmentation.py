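import numpy as np
import pytest

from optir_recon import HyperCube
from optir_recon.segmentation import (
    ClassifierParams,
    PixelDataset,
    column_split_masks,
    evaluate_segmentation,
    predict_map,
    render_rgb,
    rgb_to_labels,
    sample_training_pixels,
    train_pixel_classifier,
)


@pytest.fixture
def labeled_cube(default_truth):
    return default_truth.noisy_cube, default_truth.label_map


class TestSampling:
    def test_exact_class_balance(self, labeled_cube):
        cube, labels = labeled_cube
        ds = sample_training_pixels(cube, labels, per_class=10, seed=0)
        assert ds.spectra.shape == (30, 27)  # reference band excluded
        assert np.bincount(ds.labels).tolist() == [10, 10, 10]

    def test_seeded_selection_is_reproducible(self, labeled_cube):
        cube, labels = labeled_cube
        a = sample_training_pixels(cube, labels, 25, seed=4)
        b = sample_training_pixels(cube, labels, 25, seed=4)
        assert np.array_equal(a.provenance, b.provenance)

    def test_sampling_without_replacement(self, labeled_cube):
        cube, labels = labeled_cube
        ds = sample_training_pixels(cube, labels, 200, seed=1)
        assert len({tuple(p) for p in ds.provenance}) == len(ds.provenance)

    def test_oversized_request_names_class(self, labeled_cube):
        cube, labels = labeled_cube
        smallest = int(np.argmin(np.bincount(labels.ravel())))
        with pytest.raises(ValueError, match=f"class {smallest}"):
            sample_training_pixels(cube, labels, labels.size, seed=0)

    def test_spectra_match_cube_values(self, labeled_cube):
        cube, labels = labeled_cube
        ds = sample_training_pixels(cube, labels, 5, seed=2)
        bands = cube.wavenumbers != 1660.0
        r, c = ds.provenance[0]
        assert np.array_equal(ds.spectra[0], cube.data[bands, r, c])


class TestClassifier:
    def _separable(self, n=60):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.05, (n, 5))
        y = np.repeat([0, 1], n // 2)
        X[y == 1] += 1.0
        return PixelDataset(X, y, np.zeros((n, 2), dtype=int))

    def test_separable_data_trains_to_perfect_accuracy(self):
        ds = self._separable()
        model = train_pixel_classifier(ds)
        assert (model.predict(ds.spectra) == ds.labels).all()

    def test_single_class_rejected(self):
        ds = PixelDataset(np.zeros((5, 3)), np.zeros(5, dtype=int), np.zeros((5, 2)))
        with pytest.raises(ValueError, match="single class"):
            train_pixel_classifier(ds)

    def test_seeded_training_is_deterministic(self, labeled_cube):
        cube, labels = labeled_cube
        ds = sample_training_pixels(cube, labels, 50, seed=3)
        m1 = train_pixel_classifier(ds, ClassifierParams(seed=7))
        m2 = train_pixel_classifier(ds, ClassifierParams(seed=7))
        p1, _ = predict_map(m1, cube)
        p2, _ = predict_map(m2, cube)
        assert np.array_equal(p1, p2)

    def test_permuted_labels_give_chance_accuracy(self, labeled_cube):
        """Destroying the spectrum-label link drops held-out accuracy to
        ~1/n_classes."""
        cube, labels = labeled_cube
        train_mask, test_mask = column_split_masks(cube.shape)
        ds = sample_training_pixels(cube, labels, 300, seed=5, mask=train_mask)
        rng = np.random.default_rng(11)
        permuted = PixelDataset(ds.spectra, rng.permutation(ds.labels), ds.provenance)
        model = train_pixel_classifier(permuted, ClassifierParams(seed=5))
        pred, _ = predict_map(model, cube)
        acc = np.mean(pred[test_mask] == labels[test_mask])
        assert abs(acc - 1 / 3) < 0.10


class TestPredictMap:
    def test_probability_planes_normalized(self, labeled_cube):
        cube, labels = labeled_cube
        ds = sample_training_pixels(cube, labels, 50, seed=0)
        model = train_pixel_classifier(ds)
        pred, proba = predict_map(model, cube)
        assert pred.shape == cube.shape
        assert proba.shape == (3,) + cube.shape
        assert np.abs(proba.sum(axis=0) - 1.0).max() < 1e-6

    def test_band_count_mismatch_rejected(self, labeled_cube):
        cube, labels = labeled_cube
        ds = sample_training_pixels(cube, labels, 20, seed=0)
        model = train_pixel_classifier(ds)
        small = HyperCube(
            wavenumbers=cube.wavenumbers[:5], data=cube.data[:5],
            dx=cube.dx, dy=cube.dy,
        )
        with pytest.raises(ValueError, match="feature bands"):
            predict_map(model, small)


class TestEvaluateSegmentation:
    def test_perfect_prediction(self):
        truth = np.random.default_rng(0).integers(0, 3, size=(20, 20))
        proba = np.zeros((3,) + truth.shape)
        for c in range(3):
            proba[c][truth == c] = 1.0
        rep = evaluate_segmentation(truth, truth, probabilities=proba)
        assert rep.overall_accuracy == 100.0
        assert all(v == 100.0 for v in rep.per_class_accuracy.values())
        assert all(v == pytest.approx(1.0) for v in rep.per_class_auc.values())

    def test_hand_computed_two_class_confusion(self):
        """TP=3, FN=1, TN=4, FP=0 -> class accuracies 75% and 100%, OA 87.5%."""
        truth = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pred = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        rep = evaluate_segmentation(pred, truth)
        assert rep.per_class_accuracy[0] == 75.0
        assert rep.per_class_accuracy[1] == 100.0
        assert rep.overall_accuracy == 87.5
        assert rep.overall_accuracy == rep.pixel_accuracy
        assert rep.confusion.tolist() == [[3, 1], [0, 4]]

    def test_random_probabilities_give_chance_auc(self):
        rng = np.random.default_rng(1)
        n = 20000
        truth = rng.integers(0, 2, size=n)
        proba = rng.random((n, 2))
        rep = evaluate_segmentation(rng.integers(0, 2, size=n), truth, probabilities=proba)
        assert rep.per_class_auc[0] == pytest.approx(0.5, abs=0.05)

    def test_absent_class_reports_missing_auc(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 0, 1, 2])
        proba = np.full((4, 3), 1 / 3)
        rep = evaluate_segmentation(pred, truth, probabilities=proba, n_classes=3)
        assert rep.per_class_auc[2] is None

    def test_overall_accuracy_equals_pixel_match_fraction(self, labeled_cube):
        cube, labels = labeled_cube
        rng = np.random.default_rng(2)
        pred = np.where(rng.random(labels.shape) < 0.8, labels, (labels + 1) % 3)
        rep = evaluate_segmentation(pred, labels)
        assert rep.overall_accuracy == pytest.approx(rep.pixel_accuracy)


class TestRendering:
    def test_single_class_map_is_all_red(self):
        rgb = render_rgb(np.zeros((4, 4), dtype=int))
        assert np.array_equal(rgb[..., 0], np.full((4, 4), 255))
        assert rgb[..., 1:].max() == 0

    def test_checkerboard_channel_assignment(self):
        labels = np.indices((6, 6)).sum(axis=0) % 3
        rgb = render_rgb(labels)
        for c in range(3):
            assert np.all(rgb[labels == c, c] == 255)

    def test_palette_round_trip(self):
        labels = np.random.default_rng(0).integers(0, 3, size=(10, 10))
        assert np.array_equal(rgb_to_labels(render_rgb(labels)), labels)
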