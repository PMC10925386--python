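"""Does reconstruction preserve class-discriminative chemistry?

Trains a random forest on class-balanced pixel spectra from the right half
of a reconstructed (s=10) phantom and scores it on the held-out left half:
high overall accuracy means the fused cube still separates the tissue
classes pixel by pixel.
"""

import numpy as np

from optir_recon import (
    PhantomSpec,
    SamplingScheme,
    make_phantom,
    reconstruct_cube,
    subsample_y,
)
from optir_recon.segmentation import (
    ClassifierParams,
    column_split_masks,
    evaluate_segmentation,
    predict_map,
    sample_training_pixels,
    train_pixel_classifier,
)

truth = make_phantom(PhantomSpec(seed=5))
sparse = subsample_y(truth.noisy_cube, SamplingScheme(dy_lo=5.0))
cube = reconstruct_cube(sparse).cube

train_mask, test_mask = column_split_masks(cube.shape)
train = sample_training_pixels(
    cube, truth.label_map, per_class=1000, seed=1, mask=train_mask
)
model = train_pixel_classifier(train, ClassifierParams(seed=1))
pred, proba = predict_map(model, cube)
report = evaluate_segmentation(
    pred[test_mask], truth.label_map[test_mask],
    probabilities=proba[:, test_mask].T,
)

names = {0: "epithelium", 1: "stroma", 2: "necrosis"}
for c, acc in report.per_class_accuracy.items():
    auc = report.per_class_auc[c]
    print(f"{names.get(c, c):>10}: accuracy {acc:5.1f}%   one-vs-rest AUC {auc:.3f}")
print(f"overall accuracy {report.overall_accuracy:.1f}% on {int(report.support.sum())} held-out pixels")
print("-> the 27-band spectra of the fused cube separate the tissue classes.")
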