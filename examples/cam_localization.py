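"""Localize a lesion from a weakly-trained classifier's activation maps.

No lesion outline is used in training; the class activation map (CAM) of
the predicted class, min-max scaled, upsampled and thresholded at 0.3,
is compared with the ground-truth mask. Localization counts as correct
when the two overlap by at least one pixel.
"""

import numpy as np

from wsus import (GapClassifierConfig, GenerationConfig, LesionRanges,
                  TrainingConfig, cam_result, generate_images, localize,
                  localization_table, fisher_exact_2x2, resize_normalize,
                  train_classifier)

config = GenerationConfig(
    height=64, width=64,
    counts={"train": (30, 30), "internal_val": (15, 15),
            "external_val": (2, 2)},
    tune_per_class=5,
    ranges=LesionRanges(size_range=(0.25, 0.45),
                        benign_offset=(-0.2, -0.1),
                        malignant_offset=(-0.9, -0.75),
                        malignant_posterior=(-0.6, -0.4),
                        malignant_posterior_prob=1.0),
)
images = list(generate_images(config, seed=2))
train = [im for im in images if im.split == "train"]
val = [im for im in images if im.split == "internal_val"]

X = np.stack([resize_normalize(im.pixels, 64).pixels for im in train])
y = np.array([im.label == "malignant" for im in train], dtype=int)
model, _ = train_classifier(X, y, TrainingConfig(epochs=15, seed=0),
                            GapClassifierConfig(input_side=64))

outcomes = []
for im in val:
    fwd = model.forward(resize_normalize(im.pixels, 64).pixels)
    outcomes.append(localize(fwd, model.head_weights, im.mask,
                             true_label=int(im.label == "malignant"),
                             image_id=im.image_id))

table = localization_table(outcomes)
print("localization (correct / incorrect):")
print(f"  benign    {table.benign_correct} / {table.benign_incorrect}")
print(f"  malignant {table.malignant_correct} / {table.malignant_incorrect}")
print(f"Fisher exact p (benign vs malignant rates): "
      f"{fisher_exact_2x2(table):.3f}")

im = val[-1]
fwd = model.forward(resize_normalize(im.pixels, 64).pixels)
res = cam_result(fwd, model.head_weights,
                 int(np.argmax(fwd.probabilities)), target_side=64)
print(f"\none {im.label} case: CAM area {int(res.binary_map.sum())} px, "
      f"lesion area {int(im.mask.sum())} px, "
      f"overlap {int(np.sum(res.binary_map & im.mask))} px")
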