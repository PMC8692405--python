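"""Train a small GAP classifier from image-level labels and score a case.

Trains on 60 easy phantoms for a few epochs, then prints the probability
of malignancy (POM) for one benign and one malignant validation image and
the validation AUC — the probability that a random malignant case outscores
a random benign one.
"""

import numpy as np

from wsus import (GapClassifierConfig, GenerationConfig, LesionRanges,
                  TrainingConfig, generate_images, resize_normalize, roc_auc,
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
images = list(generate_images(config, seed=1))
train = [im for im in images if im.split == "train"]
val = [im for im in images if im.split == "internal_val"]

X = np.stack([resize_normalize(im.pixels, 64).pixels for im in train])
y = np.array([im.label == "malignant" for im in train], dtype=int)
model, log = train_classifier(X, y, TrainingConfig(epochs=15, seed=0),
                              GapClassifierConfig(input_side=64))
print(f"final training loss: {log.train_loss.iloc[-1]:.3f}")

Xv = np.stack([resize_normalize(im.pixels, 64).pixels for im in val])
yv = np.array([im.label == "malignant" for im in val], dtype=int)
poms = model.predict_pom(Xv)
est = roc_auc(poms, yv)
print(f"validation AUC: {est.auc:.3f} (95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")
for i in (0, len(val) - 1):
    print(f"  {val[i].label:9s} case -> POM {poms[i]:.3f} "
          "(softmax probability of the malignant class)")
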