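# wsus — weakly-supervised ultrasound diagnosis with CAM localization

`wsus` is a tested, reusable pipeline for studying whether a classifier
trained **only on image-level labels** (benign / malignant) can match
classifiers trained on annotated lesion regions — and whether its class
activation maps find the lesion as a by-product. It targets the
breast-ultrasound setting: B-mode images, one mass per image, internal and
external validation sets from different machines. Because clinical
ultrasound archives are private, the package includes a seeded synthetic
phantom generator that reproduces the statistical structure of such a study
(speckle texture, benign vs malignant lesion morphology, a vendor domain
shift for the external set), so every claim in the pipeline is exercised
end to end on data anyone can regenerate.

Intended users: medical-image-analysis researchers who want a transparent,
CPU-scale reference implementation of weak supervision + CAM localization
with the accompanying statistical machinery, and anyone needing the
statistics on their own (DeLong, exact McNemar, Fisher, Dice).

## The model

A convolutional backbone ends in K feature maps f_k. Global average
pooling collapses each map into a feature score, written here as the
spatial sum

    F_k = Σ_{i,j} f_k(i, j),

a bias-free linear head produces class scores

    S_c = Σ_k w_{k,c} F_k,

and softmax gives class probabilities p_c; the probability of malignancy
(POM) is the malignant-class probability. The class activation map

    M_c = Σ_k w_{k,c} f_k

re-uses the same weights at full spatial resolution; with a bias-free head
Σ_{i,j} M_c(i,j) = S_c exactly. M_c is min–max scaled, upsampled, and
binarized at M′_c ≥ 0.3; localization is correct when the binary map
overlaps the ground-truth mask by at least one pixel.

Three arms are compared on identical case rosters: **weak** (whole image),
**full_manual** (square ROI crop around the ground-truth mask, 30-pixel
margin), **full_auto** (same crop around a U-Net-predicted mask). Arms are
compared with the DeLong test on paired AUCs, the exact McNemar test on
paired sensitivity/specificity at POM ≥ 0.5, and Fisher's exact test on
benign-vs-malignant localization rates. The networks are implemented in a
compact, fully seeded numpy layer library with handwritten
backpropagation (`wsus.nn`) — no GPU or deep-learning framework needed.

## Worked example

```sh
python examples/statistics_toolbox.py
```

prints

```
AUC of 4 hand-scored cases: 0.75 (3 of 4 malignant/benign pairs correctly ordered)
DeLong paired test: AUC 0.794 vs 0.787, z = 0.12, p = 0.905 (same cases, correlated curves)
exact McNemar, 10 vs 0 discordant pairs: p = 0.00195
exact McNemar, 6 vs 6 discordant pairs:  p = 1.00
Fisher exact on ((99, 1), (100, 0)): p = 1.00
Fisher exact on ((96, 4), (98, 2)): p = 0.68
Fisher exact on ((97, 3), (100, 0)): p = 0.25
Dice of two 100-px masks overlapping by 70 px: 0.70
```

The AUC line is the Mann–Whitney probability that a malignant case
outscores a benign one (3 wins, 1 loss out of 4 pairs). The DeLong p of
0.905 says two similarly-performing arms on the same 100 cases are not
statistically different. The Fisher lines are benign-vs-malignant
localization contingency tables: ((99,1),(100,0)) means 99/100 benign and
100/100 malignant lesions localized — rates that do not differ (p = 1.00).

Other examples, one per capability: `examples/generate_phantoms.py`,
`examples/train_and_classify.py`, `examples/cam_localization.py`,
`examples/small_study.py` (a reduced three-arm study, ~1 minute). The full
study is also available from the shell:

```sh
wsus study --out study_out --seed 7          # ~10 min on one CPU
wsus generate --out phantoms --seed 0        # dataset only
```

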