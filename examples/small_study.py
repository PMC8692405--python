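"""Run a reduced three-arm study end to end and read its report.

Compares the weakly-supervised whole-image arm with the fully-supervised
manual- and automated-ROI arms on a small phantom dataset (the default
study uses 500+500 training images; this demo shrinks everything so it
finishes in a few minutes). Reports land in ./study_demo.
"""


from wsus import (GenerationConfig, LesionRanges, SegmenterConfig,
                  StudyConfig, TrainingConfig)
from wsus.experiment import run_study

config = StudyConfig(
    generation=GenerationConfig(
        counts={"train": (80, 80), "internal_val": (30, 30),
                "external_val": (30, 30)}, tune_per_class=15,
        ranges=LesionRanges(size_range=(0.15, 0.5),
                            benign_offset=(-0.35, -0.15),
                            malignant_offset=(-0.7, -0.45))),
    classifier_training=TrainingConfig(epochs=25),
    segmenter=SegmenterConfig(epochs=5),
    seg_train_per_class=40,
    n_overlays=2,
)
results = run_study(config, seed=3, out_dir="study_demo")

for split in ("internal_val", "external_val"):
    arms = results["splits"][split]["arms"]
    comp = results["splits"][split]["comparisons"]
    loc = results["splits"][split]["localization"]
    print(f"\n{split}:")
    for arm, r in arms.items():
        print(f"  {arm:12s} AUC {r['auc']:.3f} "
              f"sens {r['sensitivity']:.2f} spec {r['specificity']:.2f}")
    print(f"  DeLong weak vs manual p = {comp['delong_p_weak_vs_manual']:.3f} "
          "(> 0.05 means the weak arm is not statistically different)")
    print(f"  weak-arm localization: benign {loc['benign_rate']:.0%}, "
          f"malignant {loc['malignant_rate']:.0%}, "
          f"Fisher p = {loc['fisher_p']:.2f}")
print("\nfull reports: study_demo/report_*.md, results.json, per_case.csv")
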