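"""Full study orchestration: three supervision arms, two validation splits.

The study compares three classification pathways on identical case rosters:

* ``weak`` — the classifier sees the whole image (image-level labels only)
  and additionally localizes lesions via its class activation maps;
* ``full_manual`` — a classifier trained and evaluated on square ROI crops
  around the ground-truth lesion mask (the phantom stand-in for a manual
  annotation);
* ``full_auto`` — the same ROI classifier, but the evaluation crop is taken
  around the mask predicted by the trained segmenter. With a perfect
  segmenter the two full arms coincide exactly, which is why they share one
  model.

Evaluation mirrors the paired design: AUC with DeLong confidence intervals
and pairwise DeLong tests, exact McNemar on sensitivity (malignant cases)
and specificity (benign cases) at the POM >= 0.5 operating point, and
Fisher's exact test comparing benign vs malignant localization rates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .cam import (DEFAULT_CAM_THRESHOLD, ClassPolicy, LocalizationOutcome,
                  cam_result, localization_table, localize, save_overlay)
from .models import (ClassifierForward, GapClassifier, GapClassifierConfig,
                     SegmenterConfig, TrainingConfig, UNetSegmenter,
                     train_classifier, train_segmenter)
from .phantom import GenerationConfig, LabeledImage, generate_dataset, generate_images
from .preprocess import DEFAULT_MARGIN, crop_roi, resize_normalize
from .stats import (AucEstimate, ContingencyTable2x2, DelongResult, SensSpec,
                    delong_test, dice_coefficient, fisher_exact_2x2, mcnemar_exact,
                    roc_auc, sens_spec)

log = logging.getLogger("wsus")

Arm = Literal["weak", "full_manual", "full_auto"]
ARMS: tuple[Arm, ...] = ("weak", "full_manual", "full_auto")


@dataclass
class StudyConfig:
    """Everything needed to run the study end to end, reproducibly."""

    generation: GenerationConfig = field(default_factory=GenerationConfig)
    model: GapClassifierConfig = field(default_factory=GapClassifierConfig)
    classifier_training: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(epochs=50))
    segmenter: SegmenterConfig = field(
        default_factory=lambda: SegmenterConfig(epochs=10))
    seg_train_per_class: int = 150
    roi_margin: int = DEFAULT_MARGIN
    class_policy: ClassPolicy = "predicted"
    cam_threshold: float = DEFAULT_CAM_THRESHOLD
    operating_threshold: float = 0.5
    n_overlays: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        sub = {"generation": GenerationConfig, "model": GapClassifierConfig,
               "classifier_training": TrainingConfig,
               "segmenter": SegmenterConfig}
        for key, val in raw.items():
            if key == "generation":
                from .phantom import LesionRanges, MachineProfile
                if "internal_profile" in val:
                    val["internal_profile"] = MachineProfile(**val["internal_profile"])
                if "external_profile" in val:
                    val["external_profile"] = MachineProfile(**val["external_profile"])
                if "counts" in val:
                    val["counts"] = {k: tuple(v) for k, v in val["counts"].items()}
                if "ranges" in val:
                    val["ranges"] = LesionRanges(**{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in val["ranges"].items()})
                kwargs[key] = GenerationConfig(**val)
            elif key in sub:
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))


@dataclass
class ArmEvaluation:
    """Per-arm scores and metrics on one validation split."""

    arm: Arm
    split: str
    case_ids: list[str]
    labels: np.ndarray
    poms: np.ndarray
    auc: AucEstimate
    operating: SensSpec
    localization: list[LocalizationOutcome] | None = None
    loc_table: ContingencyTable2x2 | None = None
    dsc_mean: float | None = None
    dsc_sd: float | None = None
    n_seg_fallback: int = 0


@dataclass
class ComparisonReport:
    """Pairwise statistics between the weak and fully-supervised arms."""

    split: str
    delong: dict[str, DelongResult]
    mcnemar_sensitivity: dict[str, float]
    mcnemar_specificity: dict[str, float]
    fisher_localization: float | None


def _label_int(label: str) -> int:
    return 1 if label == "malignant" else 0


def _prepare_inputs(images: list[LabeledImage], arm: Arm, side: int,
                    margin: int, segmenter: UNetSegmenter | None
                    ) -> tuple[np.ndarray, list[float] | None, int]:
    """Stack prepared inputs for an arm; returns (X, per-case DSC, fallbacks)."""
    xs, dscs, fallback = [], [], 0
    for im in images:
        if arm == "weak":
            xs.append(resize_normalize(im.pixels, side).pixels)
        elif arm == "full_manual":
            xs.append(crop_roi(im.pixels, im.mask, margin=margin, side=side).pixels)
        else:
            if segmenter is None:
                raise ValueError("full_auto arm requires a trained segmenter")
            pred = segmenter.segment(im.pixels).mask
            dscs.append(dice_coefficient(pred, im.mask) if pred.any() else 0.0)
            if pred.any():
                xs.append(crop_roi(im.pixels, pred, margin=margin,
                                   side=side).pixels)
            else:
                fallback += 1
                xs.append(resize_normalize(im.pixels, side).pixels)
    X = np.stack(xs).astype(np.float32)
    return X, (dscs if arm == "full_auto" else None), fallback


def run_arm(images: list[LabeledImage], arm: Arm, classifier: GapClassifier,
            segmenter: UNetSegmenter | None = None,
            class_policy: ClassPolicy = "predicted",
            cam_threshold: float = DEFAULT_CAM_THRESHOLD,
            operating_threshold: float = 0.5,
            margin: int = DEFAULT_MARGIN) -> ArmEvaluation:
    """Score one arm on one split's images (all arms use identical rosters)."""
    if not images:
        raise ValueError("empty case roster")
    split = images[0].split
    side = classifier.config.input_side
    labels = np.array([_label_int(im.label) for im in images])
    X, dscs, fallback = _prepare_inputs(images, arm, side, margin, segmenter)
    poms = classifier.predict_pom(X)
    ev = ArmEvaluation(
        arm=arm, split=split, case_ids=[im.image_id for im in images],
        labels=labels, poms=poms, auc=roc_auc(poms, labels),
        operating=sens_spec(poms, labels, operating_threshold),
        dsc_mean=float(np.mean(dscs)) if dscs else None,
        dsc_sd=float(np.std(dscs, ddof=1)) if dscs else None,
        n_seg_fallback=fallback)
    if arm == "weak":
        outcomes = []
        W = classifier.head_weights
        for i in range(0, len(X), 64):
            out = classifier.forward_batch(X[i:i + 64, None])
            for j in range(out["f"].shape[0]):
                im = images[i + j]
                cf = ClassifierForward(
                    feature_maps=out["f"][j], feature_scores=out["F"][j],
                    class_scores=out["S"][j], probabilities=out["p"][j],
                    pom=float(out["pom"][j]))
                outcomes.append(localize(
                    cf, W, im.mask, policy=class_policy,
                    threshold=cam_threshold,
                    malignant_index=classifier.config.malignant_index,
                    true_label=_label_int(im.label), image_id=im.image_id))
        ev.localization = outcomes
        ev.loc_table = localization_table(outcomes)
    return ev


def compare_arms(evals: dict[Arm, ArmEvaluation],
                 operating_threshold: float = 0.5) -> ComparisonReport:
    """Pairwise DeLong / McNemar / Fisher statistics for one split."""
    weak = evals["weak"]
    for ev in evals.values():
        if ev.case_ids != weak.case_ids:
            raise ValueError("arms must share identical, identically-ordered "
                             "case rosters")
    labels = weak.labels
    delong: dict[str, DelongResult] = {}
    mc_sens: dict[str, float] = {}
    mc_spec: dict[str, float] = {}
    for arm in ("full_manual", "full_auto"):
        if arm not in evals:
            continue
        other = evals[arm]
        key = f"weak_vs_{'manual' if arm == 'full_manual' else 'auto'}"
        delong[key] = delong_test(weak.poms, other.poms, labels)
        for name, store, sel, want in (("sens", mc_sens, labels == 1, True),
                                       ("spec", mc_spec, labels == 0, False)):
            w_ok = (weak.poms[sel] >= operating_threshold) == want
            o_ok = (other.poms[sel] >= operating_threshold) == want
            b = int(np.sum(w_ok & ~o_ok))
            c = int(np.sum(~w_ok & o_ok))
            store[key] = mcnemar_exact(b, c)
    fisher_p = (fisher_exact_2x2(weak.loc_table)
                if weak.loc_table is not None else None)
    return ComparisonReport(split=weak.split, delong=delong,
                            mcnemar_sensitivity=mc_sens,
                            mcnemar_specificity=mc_spec,
                            fisher_localization=fisher_p)


# ---------------------------------------------------------------------------
# report rendering


def diagnostic_table(evals: dict[Arm, ArmEvaluation],
                     report: ComparisonReport) -> pd.DataFrame:
    """Per-split diagnostic metrics table (AUC / sensitivity / specificity)."""
    rows = []
    for metric in ("auc", "sensitivity", "specificity"):
        row: dict[str, object] = {"metric": metric}
        for arm in ARMS:
            if arm not in evals:
                continue
            ev = evals[arm]
            if metric == "auc":
                row[arm] = (f"{ev.auc.auc:.2f} "
                            f"({ev.auc.ci_low:.2f}, {ev.auc.ci_high:.2f})")
            elif metric == "sensitivity":
                row[arm] = ev.operating.format()[0]
            else:
                row[arm] = ev.operating.format()[1]
        for key in report.delong:
            if metric == "auc":
                row[f"p_{key}"] = round(report.delong[key].p, 4)
            elif metric == "sensitivity":
                row[f"p_{key}"] = round(report.mcnemar_sensitivity[key], 4)
            else:
                row[f"p_{key}"] = round(report.mcnemar_specificity[key], 4)
        rows.append(row)
    return pd.DataFrame(rows)


def localization_frame(ev: ArmEvaluation, fisher_p: float | None
                       ) -> pd.DataFrame:
    t = ev.loc_table
    assert t is not None
    return pd.DataFrame(
        [{"outcome": "correct", "benign": t.benign_correct,
          "malignant": t.malignant_correct, "fisher_p": fisher_p},
         {"outcome": "incorrect", "benign": t.benign_incorrect,
          "malignant": t.malignant_incorrect, "fisher_p": None}])


def frame_to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(
            "" if pd.isna(row[c]) else str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# end-to-end study


def _study_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4, dtype=np.uint32)
    names = ("generation", "weak", "roi", "segmenter")
    return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


def _train_stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.exception("stage %s: FAILED", name)
                raise RuntimeError(f"study stage {name!r} failed") from None
            log.info("stage %s: done in %.1f s", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_study(config: StudyConfig, seed: int, out_dir: str | Path,
              write_images: bool = False) -> dict:
    """Run the whole study and write reports; returns the results dict.

    Stages: dataset generation, segmenter training, weak- and ROI-classifier
    training, three-arm evaluation on both validation splits, pairwise
    statistics, and report/overlay output. Fully reproducible per seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO,
                            format="%(asctime)s %(name)s %(message)s")
    seeds = _study_seeds(seed)
    log.info("study start: seed=%d stage seeds=%s", seed, seeds)
    config.to_yaml(out / "study_config.yaml")

    @_train_stage("generate_dataset")
    def _generate():
        if write_images:
            data_dir = out / "data"
            generate_dataset(config.generation, data_dir, seeds["generation"])
        return list(generate_images(config.generation, seeds["generation"]))

    images = _generate()
    by_split: dict[str, list[LabeledImage]] = {}
    for im in images:
        by_split.setdefault(im.split, []).append(im)
    train = by_split["train"]
    rosters = {s: {im.image_id for im in v} for s, v in by_split.items()}
    for s in ("internal_val", "external_val"):
        if rosters["train"] & rosters[s]:
            raise RuntimeError(f"information leak: train roster intersects {s}")

    side = config.model.input_side
    y_train = np.array([_label_int(im.label) for im in train])
    tune_idx = np.array([im.is_tune for im in train])

    @_train_stage("train_segmenter")
    def _segmenter():
        per_class: dict[str, list[LabeledImage]] = {"benign": [], "malignant": []}
        for im in train:
            if len(per_class[im.label]) < config.seg_train_per_class:
                per_class[im.label].append(im)
        seg_imgs = per_class["benign"] + per_class["malignant"]
        X = np.stack([im.pixels for im in seg_imgs]).astype(np.float32)
        M = np.stack([im.mask for im in seg_imgs])
        cfg = dataclasses.replace(config.segmenter, seed=seeds["segmenter"],
                                  input_side=config.generation.height)
        model, seg_log = train_segmenter(X, M, cfg)
        seg_log.to_csv(out / "segmenter_training_log.csv", index=False)
        return model

    segmenter = _segmenter()

    @_train_stage("train_weak_classifier")
    def _weak():
        X = np.stack([resize_normalize(im.pixels, side).pixels
                      for im in train]).astype(np.float32)
        cfg = dataclasses.replace(config.classifier_training, seed=seeds["weak"])
        model, tl = train_classifier(X, y_train, cfg, config.model,
                                     X[tune_idx], y_train[tune_idx])
        tl.to_csv(out / "weak_training_log.csv", index=False)
        return model

    @_train_stage("train_roi_classifier")
    def _roi():
        X = np.stack([crop_roi(im.pixels, im.mask, margin=config.roi_margin,
                               side=side).pixels
                      for im in train]).astype(np.float32)
        cfg = dataclasses.replace(config.classifier_training, seed=seeds["roi"])
        model, tl = train_classifier(X, y_train, cfg, config.model,
                                     X[tune_idx], y_train[tune_idx])
        tl.to_csv(out / "roi_training_log.csv", index=False)
        return model

    clf_weak = _weak()
    clf_roi = _roi()

    results: dict = {"schema_version": 1, "seed": seed, "splits": {}}
    case_rows = []
    for split in ("internal_val", "external_val"):
        imgs = by_split[split]

        @_train_stage(f"evaluate_{split}")
        def _evaluate(imgs=imgs):
            evals: dict[Arm, ArmEvaluation] = {}
            for arm in ARMS:
                clf = clf_weak if arm == "weak" else clf_roi
                evals[arm] = run_arm(
                    imgs, arm, clf, segmenter=segmenter,
                    class_policy=config.class_policy,
                    cam_threshold=config.cam_threshold,
                    operating_threshold=config.operating_threshold,
                    margin=config.roi_margin)
            report = compare_arms(evals, config.operating_threshold)
            return evals, report

        evals, report = _evaluate()
        diag = diagnostic_table(evals, report)
        diag.to_csv(out / f"diagnostic_{split}.csv", index=False)
        loc = localization_frame(evals["weak"], report.fisher_localization)
        loc.to_csv(out / f"localization_{split}.csv", index=False)
        (out / f"report_{split}.md").write_text(
            f"## Diagnostic performance ({split})\n\n"
            + frame_to_markdown(diag)
            + f"\n## Weak-arm localization ({split})\n\n"
            + frame_to_markdown(loc))

        split_res: dict = {"arms": {}, "comparisons": {}, "localization": {}}
        for arm, ev in evals.items():
            split_res["arms"][arm] = {
                "n": len(ev.case_ids), "auc": ev.auc.auc,
                "auc_ci": [ev.auc.ci_low, ev.auc.ci_high],
                "sensitivity": ev.operating.sensitivity,
                "specificity": ev.operating.specificity,
            }
            if ev.dsc_mean is not None:
                split_res["arms"][arm]["dsc_mean"] = ev.dsc_mean
                split_res["arms"][arm]["dsc_sd"] = ev.dsc_sd
                split_res["arms"][arm]["n_seg_fallback"] = ev.n_seg_fallback
        for key, res in report.delong.items():
            split_res["comparisons"][f"delong_p_{key}"] = res.p
        for key, p in report.mcnemar_sensitivity.items():
            split_res["comparisons"][f"mcnemar_sens_p_{key}"] = p
        for key, p in report.mcnemar_specificity.items():
            split_res["comparisons"][f"mcnemar_spec_p_{key}"] = p
        t = evals["weak"].loc_table
        assert t is not None
        split_res["localization"] = {
            "benign_correct": t.benign_correct,
            "benign_incorrect": t.benign_incorrect,
            "malignant_correct": t.malignant_correct,
            "malignant_incorrect": t.malignant_incorrect,
            "benign_rate": t.benign_correct / (t.benign_correct + t.benign_incorrect),
            "malignant_rate": t.malignant_correct / (t.malignant_correct
                                                     + t.malignant_incorrect),
            "fisher_p": report.fisher_localization,
        }
        results["splits"][split] = split_res

        loc_by_id = {o.image_id: o for o in evals["weak"].localization or []}
        for i, cid in enumerate(evals["weak"].case_ids):
            case_rows.append({
                "case": cid, "split": split,
                "label": int(evals["weak"].labels[i]),
                "pom_weak": float(evals["weak"].poms[i]),
                "pom_full_manual": float(evals["full_manual"].poms[i]),
                "pom_full_auto": float(evals["full_auto"].poms[i]),
                "localized": loc_by_id[cid].correct if cid in loc_by_id else None,
            })

        # a few qualitative CAM overlays per split
        W = clf_weak.head_weights
        n_done = {"benign": 0, "malignant": 0}
        for im in imgs:
            if n_done[im.label] >= config.n_overlays:
                continue
            fwd = clf_weak.forward(resize_normalize(im.pixels, side).pixels)
            res = cam_result(fwd, W, int(np.argmax(fwd.probabilities)),
                             target_side=im.mask.shape[0],
                             threshold=config.cam_threshold)
            save_overlay(im.pixels, res.upsampled_map,
                         out / f"overlay_{im.image_id}.png", gt_mask=im.mask)
            n_done[im.label] += 1

    pd.DataFrame(case_rows).to_csv(out / "per_case.csv", index=False)
    results = _round_floats(results)
    (out / "results.json").write_text(json.dumps(results, indent=2))
    clf_weak.save(out / "model_weak")
    clf_roi.save(out / "model_roi")
    segmenter.save(out / "model_segmenter")
    log.info("study complete: %s", out / "results.json")
    return results
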