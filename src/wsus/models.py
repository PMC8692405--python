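"""GAP-headed convolutional classifier and encoder–decoder segmenter.

The classifier follows the class-activation-mapping construction: a small
convolutional backbone ends in K feature maps ``f_k``, a global pooling
layer collapses each map to a feature score ``F_k = sum_{i,j} f_k(i,j)``
(spatial sum by default; mean pooling available by config since the two
differ only by a constant absorbable into the head weights), and a
bias-free linear head produces class scores ``S_c = sum_k w_{k,c} F_k``
followed by a softmax. The probability of malignancy (POM) is the softmax
probability of the malignant class. The bias-free head makes the class
activation map an exact decomposition of the class score.

Training uses cross-entropy with an L2 penalty (lambda/2 ||W||^2), Adam
(lr 1e-3, beta1 0.9, beta2 0.999), batch size 64, He initialisation, and
best-tuning-AUC snapshot selection over a fixed number of epochs.

The segmenter is a compact U-Net: three pooling stages with skip
connections, trained with binary cross-entropy plus soft-Dice.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .preprocess import PreparedInput
from .stats import roc_auc

_PUBLISHED_BACKBONES = ("vgg16", "resnet34", "googlenet")


# ---------------------------------------------------------------------------
# classifier


@dataclass(frozen=True)
class GapClassifierConfig:
    """Architecture of the GAP classifier.

    ``k_channels`` is the number of final-layer feature maps K; setting
    K = num_classes recovers the literal one-map-per-class reading, while
    the default K = 32 is the standard CAM formulation.
    """

    backbone: str = "tiny"
    k_channels: int = 32
    num_classes: int = 2
    malignant_index: int = 1
    input_side: int = 128
    gap_mode: str = "sum"  # "sum" (default) or "mean"

    def __post_init__(self) -> None:
        if self.backbone in _PUBLISHED_BACKBONES:
            raise ValueError(
                f"backbone {self.backbone!r} is not provided by this package's "
                "compact numpy network stack; use 'tiny' or 'small'")
        if self.backbone not in ("tiny", "small"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if not 0 <= self.malignant_index < self.num_classes:
            raise ValueError("malignant_index out of range")
        if self.gap_mode not in ("sum", "mean"):
            raise ValueError("gap_mode must be 'sum' or 'mean'")


@dataclass
class ClassifierForward:
    """All intermediate quantities of one forward pass."""

    feature_maps: np.ndarray   # (K, h, w)
    feature_scores: np.ndarray  # (K,)
    class_scores: np.ndarray   # (N_c,)
    probabilities: np.ndarray  # (N_c,)
    pom: float


def global_average_pool(f: np.ndarray, mode: str = "sum") -> np.ndarray:
    """Collapse feature maps to feature scores F_k.

    Accepts (K, h, w) or (B, K, h, w); "sum" is the spatial sum over (i, j),
    "mean" divides by the number of spatial positions.
    """
    f = np.asarray(f)
    if f.ndim not in (3, 4) or f.shape[-1] == 0 or f.shape[-2] == 0:
        raise ValueError("feature maps must be (K,h,w) or (B,K,h,w), nonempty")
    out = f.sum(axis=(-2, -1))
    if mode == "mean":
        out = out / (f.shape[-2] * f.shape[-1])
    elif mode != "sum":
        raise ValueError("mode must be 'sum' or 'mean'")
    return out


def class_scores(feature_scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Bias-free linear head: S_c = sum_k w_{k,c} F_k."""
    F = np.asarray(feature_scores)
    W = np.asarray(weights)
    if F.shape[-1] != W.shape[0]:
        raise ValueError("feature scores and head weights disagree on K")
    return F @ W


def softmax_pom(scores: np.ndarray, malignant_index: int
                ) -> tuple[np.ndarray, float]:
    """Stable softmax probabilities and the probability of malignancy."""
    S = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(S)):
        raise ValueError("class scores must be finite")
    p = nn.softmax(S, axis=-1)
    return p, float(p[..., malignant_index])


def _backbone_plan(config: GapClassifierConfig) -> list[tuple[int, int, int]]:
    K = config.k_channels
    if config.backbone == "tiny":
        return [(1, 8, 2), (8, 16, 2), (16, 32, 2), (32, K, 2)]
    return [(1, 8, 2), (8, 16, 1), (16, 16, 2), (16, 32, 1), (32, 32, 2),
            (32, K, 2)]


class GapClassifier:
    """Convolutional classifier with a GAP + bias-free linear head."""

    def __init__(self, config: GapClassifierConfig = GapClassifierConfig()):
        self.config = config
        self.layers: list[nn.Layer] = []
        for cin, cout, stride in _backbone_plan(config):
            self.layers.append(nn.Conv2d(cin, cout, 3, stride=stride))
            self.layers.append(nn.ReLU())
        self.head = nn.Linear(config.k_channels, config.num_classes, bias=False)
        self._all = self.layers + [self.head]

    # -- parameters -----------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self._all for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._all for g in layer.grads]

    @property
    def decay_mask(self) -> list[bool]:
        return [p.ndim > 1 for layer in self._all for p in layer.params]

    @property
    def head_weights(self) -> np.ndarray:
        """The shared K x N_c head matrix W = {w_{k,c}}."""
        return self.head.w

    def init_weights(self, seed: int) -> "GapClassifier":
        rng = np.random.default_rng(seed)
        for layer in self._all:
            layer.he_init(rng)
        return self

    # -- forward / backward ---------------------------------------------
    def backbone_forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward_batch(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Forward a (B,1,S,S) batch; returns f, F, S, p, pom arrays."""
        if x.ndim != 4:
            raise ValueError("expected a (B,1,side,side) batch")
        if x.shape[2] != self.config.input_side:
            raise ValueError(
                f"input side {x.shape[2]} does not match configured "
                f"{self.config.input_side}")
        f = self.backbone_forward(x.astype(np.float32, copy=False))
        F = global_average_pool(f, self.config.gap_mode)
        S = F @ self.head.w
        self._F = F  # cached for backward
        p = nn.softmax(S.astype(np.float64), axis=1)
        return {"f": f, "F": F, "S": S, "p": p,
                "pom": p[:, self.config.malignant_index]}

    def backward_from_scores(self, dS: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the class scores S."""
        self.head._x = self._F
        dF = self.head.backward(dS.astype(np.float32))
        f_shape = self.layers[-1]._mask.shape  # last ReLU output shape
        df = np.broadcast_to(dF[:, :, None, None], f_shape).astype(np.float32)
        if self.config.gap_mode == "mean":
            df = df / (f_shape[2] * f_shape[3])
        g = df
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def forward(self, prepared: PreparedInput | np.ndarray) -> ClassifierForward:
        """Forward one image, returning every intermediate quantity."""
        x = prepared.pixels if isinstance(prepared, PreparedInput) else prepared
        out = self.forward_batch(np.asarray(x, dtype=np.float32)[None, None])
        return ClassifierForward(
            feature_maps=out["f"][0], feature_scores=out["F"][0],
            class_scores=out["S"][0], probabilities=out["p"][0],
            pom=float(out["pom"][0]))

    def predict_pom(self, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """POM for a stack of images (N,S,S) or (N,1,S,S)."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None]
        poms = [self.forward_batch(X[i:i + batch_size])["pom"]
                for i in range(0, len(X), batch_size)]
        return np.concatenate(poms)

    # -- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": p for i, p in enumerate(self.params)})
        path.with_suffix(".json").write_text(json.dumps(
            {"kind": "GapClassifier", "config": asdict(self.config)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GapClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(GapClassifierConfig(**meta["config"]))
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params):
            p[...] = data[f"p{i}"]
        return model


def init_weights(model, seed: int):
    """He-initialise every layer of a model, deterministically per seed."""
    return model.init_weights(seed)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation recipe. Defaults: Adam(1e-3, 0.9, 0.999), batch 64."""

    batch_size: int = 64
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 12
    weight_decay: float = 0.0
    seed: int = 0


def _as_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    return X[:, None] if X.ndim == 3 else X


def train_classifier(X, y, config: TrainingConfig = TrainingConfig(),
                     model_config: GapClassifierConfig = GapClassifierConfig(),
                     X_tune=None, y_tune=None,
                     ) -> tuple[GapClassifier, pd.DataFrame]:
    """Train a GAP classifier; returns (model, per-epoch log).

    Minimises cross-entropy + (weight_decay/2)*||W||^2 with Adam. When a
    tuning set is given, the parameters from the epoch with the best tuning
    AUC are restored at the end; otherwise the final epoch is kept (with a
    warning in the log).
    """
    X = _as_batch(X)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = GapClassifier(model_config).init_weights(config.seed)
    adam = nn.Adam(model.params, lr=config.learning_rate, beta1=config.beta1,
                   beta2=config.beta2, weight_decay=config.weight_decay,
                   decay_mask=model.decay_mask)
    rng = np.random.default_rng(config.seed + 1)
    has_tune = X_tune is not None and len(X_tune) > 0
    best_auc, best_params, best_epoch = -np.inf, None, -1
    rows = []
    for epoch in range(config.epochs):
        perm = rng.permutation(len(X))
        losses = []
        for i in range(0, len(X), config.batch_size):
            idx = perm[i:i + config.batch_size]
            out = model.forward_batch(X[idx])
            loss, dS = nn.softmax_xent(out["S"].astype(np.float64), y[idx])
            model.backward_from_scores(dS)
            adam.step(model.grads)
            losses.append(loss)
        tune_auc = np.nan
        if has_tune:
            tune_auc = roc_auc(model.predict_pom(X_tune), y_tune).auc
            if tune_auc > best_auc:
                best_auc, best_epoch = tune_auc, epoch
                best_params = [p.copy() for p in model.params]
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "tune_auc": tune_auc})
    log = pd.DataFrame(rows)
    if has_tune and best_params is not None:
        for p, bp in zip(model.params, best_params):
            p[...] = bp
        log.attrs["best_epoch"] = best_epoch
    else:
        log.attrs["warning"] = "no tuning set: kept final-epoch parameters"
    return model, log


@dataclass
class GridSearchResult:
    best_config: TrainingConfig
    model: GapClassifier
    results: pd.DataFrame


#: default hyper-parameter grid (learning rate x weight decay)
DEFAULT_GRID = {"learning_rate": [1e-3, 1e-4],
                "weight_decay": [0.0, 1e-4, 1e-3]}


def grid_search(X, y, grid: dict[str, list] = DEFAULT_GRID,
                config: TrainingConfig = TrainingConfig(),
                model_config: GapClassifierConfig = GapClassifierConfig(),
                tune_per_class: int | None = None) -> GridSearchResult:
    """Exhaustive hyper-parameter search scored by tuning-set AUC.

    A stratified tuning subset (default 20% per class, at most 100) is
    carved from the training set; every grid point is trained on the
    remainder and scored on it. Ties break toward lower weight decay, then
    lower learning rate. The winning configuration is finally retrained on
    the whole training set.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyper-parameter grid")
    X = _as_batch(X)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    tune_idx: list[int] = []
    for cls in np.unique(y):
        cls_idx = np.where(y == cls)[0]
        n_tune = tune_per_class or min(100, max(1, round(0.2 * len(cls_idx))))
        tune_idx += list(rng.permutation(cls_idx)[:n_tune])
    tune_mask = np.zeros(len(y), dtype=bool)
    tune_mask[tune_idx] = True

    rows = []
    keys = sorted(grid)
    for values in itertools.product(*(grid[k] for k in keys)):
        combo = dict(zip(keys, values))
        cfg = replace(config, **combo)
        if cfg.epochs > 0:
            _, log = train_classifier(X[~tune_mask], y[~tune_mask], cfg,
                                      model_config, X[tune_mask], y[tune_mask])
            auc = float(log["tune_auc"].max())
        else:
            auc = 0.5  # untrained
        rows.append({**combo, "tune_auc": auc})
    results = pd.DataFrame(rows)
    order = results.sort_values(
        by=["tune_auc", "weight_decay", "learning_rate"]
        if {"weight_decay", "learning_rate"} <= set(results.columns)
        else ["tune_auc"],
        ascending=[False, True, True]
        if {"weight_decay", "learning_rate"} <= set(results.columns)
        else [False])
    best = {k: order.iloc[0][k] for k in keys}
    best_config = replace(config, **{
        k: (type(getattr(config, k)))(v) for k, v in best.items()})
    final_model, _ = train_classifier(X, y, best_config, model_config)
    return GridSearchResult(best_config=best_config, model=final_model,
                            results=results)


# ---------------------------------------------------------------------------
# segmenter


@dataclass(frozen=True)
class SegmenterConfig:
    base_channels: int = 8
    input_side: int = 128
    batch_size: int = 8
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 10
    seed: int = 0


@dataclass
class SegmenterOutput:
    """Per-pixel lesion probability map and its 0.5-thresholded mask."""

    prob_map: np.ndarray
    mask: np.ndarray


class UNetSegmenter:
    """Compact U-Net: 3 pooling stages, nearest-neighbour upsampling,
    skip connections by channel concatenation, sigmoid output."""

    def __init__(self, config: SegmenterConfig = SegmenterConfig()):
        self.config = config
        c = config.base_channels
        self.conv_e1 = nn.Conv2d(1, c)
        self.conv_e2 = nn.Conv2d(c, 2 * c)
        self.conv_e3 = nn.Conv2d(2 * c, 4 * c)
        self.conv_b = nn.Conv2d(4 * c, 8 * c)
        self.conv_d3 = nn.Conv2d(12 * c, 4 * c)
        self.conv_d2 = nn.Conv2d(6 * c, 2 * c)
        self.conv_d1 = nn.Conv2d(3 * c, c)
        self.conv_out = nn.Conv2d(c, 1, k=1, pad=0)
        self._convs = [self.conv_e1, self.conv_e2, self.conv_e3, self.conv_b,
                       self.conv_d3, self.conv_d2, self.conv_d1, self.conv_out]
        self._relus = [nn.ReLU() for _ in range(7)]
        self._pools = [nn.MaxPool2() for _ in range(3)]
        self._ups = [nn.UpsampleNearest2() for _ in range(3)]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self._convs for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self._convs for g in l.grads]

    @property
    def decay_mask(self) -> list[bool]:
        return [p.ndim > 1 for l in self._convs for p in l.params]

    def init_weights(self, seed: int) -> "UNetSegmenter":
        rng = np.random.default_rng(seed)
        for l in self._convs:
            l.he_init(rng)
        return self

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        r, pl, up = self._relus, self._pools, self._ups
        c = self.config.base_channels
        a1 = r[0].forward(self.conv_e1.forward(x))
        a2 = r[1].forward(self.conv_e2.forward(pl[0].forward(a1)))
        a3 = r[2].forward(self.conv_e3.forward(pl[1].forward(a2)))
        bb = r[3].forward(self.conv_b.forward(pl[2].forward(a3)))
        d3 = r[4].forward(self.conv_d3.forward(
            np.concatenate([up[0].forward(bb), a3], axis=1)))
        d2 = r[5].forward(self.conv_d2.forward(
            np.concatenate([up[1].forward(d3), a2], axis=1)))
        d1 = r[6].forward(self.conv_d1.forward(
            np.concatenate([up[2].forward(d2), a1], axis=1)))
        self._split = (8 * c, 4 * c, 2 * c)
        return self.conv_out.forward(d1)

    def backward(self, glogits: np.ndarray) -> None:
        r, pl, up = self._relus, self._pools, self._ups
        s8, s4, s2 = self._split
        gc1 = self.conv_d1.backward(r[6].backward(self.conv_out.backward(glogits)))
        gu1, ga1_skip = gc1[:, :s2], gc1[:, s2:]
        gc2 = self.conv_d2.backward(r[5].backward(up[2].backward(gu1)))
        gu2, ga2_skip = gc2[:, :s4], gc2[:, s4:]
        gc3 = self.conv_d3.backward(r[4].backward(up[1].backward(gu2)))
        gu3, ga3_skip = gc3[:, :s8], gc3[:, s8:]
        gp3 = self.conv_b.backward(r[3].backward(up[0].backward(gu3)))
        ga3 = pl[2].backward(gp3) + ga3_skip
        gp2 = self.conv_e3.backward(r[2].backward(ga3))
        ga2 = pl[1].backward(gp2) + ga2_skip
        gp1 = self.conv_e2.backward(r[1].backward(ga2))
        ga1 = pl[0].backward(gp1) + ga1_skip
        self.conv_e1.backward(r[0].backward(ga1))

    def segment(self, pixels: np.ndarray, threshold: float = 0.5
                ) -> SegmenterOutput:
        """Probability map in [0,1] and binary mask for one image."""
        x = np.asarray(pixels, dtype=np.float32)[None, None]
        logits = self.forward_batch(x)[0, 0]
        prob = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        return SegmenterOutput(prob_map=prob, mask=prob >= threshold)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": p for i, p in enumerate(self.params)})
        path.with_suffix(".json").write_text(json.dumps(
            {"kind": "UNetSegmenter", "config": asdict(self.config)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(SegmenterConfig(**meta["config"]))
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params):
            p[...] = data[f"p{i}"]
        return model


def train_segmenter(X, masks, config: SegmenterConfig = SegmenterConfig()
                    ) -> tuple[UNetSegmenter, pd.DataFrame]:
    """Train the U-Net on (image, mask) pairs with BCE + soft-Dice loss."""
    X = _as_batch(X)
    M = np.asarray(masks, dtype=np.float32)
    if M.ndim == 3:
        M = M[:, None]
    if X.shape != M.shape:
        raise ValueError("images and masks must align")
    empties = ~M.any(axis=(1, 2, 3))
    if empties.any():
        raise ValueError(f"{int(empties.sum())} training masks are empty "
                         "(all-background targets are degenerate)")
    model = UNetSegmenter(config).init_weights(config.seed)
    adam = nn.Adam(model.params, lr=config.learning_rate, beta1=config.beta1,
                   beta2=config.beta2)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for epoch in range(config.epochs):
        perm = rng.permutation(len(X))
        losses = []
        for i in range(0, len(X), config.batch_size):
            idx = perm[i:i + config.batch_size]
            logits = model.forward_batch(X[idx])
            loss, glogits = nn.bce_dice_loss(logits.astype(np.float64), M[idx])
            model.backward(glogits)
            adam.step(model.grads)
            losses.append(loss)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses))})
    return model, pd.DataFrame(rows)
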