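"""Minimal numpy neural-network layers with handwritten backpropagation.

Everything here operates on float32 ``(batch, channels, height, width)``
tensors and is fully deterministic given a seeded ``numpy.random.Generator``.
The scope is deliberately small: exactly the layers needed for a compact
GAP-headed convolutional classifier and an encoder–decoder segmenter —
strided 2-D convolution, ReLU, 2x2 max-pooling, nearest-neighbour 2x
upsampling, and a (optionally bias-free) linear layer — plus Adam and the
two losses used for training (softmax cross-entropy, BCE + soft-Dice).

Convolution is evaluated as a sum over the k*k kernel offsets, each offset a
single BLAS call; the backward pass mirrors it with strided-slice
accumulation, so no im2col buffer is materialised.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "UpsampleNearest2",
    "Linear",
    "Adam",
    "he_normal",
    "softmax",
    "softmax_xent",
    "bce_dice_loss",
]


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He (fan-in, rectifier-scaled) normal initialisation: std = sqrt(2/fan_in)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    """Base class: layers expose aligned ``params`` and ``grads`` lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def he_init(self, rng: np.random.Generator) -> None:  # pragma: no cover - overridden
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation), square kernel, symmetric zero padding.

    Output spatial size is ``(H + 2p - k)//s + 1``; the default padding
    ``k // 2`` keeps size for stride 1 and halves it for stride 2 (even H).
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        self.w = np.zeros((cout, cin, k, k), dtype=np.float32)
        self.b = np.zeros(cout, dtype=np.float32) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]
        self._xpad: np.ndarray | None = None

    @property
    def fan_in(self) -> int:
        return self.cin * self.k * self.k

    def he_init(self, rng: np.random.Generator) -> None:
        self.w[...] = he_normal(rng, self.w.shape, self.fan_in)
        if self.b is not None:
            self.b[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        k, s, p = self.k, self.stride, self.pad
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xpad = xpad
        y = np.zeros((B, Ho, Wo, self.cout), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                xs = xpad[:, :, di:di + Ho * s:s, dj:dj + Wo * s:s]
                # (B,C,Ho,Wo) x (O,C) -> (B,Ho,Wo,O)
                y += np.tensordot(xs, self.w[:, :, di, dj], axes=([1], [1]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        if self.b is not None:
            y += self.b[None, :, None, None]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xpad = self._xpad
        assert xpad is not None, "forward must run before backward"
        B, _, Ho, Wo = gy.shape
        k, s, p = self.k, self.stride, self.pad
        gw = self.grads[0]
        gw[...] = 0.0
        gxpad = np.zeros_like(xpad)
        gy_l = np.ascontiguousarray(gy.transpose(0, 2, 3, 1))  # (B,Ho,Wo,O)
        for di in range(k):
            for dj in range(k):
                xs = xpad[:, :, di:di + Ho * s:s, dj:dj + Wo * s:s]
                gw[:, :, di, dj] = np.tensordot(gy_l, xs, axes=([0, 1, 2], [0, 2, 3]))
                # (B,Ho,Wo,O) x (O,C) -> (B,Ho,Wo,C); strided slices never alias
                gxpad[:, :, di:di + Ho * s:s, dj:dj + Wo * s:s] += np.tensordot(
                    gy_l, self.w[:, :, di, dj], axes=([3], [0])
                ).transpose(0, 3, 1, 2)
        if self.b is not None:
            self.grads[1][...] = gy.sum(axis=(0, 2, 3))
        self._xpad = None
        if p:
            return gxpad[:, :, p:-p, p:-p]
        return gxpad


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0).astype(np.float32, copy=False)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; requires even spatial dimensions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2 needs even spatial dimensions")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        self._shape = x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        g = self._mask * gy[:, :, :, None, :, None]
        # split ties evenly so the gradient is conserved
        g /= self._mask.sum(axis=(3, 5), keepdims=True)
        return g.reshape(B, C, H, W).astype(np.float32, copy=False)


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, H, W = gy.shape
        return gy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)).astype(
            np.float32, copy=False
        )


class Linear(Layer):
    def __init__(self, cin: int, cout: int, bias: bool = True) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        self.w = np.zeros((cin, cout), dtype=np.float32)
        self.b = np.zeros(cout, dtype=np.float32) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]

    @property
    def fan_in(self) -> int:
        return self.cin

    def he_init(self, rng: np.random.Generator) -> None:
        self.w[...] = he_normal(rng, self.w.shape, self.fan_in)
        if self.b is not None:
            self.b[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ gy
        if self.b is not None:
            self.grads[1][...] = gy.sum(axis=0)
        return (gy @ self.w.T).astype(np.float32, copy=False)


class Adam:
    """Adam with optional decoupled-from-nothing classic L2 (grad += wd * param).

    ``weight_decay`` is applied only to parameters whose index appears in
    ``decay_ids`` (weight matrices, not biases) so the L2 penalty matches
    lambda/2 * ||W||^2 added to the loss.
    """

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 decay_mask: list[bool] | None = None) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.decay_mask = decay_mask if decay_mask is not None else [True] * len(params)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if self.wd and self.decay_mask[i]:
                g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction)."""
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over a batch; returns (loss, dloss/dlogits)."""
    B = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(B), labels] + eps)))
    g = p.copy()
    g[np.arange(B), labels] -= 1.0
    return loss, (g / B).astype(np.float32)


def bce_dice_loss(logits: np.ndarray, target: np.ndarray,
                  dice_weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Binary cross-entropy (on logits) plus soft-Dice; returns (loss, dlogits).

    ``logits`` and ``target`` are (B,1,H,W); the Dice term is computed per
    image on sigmoid probabilities with an additive smoothing of 1.
    """
    t = target.astype(np.float32)
    # stable BCE-with-logits
    z = logits
    bce = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    loss_bce = float(bce.mean())
    p = 1.0 / (1.0 + np.exp(-z))
    g_bce = (p - t) / z.size

    smooth = 1.0
    axes = (1, 2, 3)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2 * inter + smooth) / (denom + smooth)
    loss_dice = float(1.0 - dice.mean())
    B = z.shape[0]
    # d(1 - dice)/dp, then chain through sigmoid
    g_dice_p = -(2 * t * (denom + smooth)[:, None, None, None]
                 - (2 * inter + smooth)[:, None, None, None]) / (
        (denom + smooth) ** 2)[:, None, None, None] / B
    g_dice = g_dice_p * p * (1 - p)
    loss = loss_bce + dice_weight * loss_dice
    grad = (g_bce + dice_weight * g_dice).astype(np.float32)
    return loss, grad
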