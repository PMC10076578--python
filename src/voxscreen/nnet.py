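"""Minimal NumPy neural-network layers with explicit backpropagation.

Sized for desk-scale speaker-embedding encoders: batched time-delay (splice)
layers over (B, T, D) sequences, 2-D convolutions with ceil-mode striding
over (B, C, F, T) maps, temporal statistics pooling, affine layers, ReLU,
softmax cross-entropy and a decoupled-weight-decay Adam optimizer. Everything
is float64 and deterministic given the initialization RNG.
"""

from __future__ import annotations

import numpy as np

from voxscreen.errors import ArgumentError

STD_FLOOR = 1e-5


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []


class SpliceAffine(Layer):
    """Time-delay layer: splice frames at the given context offsets, then affine.

    Input (B, T, D) -> output (B, T - span + 1, out_dim) where span is the
    context extent max(offsets) - min(offsets) + 1 (valid frames only).
    """

    def __init__(self, contexts: list[int], in_dim: int, out_dim: int, rng: np.random.Generator):
        self.contexts = sorted(int(c) for c in contexts)
        self.in_dim = in_dim
        self.out_dim = out_dim
        fan_in = in_dim * len(self.contexts)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_dim)))
        self.b = Param(np.zeros(out_dim))

    @property
    def span(self) -> int:
        return self.contexts[-1] - self.contexts[0] + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        T_out = T - self.span + 1
        if T_out < 1:
            raise ArgumentError(f"sequence of {T} frames shorter than context span {self.span}")
        t0 = -self.contexts[0]
        spliced = np.concatenate(
            [x[:, t0 + c : t0 + c + T_out, :] for c in self.contexts], axis=2
        )
        self._x_shape = x.shape
        self._spliced = spliced
        return spliced @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, T_out, _ = grad.shape
        self.W.grad += np.tensordot(self._spliced, grad, axes=([0, 1], [0, 1]))
        self.b.grad += grad.sum(axis=(0, 1))
        d_spliced = grad @ self.W.value.T
        dx = np.zeros(self._x_shape)
        t0 = -self.contexts[0]
        for i, c in enumerate(self.contexts):
            dx[:, t0 + c : t0 + c + T_out, :] += d_spliced[
                :, :, i * self.in_dim : (i + 1) * self.in_dim
            ]
        return dx

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Affine(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


def stats_pool(frame_activations: np.ndarray) -> np.ndarray:
    """Temporal statistics pooling: concat(mean, std) over the time axis.

    Accepts (T, D) or batched (B, T, D); std is floored at 1e-5 so constant
    activations (or single frames) stay well-defined.
    """
    x = np.asarray(frame_activations, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[1] < 1:
        raise ArgumentError("stats_pool needs at least one frame")
    mean = x.mean(axis=1)
    std = np.maximum(x.std(axis=1), STD_FLOOR)
    out = np.concatenate([mean, std], axis=1)
    return out[0] if single else out


class StatsPool(Layer):
    """stats_pool as a differentiable layer over (B, T, D)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._mean = x.mean(axis=1)
        raw_std = x.std(axis=1)
        self._std = np.maximum(raw_std, STD_FLOOR)
        self._floored = raw_std <= STD_FLOOR
        return np.concatenate([self._mean, self._std], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, T, D = self._x.shape
        d_mean, d_std = grad[:, :D], grad[:, D:]
        dx = np.repeat(d_mean[:, None, :], T, axis=1) / T
        centered = self._x - self._mean[:, None, :]
        d_std_eff = np.where(self._floored, 0.0, d_std)
        dx += d_std_eff[:, None, :] * centered / (T * self._std[:, None, :])
        return dx


class Conv2D(Layer):
    """2-D convolution over (B, C, F, T) with ceil-mode 'same' striding.

    Output spatial size is ceil(in/stride); padding is distributed
    symmetrically (extra sample after), so stride-2 maps 60 -> 30 -> 15 -> 8.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k, self.s = in_ch, out_ch, kernel, stride
        fan_in = in_ch * kernel * kernel
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch))

    @staticmethod
    def out_size(n: int, stride: int) -> int:
        return -(-n // stride)  # ceil division

    def _pad_amounts(self, n: int) -> tuple[int, int]:
        n_out = self.out_size(n, self.s)
        total = max((n_out - 1) * self.s + self.k - n, 0)
        return total // 2, total - total // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        self._orig_shape = x.shape
        ph, pw = self._pad_amounts(H), self._pad_amounts(Wd)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        Ho, Wo = self.out_size(H, self.s), self.out_size(Wd, self.s)
        self._xp, self._Ho, self._Wo = xp, Ho, Wo
        y = np.zeros((B, self.out_ch, Ho, Wo))
        for i in range(self.k):
            for j in range(self.k):
                xv = xp[:, :, i : i + self.s * Ho : self.s, j : j + self.s * Wo : self.s]
                y += np.tensordot(xv, self.W.value[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
        return y + self.b.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, Ho, Wo = self._xp, self._Ho, self._Wo
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                xv = xp[:, :, i : i + self.s * Ho : self.s, j : j + self.s * Wo : self.s]
                self.W.grad[:, :, i, j] += np.tensordot(grad, xv, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i : i + self.s * Ho : self.s, j : j + self.s * Wo : self.s] += (
                    np.tensordot(grad, self.W.value[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
                )
        self.b.grad += grad.sum(axis=(0, 2, 3))
        orig_H, orig_W = self._orig_shape[2], self._orig_shape[3]
        ph = self._pad_amounts(orig_H)
        pw = self._pad_amounts(orig_W)
        return dxp[:, :, ph[0] : ph[0] + orig_H, pw[0] : pw[0] + orig_W]

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ResBlock(Layer):
    """Basic residual block: conv-relu-conv plus (projected) shortcut, relu.

    When ``stride > 1`` or the channel count changes, the shortcut is a 1x1
    stride-s convolution so the addition is dimension-consistent.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2D(in_ch, out_ch, kernel, stride, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(out_ch, out_ch, kernel, 1, rng)
        self.downsample = stride != 1 or in_ch != out_ch
        self.shortcut = Conv2D(in_ch, out_ch, 1, stride, rng) if self.downsample else None
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        sc = self.shortcut.forward(x) if self.shortcut is not None else x
        return self.relu2.forward(y + sc)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(grad)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        dx += self.shortcut.backward(g) if self.shortcut is not None else g
        return dx

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.conv2.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits. labels: int (B,)."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    B = logits.shape[0]
    loss = -float(np.mean(np.log(np.maximum(probs[np.arange(B), labels], 1e-300))))
    grad = probs.copy()
    grad[np.arange(B), labels] -= 1.0
    return loss, grad / B


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * np.square(p.grad)
            p.value -= self.lr * (
                (m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.weight_decay * p.value
            )
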