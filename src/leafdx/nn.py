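"""Minimal NumPy neural-network layers with hand-written backprop.

Conventions: image batches are NCHW float arrays; convolutions use the
cross-correlation orientation (no kernel flip) with stride fixed at 1;
downsampling is done exclusively by 2x2 average pooling. Each layer
caches what its backward pass needs during ``forward`` and accumulates
parameter gradients in ``_grads``; composite modules recurse over named
children so a whole model can be packed into one flat parameter vector
for the Adam optimizer.
"""

from __future__ import annotations

import warnings

import numpy as np


class Module:
    """Base class: parameter/gradient bookkeeping plus child recursion."""

    def __init__(self) -> None:
        self._params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}
        self._children: list[tuple[str, "Module"]] = []

    # -- parameter plumbing -------------------------------------------------
    def add_child(self, name: str, module: "Module") -> "Module":
        self._children.append((name, module))
        return module

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children:
            out.update(child.named_params(prefix + name + "."))
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._grads.items()}
        for name, child in self._children:
            out.update(child.named_grads(prefix + name + "."))
        return out

    def set_named_params(self, mapping: dict[str, np.ndarray], prefix: str = "") -> None:
        for k in list(self._params):
            self._params[k] = np.asarray(mapping[prefix + k])
        for name, child in self._children:
            child.set_named_params(mapping, prefix + name + ".")

    def zero_grads(self) -> None:
        self._grads = {k: np.zeros_like(v) for k, v in self._params.items()}
        for _, child in self._children:
            child.zero_grads()

    # -- computation --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def conv2d(x: np.ndarray, kernels: np.ndarray, biases: np.ndarray, stride: int = 1, padding: int = 0) -> np.ndarray:
    """Plain conv layer arithmetic: out[n,o] = sum_c x[n,c] (*) K[o,c] + b[o].

    ``x`` is NCHW, ``kernels`` is (out, in, kh, kw). Stride is fixed at 1;
    other values raise. Exposed as a function so it can be checked against
    a brute-force oracle independent of the Module machinery.
    """
    if stride != 1:
        raise ValueError("stride is fixed at 1 in this network family")
    x = np.asarray(x, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    biases = np.asarray(biases, dtype=float)
    if x.ndim != 4 or kernels.ndim != 4:
        raise ValueError("x must be NCHW and kernels (out, in, kh, kw)")
    if x.shape[1] != kernels.shape[1]:
        raise ValueError(f"channel mismatch: input {x.shape[1]} vs kernel {kernels.shape[1]}")
    if biases.shape != (kernels.shape[0],):
        raise ValueError("biases must have one entry per output channel")
    n, _, h, w = x.shape
    o, c, kh, kw = kernels.shape
    p = padding
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho, wo = h + 2 * p - kh + 1, w + 2 * p - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError("kernel larger than padded input")
    out = np.zeros((n, o, ho, wo))
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + ho, j : j + wo]
            out += np.tensordot(patch, kernels[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
    return out + biases[None, :, None, None]


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, ksize: int, padding: int = 0,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_ch * ksize * ksize))
        self._params["W"] = rng.normal(0.0, std, (out_ch, in_ch, ksize, ksize))
        self._params["b"] = np.zeros(out_ch)
        self.padding = padding
        self.stride = 1

    def forward(self, x, train=False):
        self._x = np.asarray(x, dtype=float)
        return conv2d(self._x, self._params["W"], self._params["b"], padding=self.padding)

    def backward(self, dout):
        W = self._params["W"]
        o, c, kh, kw = W.shape
        p = self.padding
        xp = np.pad(self._x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, _, hp, wp = xp.shape
        ho, wo = dout.shape[2], dout.shape[3]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i : i + ho, j : j + wo]
                dW[:, :, i, j] = np.tensordot(dout, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i : i + ho, j : j + wo] += np.tensordot(
                    dout, W[:, :, i, j], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self._grads["W"] = self._grads.get("W", 0) + dW
        self._grads["b"] = self._grads.get("b", 0) + dout.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, np.asarray(x))


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = np.asarray(x) > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


def avg_pool_2x2(x: np.ndarray) -> np.ndarray:
    """2x2 mean pooling with stride 2; odd trailing row/col dropped."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None, None]
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        warnings.warn("odd spatial size: trailing row/column dropped by 2x2 pooling", stacklevel=2)
    h2, w2 = h // 2, w // 2
    out = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))
    return out[0, 0] if single else out


class AvgPool2x2(Module):
    def forward(self, x, train=False):
        self._in_shape = np.asarray(x).shape
        return avg_pool_2x2(x)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._in_shape)
        dx[:, :, : 2 * h2, : 2 * w2] = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
        return dx


class GlobalAvgPool(Module):
    def forward(self, x, train=False):
        self._in_shape = np.asarray(x).shape
        return np.asarray(x, dtype=float).mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None], self._in_shape) / (h * w)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_dim)
        self._params["W"] = rng.normal(0.0, std, (in_dim, out_dim))
        self._params["b"] = np.zeros(out_dim)

    def forward(self, x, train=False):
        self._x = np.asarray(x, dtype=float)
        return self._x @ self._params["W"] + self._params["b"]

    def backward(self, dout):
        self._grads["W"] = self._grads.get("W", 0) + self._x.T @ dout
        self._grads["b"] = self._grads.get("b", 0) + dout.sum(axis=0)
        return dout @ self._params["W"].T


class Dropout(Module):
    """Inverted dropout: active only in train mode, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return np.asarray(x, dtype=float)
        self._mask = (self.rng.random(np.asarray(x).shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Module):
    def __init__(self, layers: list[Module]) -> None:
        super().__init__()
        self.layers = layers
        for i, layer in enumerate(layers):
            self.add_child(str(i), layer)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-likelihood of integer labels under ``probs``."""
    n = probs.shape[0]
    return float(-np.log(probs[np.arange(n), labels] + eps).mean())


def softmax_ce_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the pre-softmax logits."""
    n = probs.shape[0]
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return grad / n
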