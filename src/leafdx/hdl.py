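"""Hybrid CNN-LSTM classifier with coarse and fine label heads.

The trunk follows the template ``[(CONV -> RELU) * n_cr -> POOL] * n_crp``
(with ``n_cr`` capped at 5). The final feature map is read row by row as a
sequence — each spatial row, flattened over channels and columns, is one
timestep — and consumed by a single-layer LSTM. The last hidden state
(optionally concatenated with an external feature vector, e.g. from the
SqueezeNet extractor) feeds two softmax heads:

* a **coarse** head over {deficient, healthy}, and
* a **fine** head over the six nutrient classes,

arranged in parallel (default) or sequentially (the fine head also sees
the coarse probabilities). The coarse label is a deterministic function
of the fine label: fine classes 1-5 are deficient, class 6 is healthy.

LSTM gates follow the standard form: input gate i, candidate g (tanh,
no bias), forget gate f and output gate o are affine in (x_t, h_prev);
the cell state accumulates c_t = f*c_prev + i*g and h_t = o * tanh(c_t).

Training minimizes cross-entropy(fine) + lambda * cross-entropy(coarse)
with the from-scratch Adam optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .adam import AdamHyperparams, AdamOptimizer, ShapeRegistry
from . import nn

COARSE_NAMES = ("deficient", "healthy")


def coarse_of_fine(fine_id: int) -> int:
    """Coarse index (0=deficient, 1=healthy) of a fine class id in 1..6."""
    if fine_id not in range(1, 7):
        raise ValueError(f"fine class id must be in 1..6, got {fine_id}")
    return 0 if fine_id <= 5 else 1


@dataclass(frozen=True)
class HDLSpec:
    n_cr: int = 1  # CONV->RELU repetitions per block, at most 5
    n_crp: int = 3  # number of blocks (each ends in a 2x2 avg pool)
    lstm_hidden: int = 32
    coarse_classes: int = 2
    fine_classes: int = 6
    head_arrangement: str = "parallel"
    in_channels: int = 4  # masked RGB + Gabor response by default
    base_width: int = 8
    extra_feature_dim: int = 0  # appended to h_T before the heads

    def __post_init__(self) -> None:
        if not 1 <= self.n_cr <= 5:
            raise ValueError("n_cr must be in [1, 5]")
        if self.n_crp < 1:
            raise ValueError("n_crp must be >= 1")
        if self.lstm_hidden < 1:
            raise ValueError("lstm_hidden must be >= 1")
        if self.fine_classes != 6 or self.coarse_classes != 2:
            raise ValueError("this classifier is fixed at 6 fine / 2 coarse classes")
        if self.head_arrangement not in ("parallel", "sequential"):
            raise ValueError("head_arrangement must be 'parallel' or 'sequential'")


@dataclass
class LSTMWeights:
    """Gate weights: W_*x (input), W_*h (recurrent), b_* (bias; none for g)."""

    W_ix: np.ndarray
    W_ih: np.ndarray
    b_i: np.ndarray
    W_gx: np.ndarray
    W_gh: np.ndarray
    W_fx: np.ndarray
    W_fh: np.ndarray
    b_f: np.ndarray
    W_ox: np.ndarray
    W_oh: np.ndarray
    b_o: np.ndarray


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    weights: LSTMWeights,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; returns (h_t, c_t)."""
    x_t, h_prev, c_prev = (np.asarray(a, dtype=float) for a in (x_t, h_prev, c_prev))
    w = weights
    if x_t.shape[-1] != w.W_ix.shape[0] or h_prev.shape[-1] != w.W_ih.shape[0]:
        raise ValueError("input/hidden dimensions do not match the weights")
    i_t = sigmoid(x_t @ w.W_ix + h_prev @ w.W_ih + w.b_i)
    g_t = np.tanh(x_t @ w.W_gx + h_prev @ w.W_gh)
    f_t = sigmoid(x_t @ w.W_fx + h_prev @ w.W_fh + w.b_f)
    o_t = sigmoid(x_t @ w.W_ox + h_prev @ w.W_oh + w.b_o)
    c_t = f_t * c_prev + i_t * g_t
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


class LSTM(nn.Module):
    """Single-layer LSTM over (N, T, D) sequences, returning the final h_T."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        sx, sh = np.sqrt(1.0 / input_dim), np.sqrt(1.0 / hidden)
        for gate in ("i", "g", "f", "o"):
            self._params[f"W_{gate}x"] = rng.normal(0.0, sx, (input_dim, hidden))
            self._params[f"W_{gate}h"] = rng.normal(0.0, sh, (hidden, hidden))
            if gate != "g":
                self._params[f"b_{gate}"] = np.zeros(hidden)
        self.hidden = hidden

    def weights(self) -> LSTMWeights:
        p = self._params
        return LSTMWeights(
            W_ix=p["W_ix"], W_ih=p["W_ih"], b_i=p["b_i"],
            W_gx=p["W_gx"], W_gh=p["W_gh"],
            W_fx=p["W_fx"], W_fh=p["W_fh"], b_f=p["b_f"],
            W_ox=p["W_ox"], W_oh=p["W_oh"], b_o=p["b_o"],
        )

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] == 0:
            raise ValueError("LSTM input must be a non-empty (N, T, D) sequence")
        n, t, _ = x.shape
        h = np.zeros((n, self.hidden))
        c = np.zeros((n, self.hidden))
        w = self.weights()
        self._cache = []
        self._x = x
        for step in range(t):
            x_t = x[:, step]
            i_t = sigmoid(x_t @ w.W_ix + h @ w.W_ih + w.b_i)
            g_t = np.tanh(x_t @ w.W_gx + h @ w.W_gh)
            f_t = sigmoid(x_t @ w.W_fx + h @ w.W_fh + w.b_f)
            o_t = sigmoid(x_t @ w.W_ox + h @ w.W_oh + w.b_o)
            c_new = f_t * c + i_t * g_t
            tanh_c = np.tanh(c_new)
            self._cache.append((x_t, h, c, i_t, g_t, f_t, o_t, tanh_c))
            h, c = o_t * tanh_c, c_new
        return h

    def backward(self, dh_T):
        """Backprop through time from a gradient on the final hidden state."""
        x = self._x
        n, t, d = x.shape
        w = self.weights()
        for key in self._params:
            self._grads.setdefault(key, np.zeros_like(self._params[key]))
        dx = np.zeros_like(x)
        dh = np.asarray(dh_T, dtype=float)
        dc = np.zeros((n, self.hidden))
        for step in range(t - 1, -1, -1):
            x_t, h_prev, c_prev, i_t, g_t, f_t, o_t, tanh_c = self._cache[step]
            do = dh * tanh_c
            dc = dc + dh * o_t * (1.0 - tanh_c**2)
            di, dg, df = dc * g_t, dc * i_t, dc * c_prev
            dc_prev = dc * f_t
            dzi = di * i_t * (1.0 - i_t)
            dzg = dg * (1.0 - g_t**2)
            dzf = df * f_t * (1.0 - f_t)
            dzo = do * o_t * (1.0 - o_t)
            self._grads["W_ix"] += x_t.T @ dzi
            self._grads["W_gx"] += x_t.T @ dzg
            self._grads["W_fx"] += x_t.T @ dzf
            self._grads["W_ox"] += x_t.T @ dzo
            self._grads["W_ih"] += h_prev.T @ dzi
            self._grads["W_gh"] += h_prev.T @ dzg
            self._grads["W_fh"] += h_prev.T @ dzf
            self._grads["W_oh"] += h_prev.T @ dzo
            self._grads["b_i"] += dzi.sum(axis=0)
            self._grads["b_f"] += dzf.sum(axis=0)
            self._grads["b_o"] += dzo.sum(axis=0)
            dx[:, step] = dzi @ w.W_ix.T + dzg @ w.W_gx.T + dzf @ w.W_fx.T + dzo @ w.W_ox.T
            dh = dzi @ w.W_ih.T + dzg @ w.W_gh.T + dzf @ w.W_fh.T + dzo @ w.W_oh.T
            dc = dc_prev
        return dx


class HDLModel(nn.Module):
    """CNN trunk + LSTM + parallel/sequential coarse and fine heads."""

    def __init__(self, spec: HDLSpec, image_size: tuple[int, int] = (64, 64), seed: int = 0) -> None:
        super().__init__()
        self.spec = spec
        self.image_size = image_size
        self.trained = False
        self.history: list[dict] = []
        rng = np.random.default_rng(seed)
        layers: list[nn.Module] = []
        in_ch = spec.in_channels
        width = spec.base_width
        h, w = image_size
        for _ in range(spec.n_crp):
            for _ in range(spec.n_cr):
                layers.append(nn.Conv2d(in_ch, width, 3, padding=1, rng=rng))
                layers.append(nn.ReLU())
                in_ch = width
            layers.append(nn.AvgPool2x2())
            h, w = h // 2, w // 2
            width = min(width * 2, 4 * spec.base_width)
        self.trunk = self.add_child("trunk", nn.Sequential(layers))
        self.seq_len, self.seq_dim = h, in_ch * w
        self.lstm = self.add_child("lstm", LSTM(self.seq_dim, spec.lstm_hidden, rng))
        rep = spec.lstm_hidden + spec.extra_feature_dim
        self.coarse_head = self.add_child("coarse_head", nn.Linear(rep, 2, rng=rng))
        fine_in = rep + (2 if spec.head_arrangement == "sequential" else 0)
        self.fine_head = self.add_child("fine_head", nn.Linear(fine_in, 6, rng=rng))

    # -- forward/backward ---------------------------------------------------
    def _sequence(self, feature_map: np.ndarray) -> np.ndarray:
        """Rows of the final feature map as timesteps: (N,C,H,W)->(N,H,C*W)."""
        n, c, h, w = feature_map.shape
        return feature_map.transpose(0, 2, 1, 3).reshape(n, h, c * w)

    def forward_probs(
        self, images: np.ndarray, extra: np.ndarray | None = None, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:
            images = images[None]
        fmap = self.trunk.forward(images, train=train)
        self._fmap_shape = fmap.shape
        h_T = self.lstm.forward(self._sequence(fmap), train=train)
        if self.spec.extra_feature_dim:
            if extra is None:
                raise ValueError("model expects an extra feature vector")
            rep = np.concatenate([h_T, np.asarray(extra, dtype=float)], axis=1)
        else:
            rep = h_T
        self._rep_width = rep.shape[1]
        coarse_logits = self.coarse_head.forward(rep)
        p_coarse = nn.softmax(coarse_logits)
        if self.spec.head_arrangement == "sequential":
            self._fine_in = np.concatenate([rep, p_coarse], axis=1)
        else:
            self._fine_in = rep
        p_fine = nn.softmax(self.fine_head.forward(self._fine_in))
        return p_coarse, p_fine

    def backward_from_heads(self, d_coarse_logits: np.ndarray, d_fine_logits: np.ndarray) -> None:
        """Backprop both heads into the LSTM and trunk.

        In the sequential arrangement the path from the coarse
        probabilities into the fine head input is treated as a stop-
        gradient (the coarse head still learns from its own loss).
        """
        d_fine_in = self.fine_head.backward(d_fine_logits)
        d_rep = d_fine_in[:, : self._rep_width]
        d_rep = d_rep + self.coarse_head.backward(d_coarse_logits)
        dh = d_rep[:, : self.spec.lstm_hidden]
        dseq = self.lstm.backward(dh)
        n, c, h, w = self._fmap_shape
        dmap = dseq.reshape(n, h, c, w).transpose(0, 2, 1, 3)
        self.trunk.backward(dmap)


def hdl_forward(
    model: HDLModel, images: np.ndarray, extra: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode forward pass returning (coarse, fine) probability rows."""
    return model.forward_probs(images, extra=extra, train=False)


@dataclass
class TrainConfig:
    epochs: int = 25
    batch_size: int = 16
    learning_rate: float = 0.005
    coarse_loss_weight: float = 0.5
    seed: int = 0
    hyperparams: AdamHyperparams | None = None

    def adam(self) -> AdamHyperparams:
        return self.hyperparams or AdamHyperparams(alpha=self.learning_rate)


def train_hdl(
    images: np.ndarray,
    fine_labels: Sequence[int],
    spec: HDLSpec,
    config: TrainConfig = TrainConfig(),
    extra_features: np.ndarray | None = None,
    image_size: tuple[int, int] | None = None,
) -> HDLModel:
    """Train the classifier; ``fine_labels`` are class ids in 1..6.

    Loss = CE(fine) + coarse_loss_weight * CE(coarse), minimized with Adam.
    Records per-epoch {loss, accuracy} in ``model.history``.
    """
    images = np.asarray(images, dtype=float)
    fine = np.asarray(fine_labels, dtype=int)
    if images.shape[0] != fine.shape[0] or images.shape[0] == 0:
        raise ValueError("images and labels must be non-empty and aligned")
    if np.unique(fine).size < 2:
        warnings.warn("training set contains a single class", stacklevel=2)
    fine0 = fine - 1  # 0-based head indices
    coarse = np.array([coarse_of_fine(int(f)) for f in fine])
    size = image_size or images.shape[2:]
    model = HDLModel(spec, image_size=tuple(size), seed=config.seed)

    registry = ShapeRegistry.of(model.named_params())
    theta = registry.pack(model.named_params())
    opt = AdamOptimizer(theta.shape, config.adam())
    rng = np.random.default_rng(config.seed)
    n = images.shape[0]
    lam = config.coarse_loss_weight
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            extra = extra_features[idx] if extra_features is not None else None
            model.zero_grads()
            p_coarse, p_fine = model.forward_probs(images[idx], extra=extra, train=True)
            loss = nn.cross_entropy(p_fine, fine0[idx]) + lam * nn.cross_entropy(p_coarse, coarse[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            losses.append(loss)
            correct += int((np.argmax(p_fine, axis=1) == fine0[idx]).sum())
            d_fine = nn.softmax_ce_grad(p_fine, fine0[idx])
            d_coarse = lam * nn.softmax_ce_grad(p_coarse, coarse[idx])
            model.backward_from_heads(d_coarse, d_fine)
            grads = registry.pack(model.named_grads())
            theta = opt.update(theta, grads)
            model.set_named_params(registry.unpack(theta))
        model.history.append({"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n})
    model.trained = True
    return model


def predict(
    images: np.ndarray,
    model: HDLModel,
    extra_features: np.ndarray | None = None,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict (fine ids 1..6, coarse ids 0/1, fine probability table)."""
    if not model.trained:
        raise ValueError("model has not been trained")
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    fine_ids, coarse_ids, probs = [], [], []
    for start in range(0, images.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        extra = extra_features[sl] if extra_features is not None else None
        p_coarse, p_fine = model.forward_probs(images[sl], extra=extra, train=False)
        fine_ids.append(np.argmax(p_fine, axis=1) + 1)
        coarse_ids.append(np.argmax(p_coarse, axis=1))
        probs.append(p_fine)
    return np.concatenate(fine_ids), np.concatenate(coarse_ids), np.vstack(probs)
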