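"""From-scratch Adam optimizer with bias-corrected moment estimates.

The update, per step i on parameters theta with gradient g:

    m <- beta1*m + (1-beta1)*g
    v <- beta2*v + (1-beta2)*g^2
    m_hat = m / (1 - beta1^i)
    v_hat = v / (1 - beta2^i)
    theta <- theta - alpha * m_hat / (sqrt(v_hat) + eta)

``eta`` is the small denominator offset added *after* the square root.
Defaults: alpha=0.001, beta1=0.9, beta2=0.999, eta=1e-8.

The optimizer operates on flat parameter vectors; :class:`ShapeRegistry`
packs and unpacks named arrays so the same code trains both the feature
extractor and the CNN-LSTM classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class AdamHyperparams:
    alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eta: float = 1e-8

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if not 0.0 <= self.beta1 < 1.0:
            raise ValueError("beta1 must be in [0, 1)")
        if not 0.0 <= self.beta2 < 1.0:
            raise ValueError("beta2 must be in [0, 1)")


@dataclass
class AdamState:
    m: np.ndarray
    v: np.ndarray
    step: int = 0


def adam_init(param_shape: tuple[int, ...] | int, hyperparams: AdamHyperparams = AdamHyperparams()) -> AdamState:
    """Zero-initialized moment vectors, step 0."""
    _ = hyperparams  # validated on construction
    return AdamState(m=np.zeros(param_shape), v=np.zeros(param_shape), step=0)


def adam_step(
    state: AdamState,
    params: np.ndarray,
    gradient: np.ndarray,
    hyperparams: AdamHyperparams = AdamHyperparams(),
) -> tuple[AdamState, np.ndarray]:
    """One bias-corrected update; returns new (state, params) without mutation."""
    gradient = np.asarray(gradient, dtype=float)
    params = np.asarray(params, dtype=float)
    if gradient.shape != params.shape or gradient.shape != state.m.shape:
        raise ValueError("parameter, gradient and state shapes must agree")
    if not np.all(np.isfinite(gradient)):
        raise ValueError("non-finite gradient")
    hp = hyperparams
    i = state.step + 1
    m = hp.beta1 * state.m + (1.0 - hp.beta1) * gradient
    v = hp.beta2 * state.v + (1.0 - hp.beta2) * gradient**2
    m_hat = m / (1.0 - hp.beta1**i)
    v_hat = v / (1.0 - hp.beta2**i)
    new_params = params - hp.alpha * m_hat / (np.sqrt(v_hat) + hp.eta)
    return AdamState(m=m, v=v, step=i), new_params


def minimize(
    grad_fn,
    theta0: np.ndarray,
    steps: int,
    hyperparams: AdamHyperparams = AdamHyperparams(),
    gtol: float | None = None,
) -> np.ndarray:
    """Run Adam for a fixed step budget (optionally stop on gradient norm)."""
    theta = np.asarray(theta0, dtype=float).copy()
    state = adam_init(theta.shape, hyperparams)
    for _ in range(steps):
        g = np.asarray(grad_fn(theta), dtype=float)
        if gtol is not None and np.linalg.norm(g) < gtol:
            break
        state, theta = adam_step(state, theta, g, hyperparams)
    return theta


def save_state(path: str | Path, state: AdamState) -> None:
    np.savez(path, m=state.m, v=state.v, step=np.array(state.step))


def load_state(path: str | Path) -> AdamState:
    with np.load(path) as z:
        return AdamState(m=z["m"].copy(), v=z["v"].copy(), step=int(z["step"]))


@dataclass
class ShapeRegistry:
    """Maps named parameter arrays to one flat vector and back."""

    names: list[str] = field(default_factory=list)
    shapes: list[tuple[int, ...]] = field(default_factory=list)

    @classmethod
    def of(cls, params: dict[str, np.ndarray]) -> "ShapeRegistry":
        return cls(names=list(params), shapes=[params[n].shape for n in params])

    @property
    def size(self) -> int:
        return int(sum(np.prod(s, dtype=int) for s in self.shapes))

    def pack(self, params: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([np.asarray(params[n], dtype=float).ravel() for n in self.names])

    def unpack(self, flat: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        pos = 0
        for name, shape in zip(self.names, self.shapes):
            size = int(np.prod(shape, dtype=int))
            out[name] = flat[pos : pos + size].reshape(shape)
            pos += size
        return out


class AdamOptimizer:
    """Stateful convenience wrapper over the functional update."""

    def __init__(self, param_shape, hyperparams: AdamHyperparams = AdamHyperparams()):
        self.hyperparams = hyperparams
        self.state = adam_init(param_shape, hyperparams)

    def update(self, params: np.ndarray, gradient: np.ndarray) -> np.ndarray:
        self.state, params = adam_step(self.state, params, gradient, self.hyperparams)
        return params
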