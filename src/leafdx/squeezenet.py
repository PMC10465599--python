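"""Compact SqueezeNet-style feature extractor.

The network keeps every convolution at stride 1 and defers all
downsampling to 2x2 average pooling, so the activation maps stay large
for as long as possible. Its body is four *fire modules* — a 1x1
"squeeze" convolution feeding parallel 1x1 and 3x3 "expand" convolutions
whose outputs are concatenated — followed by a deep convolution with an
enlarged 5x5 filter, dropout, global average pooling and a linear feature
head.

Layer/connection bookkeeping
----------------------------
``NetworkSpec.layer_count`` counts the nodes of the computation graph,
including the input node and, for each fire module, its seven nodes
(three convolutions, their three ReLUs, and the channel concatenation).
``connection_count`` counts graph edges: a chain of L nodes has L-1
edges, and each fire module contributes one extra edge for its second
parallel expand branch. Under this convention the default build has 39
layers and 42 connections.

Training the extractor attaches a temporary 6-way softmax head, minimizes
cross-entropy with the from-scratch Adam optimizer, and then drops the
head; no pretrained weights are involved (a weight-loading hook is
provided instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adam import AdamHyperparams, AdamOptimizer, ShapeRegistry
from . import nn


@dataclass(frozen=True)
class FireModuleSpec:
    """Squeeze/expand filter counts; output channels = e1x1 + e3x3."""

    s1x1: int
    e1x1: int
    e3x3: int

    def __post_init__(self) -> None:
        if min(self.s1x1, self.e1x1, self.e3x3) < 1:
            raise ValueError("filter counts must be positive")
        if self.s1x1 > self.e1x1 + self.e3x3:
            raise ValueError("squeeze width must not exceed total expand width")

    @property
    def out_channels(self) -> int:
        return self.e1x1 + self.e3x3


class Fire(nn.Module):
    """squeeze(1x1)+ReLU -> [expand(1x1)+ReLU || expand(3x3, pad 1)+ReLU] -> concat."""

    def __init__(self, in_ch: int, spec: FireModuleSpec, rng: np.random.Generator) -> None:
        super().__init__()
        self.spec = spec
        self.conv_s = self.add_child("squeeze", nn.Conv2d(in_ch, spec.s1x1, 1, rng=rng))
        self.conv_e1 = self.add_child("expand1", nn.Conv2d(spec.s1x1, spec.e1x1, 1, rng=rng))
        self.conv_e3 = self.add_child("expand3", nn.Conv2d(spec.s1x1, spec.e3x3, 3, padding=1, rng=rng))
        self.relu_s, self.relu_e1, self.relu_e3 = nn.ReLU(), nn.ReLU(), nn.ReLU()

    def forward(self, x, train=False):
        s = self.relu_s.forward(self.conv_s.forward(x))
        a = self.relu_e1.forward(self.conv_e1.forward(s))
        b = self.relu_e3.forward(self.conv_e3.forward(s))
        return np.concatenate([a, b], axis=1)

    def backward(self, dout):
        k = self.spec.e1x1
        da, db = dout[:, :k], dout[:, k:]
        ds = self.conv_e1.backward(self.relu_e1.backward(da))
        ds = ds + self.conv_e3.backward(self.relu_e3.backward(db))
        return self.conv_s.backward(self.relu_s.backward(ds))


@dataclass
class NetworkSpec:
    """Ordered layer descriptors plus the documented graph bookkeeping."""

    nodes: list[dict] = field(default_factory=list)
    feature_dim: int = 32

    @property
    def layer_count(self) -> int:
        total = 0
        for node in self.nodes:
            total += 7 if node["kind"] == "fire" else 1
        return total

    @property
    def connection_count(self) -> int:
        n_fire = sum(1 for node in self.nodes if node["kind"] == "fire")
        return self.layer_count - 1 + n_fire

    @property
    def fire_count(self) -> int:
        return sum(1 for node in self.nodes if node["kind"] == "fire")

    @property
    def conv_strides(self) -> list[int]:
        out = []
        for node in self.nodes:
            if node["kind"] == "conv":
                out.append(node["stride"])
            elif node["kind"] == "fire":
                out.extend([1, 1, 1])  # squeeze + both expands
        return out

    @property
    def dropout_count(self) -> int:
        return sum(1 for node in self.nodes if node["kind"] == "dropout")


class SqueezeNetFeatures(nn.Module):
    """The assembled extractor: ``net`` maps NCHW images to feature vectors."""

    def __init__(self, spec: NetworkSpec, net: nn.Sequential) -> None:
        super().__init__()
        self.spec = spec
        self.net = self.add_child("net", net)

    def forward(self, x, train=False):
        return self.net.forward(x, train=train)

    def backward(self, dout):
        return self.net.backward(dout)


def build_modified_squeezenet(
    feature_dim: int = 32,
    dropout_rate: float = 0.5,
    in_channels: int = 3,
    base_width: int = 8,
    seed: int = 0,
) -> SqueezeNetFeatures:
    """Build the default four-fire, stride-1 topology (39 layers, 42 connections).

    input -> conv3x3 + relu + pool -> fire -> pool -> fire -> fire -> pool
          -> fire -> conv5x5 + relu -> dropout -> global avg pool -> linear
    """
    if feature_dim < 1:
        raise ValueError("feature_dim must be >= 1")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    c = base_width
    fire_spec = FireModuleSpec(s1x1=max(c // 2, 1), e1x1=c // 2, e3x3=c - c // 2)
    deep_ch = 2 * c

    nodes = [
        {"kind": "input"},
        {"kind": "conv", "ksize": 3, "stride": 1, "out": c},
        {"kind": "relu"},
        {"kind": "avgpool"},
        {"kind": "fire", "spec": fire_spec},
        {"kind": "avgpool"},
        {"kind": "fire", "spec": fire_spec},
        {"kind": "fire", "spec": fire_spec},
        {"kind": "avgpool"},
        {"kind": "fire", "spec": fire_spec},
        {"kind": "conv", "ksize": 5, "stride": 1, "out": deep_ch},
        {"kind": "relu"},
        {"kind": "dropout", "rate": dropout_rate},
        {"kind": "globalpool"},
        {"kind": "linear", "out": feature_dim},
    ]
    spec = NetworkSpec(nodes=nodes, feature_dim=feature_dim)

    layers: list[nn.Module] = [
        nn.Conv2d(in_channels, c, 3, padding=1, rng=rng),
        nn.ReLU(),
        nn.AvgPool2x2(),
        Fire(c, fire_spec, rng),
        nn.AvgPool2x2(),
        Fire(fire_spec.out_channels, fire_spec, rng),
        Fire(fire_spec.out_channels, fire_spec, rng),
        nn.AvgPool2x2(),
        Fire(fire_spec.out_channels, fire_spec, rng),
        nn.Conv2d(fire_spec.out_channels, deep_ch, 5, padding=2, rng=rng),
        nn.ReLU(),
        nn.Dropout(dropout_rate, rng=np.random.default_rng(rng.integers(2**31))),
        nn.GlobalAvgPool(),
        nn.Linear(deep_ch, feature_dim, rng=rng),
    ]
    return SqueezeNetFeatures(spec=spec, net=nn.Sequential(layers))


def extract_features(images: np.ndarray, network: SqueezeNetFeatures, train_mode: bool = False) -> np.ndarray:
    """Feature vectors for an NCHW batch (deterministic when eval mode)."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    return network.forward(images, train=train_mode)


def train_feature_extractor(
    network: SqueezeNetFeatures,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int = 5,
    batch_size: int = 16,
    hyperparams: AdamHyperparams = AdamHyperparams(alpha=0.003),
    n_classes: int = 6,
    seed: int = 0,
) -> list[float]:
    """Fit the extractor through a temporary softmax head, then drop the head.

    Returns the per-epoch mean cross-entropy history.
    """
    rng = np.random.default_rng(seed)
    head = nn.Linear(network.spec.feature_dim, n_classes, rng=rng)

    class _WithHead(nn.Module):
        def __init__(self):
            super().__init__()
            self.body = self.add_child("body", network)
            self.head = self.add_child("head", head)

    model = _WithHead()
    registry = ShapeRegistry.of(model.named_params())
    theta = registry.pack(model.named_params())
    opt = AdamOptimizer(theta.shape, hyperparams)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            model.zero_grads()
            feats = network.forward(images[idx], train=True)
            probs = nn.softmax(head.forward(feats))
            losses.append(nn.cross_entropy(probs, labels[idx]))
            dfeat = head.backward(nn.softmax_ce_grad(probs, labels[idx]))
            network.backward(dfeat)
            grads = registry.pack(model.named_grads())
            theta = opt.update(theta, grads)
            model.set_named_params(registry.unpack(theta))
        history.append(float(np.mean(losses)))
    return history


def save_weights(path: str | Path, module: nn.Module) -> None:
    """Checkpoint: one archive keyed by layer-qualified parameter names."""
    np.savez(path, **module.named_params())


def load_weights(path: str | Path, module: nn.Module) -> None:
    with np.load(path) as z:
        module.set_named_params({k: z[k].copy() for k in z.files})
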