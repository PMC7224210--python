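"""Multi-scale CNN comparator matched to the capsule pipeline.

Per scale: conv (kernel 9, stride 1) -> ReLU -> conv (kernel 9, stride 2)
-> ReLU -> fully connected 32 -> ReLU -> softmax over 2 classes. The three
networks are trained independently with cross-entropy; their 32-node
penultimate layers are then concatenated (3 x 32 = 96) and passed through
the same fully connected fusion stack as the capsule model, so any metric
difference against the capsule pipeline is attributable to the model and
not to the data path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, Conv2d, Dense, ReLU, softmax
from .containers import Patch3D
from .errors import ShapeError
from .fusion import FusionNet, FusionSpec, WeightedBCEParams, train_fusion


@dataclass(frozen=True)
class BaselineSpec:
    """One single-scale comparator CNN."""

    input_size: int = 80
    in_channels: int = 3
    conv_maps: int = 256
    kernel: int = 9
    fc_dim: int = 32         # matches the 2 x 16 capsule output per scale
    n_classes: int = 2

    def grid_sizes(self) -> tuple[int, int]:
        h1 = self.input_size - self.kernel + 1
        h2 = (h1 - self.kernel) // 2 + 1
        if h2 < 1:
            raise ValueError("input too small for two kernel-9 convolutions")
        return h1, h2


TINY_BASELINE = BaselineSpec(input_size=40, conv_maps=8)


class BaselineCNN:
    """Single-scale comparator CNN with a 32-dim penultimate feature layer."""

    def __init__(self, spec: BaselineSpec = BaselineSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        _, h2 = s.grid_sizes()
        self.conv1 = Conv2d(s.in_channels, s.conv_maps, s.kernel, 1, rng)
        self.conv2 = Conv2d(s.conv_maps, s.conv_maps, s.kernel, 2, rng)
        self.fc = Dense(s.conv_maps * h2 * h2, s.fc_dim, rng)
        self.head = Dense(s.fc_dim, s.n_classes, rng)
        self.relus = [ReLU(), ReLU(), ReLU()]
        self.loss_trace: list[float] = []
        self.trained = False
        self._flat_shape: tuple | None = None

    @property
    def params(self):
        return self.conv1.params + self.conv2.params + self.fc.params + self.head.params

    def forward_batch(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(B, C, H, W) -> (32-dim features (B, 32), probabilities (B, 2))."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        s = self.spec
        if x.shape[1:] != (s.in_channels, s.input_size, s.input_size):
            raise ShapeError(
                f"expected patches of shape {(s.in_channels, s.input_size, s.input_size)}, "
                f"got {x.shape[1:]}"
            )
        h = self.relus[0].forward(self.conv1.forward(x))
        h = self.relus[1].forward(self.conv2.forward(h))
        self._flat_shape = h.shape
        flat = h.reshape(len(x), -1)
        feat = self.relus[2].forward(self.fc.forward(flat))
        probs = softmax(self.head.forward(feat), axis=-1)
        return feat, probs

    def backward_logits(self, dz: np.ndarray) -> None:
        d = self.relus[2].backward(self.head.backward(dz))
        d = self.fc.backward(d).reshape(self._flat_shape)
        d = self.conv2.backward(self.relus[1].backward(d))
        self.conv1.backward(self.relus[0].backward(d))


def forward_baseline(patch: Patch3D | np.ndarray, network: BaselineCNN) -> tuple[np.ndarray, np.ndarray]:
    """One patch -> (penultimate 32-vector, softmax probabilities)."""
    x = patch.values if isinstance(patch, Patch3D) else np.asarray(patch, dtype=float)
    feat, probs = network.forward_batch(x[None] if x.ndim == 3 else x)
    return feat[0], probs[0]


def train_baseline_scale(
    patches: np.ndarray,
    labels: np.ndarray,
    spec: BaselineSpec = TINY_BASELINE,
    *,
    epochs: int = 30,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
) -> BaselineCNN:
    """Train one comparator CNN with softmax cross-entropy."""
    x = np.asarray(patches, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 4 or len(x) != len(y) or len(x) == 0:
        raise ValueError("need a non-empty (N, C, H, W) patch array with matching labels")
    net = BaselineCNN(spec, seed=seed)
    opt = Adam(net.params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    onehot = np.eye(spec.n_classes)[y]
    for _ in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            _, probs = net.forward_batch(x[idx])
            p = np.clip(probs, 1e-12, None)
            losses.append(float(-np.mean(np.sum(onehot[idx] * np.log(p), axis=1))))
            net.backward_logits((probs - onehot[idx]) / len(idx))
            opt.step()
        net.loss_trace.append(float(np.mean(losses)))
    net.trained = True
    return net


class BaselineModel:
    """Three trained per-scale CNNs plus the fusion stack over 96 features."""

    def __init__(self, scale_nets: tuple[BaselineCNN, BaselineCNN, BaselineCNN],
                 fusion_net: FusionNet):
        self.scale_nets = tuple(scale_nets)
        self.fusion_net = fusion_net

    def fused_features(self, batches: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        feats = [net.forward_batch(b)[0] for net, b in zip(self.scale_nets, batches)]
        return np.concatenate(feats, axis=1)

    def predict_proba(self, batches: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        if not all(n.trained for n in self.scale_nets) or not self.fusion_net.trained:
            raise RuntimeError("all scale CNNs and the fusion network must be trained")
        return self.fusion_net.forward_batch(self.fused_features(batches))


def train_baseline(
    scale_batches: tuple[np.ndarray, np.ndarray, np.ndarray],
    labels: np.ndarray,
    spec: BaselineSpec = TINY_BASELINE,
    fusion_spec: FusionSpec | None = None,
    *,
    epochs: int = 30,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
) -> BaselineModel:
    """Train the three per-scale CNNs independently, then the fusion stack."""
    nets = tuple(
        train_baseline_scale(
            b, labels, spec, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed + i
        )
        for i, b in enumerate(scale_batches)
    )
    feats = np.concatenate([n.forward_batch(b)[0] for n, b in zip(nets, scale_batches)], axis=1)
    fspec = fusion_spec or FusionSpec(input_dim=feats.shape[1], hidden_sizes=(64, 32))
    fnet = train_fusion(
        feats, labels, WeightedBCEParams(), fspec,
        epochs=max(epochs * 3, 100), batch_size=batch_size, lr=lr, seed=seed + 7,
    )
    return BaselineModel(nets, fnet)
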