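"""Masking, concatenation and the multi-scale fusion network.

The three single-scale capsule networks each emit two 16-dimensional class
capsules. Per scale, the capsule of the *lower*-norm (lower probability)
class is masked to zero and the two blocks are concatenated, giving a
32-vector per scale and a 96-vector across the three scales. That vector is
passed through a fully connected stack (hidden sizes 1028/512/256 by
default) ending in a two-class softmax, trained with a class-weighted
binary cross-entropy

    loss = -(alpha * y * log p + beta * (1 - y) * log(1 - p))

where ``p`` is the predicted probability of the malignant class. ``alpha``
weights the malignant-class (y=1) term — raising it punishes missed
malignancies and trades specificity for sensitivity; ``beta`` weights the
benign-class term and trades the other way. ``alpha = beta = 1`` is plain
binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, Dense, ReLU, softmax
from .capsule import CapsuleActivations, SingleScaleCapsNet
from .containers import MultiScalePatch
from .errors import ShapeError


@dataclass(frozen=True)
class FusionSpec:
    """Fully connected fusion stack over the 96-dim masked concatenation."""

    input_dim: int = 96
    hidden_sizes: tuple[int, ...] = (1028, 512, 256)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


TINY_FUSION = FusionSpec(hidden_sizes=(64, 32))


@dataclass(frozen=True)
class WeightedBCEParams:
    alpha: float = 1.0   # weight on the malignant-class (y=1) term
    beta: float = 1.0    # weight on the benign-class (y=0) term

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


_P_CLIP = 1e-7


def weighted_bce(y: int, p: float, params: WeightedBCEParams = WeightedBCEParams()) -> float:
    """Class-weighted binary cross-entropy for one (target, probability) pair."""
    if y not in (0, 1):
        raise ValueError("y must be 0 or 1")
    p = float(np.clip(p, _P_CLIP, 1.0 - _P_CLIP))
    return float(-(params.alpha * y * np.log(p) + params.beta * (1 - y) * np.log(1.0 - p)))


def _mask_block(v: np.ndarray) -> np.ndarray:
    """Zero the lower-norm class block of (B, 2, d) activations.

    On an exact tie, class 0 is masked (deterministic tie-break).
    """
    n = np.linalg.norm(v, axis=-1)           # (B, 2)
    mask_idx = np.where(n[:, 0] <= n[:, 1], 0, 1)
    out = v.copy()
    out[np.arange(len(v)), mask_idx] = 0.0
    return out


def mask_and_concat(
    acts1: CapsuleActivations, acts2: CapsuleActivations, acts3: CapsuleActivations
) -> np.ndarray:
    """Mask each scale's lower-probability capsule and concatenate to 96 dims."""
    blocks = []
    for acts in (acts1, acts2, acts3):
        v = acts.vectors
        if v.ndim != 2 or v.shape[0] != 2:
            raise ShapeError(f"expected 2 class capsules per scale, got shape {v.shape}")
        blocks.append(_mask_block(v[None])[0].reshape(-1))
    return np.concatenate(blocks)


def mask_and_concat_batch(v1: np.ndarray, v2: np.ndarray, v3: np.ndarray) -> np.ndarray:
    """Batched masking/concatenation: three (B, 2, d) -> (B, 6d)."""
    return np.concatenate(
        [_mask_block(v).reshape(len(v), -1) for v in (v1, v2, v3)], axis=1
    )


class FusionNet:
    """Fully connected softmax classifier over fused capsule vectors."""

    def __init__(self, spec: FusionSpec = FusionSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        sizes = (spec.input_dim,) + tuple(spec.hidden_sizes) + (spec.n_classes,)
        self.layers: list = []
        for i in range(len(sizes) - 1):
            self.layers.append(Dense(sizes[i], sizes[i + 1], rng))
            if i < len(sizes) - 2:
                self.layers.append(ReLU())
        self.loss_trace: list[float] = []
        self.trained = False

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def logits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None]
        if x.shape[1] != self.spec.input_dim:
            raise ShapeError(
                f"fused vectors have dim {x.shape[1]}, spec expects {self.spec.input_dim}"
            )
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """(B, 96) -> class probabilities (B, 2), rows summing to 1."""
        return softmax(self.logits(x), axis=-1)

    def backward_logits(self, dz: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dz = layer.backward(dz)


def fusion_forward(fused: np.ndarray, net: FusionNet) -> tuple[float, float]:
    """One fused 96-vector -> (p_benign, p_malignant)."""
    p = net.forward_batch(np.asarray(fused, dtype=float)[None])[0]
    return float(p[0]), float(p[1])


def train_fusion(
    fused_train: np.ndarray,
    labels: np.ndarray,
    params: WeightedBCEParams = WeightedBCEParams(),
    spec: FusionSpec = FusionSpec(),
    *,
    epochs: int = 150,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
) -> FusionNet:
    """Train the fusion stack by Adam on the weighted binary cross-entropy."""
    x = np.asarray(fused_train, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or len(x) == 0 or len(x) != len(y):
        raise ValueError("need a non-empty (N, input_dim) array with matching labels")
    net = FusionNet(spec, seed=seed)
    opt = Adam(net.params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            yb = y[idx]
            opt.zero_grad()
            probs = net.forward_batch(x[idx])
            p1 = np.clip(probs[:, 1], _P_CLIP, 1.0 - _P_CLIP)
            loss = float(
                np.mean(
                    -(params.alpha * yb * np.log(p1)
                      + params.beta * (1 - yb) * np.log(1.0 - p1))
                )
            )
            # gradient of the weighted BCE through the two-class softmax
            dz1 = (-params.alpha * yb * (1.0 - p1) + params.beta * (1 - yb) * p1) / len(idx)
            net.backward_logits(np.stack([-dz1, dz1], axis=1))
            opt.step()
            losses.append(loss)
        net.loss_trace.append(float(np.mean(losses)))
    net.trained = True
    return net


# ---------------------------------------------------------------------------
# whole-model prediction

class MultiScaleModel:
    """Three trained single-scale capsule nets plus the trained fusion net."""

    def __init__(
        self,
        scale_nets: tuple[SingleScaleCapsNet, SingleScaleCapsNet, SingleScaleCapsNet],
        fusion_net: FusionNet,
    ):
        self.scale_nets = tuple(scale_nets)
        self.fusion_net = fusion_net

    def _require_trained(self) -> None:
        if not all(n.trained for n in self.scale_nets) or not self.fusion_net.trained:
            raise RuntimeError("all scale networks and the fusion network must be trained")

    def fused_features(self, batches: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        """Per-scale patch batches (B, C, H, W) -> masked fused vectors (B, 96)."""
        vs = [net.forward_batch(b) for net, b in zip(self.scale_nets, batches)]
        return mask_and_concat_batch(*vs)

    def predict_proba(self, batches: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        self._require_trained()
        return self.fusion_net.forward_batch(self.fused_features(batches))

    def predict_nodule(self, patch: MultiScalePatch) -> tuple[int, float]:
        """(predicted label, confidence = probability of the output class)."""
        self._require_trained()
        batches = tuple(p.values[None] for p in patch.patches)
        probs = self.predict_proba(batches)[0]
        label = int(np.argmax(probs))
        return label, float(probs[label])


def save_fusion(net: FusionNet, path: str) -> None:
    import json
    from dataclasses import asdict

    header = dict(kind="fusion", spec=asdict(net.spec), loss_trace=net.loss_trace)
    header["spec"]["hidden_sizes"] = list(header["spec"]["hidden_sizes"])
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **{f"p{i}": p.value for i, p in enumerate(net.params)},
    )


def load_fusion(path: str) -> FusionNet:
    import json

    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        spec_dict = header["spec"]
        spec_dict["hidden_sizes"] = tuple(spec_dict["hidden_sizes"])
        net = FusionNet(FusionSpec(**spec_dict))
        for i, p in enumerate(net.params):
            p.value[...] = data[f"p{i}"]
    net.loss_trace = list(header.get("loss_trace", []))
    net.trained = True
    return net


def predict_nodule(
    patch: MultiScalePatch,
    scale_nets: tuple[SingleScaleCapsNet, SingleScaleCapsNet, SingleScaleCapsNet],
    fusion_net: FusionNet,
) -> tuple[int, float]:
    """Functional form of :meth:`MultiScaleModel.predict_nodule`."""
    return MultiScaleModel(scale_nets, fusion_net).predict_nodule(patch)
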