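"""Capsule layers, routing by agreement, margin loss, and the single-scale net.

A capsule is a vector-valued unit: its norm encodes the probability that an
entity is present and its direction encodes instantiation parameters. Each
lower capsule ``i`` casts a vote for upper capsule ``j`` via a learned linear
map, ``u_hat[j|i] = W[i,j] @ u[i]``. Routing by agreement then iterates

    c[i,:] = softmax(b[i,:])            # coupling coefficients over j
    s[j]   = sum_i c[i,j] * u_hat[j|i]  # weighted vote aggregate
    v[j]   = squash(s[j])               # norm-limited output
    b[i,j] += v[j] . u_hat[j|i]         # agreement update

with the log-priors ``b`` reset to zero at each forward pass. The squash
nonlinearity is ``v = (|s|^2 / (1 + |s|^2)) * s / |s|``, keeping every
capsule norm strictly below 1.

The classification head is trained with the per-class margin loss

    l_k = T_k * max(0, m+ - |v_k|)^2 + lambda * (1 - T_k) * max(0, |v_k| - m-)^2

which pushes the present class's norm above ``m+`` and absent classes below
``m-``. During backpropagation the coupling coefficients are treated as
constants of the forward pass (the standard practice for trained routing).

The single-scale network is: 2D convolution (the 3 axial slices enter as
input channels) -> ReLU -> a second convolution whose channels are grouped
into 8-dimensional primary capsules -> squash -> one routed capsule layer
onto 2 class capsules of dimension 16.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, Conv2d, Param, glorot
from .containers import Patch3D
from .errors import ShapeError


# ---------------------------------------------------------------------------
# squash

def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Norm-limiting nonlinearity: same direction, norm |s|^2 / (1 + |s|^2)."""
    s = np.asarray(s, dtype=float)
    r2 = np.sum(s * s, axis=axis, keepdims=True)
    return s * (np.sqrt(r2) / (1.0 + r2))


def _squash_backward(dv: np.ndarray, s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vector-Jacobian product of squash at s, applied to dv."""
    r2 = np.sum(s * s, axis=axis, keepdims=True)
    r = np.sqrt(r2)
    g = r / (1.0 + r2)
    gp = (1.0 - r2) / (1.0 + r2) ** 2
    sdv = np.sum(s * dv, axis=axis, keepdims=True)
    coef = np.divide(gp, r, out=np.zeros_like(r), where=r > 1e-12)
    return g * dv + coef * sdv * s


# ---------------------------------------------------------------------------
# capsule layer primitives

@dataclass
class CapsuleLayerSpec:
    """A fully connected capsule layer: n_in capsules of d_in -> n_out of d_out."""

    n_in: int
    d_in: int
    n_out: int
    d_out: int
    W: np.ndarray | None = None          # (n_in, n_out, d_out, d_in)
    routing_iters: int = 3

    def __post_init__(self) -> None:
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.W is None:
            self.W = np.zeros((self.n_in, self.n_out, self.d_out, self.d_in))
        self.W = np.asarray(self.W, dtype=float)
        expected = (self.n_in, self.n_out, self.d_out, self.d_in)
        if self.W.shape != expected:
            raise ShapeError(f"W has shape {self.W.shape}, expected {expected}")


@dataclass
class RoutingState:
    """Final log-priors b, coupling coefficients c, and agreements a."""

    b: np.ndarray   # (n_in, n_out)
    c: np.ndarray   # (n_in, n_out), rows sum to 1
    a: np.ndarray   # (n_in, n_out)


@dataclass
class CapsuleActivations:
    """Output capsule vectors, one row per class; norms encode probability."""

    vectors: np.ndarray  # (n_caps, d)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.norms))


def compute_votes(u: CapsuleActivations | np.ndarray, spec: CapsuleLayerSpec) -> np.ndarray:
    """Votes u_hat[i, j] = W[i, j] @ u[i], shape (n_in, n_out, d_out)."""
    uv = u.vectors if isinstance(u, CapsuleActivations) else np.asarray(u, dtype=float)
    if uv.shape != (spec.n_in, spec.d_in):
        raise ShapeError(
            f"lower capsules have shape {uv.shape}, spec expects ({spec.n_in}, {spec.d_in})"
        )
    return np.einsum("ijdk,ik->ijd", spec.W, uv)


def _softmax_rows(b: np.ndarray) -> np.ndarray:
    e = np.exp(b - b.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def dynamic_route(votes: np.ndarray, iters: int = 3) -> tuple[CapsuleActivations, RoutingState]:
    """Routing by agreement over votes of shape (n_in, n_out, d_out).

    The log-priors start at zero; each round computes couplings by a softmax
    over upper capsules, aggregates and squashes, then adds the agreement
    (inner product of output and vote) back onto the log-priors. Fully
    deterministic.
    """
    if iters < 1:
        raise ValueError("routing requires at least one iteration")
    votes = np.asarray(votes, dtype=float)
    if votes.ndim != 3:
        raise ShapeError("votes must have shape (n_in, n_out, d_out)")
    n_in, n_out, _ = votes.shape
    b = np.zeros((n_in, n_out))
    c = a = None
    for _ in range(iters):
        c = _softmax_rows(b)
        s = np.einsum("ij,ijd->jd", c, votes)
        v = squash(s)
        a = np.einsum("jd,ijd->ij", v, votes)
        b = b + a
    return CapsuleActivations(v), RoutingState(b=b, c=c, a=a)


def _route_batch(votes: np.ndarray, iters: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched routing: votes (B, n_in, n_out, d) -> (s, v, c)."""
    bsz, n_in, n_out, _ = votes.shape
    b = np.zeros((bsz, n_in, n_out))
    for _ in range(iters):
        c = _softmax_rows(b)
        s = np.einsum("bij,bijd->bjd", c, votes)
        v = squash(s)
        b = b + np.einsum("bjd,bijd->bij", v, votes)
    return s, v, c


# ---------------------------------------------------------------------------
# margin loss

@dataclass(frozen=True)
class MarginLossParams:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.m_minus < self.m_plus < 1) or self.lam <= 0:
            raise ValueError("need 0 < m_minus < m_plus < 1 and lam > 0")


def margin_loss(
    activations: CapsuleActivations | np.ndarray,
    targets: np.ndarray,
    params: MarginLossParams = MarginLossParams(),
) -> float:
    """Sum over classes of the margin loss for one sample's class capsules."""
    acts = (
        activations if isinstance(activations, CapsuleActivations)
        else CapsuleActivations(activations)
    )
    t = np.asarray(targets, dtype=float)
    if t.shape != (acts.vectors.shape[0],) or not (
        np.all((t == 0) | (t == 1)) and t.sum() == 1
    ):
        raise ValueError("targets must be a one-hot vector over the class capsules")
    n = acts.norms
    present = t * np.maximum(0.0, params.m_plus - n) ** 2
    absent = params.lam * (1 - t) * np.maximum(0.0, n - params.m_minus) ** 2
    return float(np.sum(present + absent))


def _margin_loss_batch(
    v: np.ndarray, t: np.ndarray, params: MarginLossParams
) -> tuple[float, np.ndarray]:
    """Mean margin loss over a batch and its gradient wrt the class vectors."""
    n = np.linalg.norm(v, axis=-1)
    hp = np.maximum(0.0, params.m_plus - n)
    hm = np.maximum(0.0, n - params.m_minus)
    loss = float(np.mean(np.sum(t * hp**2 + params.lam * (1 - t) * hm**2, axis=-1)))
    dn = (-2.0 * t * hp + 2.0 * params.lam * (1 - t) * hm) / v.shape[0]
    unit = np.divide(v, n[..., None], out=np.zeros_like(v), where=n[..., None] > 1e-12)
    return loss, dn[..., None] * unit


# ---------------------------------------------------------------------------
# single-scale capsule network

@dataclass(frozen=True)
class CapsNetConfig:
    """Architecture of one single-scale capsule network."""

    input_size: int = 80
    in_channels: int = 3
    conv_maps: int = 256
    conv_kernel: int = 9
    conv_stride: int = 1
    primary_channels: int = 32
    primary_dim: int = 8
    primary_kernel: int = 9
    primary_stride: int = 2
    n_classes: int = 2
    class_dim: int = 16
    routing_iters: int = 3

    def grid_sizes(self) -> tuple[int, int]:
        h1 = (self.input_size - self.conv_kernel) // self.conv_stride + 1
        h2 = (h1 - self.primary_kernel) // self.primary_stride + 1
        if h2 < 1:
            raise ValueError("input too small for the configured kernels")
        return h1, h2

    @property
    def n_primary(self) -> int:
        _, h2 = self.grid_sizes()
        return self.primary_channels * h2 * h2


TINY_CAPSNET = CapsNetConfig(input_size=40, conv_maps=8, primary_channels=4)


class SingleScaleCapsNet:
    """Conv -> primary capsules -> routed class capsules, trained on one scale."""

    def __init__(self, config: CapsNetConfig = CapsNetConfig(), seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config
        self.conv1 = Conv2d(c.in_channels, c.conv_maps, c.conv_kernel, c.conv_stride, rng)
        self.conv2 = Conv2d(
            c.conv_maps, c.primary_channels * c.primary_dim, c.primary_kernel,
            c.primary_stride, rng,
        )
        # routing weights: small init keeps early vote norms in squash's
        # responsive range
        self.Wr = Param(
            0.1 * rng.standard_normal((c.n_primary, c.n_classes, c.class_dim, c.primary_dim))
        )
        self.relu_mask: np.ndarray | None = None
        self._cache: dict | None = None
        self.loss_trace: list[float] = []
        self.trained = False

    @property
    def params(self) -> list[Param]:
        return self.conv1.params + self.conv2.params + [self.Wr]

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.config
        expected = (c.in_channels, c.input_size, c.input_size)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ShapeError(f"expected patches of shape {expected}, got {x.shape[1:]}")
        return x

    def forward_batch(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """(B, C, H, W) -> class capsule vectors (B, n_classes, class_dim)."""
        x = self._check_input(x)
        c = self.config
        z1 = self.conv1.forward(x)
        mask = z1 > 0
        h1 = z1 * mask
        z2 = self.conv2.forward(h1)
        bsz = x.shape[0]
        _, g2 = c.grid_sizes()
        # (B, C*D, g, g) -> capsules (B, n_primary, primary_dim)
        prim = (
            z2.reshape(bsz, c.primary_channels, c.primary_dim, g2, g2)
            .transpose(0, 1, 3, 4, 2)
            .reshape(bsz, c.n_primary, c.primary_dim)
        )
        u = squash(prim)
        votes = np.einsum("ijdk,bik->bijd", self.Wr.value, u)
        s, v, coup = _route_batch(votes, c.routing_iters)
        if keep_cache:
            self._cache = dict(mask=mask, prim=prim, u=u, votes=votes, s=s, coup=coup, g2=g2)
        return v

    def backward_batch(self, dv: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dv from the loss."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("forward_batch(keep_cache=True) must run first")
        c = self.config
        ds = _squash_backward(dv, cache["s"])
        dvotes = cache["coup"][..., None] * ds[:, :, None, :].transpose(0, 2, 1, 3)
        self.Wr.grad += np.einsum("bijd,bik->ijdk", dvotes, cache["u"])
        du = np.einsum("ijdk,bijd->bik", self.Wr.value, dvotes)
        dprim = _squash_backward(du, cache["prim"])
        bsz = dv.shape[0]
        g2 = cache["g2"]
        dz2 = (
            dprim.reshape(bsz, c.primary_channels, g2, g2, c.primary_dim)
            .transpose(0, 1, 4, 2, 3)
            .reshape(bsz, c.primary_channels * c.primary_dim, g2, g2)
        )
        dh1 = self.conv2.backward(dz2)
        self.conv1.backward(dh1 * cache["mask"])
        self._cache = None

    def forward(self, patch: Patch3D | np.ndarray) -> CapsuleActivations:
        """Single-patch forward pass returning the two class capsules."""
        x = patch.values if isinstance(patch, Patch3D) else np.asarray(patch, dtype=float)
        v = self.forward_batch(x[None] if x.ndim == 3 else x)
        return CapsuleActivations(v[0])


def forward_single_scale(patch: Patch3D | np.ndarray, network: SingleScaleCapsNet) -> CapsuleActivations:
    """Run one patch through a single-scale capsule network."""
    return network.forward(patch)


def train_single_scale(
    train_patches: np.ndarray,
    labels: np.ndarray,
    config: CapsNetConfig = TINY_CAPSNET,
    *,
    epochs: int = 30,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
    margin_params: MarginLossParams = MarginLossParams(),
) -> SingleScaleCapsNet:
    """Train one capsule network by Adam on the margin loss.

    ``train_patches`` is (N, C, H, W); ``labels`` binary. Returns the trained
    network; the per-epoch mean loss is on ``network.loss_trace``.
    """
    x = np.asarray(train_patches, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 4 or len(x) != len(y) or len(x) == 0:
        raise ValueError("need a non-empty (N, C, H, W) patch array with matching labels")
    if len(np.unique(y)) < 2:
        warnings.warn("training set contains a single class; proceeding anyway")
    net = SingleScaleCapsNet(config, seed=seed)
    opt = Adam(net.params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    onehot = np.eye(config.n_classes)[y]
    for _ in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            v = net.forward_batch(x[idx], keep_cache=True)
            loss, dv = _margin_loss_batch(v, onehot[idx], margin_params)
            net.backward_batch(dv)
            opt.step()
            losses.append(loss)
        net.loss_trace.append(float(np.mean(losses)))
    net.trained = True
    return net


# ---------------------------------------------------------------------------
# checkpointing

def save_capsnet(net: SingleScaleCapsNet, path: str) -> None:
    header = dict(kind="capsnet", config=asdict(net.config), seed=net.seed,
                  loss_trace=net.loss_trace)
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **{f"p{i}": p.value for i, p in enumerate(net.params)},
    )


def load_capsnet(path: str) -> SingleScaleCapsNet:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        net = SingleScaleCapsNet(CapsNetConfig(**header["config"]),
                                 seed=header.get("seed", 0))
        for i, p in enumerate(net.params):
            p.value[...] = data[f"p{i}"]
    net.loss_trace = list(header.get("loss_trace", []))
    net.trained = True
    return net
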