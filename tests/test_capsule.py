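"""Capsule primitives: squash, votes, routing, margin loss, and training."""

import numpy as np
import pytest

from nodulecaps.capsule import (
    CapsNetConfig,
    CapsuleActivations,
    CapsuleLayerSpec,
    MarginLossParams,
    SingleScaleCapsNet,
    _margin_loss_batch,
    compute_votes,
    dynamic_route,
    forward_single_scale,
    load_capsnet,
    margin_loss,
    save_capsnet,
    squash,
    train_single_scale,
)
from nodulecaps.errors import ShapeError

SMALL_NET = CapsNetConfig(
    input_size=14, conv_maps=3, conv_kernel=5, primary_channels=2,
    primary_kernel=3, primary_stride=2, primary_dim=4, class_dim=4,
)


def _routing_oracle(votes: np.ndarray, iters: int):
    """Step-by-step routing with explicit loops, kept independent of the
    vectorized implementation."""
    n_in, n_out, d = votes.shape
    b = np.zeros((n_in, n_out))
    for _ in range(iters):
        c = np.empty_like(b)
        for i in range(n_in):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        s = np.zeros((n_out, d))
        for j in range(n_out):
            for i in range(n_in):
                s[j] += c[i, j] * votes[i, j]
        v = np.zeros_like(s)
        for j in range(n_out):
            norm = np.linalg.norm(s[j])
            if norm > 0:
                v[j] = (norm**2 / (1 + norm**2)) * s[j] / norm
        for i in range(n_in):
            for j in range(n_out):
                b[i, j] += float(v[j] @ votes[i, j])
    return v, c


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert not squash(np.zeros(5)).any()

    def test_unit_vector_halved(self):
        out = squash(np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(out, [0.5, 0.0, 0.0], atol=1e-15)

    def test_norm_monotone_and_bounded(self, rng):
        direction = rng.standard_normal(8)
        direction /= np.linalg.norm(direction)
        norms = [np.linalg.norm(squash(a * direction)) for a in (0.1, 1, 3, 10, 100)]
        assert all(n2 > n1 for n1, n2 in zip(norms, norms[1:]))
        assert all(n < 1 for n in norms)
        out = squash(3.0 * direction)
        np.testing.assert_allclose(out / np.linalg.norm(out), direction, atol=1e-12)


class TestVotes:
    def test_identity_weights_pass_through(self, rng):
        u = rng.standard_normal((3, 4))
        w = np.broadcast_to(np.eye(4), (3, 2, 4, 4)).copy()
        spec = CapsuleLayerSpec(n_in=3, d_in=4, n_out=2, d_out=4, W=w)
        votes = compute_votes(CapsuleActivations(u), spec)
        for j in range(2):
            np.testing.assert_allclose(votes[:, j, :], u)

    def test_zero_input_gives_zero_votes(self):
        spec = CapsuleLayerSpec(n_in=2, d_in=3, n_out=2, d_out=5,
                                W=np.ones((2, 2, 5, 3)))
        assert not compute_votes(np.zeros((2, 3)), spec).any()

    def test_matches_hand_matmul_oracle(self, rng):
        w = rng.standard_normal((2, 2, 3, 3))
        u = rng.standard_normal((2, 3))
        spec = CapsuleLayerSpec(n_in=2, d_in=3, n_out=2, d_out=3, W=w)
        votes = compute_votes(u, spec)
        for i in range(2):
            for j in range(2):
                np.testing.assert_allclose(votes[i, j], w[i, j] @ u[i], atol=1e-14)

    def test_linearity_in_input(self, rng):
        w = rng.standard_normal((2, 2, 4, 3))
        u = rng.standard_normal((2, 3))
        spec = CapsuleLayerSpec(n_in=2, d_in=3, n_out=2, d_out=4, W=w)
        np.testing.assert_allclose(
            compute_votes(2.5 * u, spec), 2.5 * compute_votes(u, spec), atol=1e-12
        )

    def test_dimension_mismatch_raises(self):
        spec = CapsuleLayerSpec(n_in=2, d_in=3, n_out=2, d_out=4)
        with pytest.raises(ShapeError):
            compute_votes(np.zeros((2, 5)), spec)


class TestRouting:
    def test_single_upper_capsule_couplings_are_one(self, rng):
        votes = rng.standard_normal((4, 1, 3))
        acts, state = dynamic_route(votes, iters=3)
        np.testing.assert_allclose(state.c, 1.0)
        np.testing.assert_allclose(acts.vectors[0], squash(votes[:, 0].sum(axis=0)), atol=1e-12)

    def test_zero_votes_give_zero_output(self, rng):
        votes = np.zeros((3, 2, 4))
        votes[:, 0, :] = 5.0  # aligned, large votes for capsule 1 only
        acts, _ = dynamic_route(votes, iters=3)
        norms = acts.norms
        assert norms[1] == 0.0 and norms[0] > 0.5

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_in, n_out, d = rng.integers(1, 5, size=3)
            iters = int(rng.integers(1, 4))
            votes = rng.standard_normal((n_in, n_out, d))
            acts, state = dynamic_route(votes, iters=iters)
            v_ref, c_ref = _routing_oracle(votes, iters)
            np.testing.assert_allclose(acts.vectors, v_ref, atol=1e-12)
            np.testing.assert_allclose(state.c, c_ref, atol=1e-12)

    def test_couplings_normalized_and_norms_bounded(self, rng):
        votes = 3.0 * rng.standard_normal((5, 3, 4))
        acts, state = dynamic_route(votes, iters=4)
        np.testing.assert_allclose(state.c.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(state.c >= 0)
        assert np.all(acts.norms < 1)

    def test_rejects_zero_iterations(self):
        with pytest.raises(ValueError):
            dynamic_route(np.zeros((2, 2, 2)), iters=0)


class TestMarginLoss:
    def test_confident_correct_is_zero(self):
        acts = np.array([[0.9, 0.0], [0.1, 0.0]])
        assert margin_loss(acts, [1, 0]) == 0.0

    def test_present_class_hinge(self):
        acts = np.zeros((2, 2))
        acts[0, 0] = 0.4
        acts[1, 0] = 0.1
        assert margin_loss(acts, [1, 0]) == pytest.approx(0.25)

    def test_absent_class_hinge_with_lambda(self):
        acts = np.zeros((2, 2))
        acts[0, 0] = 0.6
        acts[1, 0] = 0.95
        loss = margin_loss(acts, [0, 1], MarginLossParams(lam=0.5))
        assert loss == pytest.approx(0.5 * 0.5**2)

    def test_nonnegative_random(self, rng):
        for _ in range(50):
            acts = squash(rng.standard_normal((2, 4)))
            assert margin_loss(acts, [0, 1]) >= 0

    def test_malformed_one_hot_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(np.zeros((2, 3)), [1, 1])


class TestForward:
    def test_two_16dim_class_capsules(self):
        net = SingleScaleCapsNet(CapsNetConfig(input_size=40, conv_maps=4,
                                               primary_channels=2), seed=0)
        acts = forward_single_scale(np.zeros((3, 40, 40)), net)
        assert acts.vectors.shape == (2, 16)
        assert np.all(acts.norms < 1)

    def test_deterministic_forward(self, rng):
        net = SingleScaleCapsNet(SMALL_NET, seed=1)
        x = rng.random((3, 14, 14))
        a = net.forward(x).vectors
        b = net.forward(x).vectors
        np.testing.assert_array_equal(a, b)

    def test_wrong_shape_rejected(self):
        net = SingleScaleCapsNet(SMALL_NET, seed=0)
        with pytest.raises(ShapeError):
            net.forward(np.zeros((3, 20, 20)))


class TestGradientsAndTraining:
    def test_backprop_matches_finite_differences_with_fixed_couplings(self, rng):
        # with a single routing iteration the couplings are constants, so the
        # analytic gradient must agree with finite differences everywhere
        import dataclasses

        cfg = dataclasses.replace(SMALL_NET, routing_iters=1)
        net = SingleScaleCapsNet(cfg, seed=0)
        x = rng.standard_normal((2, 3, 14, 14))
        t = np.eye(2)
        params = MarginLossParams()
        for p in net.params:
            p.zero_grad()
        v = net.forward_batch(x, keep_cache=True)
        _, dv = _margin_loss_batch(v, t, params)
        net.backward_batch(dv)
        eps = 1e-6
        for p in net.params:
            flat = p.value.ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = _margin_loss_batch(net.forward_batch(x), t, params)
                flat[i] = orig - eps
                lm, _ = _margin_loss_batch(net.forward_batch(x), t, params)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert p.grad.ravel()[i] == pytest.approx(num, abs=1e-6, rel=1e-4)

    def _toy_patches(self, rng, n=24, size=14):
        # class 1 blobs are larger: a learnable, size-driven problem
        xs, ys = [], []
        yy, xx = np.mgrid[:size, :size]
        for i in range(n):
            label = i % 2
            r = 2.0 + 2.5 * label + 0.3 * rng.standard_normal()
            img = ((xx - size / 2) ** 2 + (yy - size / 2) ** 2 < r**2).astype(float)
            xs.append(np.stack([img] * 3) + 0.05 * rng.standard_normal((3, size, size)))
            ys.append(label)
        return np.array(xs), np.array(ys)

    def test_training_reduces_loss(self, rng):
        x, y = self._toy_patches(rng)
        net = train_single_scale(x, y, SMALL_NET, epochs=8, batch_size=8, seed=3)
        assert net.loss_trace[-1] < net.loss_trace[0]
        assert net.trained

    def test_training_reproducible_under_seed(self, rng):
        x, y = self._toy_patches(rng)
        n1 = train_single_scale(x, y, SMALL_NET, epochs=3, seed=5)
        n2 = train_single_scale(x, y, SMALL_NET, epochs=3, seed=5)
        assert n1.loss_trace == n2.loss_trace

    def test_single_class_warns_but_proceeds(self, rng):
        x, y = self._toy_patches(rng, n=6)
        with pytest.warns(UserWarning, match="single class"):
            train_single_scale(x, np.zeros_like(y), SMALL_NET, epochs=1, seed=0)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        x, y = self._toy_patches(rng, n=8)
        net = train_single_scale(x, y, SMALL_NET, epochs=2, seed=2)
        path = tmp_path / "net.npz"
        save_capsnet(net, str(path))
        loaded = load_capsnet(str(path))
        np.testing.assert_array_equal(
            net.forward_batch(x[:3]), loaded.forward_batch(x[:3])
        )
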