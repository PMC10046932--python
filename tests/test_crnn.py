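import numpy as np
import pytest

from gliopipe import crnn, phantom
from gliopipe._nn import Dense, LRNConfig, RCLBlock


def _toy_params(rng, cin=1, cout=1, k=1, T=3):
    return crnn.RCLParams(
        feedforward_weights=rng.normal(size=(cout, cin, k, k)),
        recurrent_weights=rng.normal(size=(cout, cout, k, k)),
        bias=rng.normal(size=cout),
        unroll_steps=T)


def _conv_same_oracle(x, W, b):
    """Direct nested-loop same-padding convolution for tiny inputs."""
    C, H, Wd = x.shape
    F, _, k, _ = W.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    out = np.zeros((F, H, Wd))
    for f in range(F):
        for i in range(H):
            for j in range(Wd):
                out[f, i, j] = b[f] + sum(
                    W[f, c, di, dj] * xp[c, i + di, j + dj]
                    for c in range(C) for di in range(k) for dj in range(k))
    return out


class TestRclStep:
    def test_zero_recurrent_reduces_to_convolution(self, rng):
        params = _toy_params(rng, cin=2, cout=3, k=3)
        params.recurrent_weights[...] = 0.0
        x = rng.random((2, 5, 5))
        state = rng.random((3, 5, 5))
        plain = crnn.rcl_step(x, None, params)
        with_state = crnn.rcl_step(x, state, params)
        assert np.allclose(plain, with_state)

    def test_zero_input_and_state_gives_bias(self, rng):
        params = _toy_params(rng, cout=2, k=3)
        out = crnn.rcl_step(np.zeros((1, 4, 4)), np.zeros((2, 4, 4)), params)
        assert np.allclose(out, params.bias[:, None, None])

    def test_one_by_one_kernel_affine_map(self):
        params = crnn.RCLParams(
            feedforward_weights=np.array([[[[2.0]]]]),
            recurrent_weights=np.array([[[[0.5]]]]),
            bias=np.array([0.25]))
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        s = np.array([[[4.0, 3.0], [2.0, 1.0]]])
        out = crnn.rcl_step(x, s, params)
        assert np.allclose(out, 2.0 * x + 0.5 * s + 0.25)

    def test_step_matches_loop_convolution_oracle(self, rng):
        params = _toy_params(rng, cin=2, cout=2, k=3)
        x = rng.random((2, 4, 4))
        out = crnn.rcl_step(x, None, params)
        expected = _conv_same_oracle(x, params.feedforward_weights, params.bias)
        assert np.allclose(out, expected, atol=1e-12)


class TestActivations:
    def test_relu_cases(self):
        assert np.all(crnn.relu(np.array([-3.0, -0.1])) == 0)
        x = np.array([0.0, 0.5, 2.0])
        assert np.array_equal(crnn.relu(x), x)
        assert np.array_equal(crnn.relu(np.array([-1.0, 0.0, 2.0])),
                              np.array([0.0, 0.0, 2.0]))

    def test_lrn_zero_input(self):
        assert np.all(crnn.lrn(np.zeros((3, 4, 4))) == 0)

    def test_lrn_single_channel_closed_form(self):
        cfg = LRNConfig(depth_radius=1, alpha=1.0, beta=1.0, bias_k=1.0)
        v = 0.7
        out = crnn.lrn(np.full((1, 2, 2), v), cfg)
        assert np.allclose(out, v / (1 + v * v))

    def test_lrn_matches_position_loop_oracle(self, rng):
        cfg = LRNConfig(depth_radius=2, alpha=0.3, beta=0.75, bias_k=1.5)
        x = rng.normal(size=(6, 3, 3))
        out = crnn.lrn(x, cfg)
        C = x.shape[0]
        for c in range(C):
            lo, hi = max(0, c - 2), min(C - 1, c + 2)
            S = (x[lo:hi + 1] ** 2).sum(axis=0)
            expected = x[c] / (1.5 + 0.3 * S) ** 0.75
            assert np.allclose(out[c], expected, atol=1e-10)


class TestUnroll:
    def test_t0_is_conv_relu_lrn(self, rng):
        params = _toy_params(rng, cin=1, cout=2, k=3, T=0)
        x = rng.random((1, 5, 5))
        out = crnn.rcl_unroll(x, params)
        expected = crnn.lrn(crnn.relu(crnn.rcl_step(x, None, params)))
        assert np.allclose(out, expected)

    def test_zero_recurrent_independent_of_t(self, rng):
        x = rng.random((1, 5, 5))
        outs = []
        for T in (0, 1, 3):
            params = _toy_params(rng, cin=1, cout=2, k=3, T=T)
            params.feedforward_weights[...] = 0.3
            params.recurrent_weights[...] = 0.0
            params.bias[...] = 0.1
            outs.append(crnn.rcl_unroll(x, params))
        assert np.allclose(outs[0], outs[1]) and np.allclose(outs[0], outs[2])

    def test_matches_scripted_recomputation(self, rng):
        cfg = LRNConfig(depth_radius=1, alpha=0.2, beta=0.75, bias_k=1.0)
        params = _toy_params(rng, cin=1, cout=2, k=3, T=3)
        x = rng.random((1, 4, 4))
        out = crnn.rcl_unroll(x, params, cfg)

        ff = _conv_same_oracle(x, params.feedforward_weights, params.bias)

        def lrn_oracle(a):
            C = a.shape[0]
            res = np.empty_like(a)
            for c in range(C):
                lo, hi = max(0, c - 1), min(C - 1, c + 1)
                S = (a[lo:hi + 1] ** 2).sum(axis=0)
                res[c] = a[c] / (1.0 + 0.2 * S) ** 0.75
            return res

        state = lrn_oracle(np.maximum(ff, 0))
        for _ in range(3):
            rec = _conv_same_oracle(state, params.recurrent_weights,
                                    np.zeros(2))
            state = lrn_oracle(np.maximum(ff + rec, 0))
        assert np.allclose(out, state, atol=1e-10)

    def test_block_matches_functional_unroll(self, rng):
        blk = RCLBlock(2, 3, 3, 2, LRNConfig(), rng, np.float64)
        x = rng.random((1, 2, 6, 6))
        params = crnn.RCLParams(blk.W_ff, blk.W_rec, blk.b, unroll_steps=2)
        assert np.allclose(blk.forward(x), crnn.rcl_unroll(x, params))


class TestGradients:
    def test_unrolled_rcl_gradients_match_finite_differences(self):
        """Analytic backprop through conv + relu + LRN over T=3 unrolled
        steps agrees with central differences on a 4x4x2 toy."""
        rng = np.random.default_rng(0)
        blk = RCLBlock(2, 3, kernel=3, unroll=3,
                       lrn_cfg=LRNConfig(depth_radius=2, alpha=0.1,
                                         beta=0.75, bias_k=2.0),
                       rng=rng, dtype=np.float64)
        blk.b[:] = rng.normal(0.3, 0.1, blk.b.shape)
        x = rng.normal(0.0, 1.0, (1, 2, 4, 4))

        def loss():
            return 0.5 * float((blk.forward(x) ** 2).sum())

        out = blk.forward(x)
        dx = blk.backward(out)
        h = 1e-6
        for p, g in zip(blk.params() + [x], blk.grads() + [dx]):
            flat = p.reshape(-1)
            gflat = g.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 12)):
                old = flat[idx]
                flat[idx] = old + h
                lp = loss()
                flat[idx] = old - h
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * h)
                rel = abs(num - gflat[idx]) / max(1e-8, abs(num) + abs(gflat[idx]))
                assert rel < 1e-4


class TestNetwork:
    def test_forward_softmax_contract(self, rng):
        net = crnn.build_network(crnn.NetworkSpec.compact(16), seed=0)
        probs = net.predict_proba(rng.random((3, 3, 16, 16)).astype(np.float32))
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0

    def test_table_reference_spec_type_checks(self):
        spec = crnn.NetworkSpec.table_default()
        assert spec.input_size == 64 and spec.num_filters == 256
        assert spec.flat_units() == 256 * 16 * 16
        spec.validate()

    def test_seed_reproducibility(self, rng):
        x = rng.random((2, 3, 16, 16)).astype(np.float32)
        a = crnn.build_network(crnn.NetworkSpec.compact(16), seed=4)
        b = crnn.build_network(crnn.NetworkSpec.compact(16), seed=4)
        assert np.array_equal(a.forward(x), b.forward(x))

    def test_doubling_logits_sharpens_softmax(self, rng):
        from gliopipe._nn import softmax

        net = crnn.build_network(crnn.NetworkSpec.compact(16), seed=1)
        logits = net.forward(rng.random((4, 3, 16, 16)).astype(np.float32))
        p1 = softmax(logits)
        p2 = softmax(2.0 * logits)
        assert np.all(p2.max(axis=1) >= p1.max(axis=1) - 1e-7)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = crnn.build_network(crnn.NetworkSpec.compact(16), seed=2)
        x = rng.random((2, 3, 16, 16)).astype(np.float32)
        net.save(tmp_path / "m.npz")
        loaded = crnn.Network.load(tmp_path / "m.npz")
        assert np.array_equal(net.forward(x), loaded.forward(x))
        assert loaded.spec == net.spec


def _tiny_training_set(n=12, size=16, contrast=0.45, noise=0.0005, seed=2):
    base = phantom.PhantomSpec(height=size, width=size,
                               tumor_contrast=contrast, noise_variance=noise)
    items = phantom.make_dataset(n, 0.5, base, seed=seed)
    x = np.stack([it.image for it in items])
    y = np.array([it.label == "tumor" for it in items], dtype=np.int64)
    return x, y


class TestTraining:
    def test_zero_lr_leaves_parameters_unchanged(self):
        x, y = _tiny_training_set()
        # dropout off so the forward pass is deterministic and the flat-loss
        # check is exact
        net = crnn.build_network(crnn.NetworkSpec(input_size=16, num_filters=4,
                                                  hidden_units=8, dropout=0.0),
                                 seed=0)
        before = [p.copy() for p in net.params()]
        hist = crnn.train(net, x, y, crnn.TrainConfig(
            initial_lr=0.0, final_lr=0.0, epochs=3, batch_size=4))
        for p, q in zip(net.params(), before):
            assert np.array_equal(p, q)
        losses = [h["loss"] for h in hist]
        assert max(losses) - min(losses) < 1e-6

    def test_loss_decreases_over_first_epochs(self):
        x, y = _tiny_training_set(n=16)
        net = crnn.build_network(crnn.NetworkSpec(input_size=16, num_filters=4,
                                                  hidden_units=8), seed=0)
        hist = crnn.train(net, x, y, crnn.TrainConfig(
            initial_lr=0.002, final_lr=0.002, epochs=5, batch_size=16))
        assert hist[4]["loss"] < hist[0]["loss"]

    def test_training_is_reproducible(self):
        x, y = _tiny_training_set()
        cfg = crnn.TrainConfig(epochs=2, batch_size=4, seed=3)
        runs = []
        for _ in range(2):
            net = crnn.build_network(crnn.NetworkSpec(
                input_size=16, num_filters=4, hidden_units=8), seed=3)
            runs.append(crnn.train(net, x, y, cfg))
        assert runs[0][0]["loss"] == runs[1][0]["loss"]
        assert runs[0] == runs[1]

    def test_single_class_rejected(self):
        x, _ = _tiny_training_set()
        net = crnn.build_network(crnn.NetworkSpec(input_size=16, num_filters=4,
                                                  hidden_units=8), seed=0)
        with pytest.raises(ValueError):
            crnn.train(net, x, np.zeros(len(x), dtype=np.int64))

    def test_overfits_small_high_contrast_set(self):
        """Capacity check: the network should fit 40 high-contrast phantoms
        essentially perfectly in 30 epochs at the base learning rate."""
        base = phantom.PhantomSpec(height=32, width=32, tumor_contrast=0.45,
                                   noise_variance=0.0005)
        items = phantom.make_dataset(40, 0.5, base, seed=2)
        x = np.stack([it.image for it in items])
        y = np.array([it.label == "tumor" for it in items], dtype=np.int64)
        net = crnn.build_network(crnn.NetworkSpec(input_size=32, num_filters=8,
                                                  hidden_units=64), seed=0)
        crnn.train(net, x, y, crnn.TrainConfig(
            initial_lr=0.002, final_lr=0.002, epochs=30, batch_size=8, seed=0))
        probs = net.predict_proba(crnn.adapt_images(x, 3))
        acc = ((probs[:, 1] > probs[:, 0]).astype(np.int64) == y).mean()
        assert acc >= 0.95

    def test_schedule_endpoints(self):
        cfg = crnn.TrainConfig(epochs=30)
        assert cfg.lr_at(0) == pytest.approx(0.002)
        assert cfg.lr_at(29) == pytest.approx(3e-6)
        assert cfg.momentum_at(0) == pytest.approx(0.5)
        assert cfg.momentum_at(29) == pytest.approx(0.9)
        lrs = [cfg.lr_at(e) for e in range(30)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))


class TestPredict:
    def test_probabilities_and_adapter(self, rng):
        net = crnn.build_network(crnn.NetworkSpec.compact(16), seed=0)
        label, probs, meta = crnn.predict_image(net, rng.random((16, 16)))
        assert label in ("tumor", "normal")
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert meta["trained"] is False

    def test_classifier_sklearn_contract(self):
        from sklearn.base import clone

        x, y = _tiny_training_set(n=12)
        labels = np.where(y == 1, "tumor", "normal")
        clf = crnn.CRNNClassifier(
            spec=crnn.NetworkSpec(input_size=16, num_filters=4, hidden_units=8),
            epochs=2, batch_size=4, random_state=0)
        clone(clf)
        clf.fit(x, labels)
        assert list(clf.classes_) == ["normal", "tumor"]
        pred = clf.predict(x)
        assert set(pred) <= {"normal", "tumor"}
        proba = clf.predict_proba(x)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
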