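"""Training protocol: splits, the SGDM update rule, schedules, determinism."""

import numpy as np
import pandas as pd
import pytest

from octattn.network import NetworkConfig, StageConfig, build_network
from octattn.nn.functional import cross_entropy, softmax
from octattn.training import (
    TrainConfig,
    predict,
    sgdm_step,
    stratified_split,
    train,
)


def _manifest_df(n_bipolar, n_control):
    rows = [("b%d" % i, "left_to_right", "bipolar", "train", "none") for i in range(n_bipolar)]
    rows += [("c%d" % i, "left_to_right", "control", "train", "none") for i in range(n_control)]
    return pd.DataFrame(rows, columns=["id", "case", "class", "split", "path"])


def _toy_dataset(rng, n_per_class=16, side=16, channels=2, shift=3.0):
    """Two linearly separable blobs rendered as images."""
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, channels, side, side))
    X1 = rng.normal(0.0, 1.0, size=(n_per_class, channels, side, side))
    X1[:, 0, :4] += shift  # class-1 images carry a bright top stripe
    X = np.concatenate([X0, X1]).astype(np.float32)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def _tiny_net(seed=0, dtype=np.float32, side=16):
    cfg = NetworkConfig(
        input_side=side, input_channels=2, stem_filters=4, stem_kernel=2,
        stem_stride=2,
        stages=(StageConfig(4, repeats=1),
                StageConfig(8, repeats=1, followed_by_downsample=False)),
        num_classes=2,
    )
    return build_network(cfg, seed=seed, dtype=dtype)


class TestStratifiedSplit:
    def test_published_counts_round_half_even(self):
        df = _manifest_df(303, 684)
        tr, val = stratified_split(df, 0.2, seed=0)
        assert (val["class"] == "bipolar").sum() == 61    # round(60.6)
        assert (val["class"] == "control").sum() == 137   # round(136.8)
        assert len(tr) + len(val) == 987

    def test_small_even_split(self):
        tr, val = stratified_split(_manifest_df(10, 10), 0.2, seed=0)
        assert (val["class"] == "bipolar").sum() == 2
        assert (val["class"] == "control").sum() == 2

    def test_disjoint_union(self):
        df = _manifest_df(9, 13)
        tr, val = stratified_split(df, 0.25, seed=3)
        ids = set(tr["id"]) | set(val["id"])
        assert len(ids) == 22 and not (set(tr["id"]) & set(val["id"]))

    def test_deterministic_under_seed(self):
        df = _manifest_df(20, 30)
        a = stratified_split(df, 0.2, seed=5)
        b = stratified_split(df, 0.2, seed=5)
        assert a[0]["id"].tolist() == b[0]["id"].tolist()
        assert a[1]["id"].tolist() == b[1]["id"].tolist()

    def test_empty_class_rejected(self):
        df = _manifest_df(5, 5).iloc[:0]
        with pytest.raises(ValueError):
            stratified_split(df, 0.2, seed=0)


class TestSgdmStep:
    def test_momentum_update_matches_hand_computation(self):
        """One step on a frozen batch equals v = m*v - lr*g; w += v (l2 = 0)."""
        rng = np.random.default_rng(0)
        net = _tiny_net(dtype=np.float64)
        X = rng.normal(size=(4, 2, 16, 16))
        y = np.array([0, 1, 0, 1])

        def grads():
            net.zero_grad()
            logits = net.forward_logits(X, training=True)
            d = softmax(logits, axis=1)
            d[np.arange(4), y] -= 1
            d /= 4
            net.backward(d)
            return {n: l.grads[p].copy() for n, l, p, _ in net.named_parameters()}

        w_before = {n: a.copy() for n, _, _, a in net.named_parameters()}
        g1 = grads()
        velocity = {}
        sgdm_step(net, velocity, lr=0.05, momentum=0.9, l2=0.0)
        for n, _, _, arr in net.named_parameters():
            np.testing.assert_allclose(arr, w_before[n] - 0.05 * g1[n], rtol=1e-12)
        # second step on the same frozen batch: v = 0.9*v - lr*g2
        w_mid = {n: a.copy() for n, _, _, a in net.named_parameters()}
        g2 = grads()
        sgdm_step(net, velocity, lr=0.05, momentum=0.9, l2=0.0)
        for n, _, _, arr in net.named_parameters():
            v_expect = 0.9 * (-0.05 * g1[n]) - 0.05 * g2[n]
            np.testing.assert_allclose(arr, w_mid[n] + v_expect, rtol=1e-10)

    def test_l2_applies_to_weights_only(self):
        net = _tiny_net(dtype=np.float64)
        net.zero_grad()  # zero gradients isolate the decay term
        before = {n: a.copy() for n, _, _, a in net.named_parameters()}
        sgdm_step(net, {}, lr=1.0, momentum=0.0, l2=0.01)
        for (n, layer, pname, arr) in net.named_parameters():
            if pname in layer.weight_decay:
                np.testing.assert_allclose(arr, before[n] * 0.99, rtol=1e-12)
            else:
                np.testing.assert_array_equal(arr, before[n])


class TestTrainLoop:
    def test_lr_schedule_is_stepwise(self):
        cfg = TrainConfig(initial_lr=0.01, lr_drop_factor=0.1, lr_drop_period=10)
        assert cfg.lr_at_epoch(0) == pytest.approx(0.01)
        assert cfg.lr_at_epoch(9) == pytest.approx(0.01)
        assert cfg.lr_at_epoch(10) == pytest.approx(0.001)
        assert cfg.lr_at_epoch(25) == pytest.approx(0.0001)

    def test_logged_lr_follows_schedule(self):
        rng = np.random.default_rng(0)
        X, y = _toy_dataset(rng, n_per_class=8)
        net = _tiny_net()
        res = train(net, (X, y), None,
                    TrainConfig(epochs=6, mini_batch=8, lr_drop_period=3, seed=0))
        log = res.iteration_log
        for _, row in log.iterrows():
            assert row["lr"] == pytest.approx(0.01 * 0.1 ** (row["epoch"] // 3))

    def test_loss_decreases_on_separable_data(self):
        rng = np.random.default_rng(1)
        X, y = _toy_dataset(rng, n_per_class=16)
        net = _tiny_net(seed=1)
        res = train(net, (X, y), None, TrainConfig(epochs=8, mini_batch=8, seed=1))
        per_epoch = res.iteration_log.groupby("epoch")["loss"].mean()
        assert per_epoch.iloc[-1] < per_epoch.iloc[0]

    def test_single_batch_overfit_reaches_full_training_accuracy(self):
        """Capacity sanity check: 8 images, 50 epochs, one batch per epoch.

        The drop period is set past the horizon so the check isolates model
        capacity from the step schedule (which would freeze the learning
        rate at 1e-5 by epoch 30 and stall the fit).
        """
        rng = np.random.default_rng(2)
        X, y = _toy_dataset(rng, n_per_class=4, shift=2.0)
        net = _tiny_net(seed=2)
        train(net, (X, y), None,
              TrainConfig(epochs=50, mini_batch=8, seed=2, lr_drop_period=50))
        pred, _ = predict(net, X)
        assert (pred == y).mean() == 1.0

    def test_full_run_determinism(self):
        rng = np.random.default_rng(3)
        X, y = _toy_dataset(rng, n_per_class=8)
        results = []
        for _ in range(2):
            net = _tiny_net(seed=3)
            train(net, (X.copy(), y.copy()), None,
                  TrainConfig(epochs=3, mini_batch=8, seed=3))
            results.append({n: a.copy() for n, _, _, a in net.named_parameters()})
        for n in results[0]:
            np.testing.assert_array_equal(results[0][n], results[1][n])

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)

    def test_oversized_batch_rejected(self):
        rng = np.random.default_rng(0)
        X, y = _toy_dataset(rng, n_per_class=2)
        with pytest.raises(ValueError, match="reduce"):
            train(_tiny_net(), (X, y), None, TrainConfig(epochs=1, mini_batch=64))

    def test_validation_accuracy_tracked_per_epoch(self):
        rng = np.random.default_rng(4)
        X, y = _toy_dataset(rng, n_per_class=8)
        Xv, yv = _toy_dataset(rng, n_per_class=4)
        net = _tiny_net(seed=4)
        res = train(net, (X, y), (Xv, yv), TrainConfig(epochs=4, mini_batch=8, seed=4))
        assert len(res.val_accuracy) == 4
        assert all(0.0 <= v <= 100.0 for v in res.val_accuracy)
        assert res.final_val_accuracy == res.val_accuracy[-1]


class TestPredict:
    def test_argmax_with_low_index_tie_break(self):
        net = _tiny_net()
        # zero FC weights -> uniform probabilities -> class 0 by tie-break
        head = net.blocks["head"]
        head.fc.params["weight"][:] = 0
        head.fc.params["bias"][:] = 0
        X = np.random.default_rng(0).random((3, 2, 16, 16), dtype=np.float32)
        labels, probs = predict(net, X)
        np.testing.assert_allclose(probs, 0.5, atol=1e-6)
        assert (labels == 0).all()

    def test_batch_shape_contract(self):
        net = _tiny_net()
        X = np.random.default_rng(0).random((5, 2, 16, 16), dtype=np.float32)
        labels, probs = predict(net, X, batch=2)
        assert labels.shape == (5,) and probs.shape == (5, 2)
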