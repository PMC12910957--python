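"""Splitting, optimization, determinism and the classifier CV harness."""

import numpy as np
import pytest

from hdgsnet.genome_io import DatasetContainer
from hdgsnet.model import (BranchSpec, ConvModuleSpec, HDGSModelConfig,
                           build_hdgs)
from hdgsnet.nn import Adam, Dense, Sequential
from hdgsnet.training import (TrainingConfig, crossvalidate_classifier,
                              predict, split_311, train)


def make_container(n, labels=None, seed=0, gc_rich_mask=None):
    """Random one-hot containers; optionally make some windows GC-rich."""
    rng = np.random.default_rng(seed)
    feats = np.zeros((n, 16, 146), dtype=np.uint8)
    rows = rng.integers(0, 16, size=(n, 146))
    if gc_rich_mask is not None:
        # GC-type dinucleotide rows: GG=10, CC=5, GC=9, CG=6
        gc_rows = rng.choice([10, 5, 9, 6], size=(n, 146))
        at_rows = rng.choice([0, 15, 3, 12], size=(n, 146))
        rows = np.where(gc_rich_mask[:, None], gc_rows, at_rows)
    feats[np.arange(n)[:, None], rows, np.arange(146)[None, :]] = 1
    if labels is None:
        labels = rng.random(n).astype(np.float32)
    return DatasetContainer(feats, np.asarray(labels, dtype=np.float32),
                            np.array(["c1"] * n, dtype=object),
                            np.arange(n, dtype=np.int64),
                            np.array(["+"] * n))


def micro_config(head="regression"):
    """Two tiny modules exercising gated/dilated/separable branches."""
    return HDGSModelConfig(modules=(
        ConvModuleSpec("A", (BranchSpec("gc", 3),
                             BranchSpec("dc", 7, dilation=3)), 4),
        ConvModuleSpec("B", (BranchSpec("gc", 3, separable=True),), 4),
    ), fc_widths=(16,), head=head)


class TestSplit311:
    def test_n100_gives_60_20_20(self):
        sizes = [len(s) for s in split_311(make_container(100), seed=0)]
        assert sizes == [60, 20, 20]

    def test_n101_largest_remainder(self):
        sizes = [len(s) for s in split_311(make_container(101), seed=0)]
        assert sizes == [61, 20, 20]

    def test_same_seed_same_split(self):
        c = make_container(50)
        a = split_311(c, seed=9)
        b = split_311(c, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.positions, y.positions)

    def test_disjoint_and_exhaustive(self):
        c = make_container(83)
        parts = split_311(c, seed=3)
        seen = np.concatenate([p.positions for p in parts])
        assert sorted(seen) == list(range(83))

    def test_too_small_is_error(self):
        with pytest.raises(ValueError):
            split_311(make_container(4))


class TestTrain:
    def test_constant_labels_learned(self):
        c = make_container(120, labels=np.full(120, 2.0))
        net = build_hdgs(micro_config(), seed=0)
        cfg = TrainingConfig(learning_rate=1e-2, batch_size=8, epochs=30,
                             seed=0)
        hist = train(net, split_311(c, seed=0), cfg)
        preds = predict(net, c)
        assert hist["val_loss"].iloc[-1] < 0.2
        assert np.allclose(preds, 2.0, atol=0.5)

    def test_two_runs_identical_history(self):
        c = make_container(60)
        cfg = TrainingConfig(learning_rate=1e-3, batch_size=16, epochs=3,
                             seed=5)
        hists = []
        for _ in range(2):
            net = build_hdgs(micro_config(), seed=7)
            hists.append(train(net, split_311(c, seed=1), cfg))
        assert hists[0].equals(hists[1])

    def test_best_epoch_is_min_val_loss(self):
        c = make_container(80)
        net = build_hdgs(micro_config(), seed=2)
        cfg = TrainingConfig(learning_rate=1e-3, batch_size=16, epochs=4,
                             seed=2)
        hist = train(net, split_311(c, seed=2), cfg)
        assert hist.attrs["best_val_loss"] == pytest.approx(
            hist["val_loss"].min())

    def test_plateau_reduces_lr(self):
        c = make_container(40, labels=np.full(40, 1.0))
        net = build_hdgs(micro_config(), seed=0)
        cfg = TrainingConfig(learning_rate=1e-9, batch_size=16, epochs=6,
                             plateau_patience=2, plateau_factor=0.5,
                             min_lr=1e-12, seed=0)
        hist = train(net, split_311(c, seed=0), cfg)
        assert hist["lr"].iloc[-1] < hist["lr"].iloc[0]


class TestPredict:
    def test_order_and_nonnegativity(self):
        c = make_container(3)
        net = build_hdgs(micro_config(), seed=0)
        p = predict(net, c)
        assert p.shape == (3,) and np.all(p >= 0)
        # order preserving: batching must not permute
        p_again = np.concatenate([predict(net, c.subset(np.array([i])))
                                  for i in range(3)])
        assert np.allclose(p, p_again, atol=1e-5)

    def test_empty_container(self):
        net = build_hdgs(micro_config(), seed=0)
        assert predict(net, make_container(0)).shape == (0,)


class TestGradientOracle:
    def test_one_step_matches_hand_computed_mse_gradient(self):
        """Plain gradient descent on a 1-layer linear model vs closed form."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3)).astype(np.float32)
        y = rng.normal(size=8)
        dense = Dense(3, 1, rng=rng)
        w0 = dense.w.v.copy()
        b0 = dense.b.v.copy()
        pred = dense.forward(x)[:, 0]
        grad_out = (2.0 / 8) * (pred - y)
        dense.w.g[...] = 0
        dense.b.g[...] = 0
        dense.backward(grad_out[:, None].astype(np.float32))
        # hand-computed: dL/dW = (2/n) X^T (Xw + b - y)
        resid = x @ w0[:, 0] + b0[0] - y
        grad_w = (2.0 / 8) * x.T @ resid
        grad_b = (2.0 / 8) * resid.sum()
        assert np.allclose(dense.w.g[:, 0], grad_w, atol=1e-5)
        assert np.allclose(dense.b.g[0], grad_b, atol=1e-5)


class TestClassifierCV:
    def test_separable_classes_high_accuracy(self):
        n = 200
        labels = (np.arange(n) % 2).astype(float)
        c = make_container(n, labels=labels, seed=1,
                           gc_rich_mask=labels.astype(bool))
        result = crossvalidate_classifier(
            micro_config(head="classification"), c.features, labels,
            k=5, seed=0,
            train_config=TrainingConfig(learning_rate=3e-3, batch_size=16,
                                        epochs=3, loss="bce", seed=0))
        assert result["mean_accuracy"] >= 0.95
        assert len(result["fold_accuracy"]) == 5

    def test_shuffled_labels_near_chance(self):
        n = 200
        rng = np.random.default_rng(4)
        labels = (np.arange(n) % 2).astype(float)
        c = make_container(n, labels=labels, seed=1,
                           gc_rich_mask=labels.astype(bool))
        shuffled = rng.permutation(labels)
        result = crossvalidate_classifier(
            micro_config(head="classification"), c.features, shuffled,
            k=5, seed=0,
            train_config=TrainingConfig(learning_rate=3e-3, batch_size=16,
                                        epochs=3, loss="bce", seed=0))
        assert abs(result["mean_accuracy"] - 0.5) <= 0.1

    def test_single_class_is_error(self):
        c = make_container(20, labels=np.ones(20))
        with pytest.raises(ValueError, match="class"):
            crossvalidate_classifier(micro_config(head="classification"),
                                     c.features, np.ones(20))

    def test_k_exceeding_minority_is_error(self):
        labels = np.array([0.0] * 17 + [1.0] * 3)
        c = make_container(20, labels=labels)
        with pytest.raises(ValueError, match="minority"):
            crossvalidate_classifier(micro_config(head="classification"),
                                     c.features, labels, k=5)
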