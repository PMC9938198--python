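"""Training regime, tuning, ensembling, and binarization."""

import numpy as np
import pytest

from rnapart.labeler import (
    LabelerEnsemble,
    ModelConfig,
    TrainConfig,
    WindowDataset,
    build_model,
    ensemble_predict,
    load_checkpoint,
    predict_labels,
    save_checkpoint,
    train,
    transfer_train,
    tune_hyperparameters,
)
from rnapart.windows import make_windows


def _toy_dataset(n: int, L: int, seed: int) -> WindowDataset:
    """Linearly separable labeling task: a base is positive iff 'A'.

    Channel order is -UGCA, so channel 4 carries the answer directly —
    any correctly wired stack should drive MCC to ~1.
    """
    rng = np.random.default_rng(seed)
    seqs = rng.integers(0, 4, size=(n, L))  # 0..3 -> U,G,C,A channels 1..4
    x = np.zeros((n, 5, L), dtype=np.float32)
    for ch in range(4):
        x[:, ch + 1, :] = seqs == ch
    y = (seqs == 3).astype(np.int8)
    mask = np.ones((n, L), dtype=np.uint8)
    return WindowDataset(x, y, mask)


TINY = ModelConfig(K=3, C=8, U=8, N=16, L=30)


class TestTrain:
    def test_learns_separable_toy_task(self):
        train_set = _toy_dataset(120, TINY.L, seed=0)
        val_set = _toy_dataset(40, TINY.L, seed=1)
        tc = TrainConfig(patience=20, max_epochs=20, batch_size=32,
                         learning_rate=3e-3, seed=0)
        model = build_model(TINY, seed=0)
        model, history = train(model, train_set, val_set, tc)
        best = max(h["val_mcc"] for h in history if h["val_mcc"] is not None)
        assert best >= 0.95

    def test_early_stopping_rule_with_constant_metric(self):
        """patience=1 and a constant metric stop after 2 epochs."""
        train_set = _toy_dataset(8, TINY.L, seed=0)
        # a fully masked validation set pins the monitored loss at 0.0:
        # epoch 1 'improves' over the initial state, epoch 2 cannot
        val_set = _toy_dataset(4, TINY.L, seed=1)
        val_set.mask[:] = 0
        tc = TrainConfig(patience=1, max_epochs=50, batch_size=8, seed=0,
                         monitor="val_loss")
        model = build_model(TINY, seed=0)
        _, history = train(model, train_set, val_set, tc)
        assert len(history) == 2

    def test_restores_best_epoch_weights(self):
        train_set = _toy_dataset(120, TINY.L, seed=0)
        val_set = _toy_dataset(40, TINY.L, seed=1)
        tc = TrainConfig(patience=3, max_epochs=15, batch_size=32,
                         learning_rate=3e-3, seed=0)
        model = build_model(TINY, seed=0)
        model, history = train(model, train_set, val_set, tc)
        from rnapart.labeler import _validation_scores

        _, mcc = _validation_scores(model, val_set, 64)
        best = max(h["val_mcc"] for h in history if h["val_mcc"] is not None)
        assert mcc == pytest.approx(best)

    def test_empty_dataset_rejected(self):
        empty = WindowDataset(
            np.zeros((0, 5, TINY.L)), np.zeros((0, TINY.L)), np.zeros((0, TINY.L))
        )
        with pytest.raises(ValueError):
            train(build_model(TINY), empty, empty, TrainConfig())

    def test_training_is_bitwise_reproducible(self):
        train_set = _toy_dataset(30, TINY.L, seed=0)
        val_set = _toy_dataset(10, TINY.L, seed=1)
        tc = TrainConfig(patience=3, max_epochs=3, batch_size=16, seed=5)
        states = []
        for _ in range(2):
            m = build_model(TINY, seed=5)
            m, _ = train(m, train_set, val_set, tc)
            states.append(m.get_state())
        for a, b in zip(*states):
            for k in a:
                assert np.array_equal(a[k], b[k])


class TestTransferTrain:
    def test_empty_accurate_set_degenerates_to_pretraining(self):
        train_set = _toy_dataset(30, TINY.L, seed=0)
        val_set = _toy_dataset(10, TINY.L, seed=1)
        empty = WindowDataset(
            np.zeros((0, 5, TINY.L)), np.zeros((0, TINY.L)), np.zeros((0, TINY.L))
        )
        tc = TrainConfig(patience=2, max_epochs=3, seed=0)
        model = build_model(TINY, seed=0)
        model, hist = transfer_train(model, train_set, val_set, empty, empty, tc)
        assert hist["transtrain"] == []
        assert len(hist["pretrain"]) >= 1

    def test_weights_change_in_stage_two(self):
        coarse = _toy_dataset(30, TINY.L, seed=0)
        cval = _toy_dataset(10, TINY.L, seed=1)
        accurate = _toy_dataset(30, TINY.L, seed=2)
        aval = _toy_dataset(10, TINY.L, seed=3)
        tc = TrainConfig(patience=2, max_epochs=2, seed=0)
        m = build_model(TINY, seed=0)
        m, _ = train(m, coarse, cval, tc)
        stage1 = m.get_state()
        m, _ = transfer_train(build_model(TINY, seed=0), coarse, cval, accurate, aval, tc)
        changed = any(
            not np.array_equal(a[k], b[k])
            for a, b in zip(stage1, m.get_state())
            for k in a
        )
        assert changed


class TestTune:
    def test_budget_one_returns_single_config(self):
        train_set = _toy_dataset(20, TINY.L, seed=0)
        val_set = _toy_dataset(8, TINY.L, seed=1)
        tc = TrainConfig(patience=1, max_epochs=1, seed=0)
        space = {"K": (3, 5), "C": (4, 8), "U": (4, 8), "N": (8, 16)}
        trials = tune_hyperparameters(space, 1, train_set, val_set, tc, seed=0)
        assert len(trials) == 1

    def test_trials_sorted_and_reproducible(self):
        train_set = _toy_dataset(20, TINY.L, seed=0)
        val_set = _toy_dataset(8, TINY.L, seed=1)
        tc = TrainConfig(patience=1, max_epochs=2, seed=0)
        space = {"K": (3, 5), "C": (4, 8), "U": (4, 8), "N": (8, 16)}
        t1 = tune_hyperparameters(space, 4, train_set, val_set, tc, seed=3)
        t2 = tune_hyperparameters(space, 4, train_set, val_set, tc, seed=3)
        mccs = [m for _, m in t1 if m is not None]
        assert mccs == sorted(mccs, reverse=True)
        assert [(c.K, c.C, c.U, c.N) for c, _ in t1] == [
            (c.K, c.C, c.U, c.N) for c, _ in t2
        ]

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters({}, 1, None, None, TrainConfig())


class TestEnsemble:
    def test_single_member_equals_model(self, rng):
        m = build_model(TINY, seed=0)
        ens = LabelerEnsemble([m])
        x = rng.random((2, 5, TINY.L))
        mask = np.ones((2, TINY.L))
        assert np.allclose(ens.predict_window_probs(x, mask), m.predict_proba(x, mask))

    def test_mean_of_members_and_bounds(self, rng):
        members = [build_model(TINY, seed=s) for s in range(3)]
        ens = LabelerEnsemble(members)
        x = rng.random((2, 5, TINY.L))
        mask = np.ones((2, TINY.L))
        probs = [m.predict_proba(x, mask) for m in members]
        out = ens.predict_window_probs(x, mask)
        assert np.allclose(out, np.mean(probs, axis=0))
        assert np.all(out >= np.min(probs, axis=0) - 1e-12)
        assert np.all(out <= np.max(probs, axis=0) + 1e-12)

    def test_mismatched_window_lengths_rejected(self):
        a = build_model(ModelConfig(K=3, C=4, U=4, N=8, L=30))
        b = build_model(ModelConfig(K=3, C=4, U=4, N=8, L=40))
        with pytest.raises(ValueError, match="mismatched"):
            LabelerEnsemble([a, b])

    def test_ensemble_predict_stitches_to_parent_length(self):
        m = build_model(TINY, seed=0)
        ens = LabelerEnsemble([m])
        ws = make_windows("ACGU" * 20, L=TINY.L, step=15)
        out = ensemble_predict(ens, ws)
        assert out.shape == (80,)
        assert np.all((out >= 0) & (out <= 1))


class TestPredictLabels:
    def test_threshold_edges(self):
        probs = np.array([0.0, 0.49, 0.5, 1.0])
        assert predict_labels(probs).tolist() == [0, 0, 1, 1]  # >= tie rule
        assert predict_labels(probs, threshold=0.0).tolist() == [1, 1, 1, 1]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            predict_labels(np.array([0.5]), threshold=1.5)

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            predict_labels(np.array([-0.1, 0.5]))


def test_checkpoint_roundtrip(tmp_path, rng):
    m = build_model(TINY, seed=0)
    save_checkpoint(m, tmp_path / "ckpt")
    m2 = load_checkpoint(tmp_path / "ckpt")
    x = rng.random((2, 5, TINY.L))
    mask = np.ones((2, TINY.L))
    assert np.array_equal(m.predict_proba(x, mask), m2.predict_proba(x, mask))
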