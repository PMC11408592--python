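"""Training loop, confusion-matrix metrics, evaluation, and reports."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_recall_fscore_support, recall_score

import kidneyfusion as kf
from kidneyfusion.trainer import (
    ConfusionMatrix,
    TrainConfig,
    confusion_matrix,
    evaluate,
    load_checkpoint,
    per_class_metrics,
    save_checkpoint,
    train,
    write_report,
)


def expand(cm_counts):
    """Turn a count matrix back into (y_true, y_pred) label arrays."""
    y_true, y_pred = [], []
    for i, row in enumerate(cm_counts):
        for j, n in enumerate(row):
            y_true.extend([i] * n)
            y_pred.extend([j] * n)
    return np.asarray(y_true), np.asarray(y_pred)


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

def test_confusion_perfect_predictions():
    y = np.repeat(np.arange(4), [3, 3, 2, 2])
    cm = confusion_matrix(y, y, n_classes=4)
    assert np.trace(cm.counts) == 10
    assert cm.counts.sum() - np.trace(cm.counts) == 0
    assert cm.class_names == kf.CLASSES


def test_confusion_single_off_diagonal():
    cm = confusion_matrix([0], [3], n_classes=4)  # true Cyst, predicted Tumor
    assert cm.counts[0, 3] == 1
    assert cm.counts.sum() == 1


def test_confusion_twelve_sample_hand_case():
    y_true = [0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3]
    y_pred = [0, 1, 0, 1, 1, 2, 2, 2, 0, 3, 3, 1]
    # independent brute-force tally
    expected = np.zeros((4, 4), np.int64)
    for t, p in zip(y_true, y_pred):
        expected[t][p] += 1
    cm = confusion_matrix(y_true, y_pred, n_classes=4)
    assert np.array_equal(cm.counts, expected)
    assert cm.total == 12


def test_confusion_validation_errors():
    with pytest.raises(ValueError, match="length mismatch"):
        confusion_matrix([0, 1], [0], n_classes=4)
    with pytest.raises(ValueError, match="labels"):
        confusion_matrix([0, 4], [0, 0], n_classes=4)


# ---------------------------------------------------------------------------
# per-class metrics
# ---------------------------------------------------------------------------

def test_metrics_perfect_predictions():
    cm = ConfusionMatrix(np.diag([5, 5, 5, 5]), kf.CLASSES)
    rep = per_class_metrics(cm)
    for arr in (rep.precision, rep.recall, rep.f1, rep.specificity):
        assert np.allclose(arr, 1.0)
    assert np.allclose(rep.error_rate, 0.0)
    assert rep.accuracy == 1.0
    assert not rep.zero_division_flags


def test_metrics_binary_style_hand_case():
    # class 0: TP=8, FP=2, FN=1; everything else on the diagonal
    counts = np.array([
        [8, 1, 0, 0],
        [2, 8, 0, 0],
        [0, 0, 5, 0],
        [0, 0, 0, 5],
    ])
    rep = per_class_metrics(ConfusionMatrix(counts, kf.CLASSES))
    assert rep.precision[0] == pytest.approx(0.8)
    assert rep.recall[0] == pytest.approx(8 / 9)
    assert rep.f1[0] == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))
    assert rep.error_rate[0] == pytest.approx(1 - 8 / 9)


def test_metrics_never_predicted_class_flagged():
    counts = np.array([
        [5, 0, 0, 0],
        [0, 5, 0, 0],
        [3, 0, 0, 2],
        [0, 0, 0, 5],
    ])  # Stone never predicted
    with pytest.warns(RuntimeWarning, match="0/0"):
        rep = per_class_metrics(ConfusionMatrix(counts, kf.CLASSES))
    assert rep.precision[2] == 0.0
    assert "precision[Stone]" in rep.zero_division_flags


def test_metrics_agree_with_sklearn_on_random_matrices():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        counts = rng.integers(0, 40, size=(4, 4))
        if counts.sum() == 0:
            counts[0, 0] = 1
        y_true, y_pred = expand(counts)
        rep = per_class_metrics(ConfusionMatrix(counts, kf.CLASSES))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=0.0
        )
        assert np.all(np.abs(rep.precision - p) < 1e-12)
        assert np.all(np.abs(rep.recall - r) < 1e-12)
        assert np.all(np.abs(rep.f1 - f) < 1e-12)
        for i in range(4):
            spec = recall_score(y_true != i, y_pred != i, zero_division=0.0)
            assert abs(rep.specificity[i] - spec) < 1e-12
        assert abs(rep.accuracy - (y_true == y_pred).mean()) < 1e-12


def test_macro_metrics_invariant_to_class_permutation():
    rng = np.random.default_rng(5)
    counts = rng.integers(1, 30, size=(4, 4))
    rep = per_class_metrics(ConfusionMatrix(counts, kf.CLASSES))
    perm = [2, 0, 3, 1]
    permuted = counts[np.ix_(perm, perm)]
    names = tuple(kf.CLASSES[i] for i in perm)
    rep_p = per_class_metrics(ConfusionMatrix(permuted, names))
    assert rep.macro_precision == pytest.approx(rep_p.macro_precision, abs=1e-15)
    assert rep.macro_recall == pytest.approx(rep_p.macro_recall, abs=1e-15)
    assert rep.accuracy == pytest.approx(rep_p.accuracy, abs=1e-15)


def test_accuracy_equals_one_minus_error_mass():
    rng = np.random.default_rng(8)
    counts = rng.integers(0, 25, size=(4, 4))
    counts[0, 0] += 1
    rep = per_class_metrics(ConfusionMatrix(counts, kf.CLASSES))
    errors = counts.sum(axis=1) - np.diag(counts)
    assert rep.accuracy == pytest.approx(1 - errors.sum() / counts.sum())


def test_empty_confusion_rejected():
    with pytest.raises(ValueError, match="empty"):
        per_class_metrics(ConfusionMatrix(np.zeros((4, 4), int), kf.CLASSES))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def small_loaders(manifest, aug, batch=8, train_mode=True):
    tr = kf.ImageBatchLoader(manifest, aug, batch, training=train_mode, seed=0)
    va = kf.ImageBatchLoader(manifest, aug, batch, training=False, seed=0)
    return tr, va


def test_history_has_one_record_per_epoch(small_manifest, small_aug):
    sub = small_manifest.subset(range(8))
    tr, va = small_loaders(sub, small_aug)
    model = kf.build_single_classifier(kf.lookup("tiny_a"), head_seed=1)
    cfg = TrainConfig(learning_rate=1e-3, epochs=1, batch_size=8, seed=1)
    _, hist = train(model, tr, va, cfg)
    assert len(hist) == 1
    frame = hist.to_frame()
    assert list(frame.columns) == [
        "epoch", "train_loss", "val_loss", "train_accuracy", "val_accuracy"
    ]


def test_empty_loader_rejected(small_aug):
    empty = kf.DatasetManifest.from_records([])
    loader = kf.ImageBatchLoader(empty, small_aug, 8)
    model = kf.build_single_classifier(kf.lookup("tiny_a"))
    cfg = TrainConfig(epochs=1)
    with pytest.raises(ValueError, match="empty"):
        train(model, loader, loader, cfg)


def test_label_outside_head_range_rejected(small_manifest, small_aug):
    model = kf.build_single_classifier(
        kf.lookup("tiny_a"), n_classes=2, class_names=("A", "B")
    )
    tr, va = small_loaders(small_manifest, small_aug)  # yields labels 0..3
    cfg = TrainConfig(epochs=1)
    with pytest.raises(ValueError, match=r"\[0, 2\)"):
        train(model, tr, va, cfg)


def test_training_improves_on_separable_synthetic_data(small_manifest, small_aug):
    tr, va = small_loaders(small_manifest, small_aug, batch=8)
    model = kf.build_fused_classifier(kf.lookup("tiny_a"), kf.lookup("tiny_b"),
                                      head_seed=3)
    cfg = TrainConfig(learning_rate=3e-3, epochs=10, batch_size=8,
                      optimizer_name="custom_adam", seed=3,
                      beta1=0.98, beta2=0.9999, epsilon=1e-2)
    _, hist = train(model, tr, va, cfg)
    assert hist.train_accuracy[-1] > hist.train_accuracy[0]


def test_train_reproducible_under_seed(small_manifest, small_aug):
    results = []
    for _ in range(2):
        tr, va = small_loaders(small_manifest, small_aug)
        model = kf.build_fused_classifier(kf.lookup("tiny_a"),
                                          kf.lookup("tiny_b"), head_seed=2)
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=8, seed=2)
        model, hist = train(model, tr, va, cfg)
        results.append((model.head.weight.data.copy(), tuple(hist.train_loss)))
    assert np.array_equal(results[0][0], results[1][0])
    assert results[0][1] == results[1][1]


def test_config_validation():
    with pytest.raises(ValueError, match="epochs"):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError, match="optimizer"):
        TrainConfig(optimizer_name="sgd")
    with pytest.raises(ValueError, match="cross_entropy"):
        TrainConfig(loss="hinge")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def test_evaluate_deterministic(small_manifest, small_aug, tiny_fused):
    loader = kf.ImageBatchLoader(small_manifest, small_aug, 16, training=False)
    cm1, rep1 = evaluate(tiny_fused, loader)
    cm2, rep2 = evaluate(tiny_fused, loader)
    assert np.array_equal(cm1.counts, cm2.counts)
    assert rep1.accuracy == rep2.accuracy


def test_constant_classifier_recall_pattern(small_manifest, small_aug):
    model = kf.build_single_classifier(kf.lookup("tiny_a"))
    model.head.weight.data[:] = 0.0
    model.head.bias.data[:] = np.array([1.0, 0, 0, 0], np.float32)
    loader = kf.ImageBatchLoader(small_manifest, small_aug, 16, training=False)
    with pytest.warns(RuntimeWarning):
        cm, rep = evaluate(model, loader)
    assert rep.recall[0] == 1.0
    assert np.all(rep.recall[1:] == 0.0)
    assert cm.counts[:, 0].sum() == len(small_manifest)


def test_evaluate_empty_loader_rejected(small_aug, tiny_fused):
    empty = kf.DatasetManifest.from_records([])
    loader = kf.ImageBatchLoader(empty, small_aug, 8, training=False)
    with pytest.raises(ValueError, match="empty"):
        evaluate(tiny_fused, loader)


# ---------------------------------------------------------------------------
# reports and checkpoints
# ---------------------------------------------------------------------------

def test_write_report_files_and_round_trip(tmp_path, small_manifest, small_aug):
    sub = small_manifest.subset(range(0, 40, 2))
    tr, va = small_loaders(sub, small_aug)
    model = kf.build_fused_classifier(kf.lookup("tiny_a"), kf.lookup("tiny_b"),
                                      head_seed=4)
    cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=8, seed=4)
    model, hist = train(model, tr, va, cfg)
    cm, rep = evaluate(model, va)
    written = write_report(cm, rep, hist, tmp_path / "out")
    names = {p.split("/")[-1] for p in written}
    assert {"metrics.csv", "confusion_matrix.csv", "summary.json",
            "history.csv", "curves.png", "error_rates.png"} <= names

    metrics = pd.read_csv(tmp_path / "out" / "metrics.csv")
    assert len(metrics) == 5  # four classes + macro row
    assert list(metrics["class"]) == list(kf.CLASSES) + ["macro"]

    back = ConfusionMatrix.from_frame(
        pd.read_csv(tmp_path / "out" / "confusion_matrix.csv", index_col=0)
    )
    assert np.array_equal(back.counts, cm.counts)

    # deterministic rerun produces identical CSVs
    write_report(cm, rep, hist, tmp_path / "out2")
    for name in ("metrics.csv", "confusion_matrix.csv", "history.csv"):
        assert (tmp_path / "out" / name).read_bytes() == \
            (tmp_path / "out2" / name).read_bytes()


def test_checkpoint_round_trip(tmp_path, small_manifest, small_aug, tiny_fused):
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_fused, path)
    restored = load_checkpoint(path)
    x = np.random.default_rng(6).random((4, 3, 64, 64), dtype=np.float32)
    assert np.allclose(tiny_fused(x), restored(x), atol=1e-6)
    for name, p in restored.named_parameters():
        assert p.trainable == name.startswith("head.")
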