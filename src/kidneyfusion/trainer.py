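"""Training loop, confusion-matrix metrics, evaluation, and reports.

Training minimizes softmax cross-entropy over the linear head only; the
frozen extractors never change.  The head gradient is closed form: with
softmax probabilities ``p`` and one-hot targets ``y``,
``dL/dlogits = (p - y) / B``, so ``dW = dlogits^T F`` and ``db = sum of
dlogits`` for the feature matrix ``F``.  Parameters are advanced through
the package optimizer (standard Adam or the gradient-norm-scaled variant),
with frozen parameters passed as absent gradients.

Metric definitions (one-vs-rest per class ``i``):

* precision_i  = TP_i / (TP_i + FP_i)
* recall_i     = TP_i / (TP_i + FN_i)          (sensitivity)
* f1_i         = 2 P R / (P + R)
* specificity_i = TN_i / (TN_i + FP_i)         (true-negative rate)
* error_rate_i = 1 - recall_i                  (class-wise error rate)

Macro averages are unweighted means over classes; accuracy is the
confusion-matrix trace over its total.  Any 0/0 ratio is reported as 0.0
and flagged, keeping reports machine-readable.
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .backbones import lookup
from .datapipe import CLASSES
from .fusion import FusedClassifier, build_fused_classifier, build_single_classifier
from .optim import OPTIMIZER_NAMES, AdamHyperparams, Optimizer


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    loss: str = "cross_entropy"
    optimizer_name: str = "custom_adam"
    seed: int = 0
    # moment/stability hyperparameters of the optim block
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")
        if self.optimizer_name not in OPTIMIZER_NAMES:
            raise ValueError(
                f"unknown optimizer {self.optimizer_name!r}; "
                f"expected one of {sorted(OPTIMIZER_NAMES)}"
            )


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def append(self, tl, vl, ta, va):
        self.train_loss.append(float(tl))
        self.val_loss.append(float(vl))
        self.train_accuracy.append(float(ta))
        self.val_accuracy.append(float(va))

    def __len__(self):
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_accuracy": self.train_accuracy,
                "val_accuracy": self.val_accuracy,
            }
        )


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = number of samples with true class i predicted as j."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.class_names)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be C x C for C class names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConfusionMatrix":
        return cls(df.to_numpy(), tuple(df.index))


def confusion_matrix(y_true, y_pred, n_classes: int | None = None,
                     class_names=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted"
        )
    if class_names is None:
        if n_classes is None:
            raise ValueError("provide n_classes or class_names")
        class_names = CLASSES if n_classes == len(CLASSES) else tuple(
            f"class_{i}" for i in range(n_classes)
        )
    C = len(class_names)
    for arr, what in ((y_true, "true"), (y_pred, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= C):
            raise ValueError(f"{what} labels must lie in [0, {C})")
    counts = np.zeros((C, C), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, tuple(class_names))


@dataclass
class MetricsReport:
    class_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    specificity: np.ndarray
    error_rate: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_specificity: float
    zero_division_flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.class_names):
            rows.append(
                {
                    "class": c,
                    "precision": self.precision[i],
                    "recall": self.recall[i],
                    "f1": self.f1[i],
                    "specificity": self.specificity[i],
                    "error_rate": self.error_rate[i],
                }
            )
        rows.append(
            {
                "class": "macro",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
                "specificity": self.macro_specificity,
                "error_rate": float(np.mean(self.error_rate)),
            }
        )
        df = pd.DataFrame(rows)
        df.attrs["accuracy"] = self.accuracy
        return df


def _safe_ratio(num, den, flags, what):
    out = np.zeros_like(num, dtype=np.float64)
    for i in range(num.size):
        if den[i] == 0:
            flags.append(what[i])
        else:
            out[i] = num[i] / den[i]
    return out


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest metrics of a confusion matrix (see module docstring)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = counts.sum() - tp - fp - fn
    names = cm.class_names
    flags: list[str] = []
    precision = _safe_ratio(tp, tp + fp, flags, [f"precision[{c}]" for c in names])
    recall = _safe_ratio(tp, tp + fn, flags, [f"recall[{c}]" for c in names])
    f1 = _safe_ratio(2 * precision * recall, precision + recall, flags,
                     [f"f1[{c}]" for c in names])
    specificity = _safe_ratio(tn, tn + fp, flags,
                              [f"specificity[{c}]" for c in names])
    if flags:
        warnings.warn(
            f"0/0 metric cells reported as 0: {flags}", RuntimeWarning, stacklevel=2
        )
    return MetricsReport(
        class_names=names,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        error_rate=1.0 - recall,
        accuracy=float(tp.sum() / counts.sum()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        macro_specificity=float(specificity.mean()),
        zero_division_flags=flags,
    )


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

def _cross_entropy(logits, labels):
    p = nn.softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(labels.size), labels] + eps).mean()
    return float(loss), p


def _check_labels(labels, C):
    if labels.size and (labels.min() < 0 or labels.max() >= C):
        raise ValueError(f"labels must lie in [0, {C})")


def train(model: FusedClassifier, train_loader, val_loader, cfg: TrainConfig,
          verbose: bool = False):
    """Train the classifier head; returns ``(model, TrainHistory)``.

    Only head parameters change (frozen extractors are passed to the
    optimizer with absent gradients and skipped).  Fully reproducible under
    ``cfg.seed`` on a single worker.
    """
    if len(train_loader) == 0:
        raise ValueError("training loader is empty")
    if len(val_loader) == 0:
        raise ValueError("validation loader is empty")
    params = model.parameters()
    wp, bp = model.head.weight, model.head.bias
    hp = AdamHyperparams(
        alpha=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2,
        epsilon=cfg.epsilon, variant=OPTIMIZER_NAMES[cfg.optimizer_name],
    )
    opt = Optimizer(hp)
    history = TrainHistory()
    C = model.n_classes

    for epoch in range(cfg.epochs):
        model.train()
        for i, mod in enumerate(model.modules()):
            if isinstance(mod, nn.Dropout):
                mod.reseed(np.random.SeedSequence((cfg.seed, epoch, i, 0xD0)))
        loss_sum = correct = seen = 0
        for images, labels in train_loader.batches(epoch):
            _check_labels(labels, C)
            feats = model.features(images)
            logits = model.head(feats)
            loss, p = _cross_entropy(logits, labels)
            B = labels.size
            dlogits = (p - np.eye(C)[labels]) / B
            grads = []
            for q in params:
                if q is wp:
                    grads.append(dlogits.T @ feats)
                elif q is bp:
                    grads.append(dlogits.sum(axis=0))
                else:
                    grads.append(None)
            new_data = opt.step([q.data for q in params], grads)
            for q, nd in zip(params, new_data):
                if nd is not q.data:
                    q.data = nd
            loss_sum += loss * B
            correct += int((np.argmax(logits, axis=1) == labels).sum())
            seen += B
        train_loss, train_acc = loss_sum / seen, correct / seen

        model.eval()
        vloss_sum = vcorrect = vseen = 0
        for images, labels in val_loader.batches(epoch):
            _check_labels(labels, C)
            logits = model(images)
            loss, _ = _cross_entropy(logits, labels)
            vloss_sum += loss * labels.size
            vcorrect += int((np.argmax(logits, axis=1) == labels).sum())
            vseen += labels.size
        val_loss, val_acc = vloss_sum / vseen, vcorrect / vseen
        history.append(train_loss, val_loss, train_acc, val_acc)
        if verbose:
            print(
                f"epoch {epoch + 1}/{cfg.epochs} "
                f"train_loss={train_loss:.4f} train_acc={train_acc:.4f} "
                f"val_loss={val_loss:.4f} val_acc={val_acc:.4f}",
                file=sys.stderr,
            )
    model.eval()
    return model, history


def evaluate(model: FusedClassifier, loader):
    """Argmax evaluation -> ``(ConfusionMatrix, MetricsReport)``.

    Deterministic given the model and the loader's configuration (the model
    is put in evaluation mode; stochastic layers are disabled)."""
    if len(loader) == 0:
        raise ValueError("evaluation loader is empty")
    model.eval()
    ys, ps = [], []
    for images, labels in loader.batches(0):
        _check_labels(labels, model.n_classes)
        ys.append(labels)
        ps.append(model.predict(images))
    cm = confusion_matrix(
        np.concatenate(ys), np.concatenate(ps), class_names=model.class_names
    )
    return cm, per_class_metrics(cm)


# ---------------------------------------------------------------------------
# reports and checkpoints
# ---------------------------------------------------------------------------

def write_report(cm: ConfusionMatrix, report: MetricsReport,
                 history: TrainHistory | None, out_dir) -> list[str]:
    """Write metrics/confusion/history CSVs and PNG plots; returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    mpath = out_dir / "metrics.csv"
    report.to_frame().to_csv(mpath, index=False)
    written.append(str(mpath))

    cpath = out_dir / "confusion_matrix.csv"
    cm.to_frame().to_csv(cpath)
    written.append(str(cpath))

    apath = out_dir / "summary.json"
    apath.write_text(json.dumps(
        {
            "accuracy": report.accuracy,
            "macro_precision": report.macro_precision,
            "macro_recall": report.macro_recall,
            "macro_f1": report.macro_f1,
            "macro_specificity": report.macro_specificity,
            "zero_division_flags": report.zero_division_flags,
        },
        indent=2,
    ))
    written.append(str(apath))

    if history is not None and len(history):
        hpath = out_dir / "history.csv"
        history.to_frame().to_csv(hpath, index=False)
        written.append(str(hpath))
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        ep = np.arange(1, len(history) + 1)
        axes[0].plot(ep, history.train_loss, label="train")
        axes[0].plot(ep, history.val_loss, label="validation")
        axes[0].set_xlabel("epoch"); axes[0].set_ylabel("loss")
        axes[0].set_title("Training and validation loss"); axes[0].legend()
        axes[1].plot(ep, history.train_accuracy, label="train")
        axes[1].plot(ep, history.val_accuracy, label="validation")
        axes[1].set_xlabel("epoch"); axes[1].set_ylabel("accuracy")
        axes[1].set_title("Training and validation accuracy"); axes[1].legend()
        fig.tight_layout()
        ppath = out_dir / "curves.png"
        fig.savefig(ppath, dpi=100)
        plt.close(fig)
        written.append(str(ppath))

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(list(cm.class_names), report.error_rate)
    ax.set_ylabel("class-wise error rate (1 - recall)")
    ax.set_title("Class-wise error rate")
    fig.tight_layout()
    epath = out_dir / "error_rates.png"
    fig.savefig(epath, dpi=100)
    plt.close(fig)
    written.append(str(epath))
    return written


def save_checkpoint(model: FusedClassifier, path) -> None:
    """Serialize the full model (architecture metadata + all weights)."""
    meta = {
        "backbone_a": model.extractor_a.spec.name,
        "policy_a": model.extractor_a.spec.truncation_policy,
        "backbone_b": model.extractor_b.spec.name if model.extractor_b else None,
        "policy_b": model.extractor_b.spec.truncation_policy if model.extractor_b else None,
        "n_classes": model.n_classes,
        "class_names": list(model.class_names),
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ), **model.state())


def load_checkpoint(path) -> FusedClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec_a = lookup(meta["backbone_a"], meta["policy_a"]
                    if meta["backbone_a"] == "convnext_large" else None)
    if meta["backbone_b"]:
        spec_b = lookup(meta["backbone_b"], meta["policy_b"]
                        if meta["backbone_b"] == "convnext_large" else None)
        model = build_fused_classifier(spec_a, spec_b, meta["n_classes"],
                                       tuple(meta["class_names"]),
                                       weights_a="zeros", weights_b="zeros")
    else:
        model = build_single_classifier(spec_a, meta["n_classes"],
                                        tuple(meta["class_names"]),
                                        weights="zeros")
    model.load_state(state)
    for name, p in model.named_parameters():
        p.trainable = name.startswith("head.")
    return model
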