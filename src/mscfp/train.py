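"""Training loop, metric computation and the 8-way ablation runner.

Training follows the published protocol — cross-entropy minimized by SGD
for a configurable number of epochs (100 by default) on the 9:1 stratified
split — with the unstated hyperparameters fixed at lr 0.01, momentum 0.9,
weight decay 1e-4 and batch size 16.  Inputs are normalized per image to
[0, 1]; THz slices are geometry-calibrated, so no augmentation is applied.
Evaluation reports the confusion matrix and macro-averaged precision,
recall and F1 (percentages) over the four mold classes; per-class accuracy
is reported one-vs-rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .data import MOLD_CLASSES, TEST, TRAIN, LabeledImageSet
from .model import ModelConfig, MSCFPNet
from .nn import SGD, cross_entropy, softmax

log = logging.getLogger(__name__)


def normalize_images(images: list[np.ndarray], dtype=np.float32) -> np.ndarray:
    """Per-image min-max normalization to [0, 1], stacked as [N, 1, H, W]."""
    out = np.empty((len(images), 1) + images[0].shape, dtype=dtype)
    for i, img in enumerate(images):
        lo, hi = float(img.min()), float(img.max())
        span = hi - lo
        out[i, 0] = (img - lo) / span if span > 0 else 0.0
    return out


@dataclass
class EvalReport:
    confusion: np.ndarray          # [K, K] rows = true class
    accuracy: float                # %
    precision: float               # % macro
    recall: float                  # % macro
    f1: float                      # % macro
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "confusion": self.confusion.tolist(),
                "per_class": self.per_class}


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    n_classes: int = 4) -> EvalReport:
    labels = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    acc = 100.0 * np.trace(cm) / cm.sum()
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0)
    pc_p, pc_r, pc_f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0)
    total = cm.sum()
    per_class = {}
    for k in range(n_classes):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        per_class[MOLD_CLASSES[k] if k < len(MOLD_CLASSES) else str(k)] = {
            "precision": 100.0 * pc_p[k],
            "recall": 100.0 * pc_r[k],
            "f1": 100.0 * pc_f1[k],
            "accuracy_ovr": 100.0 * (tp + tn) / total,
        }
    return EvalReport(confusion=cm, accuracy=float(acc),
                      precision=float(100.0 * p), recall=float(100.0 * r),
                      f1=float(100.0 * f1), per_class=per_class)


def predict(model: MSCFPNet, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    model.eval()
    preds = []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size])
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


@dataclass
class TrainResult:
    model: MSCFPNet
    history: pd.DataFrame          # epoch, loss, accuracy


def train(cfg: ModelConfig, data: LabeledImageSet, epochs: int = 100,
          seed: int = 0, lr: float = 0.01, momentum: float = 0.9,
          weight_decay: float = 1e-4, batch_size: int = 16,
          dtype=np.float32) -> TrainResult:
    """Fit MSCFP-Net on the train split of ``data``.

    Deterministic given ``seed`` (parameter init and batch order both derive
    from it).  Aborts with a diagnostic if the loss goes non-finite.
    """
    train_set = data.subset(TRAIN)
    if len(train_set) == 0:
        raise ValueError("empty train split")
    x = normalize_images(train_set.images, dtype=dtype)
    y = train_set.labels
    model = MSCFPNet(cfg, seed=seed, dtype=dtype)
    opt = SGD(model.params(), lr=lr, momentum=momentum,
              weight_decay=weight_decay)
    rng = np.random.default_rng([seed, 1])
    rows = []
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(len(x))
        losses, hits = [], 0
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb)
            loss, dlogits = cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // batch_size}"
                    f" (lr={lr}); reduce the learning rate")
            opt.zero_grad()
            model.backward(dlogits.astype(dtype))
            opt.step()
            losses.append(loss * len(idx))
            hits += int((np.argmax(logits, axis=1) == yb).sum())
        rows.append({"epoch": epoch + 1,
                     "loss": float(np.sum(losses) / len(x)),
                     "accuracy": 100.0 * hits / len(x)})
        log.info("epoch %d/%d loss %.4f acc %.2f%%", epoch + 1, epochs,
                 rows[-1]["loss"], rows[-1]["accuracy"])
    return TrainResult(model=model, history=pd.DataFrame(rows))


def evaluate(model: MSCFPNet, data: LabeledImageSet,
             split: str = TEST) -> EvalReport:
    """Metrics on one split of ``data`` (the test split by default)."""
    subset = data.subset(split)
    if len(subset) == 0:
        raise ValueError(f"empty {split} split")
    x = normalize_images(subset.images,
                         dtype=model.head.fc.weight.data.dtype)
    y_pred = predict(model, x)
    return compute_metrics(subset.labels, y_pred, n_classes=model.cfg.n_classes)


#: The ablation grid: every on/off combination of the three modules, in the
#: order baseline -> single additions -> pairs -> full model.
ABLATION_TOGGLES = [
    (False, False, False), (True, False, False), (False, True, False),
    (False, False, True), (True, True, False), (True, False, True),
    (False, True, True), (True, True, True),
]


def run_ablation(base_cfg: ModelConfig, data: LabeledImageSet, seed: int = 0,
                 toggles: list[tuple] = None, epochs: int = 100,
                 **train_kw) -> pd.DataFrame:
    """Train/evaluate one model per toggle triple (MCFEM, CA, Bi-FPN).

    All runs share the data, seed and hyperparameters; returns one result
    row per configuration.
    """
    toggles = list(toggles) if toggles is not None else list(ABLATION_TOGGLES)
    if len(set(toggles)) != len(toggles):
        raise ValueError("duplicate ablation configurations")
    rows = []
    for g, (mc, ca, bf) in enumerate(toggles, start=1):
        cfg = base_cfg.with_toggles(mcfem=mc, ca=ca, bifpn=bf)
        result = train(cfg, data, epochs=epochs, seed=seed, **train_kw)
        report = evaluate(result.model, data)
        rows.append({"group": g, "mcfem": mc, "ca": ca, "bifpn": bf,
                     "accuracy": report.accuracy, "precision": report.precision,
                     "recall": report.recall, "f1": report.f1})
        log.info("ablation group %d (mcfem=%s ca=%s bifpn=%s): acc %.2f%%",
                 g, mc, ca, bf, report.accuracy)
    return pd.DataFrame(rows)
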