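"""Evaluation battery: confusion matrix, Top-1, per-class precision /
one-vs-rest accuracy / recall / F1, and OvR ROC-AUC with micro, macro and
class-proportion-weighted averaging.

Conventions (the source formulas leave these open):

- argmax ties break toward the lowest class index;
- a metric whose denominator is zero is reported as 0.0 with a warning;
- per-class AUC is rank-based (Mann-Whitney with mid-rank ties, identical
  to trapezoidal ROC integration); a class with no positives or no
  negatives has undefined AUC and is excluded from the macro and weighted
  averages with a warning (the weighted average renormalizes the remaining
  class proportions).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

#: display names of the five retained growth stages, in label order 0..4.
STAGE_NAMES = ("Tillering", "Mid Vegetative", "Booting", "Heading", "Milking")


@dataclass
class ConfusionMatrix:
    """Counts[t, p] = number of samples with true class t predicted as p."""

    counts: np.ndarray  # int [K, K]

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def tn(self) -> np.ndarray:
        return self.total - self.tp() - self.fp() - self.fn()


def _validate_labels(y: np.ndarray, k: int, name: str) -> np.ndarray:
    y = np.asarray(y)
    bad = np.nonzero((y < 0) | (y >= k))[0]
    if bad.size:
        raise ValueError(
            f"{name}[{bad[0]}] = {y[bad[0]]} outside label range [0, {k})")
    return y.astype(np.intp)


def confusion_matrix(y_true, y_pred, num_classes: int) -> ConfusionMatrix:
    y_true = _validate_labels(y_true, num_classes, "y_true")
    y_pred = _validate_labels(y_pred, num_classes, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    counts = np.bincount(y_true * num_classes + y_pred,
                         minlength=num_classes * num_classes)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes))


def top1_accuracy(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("top1_accuracy undefined on empty input")
    return float((y_true == y_pred).mean())


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        warnings.warn(f"{what}: zero denominator for class(es) "
                      f"{np.nonzero(~ok)[0].tolist()}; reporting 0.0")
    return out


def per_class_metrics(cm: ConfusionMatrix):
    """(precision_i, ovr_accuracy_i, recall_i, f1_i) per class."""
    tp, fp, fn, tn = cm.tp(), cm.fp(), cm.fn(), cm.tn()
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    ovr_accuracy = _safe_div(tp + tn, tp + tn + fp + fn, "ovr_accuracy")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return precision, ovr_accuracy, recall, f1


def _binary_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with mid-rank tie handling; nan if degenerate."""
    pos = labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def _roc_curve(labels: np.ndarray, scores: np.ndarray):
    """(fpr, tpr) point table, thresholds descending."""
    order = np.argsort(-scores, kind="stable")
    labels = labels[order].astype(bool)
    scores = scores[order]
    distinct = np.r_[np.nonzero(np.diff(scores))[0], labels.size - 1]
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(~labels)[distinct]
    tps = np.r_[0, tps]
    fps = np.r_[0, fps]
    n_pos = max(int(labels.sum()), 1)
    n_neg = max(int((~labels).sum()), 1)
    return fps / n_neg, tps / n_pos


@dataclass
class RocResult:
    curves: list[tuple[np.ndarray, np.ndarray]]  # per-class (fpr, tpr)
    auc_per_class: np.ndarray                    # nan where undefined
    auc_micro: float
    auc_macro: float
    auc_weighted_ovr: float


def roc_auc_ovr(y_true, scores) -> RocResult:
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("score matrix contains non-finite values")
    m, k = scores.shape
    y_true = _validate_labels(y_true, k, "y_true")
    onehot = np.zeros((m, k), dtype=int)
    onehot[np.arange(m), y_true] = 1

    aucs = np.array([_binary_auc(onehot[:, i], scores[:, i]) for i in range(k)])
    curves = [_roc_curve(onehot[:, i], scores[:, i]) for i in range(k)]
    defined = ~np.isnan(aucs)
    if not defined.all():
        warnings.warn("classes with no positives or no negatives excluded "
                      f"from AUC averages: {np.nonzero(~defined)[0].tolist()}")

    proportions = np.bincount(y_true, minlength=k) / m
    present = proportions > 0
    macro_mask = defined & present
    auc_macro = float(aucs[macro_mask].mean()) if macro_mask.any() else float("nan")
    wmask = defined & (proportions > 0)
    wsum = proportions[wmask].sum()
    auc_weighted = (float((aucs[wmask] * proportions[wmask]).sum() / wsum)
                    if wsum > 0 else float("nan"))
    auc_micro = _binary_auc(onehot.ravel(), scores.ravel())
    return RocResult(curves, aucs, auc_micro, auc_macro, auc_weighted)


@dataclass
class MetricReport:
    """Everything the evaluation protocol reports for one model/test set."""

    confusion: ConfusionMatrix
    top1: float
    precision: np.ndarray
    ovr_accuracy: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    proportions: np.ndarray
    auc_per_class: np.ndarray
    auc_micro: float
    auc_macro: float
    auc_weighted_ovr: float
    class_names: tuple[str, ...] = field(default=STAGE_NAMES)

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_dict(self) -> dict:
        per_class = {}
        for i, name in enumerate(self.class_names):
            per_class[name] = {
                "precision": float(self.precision[i]),
                "ovr_accuracy": float(self.ovr_accuracy[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
                "proportion": float(self.proportions[i]),
                "auc": (None if np.isnan(self.auc_per_class[i])
                        else float(self.auc_per_class[i])),
            }
        return {
            "top1": self.top1,
            "macro_f1": self.macro_f1,
            "auc_micro": self.auc_micro,
            "auc_macro": self.auc_macro,
            "auc_weighted_ovr": self.auc_weighted_ovr,
            "per_class": per_class,
            "confusion_matrix": self.confusion.counts.tolist(),
        }


def compute_report(y_true, y_pred, scores=None, num_classes: int | None = None,
                   class_names: tuple[str, ...] | None = None) -> MetricReport:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        k = scores.shape[1]
    else:
        k = num_classes
    if k is None:
        raise ValueError("num_classes required when scores are absent")
    names = tuple(class_names) if class_names else (
        STAGE_NAMES if k == 5 else tuple(f"class_{i}" for i in range(k)))
    cm = confusion_matrix(y_true, y_pred, k)
    precision, ovr_acc, recall, f1 = per_class_metrics(cm)
    proportions = np.bincount(_validate_labels(y_true, k, "y_true"),
                              minlength=k) / max(len(y_true), 1)
    if scores is not None:
        roc = roc_auc_ovr(y_true, scores)
        aucs, micro, macro, weighted = (roc.auc_per_class, roc.auc_micro,
                                        roc.auc_macro, roc.auc_weighted_ovr)
    else:
        aucs = np.full(k, np.nan)
        micro = macro = weighted = float("nan")
    return MetricReport(cm, top1_accuracy(y_true, y_pred), precision, ovr_acc,
                        recall, f1, proportions, aucs, micro, macro, weighted,
                        names)


# -- report writers ------------------------------------------------------------

def write_report(report: MetricReport, out_dir: str | Path,
                 roc: RocResult | None = None) -> dict[str, Path]:
    """JSON + CSV report files; confusion matrix CSV has stage-name header
    row/column; optional per-class ROC point tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["json"] = out_dir / "metrics.json"
    paths["json"].write_text(json.dumps(report.to_dict(), indent=2))

    paths["csv"] = out_dir / "metrics.csv"
    with paths["csv"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "precision", "ovr_accuracy", "recall", "f1",
                    "proportion", "auc"])
        for i, name in enumerate(report.class_names):
            auc = report.auc_per_class[i]
            w.writerow([name, f"{report.precision[i]:.6f}",
                        f"{report.ovr_accuracy[i]:.6f}",
                        f"{report.recall[i]:.6f}", f"{report.f1[i]:.6f}",
                        f"{report.proportions[i]:.6f}",
                        "" if np.isnan(auc) else f"{auc:.6f}"])

    paths["confusion"] = out_dir / "confusion_matrix.csv"
    with paths["confusion"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["true\\pred", *report.class_names])
        for i, name in enumerate(report.class_names):
            w.writerow([name, *report.confusion.counts[i].tolist()])

    if roc is not None:
        for i, (fpr, tpr) in enumerate(roc.curves):
            p = out_dir / f"roc_{report.class_names[i].replace(' ', '_')}.csv"
            with p.open("w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["fpr", "tpr"])
                w.writerows(zip(fpr, tpr))
            paths[f"roc_{i}"] = p
    return paths
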