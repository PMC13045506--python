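"""Independent brute-force oracles for the metric tests.

Deliberately naive (loops, exhaustive pair counting) so they share no code
path with the implementation they check.
"""

import numpy as np


def tally_confusion(y_true, y_pred, k):
    counts = [[0] * k for _ in range(k)]
    for t, p in zip(y_true, y_pred):
        counts[int(t)][int(p)] += 1
    return np.array(counts)


def tally_accuracy(y_true, y_pred):
    return sum(int(t == p) for t, p in zip(y_true, y_pred)) / len(y_true)


def per_class_from_counts(counts, i):
    k = counts.shape[0]
    m = counts.sum()
    tp = counts[i][i]
    fp = sum(counts[t][i] for t in range(k)) - tp
    fn = sum(counts[i][p] for p in range(k)) - tp
    tn = m - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    ovr_acc = (tp + tn) / m
    return precision, ovr_acc, recall, f1


def pair_counting_auc(labels, scores):
    """AUC by exhaustive positive-negative pair comparison (ties = 1/2)."""
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
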