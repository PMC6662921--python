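"""Ranking metrics for heavily imbalanced binary classification."""

from __future__ import annotations

import numpy as np

from .errors import UndefinedMetricError


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve via the average-precision
    estimator (step interpolation).

    Positives are visited in descending-score order and the precision at each
    positive's rank is averaged.  Equal scores are treated as one group and
    receive the precision at the end of the group, so the value is invariant
    to the ordering of ties.  Under a constant score the result equals the
    prevalence; under a perfect ranking it equals 1.
    """
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.size != s.size:
        raise ValueError(f"labels and scores differ in length ({y.size} != {s.size})")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise UndefinedMetricError(
            "average precision is undefined for single-class labels"
        )
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tp = np.cumsum(ys)
    # index of the last element of each tie group
    group_end = np.flatnonzero(np.diff(ss) != 0)
    group_end = np.concatenate([group_end, [y.size - 1]])
    tp_end = tp[group_end]
    precision = tp_end / (group_end + 1)
    delta_tp = np.diff(np.concatenate([[0.0], tp_end]))
    return float(np.sum(precision * delta_tp) / n_pos)


def auprc_bruteforce(labels, scores) -> float:
    """O(n^2) reference for :func:`auprc`: for each positive, the precision
    over the set of items scoring at least as high, averaged over positives.

    Kept deliberately naive as an independent cross-check.
    """
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise UndefinedMetricError(
            "average precision is undefined for single-class labels"
        )
    total = 0.0
    for i in range(y.size):
        if y[i] != 1:
            continue
        at_least = s >= s[i]
        total += y[at_least].sum() / at_least.sum()
    return float(total / n_pos)
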