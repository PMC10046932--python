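"""Dataset splitting and confusion-matrix diagnostics.

Accuracy, sensitivity (true-positive rate) and specificity (true-negative
rate) are computed from the 2x2 confusion table with "tumor" as the
positive class:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def split_dataset(items: list, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[list, list]:
    """Stratified, reproducible train/test split.

    The overall training size is exactly ``round(n * train_fraction)``;
    per-class allocations use largest-remainder rounding so label
    proportions are preserved within one item per class.  Items must expose
    a ``label`` attribute (or be (item, label) pairs).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    labels = [getattr(it, "label", it[1] if isinstance(it, tuple) else None)
              for it in items]
    if any(lbl is None for lbl in labels):
        raise ValueError("items must carry a label")
    n = len(items)
    n_train = int(round(n * train_fraction))
    rng = np.random.default_rng(seed)

    by_class: dict = {}
    for i, lbl in enumerate(labels):
        by_class.setdefault(lbl, []).append(i)
    for lbl, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {lbl!r} has fewer than 2 items")

    # Largest-remainder allocation of n_train across classes.
    classes = sorted(by_class)
    exact = {lbl: len(by_class[lbl]) * n_train / n for lbl in classes}
    alloc = {lbl: int(np.floor(exact[lbl])) for lbl in classes}
    short = n_train - sum(alloc.values())
    for lbl in sorted(classes, key=lambda c: exact[c] - alloc[c], reverse=True):
        if short <= 0:
            break
        alloc[lbl] += 1
        short -= 1

    train_idx, test_idx = [], []
    for lbl in classes:
        idx = np.array(by_class[lbl])
        rng.shuffle(idx)
        train_idx.extend(idx[:alloc[lbl]])
        test_idx.extend(idx[alloc[lbl]:])
    rng.shuffle(train_idx)
    rng.shuffle(test_idx)
    return [items[i] for i in train_idx], [items[i] for i in test_idx]


def confusion(predicted, truth, positive_class="tumor") -> ConfusionCounts:
    """Standard 2x2 confusion counts with the given positive class."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    p_pos = pred == positive_class
    t_pos = true == positive_class
    return ConfusionCounts(
        tp=int(np.sum(p_pos & t_pos)),
        tn=int(np.sum(~p_pos & ~t_pos)),
        fp=int(np.sum(p_pos & ~t_pos)),
        fn=int(np.sum(~p_pos & t_pos)),
    )


def accuracy(cc: ConfusionCounts) -> float:
    if cc.total == 0:
        raise ValueError("empty confusion counts")
    return (cc.tp + cc.tn) / cc.total


def sensitivity(cc: ConfusionCounts) -> float:
    if cc.tp + cc.fn == 0:
        raise ValueError("no positive items")
    return cc.tp / (cc.tp + cc.fn)


def specificity(cc: ConfusionCounts) -> float:
    if cc.tn + cc.fp == 0:
        raise ValueError("no negative items")
    return cc.tn / (cc.tn + cc.fp)


def metric_report(cc: ConfusionCounts) -> dict:
    """JSON-ready report of the counts and the three metrics."""
    return {
        "tp": cc.tp, "tn": cc.tn, "fp": cc.fp, "fn": cc.fn,
        "accuracy": accuracy(cc),
        "sensitivity": sensitivity(cc),
        "specificity": specificity(cc),
    }
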