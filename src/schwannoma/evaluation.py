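"""Classification performance metrics and balanced data partitioning.

Conventions: the positive class is the active-treatment decision.  Every
metric with an undefined denominator (e.g. TNR when there are no real
negatives) is reported as ``None`` — never coerced to zero.

ACC = (TP+TN)/(P+N), TPR = TP/P, TNR = TN/N, PPV = TP/(TP+FP); AUC is the
area under the ROC curve (equivalently the tie-adjusted Mann-Whitney
probability that a positive outscores a negative); ASE is the mean squared
difference between the 0/1 target and the continuous classifier output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def _as01(labels: Sequence, positive=None) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        if positive is None:
            positive = "Active" if "Active" in arr else "Yes"
        return (arr == positive).astype(int)
    return arr.astype(int)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n


def confusion(labels: Sequence, predictions: Sequence, positive=None) -> ConfusionCounts:
    """Cross-tabulate binary labels against predictions."""
    y = _as01(labels, positive)
    yhat = _as01(predictions, positive)
    if len(y) != len(yhat):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(yhat)} predictions")
    if len(y) == 0:
        raise ValueError("empty inputs")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


@dataclass(frozen=True)
class MetricsReport:
    acc: float | None
    tpr: float | None
    tnr: float | None
    ppv: float | None
    auc: float | None = None
    ase: float | None = None
    #: True when auc was computed from hard class predictions rather than a
    #: continuous score (two-point ROC).
    degenerate_scores: bool = False

    def as_dict(self) -> dict:
        return dict(acc=self.acc, tpr=self.tpr, tnr=self.tnr, ppv=self.ppv,
                    auc=self.auc, ase=self.ase)


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve; ties between scores count one half.

    Delegates to the trapezoidal ROC integral, which equals the normalized
    Mann-Whitney U statistic.
    """
    from sklearn.metrics import roc_auc_score

    y = _as01(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def ase(targets: Sequence, outputs: Sequence[float]) -> float:
    """Average square error between 0/1 targets and continuous outputs."""
    y = _as01(targets).astype(float)
    out = np.asarray(outputs, dtype=float)
    if len(y) != len(out):
        raise ValueError("length mismatch")
    return float(np.mean((y - out) ** 2))


def metrics(
    counts: ConfusionCounts,
    scores: Sequence[float] | None = None,
    labels: Sequence | None = None,
    degenerate_scores: bool = False,
) -> MetricsReport:
    """Apply the metric formulas to confusion counts (+AUC/ASE when scored)."""
    def ratio(num, den):
        return num / den if den > 0 else None

    auc_v = ase_v = None
    if scores is not None:
        if labels is None:
            raise ValueError("scores given without labels")
        y = _as01(labels)
        auc_v = roc_auc(scores, y) if len(set(y.tolist())) == 2 else None
        ase_v = ase(y, scores)
    return MetricsReport(
        acc=ratio(counts.tp + counts.tn, counts.total),
        tpr=ratio(counts.tp, counts.p),
        tnr=ratio(counts.tn, counts.n),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        auc=auc_v,
        ase=ase_v,
        degenerate_scores=degenerate_scores,
    )


# ---------------------------------------------------------------------------
# balanced splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions (percent), balancing flag, and seed."""

    proportions: tuple[int, int, int] = (50, 30, 20)
    balanced: bool = True
    seed: int = 0

    def __post_init__(self):
        if sum(self.proportions) != 100:
            raise ValueError("split proportions must sum to 100")


def _largest_remainder(n: int, proportions: Sequence[int]) -> list[int]:
    quotas = [n * p / 100.0 for p in proportions]
    sizes = [int(q) for q in quotas]
    remainder = n - sum(sizes)
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def balanced_split(dataset, target: str, spec: SplitSpec = SplitSpec()):
    """Class-balance (majority down-sampled, seeded) then split 50:30:20.

    Partition sizes per class follow the largest-remainder rule, so the class
    ratio is equal across partitions up to rounding.  Returns three disjoint
    DataFrames whose union is the balanced set.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    classes = list(pd.unique(dataset[target]))
    if len(classes) != 2:
        raise ValueError(f"target must be binary, got {classes}")
    groups = {c: dataset.index[dataset[target] == c].to_numpy() for c in classes}
    n_min = min(len(v) for v in groups.values())
    if n_min < 5:
        raise ValueError(f"a class has fewer than 5 members (minority={n_min})")

    parts: list[list] = [[], [], []]
    for c in sorted(classes, key=str):
        idx = np.array(sorted(groups[c], key=str))
        if spec.balanced and len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        idx = rng.permutation(idx)
        sizes = _largest_remainder(len(idx), spec.proportions)
        a, b = sizes[0], sizes[0] + sizes[1]
        parts[0].append(idx[:a])
        parts[1].append(idx[a:b])
        parts[2].append(idx[b:])
    out = tuple(dataset.loc[np.concatenate(chunk)] for chunk in parts)
    return out
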