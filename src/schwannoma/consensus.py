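"""Ensemble-consensus feature selection.

Five supervised rankers (decision tree, random forest, gradient boosting,
logistic regression, LASSO) each nominate their ten most important variables.
The consensus table counts, for every nominated variable, in how many top-10
lists it occurs (``Num``) and its average rank over those lists (``Avg``,
rank 1 = most important).  A variable is a selection candidate when
``Num >= 3`` or ``Avg <= 5`` — the occurrence/ranking rule used for the
expert shortlists; the final minimal set is an expert judgment, so
:func:`select_candidates` also accepts an explicit override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RANKER_IDS = (
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "logistic_regression",
    "lasso",
)


@dataclass(frozen=True)
class RankedList:
    """Ordered top variables of one ranker; entries[0] has rank 1.

    ``ranks`` may be given explicitly when a list has gaps (e.g. a source
    table entry that had to be discarded); it defaults to 1..len(entries).
    """

    method_id: str
    entries: tuple[str, ...]
    ranks: tuple[int, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        if self.ranks is None:
            object.__setattr__(self, "ranks", tuple(range(1, len(self.entries) + 1)))
        else:
            object.__setattr__(self, "ranks", tuple(self.ranks))
        if len(set(self.entries)) != len(self.entries):
            raise ValueError(f"{self.method_id}: duplicate variables in ranked list")
        if len(self.ranks) != len(self.entries):
            raise ValueError(f"{self.method_id}: ranks/entries length mismatch")
        if any(b <= a for a, b in zip(self.ranks, self.ranks[1:])):
            raise ValueError(f"{self.method_id}: ranks must be strictly increasing")
        if self.ranks and not (1 <= self.ranks[0] and self.ranks[-1] <= 10):
            raise ValueError(f"{self.method_id}: ranks must lie within 1..10")

    def rank_of(self, variable: str) -> int | None:
        try:
            return self.ranks[self.entries.index(variable)]
        except ValueError:
            return None


@dataclass(frozen=True)
class ConsensusEntry:
    variable: str
    num: int
    rank_sum: int
    avg: float
    selected: bool

    @property
    def avg_display(self) -> float:
        """Avg rounded to one decimal, half away from zero (13/4 -> 3.3)."""
        exact = Decimal(self.rank_sum) / Decimal(self.num)
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def consensus_table(
    lists: Sequence[RankedList],
    min_occurrence: int = 3,
    max_avg_rank: float = 5.0,
) -> list[ConsensusEntry]:
    """Aggregate ranked lists into per-variable (Num, Avg, selected) entries.

    Entries are ordered by (Num descending, Avg ascending, name); Avg is
    computed only over the lists containing the variable.
    """
    if not lists:
        raise ValueError("consensus_table requires at least one ranked list")
    variables: dict[str, list[int]] = {}
    for rl in lists:
        for var, rank in zip(rl.entries, rl.ranks):
            variables.setdefault(var, []).append(rank)
    entries = []
    for var, ranks in variables.items():
        num = len(ranks)
        rank_sum = sum(ranks)
        avg = rank_sum / num
        entries.append(
            ConsensusEntry(
                variable=var,
                num=num,
                rank_sum=rank_sum,
                avg=avg,
                selected=(num >= min_occurrence) or (avg <= max_avg_rank),
            )
        )
    entries.sort(key=lambda e: (-e.num, e.avg, e.variable))
    return entries


def select_candidates(
    table: Sequence[ConsensusEntry],
    override: Iterable[str] | None = None,
) -> set[str]:
    """Variables passing the consensus rule, or an explicit expert override."""
    if override is not None:
        return set(override)
    return {e.variable for e in table if e.selected}


def consensus_frame(table: Sequence[ConsensusEntry]) -> pd.DataFrame:
    """Consensus entries as a table mirroring the published layout."""
    return pd.DataFrame(
        {
            "variable": [e.variable for e in table],
            "Num": [e.num for e in table],
            "Avg": [e.avg_display for e in table],
            "selected": [e.selected for e in table],
        }
    )


# ---------------------------------------------------------------------------
# supervised rankers
# ---------------------------------------------------------------------------

def _importance(X: np.ndarray, y: np.ndarray, method_id: str, seed: int) -> np.ndarray:
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import Lasso, LogisticRegression
    from sklearn.preprocessing import StandardScaler
    from sklearn.tree import DecisionTreeClassifier

    if method_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed).fit(X, y).feature_importances_
    if method_id == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed).fit(X, y).feature_importances_
    if method_id == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed).fit(X, y).feature_importances_
    Xs = StandardScaler().fit_transform(X)
    if method_id == "logistic_regression":
        model = LogisticRegression(max_iter=2000, random_state=seed).fit(Xs, y)
        return np.abs(model.coef_[0])
    if method_id == "lasso":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = Lasso(alpha=0.01, random_state=seed).fit(Xs, y.astype(float))
        return np.abs(model.coef_)
    raise ValueError(f"unknown ranker {method_id!r}; expected one of {RANKER_IDS}")


def rank_features(
    dataset: pd.DataFrame,
    target: str,
    method_id: str,
    seed: int = 0,
    top: int = 10,
) -> RankedList:
    """Top-``top`` variables of one ranker; ties broken by column order.

    The dataset must be a complete numeric matrix with a binary target column.
    """
    features = [c for c in dataset.columns if c != target]
    X = dataset[features].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("rank_features requires a complete matrix (clean first)")
    y_raw = dataset[target].to_numpy()
    classes = pd.unique(y_raw)
    if len(classes) < 2:
        raise ValueError("constant target: nothing to rank against")
    if len(classes) > 2:
        raise ValueError("target must be binary")
    y = (y_raw == classes[1]).astype(int) if y_raw.dtype == object else y_raw.astype(int)

    imp = _importance(X, y, method_id, seed)
    if len(features) < top:
        warnings.warn(
            f"only {len(features)} variables available; ranked list shorter than {top}"
        )
    # stable sort: descending importance, ties by column order
    order = np.lexsort((np.arange(len(features)), -imp))
    entries = tuple(features[i] for i in order[:top])
    return RankedList(method_id=method_id, entries=entries)


def rank_all(
    dataset: pd.DataFrame,
    target: str,
    seed: int = 0,
    methods: Sequence[str] = RANKER_IDS,
    top: int = 10,
) -> list[RankedList]:
    """Run every ranker on the same dataset (one derived seed per method)."""
    return [
        rank_features(dataset, target, m, seed=seed + i, top=top)
        for i, m in enumerate(methods)
    ]
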