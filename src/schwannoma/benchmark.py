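"""Selector x classifier benchmark grid.

Reproduces the batch-evaluation harness: every feature-selection method
(the five supervised rankers plus fixed expert sets) is crossed with six
classifier families; each cell reports test-set metrics along with the
average of the train and validation partition metrics.  Feature selection is
fit on the training partition only; the whole grid is seeded and a failing
cell is recorded as missing instead of aborting the run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import RANKER_IDS, rank_features
from .evaluation import MetricsReport, SplitSpec, balanced_split, confusion, metrics

logger = logging.getLogger(__name__)

CLASSIFIER_IDS = (
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "logistic_regression",
    "svm_rbf",
    "neural_network",
)


def _make_classifier(cid: str, seed: int):
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if cid == "decision_tree":
        return DecisionTreeClassifier(max_depth=5, random_state=seed)
    if cid == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if cid == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if cid == "logistic_regression":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed))
    if cid == "svm_rbf":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    if cid == "neural_network":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=800, random_state=seed),
        )
    raise ValueError(f"unknown classifier {cid!r}")


def _scores(model, X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Continuous outputs in [0,1]-ish scale; flag when only hard labels exist."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1], False
    if hasattr(model, "decision_function"):
        raw = model.decision_function(X)
        return 1.0 / (1.0 + np.exp(-raw)), False
    return model.predict(X).astype(float), True


@dataclass
class BenchmarkResult:
    """Per-cell metrics plus the marginal test-accuracy averages."""

    test_accuracy: pd.DataFrame
    reports: dict[tuple[str, str], dict[str, MetricsReport | None]]
    selected_features: dict[str, list[str]]

    def with_margins(self) -> pd.DataFrame:
        df = self.test_accuracy.copy()
        df["Avg"] = df.mean(axis=1, skipna=True)
        df.loc["Avg"] = df.mean(axis=0, skipna=True)
        return df


def _partition_report(model, X, y) -> MetricsReport:
    preds = model.predict(X)
    sc, degenerate = _scores(model, X)
    return metrics(confusion(y, preds), scores=sc, labels=y, degenerate_scores=degenerate)


def grid_benchmark(
    dataset: pd.DataFrame,
    target: str,
    selectors: Mapping[str, Sequence[str] | None] | None = None,
    classifiers: Sequence[str] = CLASSIFIER_IDS,
    spec: SplitSpec = SplitSpec(),
    top: int = 10,
) -> BenchmarkResult:
    """Run the full selector x classifier grid on one dataset.

    ``selectors`` maps a display name either to ``None`` (meaning: run the
    ranker of that name on the training partition and keep its top variables)
    or to an explicit fixed variable list (an expert set).  Default: the five
    rankers plus nothing — pass expert sets explicitly.
    """
    if selectors is None:
        selectors = {m: None for m in RANKER_IDS}
    feature_cols = [c for c in dataset.columns if c != target]
    data = dataset.dropna(subset=feature_cols)
    if len(data) < len(dataset):
        logger.warning("grid_benchmark: dropped %d incomplete rows", len(dataset) - len(data))

    train, valid, test = balanced_split(data, target, spec)
    pos = _positive(data[target])
    y = {k: (v[target] == pos).astype(int)
         for k, v in (("train", train), ("valid", valid), ("test", test))}

    selected: dict[str, list[str]] = {}
    for name, fixed in selectors.items():
        if fixed is not None:
            selected[name] = [c for c in feature_cols if c in set(fixed)]
        else:
            ranked = rank_features(train[feature_cols + [target]], target, name,
                                   seed=spec.seed, top=top)
            selected[name] = list(ranked.entries)

    acc = pd.DataFrame(index=list(selectors), columns=list(classifiers), dtype=float)
    reports: dict[tuple[str, str], dict[str, MetricsReport | None]] = {}
    for sel_name, feats in selected.items():
        for cid in classifiers:
            cell = {"train": None, "valid": None, "test": None, "train_valid_avg": None}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = _make_classifier(cid, spec.seed)
                    model.fit(train[feats].to_numpy(), y["train"].to_numpy())
                    for part, frame in (("train", train), ("valid", valid), ("test", test)):
                        cell[part] = _partition_report(
                            model, frame[feats].to_numpy(), y[part].to_numpy()
                        )
                cell["train_valid_avg"] = _average_reports(cell["train"], cell["valid"])
                acc.loc[sel_name, cid] = cell["test"].acc
            except Exception as exc:  # a failing cell must not abort the grid
                logger.warning("cell (%s, %s) failed: %s", sel_name, cid, exc)
                acc.loc[sel_name, cid] = np.nan
            reports[(sel_name, cid)] = cell
    return BenchmarkResult(test_accuracy=acc, reports=reports, selected_features=selected)


def _positive(series: pd.Series):
    vals = set(series.unique().tolist())
    for cand in ("Active", "Yes", 1):
        if cand in vals:
            return cand
    return sorted(vals, key=str)[-1]


def _average_reports(a: MetricsReport | None, b: MetricsReport | None) -> MetricsReport | None:
    """Average of two partition-level reports, field-wise (None-propagating)."""
    if a is None or b is None:
        return None

    def avg(x, y):
        return None if x is None or y is None else (x + y) / 2.0

    return MetricsReport(
        acc=avg(a.acc, b.acc), tpr=avg(a.tpr, b.tpr), tnr=avg(a.tnr, b.tnr),
        ppv=avg(a.ppv, b.ppv), auc=avg(a.auc, b.auc), ase=avg(a.ase, b.ase),
        degenerate_scores=a.degenerate_scores or b.degenerate_scores,
    )
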