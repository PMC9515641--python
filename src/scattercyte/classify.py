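"""Supervised phenotype classification on four-feature tables.

Reproduces the study's machine-learning stage: a small zoo of classifiers
(linear/quadratic/cubic SVM, fine and cosine KNN, a depth-limited tree),
repeated stratified k-fold cross-validation, confusion matrices with
per-class positive predictive value (PPV) and false discovery rate (FDR),
misclassification cost with unit costs, and one-way ANOVA with Tukey's
post-hoc comparison for property-level group differences.

Naming follows the originating ML toolbox's presets: "quadratic SVM" is an
SVM with a 2nd-degree polynomial kernel (box constraint 1, kernel scale 1,
one-vs-one multiclass); "cosine KNN" uses 10 neighbours, cosine distance
and equal weights; "fine KNN" is 1-NN Euclidean; "medium tree" is capped at
20 leaf nodes.  Features are z-scored inside each training fold only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FEATURE_COLUMNS",
    "ClassifierConfig",
    "ClassificationReport",
    "AnovaResult",
    "cross_validate",
    "confusion_stats",
    "compare_classifiers",
    "anova_tukey",
    "significance_code",
]

FEATURE_COLUMNS = ("D_um", "nc_ratio", "ri_n", "ri_c")

_KINDS = ("linear_svm", "quadratic_svm", "cubic_svm", "fine_knn", "cosine_knn", "medium_tree")


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier preset plus the cross-validation protocol."""

    kind: str = "quadratic_svm"
    box_constraint: float = 1.0
    kernel_scale: float = 1.0
    knn_k: int = 10
    knn_metric: str = "cosine"
    folds: int = 5
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {_KINDS}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.box_constraint <= 0 or self.kernel_scale <= 0:
            raise ValueError("box_constraint and kernel_scale must be positive")

    def make_estimator(self) -> Pipeline:
        """Fresh estimator pipeline: per-fold z-scoring then the classifier."""
        g = 1.0 / self.kernel_scale**2
        if self.kind == "linear_svm":
            clf = SVC(kernel="linear", C=self.box_constraint, decision_function_shape="ovo")
        elif self.kind == "quadratic_svm":
            clf = SVC(
                kernel="poly", degree=2, gamma=g, coef0=1.0,
                C=self.box_constraint, decision_function_shape="ovo",
            )
        elif self.kind == "cubic_svm":
            clf = SVC(
                kernel="poly", degree=3, gamma=g, coef0=1.0,
                C=self.box_constraint, decision_function_shape="ovo",
            )
        elif self.kind == "fine_knn":
            clf = KNeighborsClassifier(n_neighbors=1, metric="euclidean", weights="uniform")
        elif self.kind == "cosine_knn":
            clf = KNeighborsClassifier(
                n_neighbors=self.knn_k, metric=self.knn_metric, weights="uniform"
            )
        else:  # medium_tree
            clf = DecisionTreeClassifier(max_leaf_nodes=20, random_state=self.seed)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class ClassificationReport:
    """Aggregated repeated-CV outcome.

    confusions: one (true x predicted) integer matrix per repeat, classes in
    sorted label order.  accuracy/cost are per-repeat; PPV/FDR come from the
    summed confusion matrix.
    """

    classes: list[str]
    confusions: list[np.ndarray]
    accuracies: list[float]          # per repeat, %
    costs: list[int]                 # per repeat, off-diagonal counts
    mean_accuracy: float             # %
    ppv: dict[str, float]            # %
    fdr: dict[str, float]            # %
    config: ClassifierConfig | None = None

    def summed_confusion(self) -> np.ndarray:
        return np.sum(self.confusions, axis=0)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusions": [c.tolist() for c in self.confusions],
            "accuracies": self.accuracies,
            "costs": self.costs,
            "mean_accuracy": self.mean_accuracy,
            "mean_cost": float(np.mean(self.costs)),
            "ppv": self.ppv,
            "fdr": self.fdr,
            "config": None if self.config is None else self.config.__dict__,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def _validate_features(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    missing = [c for c in (*FEATURE_COLUMNS, "label") if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = features.loc[:, FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    y = features["label"].to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    return X, y, classes


def _repeat_splits(y: np.ndarray, cfg: ClassifierConfig) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified folds for each repeat; repeat r uses seed seed+r so the
    same splits can be reused across classifiers for paired comparisons."""
    counts = pd.Series(y).value_counts()
    if counts.min() < cfg.folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} members, fewer than {cfg.folds} folds"
        )
    out = []
    for r in range(cfg.repeats):
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed + r)
        out.append(list(skf.split(np.zeros(len(y)), y)))
    return out


def cross_validate(
    features: pd.DataFrame,
    cfg: ClassifierConfig,
    splits: list[list[tuple[np.ndarray, np.ndarray]]] | None = None,
) -> ClassificationReport:
    """Repeated stratified k-fold cross-validation of one classifier.

    Each repeat draws fresh stratified folds from a seed derived from
    ``cfg.seed``; out-of-fold predictions across the repeat's folds form one
    confusion matrix.  Deterministic: identical data, config and seed give
    an identical report.
    """
    X, y, classes = _validate_features(features)
    if splits is None:
        splits = _repeat_splits(y, cfg)
    confusions, accuracies, costs = [], [], []
    for folds in splits:
        pred = np.empty(len(y), dtype=object)
        for train, test in folds:
            est = cfg.make_estimator()
            est.fit(X[train], y[train])
            pred[test] = est.predict(X[test])
        cm = confusion_matrix(y, pred.astype(str), labels=classes)
        confusions.append(cm)
        accuracies.append(100.0 * np.trace(cm) / cm.sum())
        costs.append(int(cm.sum() - np.trace(cm)))
    total = np.sum(confusions, axis=0)
    ppv, fdr, _, _ = confusion_stats(total)
    return ClassificationReport(
        classes=classes,
        confusions=confusions,
        accuracies=accuracies,
        costs=costs,
        mean_accuracy=float(np.mean(accuracies)),
        ppv=dict(zip(classes, ppv)),
        fdr=dict(zip(classes, fdr)),
        config=cfg,
    )


def confusion_stats(confmat: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Per-class PPV/FDR (percent), overall accuracy (percent) and unit
    misclassification cost of a square confusion matrix (rows = true).

    PPV_c = 100 TP_c / column-sum_c and FDR_c = 100 - PPV_c; a class never
    predicted has undefined PPV/FDR, reported as NaN.
    """
    cm = np.asarray(confmat)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0) or not np.allclose(cm, np.round(cm)):
        raise ValueError("confusion matrix must hold nonnegative integers")
    col = cm.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = 100.0 * np.diag(cm) / col
    ppv = np.where(col > 0, ppv, np.nan)
    fdr = 100.0 - ppv
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    cost = int(cm.sum() - np.trace(cm))
    return ppv, fdr, float(accuracy), cost


def compare_classifiers(
    features: pd.DataFrame, cfgs: Sequence[ClassifierConfig]
) -> pd.DataFrame:
    """Paired comparison of classifier presets on identical CV splits.

    All configs are evaluated on the splits generated from the first
    config's protocol (folds/repeats/seed), so accuracy differences reflect
    the classifiers and not the partitioning.  Returns a table sorted by
    mean accuracy, descending.
    """
    if len(cfgs) < 2:
        raise ValueError("need at least two classifier configs to compare")
    base = cfgs[0]
    harmonized = [
        replace(c, folds=base.folds, repeats=base.repeats, seed=base.seed) for c in cfgs
    ]
    _, y, _ = _validate_features(features)
    splits = _repeat_splits(y, base)
    rows = []
    for cfg in harmonized:
        rep = cross_validate(features, cfg, splits=splits)
        rows.append(
            {
                "kind": cfg.kind,
                "mean_accuracy": rep.mean_accuracy,
                "sd_accuracy": float(np.std(rep.accuracies)),
                "mean_cost": float(np.mean(rep.costs)),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("mean_accuracy", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def significance_code(p: float) -> str:
    """Conventional star codes: n.s. > 0.05; * < 0.05; ** < 0.01; *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc comparisons."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame       # group1, group2, p_adj, code
    degenerate: bool = False     # all groups constant -> F reported infinite

    def code(self) -> str:
        return significance_code(self.p_value)


def anova_tukey(values: Sequence[float] | np.ndarray, groups: Sequence[str]) -> AnovaResult:
    """Classical one-way ANOVA plus Tukey's multiple comparison.

    values/groups are parallel sequences (one observation per entry).  With
    zero within-group variance everywhere the F statistic is reported as
    infinite with p = 0 and the result flagged degenerate.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be parallel 1-D sequences")
    names = sorted(set(groups.tolist()))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in names]
    if min(len(s) for s in samples) < 2:
        raise ValueError("each group needs at least two observations")
    if all(np.ptp(s) == 0 for s in samples):
        means = [s[0] for s in samples]
        if np.ptp(means) == 0:
            raise ValueError("all observations identical; ANOVA undefined")
        pairs = [
            (a, b, 0.0, "***") for i, a in enumerate(names) for b in names[i + 1 :]
        ]
        pairwise = pd.DataFrame(pairs, columns=["group1", "group2", "p_adj", "code"])
        return AnovaResult(np.inf, 0.0, pairwise, degenerate=True)
    f, p = stats.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values, groups)
    tbl = tk.summary()
    summary = pd.DataFrame(tbl.data[1:], columns=[str(c) for c in tbl.data[0]])
    pairwise = pd.DataFrame(
        {
            "group1": summary["group1"].astype(str),
            "group2": summary["group2"].astype(str),
            "p_adj": np.asarray(tk.pvalues, dtype=float),
        }
    )
    pairwise["code"] = [significance_code(x) for x in pairwise["p_adj"]]
    return AnovaResult(float(f), float(p), pairwise)
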