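"""RAS-index computation, five-group RAG assignment and classification.

The RAS index (RI) is the per-sample mean expression of the signature genes.
Patient cohorts are stratified into five RAS Activity Groups (RAG-0 lowest to
RAG-4 highest mean signature expression) by Ward hierarchical clustering; an
RBF-kernel SVM trained on those labels lets new samples be classified without
re-clustering, and a random-forest importance ranking drives iterative
reduction of the signature to smaller classifier gene panels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .datamodel import ActivityGrouping, ExpressionMatrix, GeneSignature, Scale
from .derive import cluster_activity_groups

logger = logging.getLogger(__name__)

DEFAULT_COST_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


def compute_ri(expr: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Per-sample RAS index: arithmetic mean over available signature genes."""
    genes = sig.present_in(expr)
    if not genes:
        raise ValueError("no signature genes present in expression matrix")
    return pd.Series(
        expr.values.loc[list(genes)].mean(axis=0), index=expr.sample_ids, name="RI"
    )


def assign_rags(expr: ExpressionMatrix, sig: GeneSignature) -> ActivityGrouping:
    """Five-way RAG stratification (RAG-0..RAG-4 ascending mean expression)."""
    return cluster_activity_groups(expr, sig, k=5)


# ---------------------------------------------------------------------------
# SVM classifier


def _rbf_gamma(X: np.ndarray) -> float:
    """Kernel width from the 0.1/0.9 quantiles of pairwise squared distances.

    gamma = 1 / (q10 + q90), i.e. 1/(2 * midpoint of the two quantiles) --
    the quantile heuristic used by common RBF-width estimators.
    """
    if len(X) > 400:
        rng = np.random.default_rng(0)
        X = X[rng.choice(len(X), 400, replace=False)]
    d2 = pdist(X, metric="sqeuclidean")
    q10, q90 = np.quantile(d2[d2 > 0], [0.1, 0.9])
    return float(1.0 / (q10 + q90))


@dataclass
class ClassifierModel:
    """Fitted RBF-SVM with its preprocessing contract.

    Expression is standardized per gene with the stored training mean/sd
    before prediction.  The training matrix and labels are retained so the
    model can be serialized to JSON and rebuilt bit-identically by refitting
    (SVM training is deterministic given data and hyperparameters).
    """

    genes: tuple[str, ...]
    train_mean: pd.Series
    train_sd: pd.Series
    gamma: float
    cost: float
    classes: tuple[str, ...]
    seed: int
    cv_accuracy: float
    train_x: np.ndarray
    train_y: np.ndarray
    svc: SVC = field(repr=False)

    def predict(self, expr: ExpressionMatrix) -> pd.Series:
        return classify(self, expr)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": list(self.genes),
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "gamma": self.gamma,
            "cost": self.cost,
            "classes": list(self.classes),
            "seed": self.seed,
            "cv_accuracy": self.cv_accuracy,
            "train_x": self.train_x.tolist(),
            "train_y": self.train_y.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        train_x = np.asarray(payload["train_x"], dtype=float)
        train_y = np.asarray(payload["train_y"], dtype=object)
        svc = SVC(kernel="rbf", gamma=payload["gamma"], C=payload["cost"])
        svc.fit(train_x, train_y)
        return cls(
            genes=tuple(payload["genes"]),
            train_mean=pd.Series(payload["train_mean"], index=payload["genes"]),
            train_sd=pd.Series(payload["train_sd"], index=payload["genes"]),
            gamma=payload["gamma"],
            cost=payload["cost"],
            classes=tuple(payload["classes"]),
            seed=payload["seed"],
            cv_accuracy=payload["cv_accuracy"],
            train_x=train_x,
            train_y=train_y,
            svc=svc,
        )


@dataclass
class HoldoutReport:
    accuracy: float
    confusion: pd.DataFrame
    holdout_samples: tuple[str, ...]
    predictions: pd.Series


def _standardize(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd


def train_classifier(
    expr: ExpressionMatrix,
    labels: pd.Series,
    seed: int,
    holdout: float = 0.2,
    cv_folds: int = 10,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
) -> tuple[ClassifierModel, HoldoutReport]:
    """Train an RBF-SVM on z-scored expression with a stratified holdout.

    The cohort is split 80/20 stratified by class (seeded); the cost
    parameter is tuned by stratified k-fold cross-validation over a small
    grid with the kernel width set analytically from pairwise-distance
    quantiles.  Returns the fitted model plus the holdout confusion matrix.
    """
    if expr.scale is not Scale.zscore:
        raise ValueError("classifier training expects z-scored expression")
    labels = labels.loc[expr.sample_ids]
    classes = tuple(sorted(labels.unique()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    X = expr.values.to_numpy(dtype=float).T
    y = labels.to_numpy()
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=holdout, stratify=y, random_state=seed
    )
    y_train = y[train_idx]
    counts = pd.Series(y_train).value_counts()
    if set(counts.index) != set(classes):
        missing = sorted(set(classes) - set(counts.index))
        raise ValueError(f"classes absent from training split: {missing}")
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest training class has {counts.min()} samples; need >= {cv_folds}"
        )

    mean = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0, ddof=1)
    X_train = _standardize(X[train_idx], mean, sd)
    X_test = _standardize(X[test_idx], mean, sd)

    gamma = _rbf_gamma(X_train)
    grid = GridSearchCV(
        SVC(kernel="rbf", gamma=gamma),
        {"C": list(cost_grid)},
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    grid.fit(X_train, y_train)
    svc: SVC = grid.best_estimator_

    pred = svc.predict(X_test)
    acc = float(accuracy_score(y[test_idx], pred))
    conf = pd.DataFrame(
        confusion_matrix(y[test_idx], pred, labels=list(classes)),
        index=list(classes), columns=list(classes),
    )
    model = ClassifierModel(
        genes=tuple(expr.gene_ids),
        train_mean=pd.Series(mean, index=expr.gene_ids),
        train_sd=pd.Series(sd, index=expr.gene_ids),
        gamma=gamma,
        cost=float(svc.C),
        classes=classes,
        seed=seed,
        cv_accuracy=float(grid.best_score_),
        train_x=X_train,
        train_y=y_train,
        svc=svc,
    )
    report = HoldoutReport(
        accuracy=acc,
        confusion=conf,
        holdout_samples=tuple(expr.sample_ids[test_idx]),
        predictions=pd.Series(pred, index=expr.sample_ids[test_idx]),
    )
    return model, report


def classify(model: ClassifierModel, expr: ExpressionMatrix) -> pd.Series:
    """Apply the stored preprocessing and model; one label per sample."""
    if expr.scale is not Scale.zscore:
        raise ValueError("classification expects z-scored expression")
    missing = [g for g in model.genes if g not in expr.gene_ids]
    if missing:
        raise ValueError(f"model genes missing from expression matrix: {missing[:10]}")
    X = expr.values.loc[list(model.genes)].to_numpy(dtype=float).T
    X = _standardize(X, model.train_mean.to_numpy(), model.train_sd.to_numpy())
    return pd.Series(model.svc.predict(X), index=expr.sample_ids, name="label")


# ---------------------------------------------------------------------------
# Importance ranking and signature reduction


def rank_gene_importance(
    expr: ExpressionMatrix,
    labels: pd.Series,
    seed: int,
    n_trees: int = 500,
    n_repeats: int = 10,
) -> list[str]:
    """Random-forest permutation-importance ranking of signature genes.

    Descending importance; ties broken by gene id.  A single class is an
    error; pure-noise genes receive importances centred at zero.
    """
    labels = labels.loc[expr.sample_ids]
    if labels.nunique() < 2:
        raise ValueError("need >= 2 classes for importance ranking")
    X = expr.values.to_numpy(dtype=float).T
    y = labels.to_numpy()
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    imp = permutation_importance(
        forest, X, y, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    order = sorted(
        zip(-imp.importances_mean, expr.gene_ids), key=lambda t: (t[0], t[1])
    )
    return [g for _, g in order]


@dataclass
class ReductionCurve:
    """Classifier performance as a function of gene-panel size.

    ``metrics`` holds one row per evaluated prefix size with accuracy and
    per-class sensitivity/specificity on the fixed holdout.  ``best_size`` is
    the smallest size attaining maximum accuracy; the floor sizes are the
    smallest panels meeting the stated per-class floors in every class.
    """

    metrics: pd.DataFrame
    best_size: int
    min_size_sensitivity: int | None
    min_size_specificity: int | None
    sensitivity_floor: float
    specificity_floor: float


def _per_class_sens_spec(conf: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    total = conf.to_numpy().sum()
    sens, spec = {}, {}
    for c in conf.index:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = tp / (tp + fn) if tp + fn else np.nan
        spec[c] = tn / (tn + fp) if tn + fp else np.nan
    return pd.Series(sens), pd.Series(spec)


def reduce_signature(
    ranked_genes: Sequence[str],
    expr: ExpressionMatrix,
    labels: pd.Series,
    seed: int,
    *,
    sizes: Sequence[int] | None = None,
    sensitivity_floor: float = 0.8,
    specificity_floor: float = 0.9,
    cv_folds: int = 10,
) -> ReductionCurve:
    """Retrain classifiers on importance-ranked gene prefixes.

    For each prefix size a classifier is trained with the same protocol and
    seed (hence the same sample split) and scored on the fixed holdout.
    Reports the smallest size attaining maximum accuracy and the smallest
    sizes meeting the sensitivity/specificity floors in every class.
    """
    if not ranked_genes:
        raise ValueError("ranked gene list is empty")
    sizes = list(sizes) if sizes is not None else list(range(1, len(ranked_genes) + 1))
    if sorted(set(sizes)) != sizes:
        raise ValueError("sizes must be strictly increasing")
    rows = []
    sens_ok: list[int] = []
    spec_ok: list[int] = []
    for size in sizes:
        sub = expr.subset_genes(list(ranked_genes[:size]))
        _, report = train_classifier(
            sub, labels, seed=seed, cv_folds=cv_folds
        )
        sens, spec = _per_class_sens_spec(report.confusion)
        rows.append({
            "size": size,
            "accuracy": report.accuracy,
            **{f"sens_{c}": v for c, v in sens.items()},
            **{f"spec_{c}": v for c, v in spec.items()},
        })
        if (sens >= sensitivity_floor).all():
            sens_ok.append(size)
        if (spec >= specificity_floor).all():
            spec_ok.append(size)
    metrics = pd.DataFrame(rows).set_index("size")
    best_acc = metrics["accuracy"].max()
    best_size = int(metrics.index[metrics["accuracy"] == best_acc][0])
    return ReductionCurve(
        metrics=metrics,
        best_size=best_size,
        min_size_sensitivity=min(sens_ok) if sens_ok else None,
        min_size_specificity=min(spec_ok) if spec_ok else None,
        sensitivity_floor=sensitivity_floor,
        specificity_floor=specificity_floor,
    )
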