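"""Random-forest training, cross-validated evaluation and candidate ranking.

The classifier back-end is a random forest over the (optionally
IPCA-reduced) pair features.  Evaluation follows the usual link-prediction
protocol: stratified 10-fold cross-validation with the centring mean, the
IPCA basis and the forest all fitted on the training fold only; per-fold
accuracy, precision, recall, F1 and ROC/AUC; a grid search over the number
of trees using inner cross-validation; and per-disease ranking of candidate
lncRNAs (pairs not yet in the association matrix) by predicted probability.

Undefined metric ratios (e.g. precision when nothing is predicted positive)
return NaN rather than raising, so fold aggregates can skip and warn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .data_io import AssociationMatrix
from .features import FeatureTable, pair_feature
from .ipca import IPCAModel, ipca_fit, ipca_transform
from .semantic import SimilarityMatrix

logger = logging.getLogger("ipcarf")

DEFAULT_N_ESTIMATORS = 1500          # grid-search optimum on the full-scale data
DEFAULT_GRID = (100, 500, 1000, 1500, 2000, 2500)


@dataclass
class RFConfig:
    n_estimators: int = DEFAULT_N_ESTIMATORS
    seed: int = 0
    extra: dict[str, Any] = field(default_factory=dict)  # passthrough tree options

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class PipelineSpec:
    """What to fit per fold: an optional IPCA stage followed by the forest."""

    use_ipca: bool = True
    k: int | None = None
    n_components: int | None = None
    rf: RFConfig = field(default_factory=RFConfig)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class FoldMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float


@dataclass
class CVReport:
    per_fold: list[FoldMetrics]
    aggregate: dict[str, dict[str, float]]   # metric -> {"mean": ..., "std": ...}
    config: dict[str, Any]
    roc_points: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return self.aggregate["auc"]["mean"]

    def to_dict(self) -> dict[str, Any]:
        return {
            "per_fold": [asdict(f) for f in self.per_fold],
            "aggregate": self.aggregate,
            "config": self.config,
        }


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def train_rf(features: np.ndarray, labels: np.ndarray, config: RFConfig) -> RandomForestClassifier:
    """Fit the random forest; class-probability scores via predict_proba."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=config.n_estimators,
        random_state=config.seed,
        n_jobs=1,
        **config.extra,
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


def _positive_scores(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    pos_col = int(np.where(clf.classes_ == 1)[0][0])
    return clf.predict_proba(np.asarray(X, dtype=float))[:, pos_col]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.size == 0 or y.shape != p.shape:
        raise ValueError("labels and predictions must be equal-length, non-empty")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def fpr(c: ConfusionCounts) -> float:
    return _ratio(c.fp, c.fp + c.tn)


def f1_score(c: ConfusionCounts, variant: str = "standard") -> float:
    """Harmonic-mean F1.

    ``variant="standard"`` combines precision and recall.  ``variant="printed"``
    combines accuracy and recall instead — an alternative sometimes seen in
    the applied literature, kept for exact comparability.
    """
    r = recall(c)
    first = accuracy(c) if variant == "printed" else precision(c)
    if np.isnan(first) or np.isnan(r) or (first + r) == 0:
        return float("nan")
    return 2 * first * r / (first + r)


def roc_and_auc(labels: Sequence[int], scores: Sequence[float]) -> RocCurve:
    """ROC over all unique score thresholds, AUC by trapezoid."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    fpr_arr, tpr_arr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(thresholds=thr, fpr=fpr_arr, tpr=tpr_arr, auc=auc)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def kfold_split(n: int, folds: int = 10, stratify_labels: Sequence[int] | None = None,
                seed: int = 0) -> list[np.ndarray]:
    """Seeded (stratified) fold test-index lists partitioning range(n)."""
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    y = np.asarray(stratify_labels) if stratify_labels is not None else np.zeros(n, dtype=int)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros((n, 1)), y)]


def _fit_fold(spec: PipelineSpec, X_train: np.ndarray, y_train: np.ndarray,
              fold_seed: int) -> tuple[IPCAModel | None, RandomForestClassifier]:
    reducer = None
    Xt = X_train
    if spec.use_ipca:
        reducer = ipca_fit(X_train, k=spec.k, n_components=spec.n_components)
        Xt = ipca_transform(reducer, X_train)
    rf_cfg = RFConfig(spec.rf.n_estimators, seed=fold_seed, extra=dict(spec.rf.extra))
    clf = train_rf(Xt, y_train, rf_cfg)
    return reducer, clf


def _apply(reducer: IPCAModel | None, X: np.ndarray) -> np.ndarray:
    return ipca_transform(reducer, X) if reducer is not None else X


def cross_validate(spec: PipelineSpec, dataset: FeatureTable, folds: int = 10,
                   seed: int = 0, keep_roc: bool = False) -> CVReport:
    """Per-fold IPCA+RF fit on the training split only; metrics on the held-out fold."""
    X, y = dataset.features, dataset.labels
    test_folds = kfold_split(len(y), folds=folds, stratify_labels=y, seed=seed)
    per_fold: list[FoldMetrics] = []
    roc_points: list[tuple[np.ndarray, np.ndarray]] = []
    all_idx = np.arange(len(y))
    for fold_no, test_idx in enumerate(test_folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        reducer, clf = _fit_fold(spec, X[train_idx], y[train_idx], fold_seed=seed + fold_no)
        scores = _positive_scores(clf, _apply(reducer, X[test_idx]))
        preds = (scores >= 0.5).astype(int)
        c = confusion(y[test_idx], preds)
        roc = roc_and_auc(y[test_idx], scores)
        per_fold.append(FoldMetrics(accuracy(c), precision(c), recall(c), f1_score(c), roc.auc))
        if keep_roc:
            roc_points.append((roc.fpr, roc.tpr))
        logger.debug("fold %d: auc=%.4f acc=%.4f", fold_no, roc.auc, accuracy(c))

    aggregate: dict[str, dict[str, float]] = {}
    for metric in ("accuracy", "precision", "recall", "f1", "auc"):
        vals = np.array([getattr(f, metric) for f in per_fold])
        ok = vals[~np.isnan(vals)]
        if len(ok) < len(vals):
            logger.warning("%d fold(s) had undefined %s; skipped in aggregate",
                           len(vals) - len(ok), metric)
        aggregate[metric] = {"mean": float(ok.mean()), "std": float(ok.std(ddof=0))}
    config = {
        "use_ipca": spec.use_ipca, "k": spec.k, "n_components": spec.n_components,
        "n_estimators": spec.rf.n_estimators, "folds": folds, "seed": seed,
    }
    return CVReport(per_fold, aggregate, config, roc_points)


def grid_search_n_estimators(dataset: FeatureTable, grid: Sequence[int] = DEFAULT_GRID,
                             folds: int = 5, seed: int = 0,
                             spec: PipelineSpec | None = None) -> tuple[int, dict[int, float]]:
    """Pick n_estimators by k-fold mean AUC; ties go to the smaller forest."""
    if not grid:
        raise ValueError("grid must be non-empty")
    base = spec or PipelineSpec()
    table: dict[int, float] = {}
    for n_est in grid:
        trial = PipelineSpec(base.use_ipca, base.k, base.n_components,
                             RFConfig(n_est, seed=base.rf.seed, extra=dict(base.rf.extra)))
        table[int(n_est)] = cross_validate(trial, dataset, folds=folds, seed=seed).mean_auc
    best = min((n for n, v in table.items() if v == max(table.values())))
    logger.info("grid search: %s -> best n_estimators=%d", table, best)
    return best, table


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------

def rank_candidates(predictor: RandomForestClassifier, disease: str, A: AssociationMatrix,
                    SL: SimilarityMatrix, SD: SimilarityMatrix,
                    reducer: IPCAModel | None = None) -> list[tuple[str, float]]:
    """Score every lncRNA not yet associated with the disease, best first.

    Ties are broken lexicographically by lncRNA label so rankings are
    deterministic.
    """
    j = A.dis_index(disease)
    candidates = [A.lnc_labels[i] for i in np.flatnonzero(A.values[:, j] == 0)]
    if not candidates:
        return []
    X = np.vstack([pair_feature(l, disease, SL, SD) for l in candidates])
    scores = _positive_scores(predictor, _apply(reducer, X))
    order = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    return [(l, float(s)) for l, s in order]


def fit_final_model(spec: PipelineSpec, dataset: FeatureTable,
                    seed: int = 0) -> tuple[IPCAModel | None, RandomForestClassifier]:
    """Fit the reducer and forest on the full sampled dataset (for ranking)."""
    return _fit_fold(spec, dataset.features, dataset.labels, fold_seed=seed)
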