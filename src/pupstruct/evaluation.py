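"""Stratified cross-validation, performance metrics and ROC analysis.

Performance is summarized by five confusion-matrix metrics —

    Sn  = TP / (TP + FN)                    (sensitivity)
    Sp  = TN / (TN + FP)                    (specificity)
    Pre = TP / (TP + FP)                    (precision)
    Acc = (TP + TN) / (TP + FN + TN + FP)   (accuracy)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

— plus the area under the ROC curve. Cross-validation is stratified:
within each class the seeded generator shuffles the samples and deals
them round-robin, so per-class fold sizes differ by at most one. Inside
each fold, feature normalization is fit on the training folds only and
the held-out fold is transformed with those parameters; headline metrics
are arithmetic means over folds (pooled-count metrics are also reported).

The module also hosts two harnesses built on the same machinery: a
feature-subset ablation (same folds reused across subsets so rows are
comparable) and a window-size scan that reruns the full
encode -> clean -> cross-validate pipeline per width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import sklearn.metrics as _skm

from .cleaning import CleaningConfig, knn_clean
from .encoding import (
    CHANNEL_SUBSETS,
    LabeledDataset,
    WindowSpec,
    apply_normalization,
    build_dataset,
    fit_normalization,
    select_features,
)
from .io_formats import ProteinRecord, ResidueProfile, SiteLabel
from .model import SvmConfig, predict, train

__all__ = [
    "FoldSplit",
    "ConfusionCounts",
    "Metrics",
    "RocCurve",
    "FoldResult",
    "MetricsReport",
    "stratified_folds",
    "compute_metrics",
    "roc_curve",
    "cross_validate",
    "ablation_run",
    "window_scan",
    "ABLATION_MENU",
]

#: The standard ablation menu: feature groups and single channels whose
#: contributions are compared under identical folds.
ABLATION_MENU = (
    "asa", "sspre", "ph", "pe", "pc", "torsion",
    "phi", "psi", "theta", "tau", "asa+sspre", "all",
)

_METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "mcc")


@dataclass(frozen=True)
class FoldSplit:
    """A stratified partition: per-sample fold index in [0, n_folds)."""

    n_folds: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _METRIC_NAMES}


@dataclass
class RocCurve:
    """Ordered (fpr, tpr) points from (0,0) to (1,1) and the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: Metrics
    roc: RocCurve


@dataclass
class MetricsReport:
    """Cross-validation outcome: per-fold and averaged metrics plus ROC."""

    per_fold: list[FoldResult]
    mean_metrics: Metrics
    pooled_counts: ConfusionCounts
    pooled_metrics: Metrics
    auc_per_fold: list[float]
    mean_auc: float
    mean_roc_fpr: np.ndarray
    mean_roc_tpr: np.ndarray
    split: FoldSplit

    def to_dict(self) -> dict:
        return {
            "n_folds": self.split.n_folds,
            "seed": self.split.seed,
            "mean": self.mean_metrics.as_dict(),
            "pooled": self.pooled_metrics.as_dict(),
            "pooled_counts": {
                "tp": self.pooled_counts.tp, "fn": self.pooled_counts.fn,
                "tn": self.pooled_counts.tn, "fp": self.pooled_counts.fp,
            },
            "auc_per_fold": [round(a, 10) for a in self.auc_per_fold],
            "mean_auc": round(self.mean_auc, 10),
            "per_fold": [
                {
                    "fold": fr.fold,
                    "counts": {"tp": fr.counts.tp, "fn": fr.counts.fn,
                               "tn": fr.counts.tn, "fp": fr.counts.fp},
                    "metrics": {k: round(v, 10) for k, v in fr.metrics.as_dict().items()},
                    "auc": round(fr.roc.auc, 10),
                }
                for fr in self.per_fold
            ],
        }


def stratified_folds(labels: Sequence[int], n_folds: int, seed: int) -> FoldSplit:
    """Deal each class round-robin into n folds after a seeded shuffle.

    Guarantees per-class fold sizes differing by at most one and is
    deterministic for a fixed seed. Every class must have at least
    n_folds members.
    """
    y = np.asarray(labels, dtype=int)
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    rng = np.random.default_rng(seed)
    assignments = np.full(len(y), -1, dtype=int)
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < n_folds:
            raise ValueError(
                f"class {cls} has {len(members)} members, fewer than n_folds={n_folds}"
            )
        shuffled = rng.permutation(members)
        assignments[shuffled] = np.arange(len(shuffled)) % n_folds
    return FoldSplit(n_folds=n_folds, assignments=assignments, seed=seed)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator computing {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """The five metrics from one confusion matrix.

    Any metric with a zero denominator is reported as 0 with a warning so
    sweeps over degenerate folds keep running visibly.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    mcc_den = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return Metrics(
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        precision=_safe_ratio(tp, tp + fp, "precision"),
        accuracy=_safe_ratio(tp + tn, tp + fn + tn + fp, "accuracy"),
        mcc=_safe_ratio(tp * tn - fp * fn, float(np.sqrt(mcc_den)), "mcc"),
    )


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC points over descending score thresholds and the trapezoidal AUC.

    Tied scores are processed as one threshold step, so the AUC equals the
    pairwise concordance statistic P(score_pos > score_neg) + 0.5 P(tie).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires at least one positive and one negative label")
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def _mean_roc(curves: Sequence[RocCurve], n_grid: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Vertical averaging of tpr over a fixed fpr grid."""
    grid = np.linspace(0.0, 1.0, n_grid)
    stacked = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    return grid, stacked.mean(axis=0)


def cross_validate(
    dataset: LabeledDataset,
    n_folds: int = 6,
    seed: int = 0,
    svm_config: SvmConfig = SvmConfig(),
    folds: Optional[FoldSplit] = None,
    fold_cleaning: Optional[CleaningConfig] = None,
) -> MetricsReport:
    """Stratified n-fold cross-validation of the window classifier.

    Per fold: fit min-max normalization on the training folds, train the
    SVM, score the held-out fold, and accumulate confusion counts, metrics
    and the fold's ROC curve. Headline metrics are fold averages; metrics
    of the pooled counts are reported alongside. ``fold_cleaning`` enables
    the leakage-safe variant in which k-NN cleaning is re-run inside each
    fold on the training portion only (by default cleaning, if wanted, is
    applied once to the whole dataset before this function, mirroring the
    procedure's original ordering).
    """
    dataset.require_labels()
    split = folds if folds is not None else stratified_folds(dataset.y, n_folds, seed)
    if len(split.assignments) != len(dataset):
        raise ValueError("fold split does not cover the dataset")
    results: list[FoldResult] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in range(split.n_folds):
        train_set = dataset.take(split.train_indices(fold))
        test_set = dataset.take(split.test_indices(fold))
        if train_set.n_pos == 0 or train_set.n_neg == 0:
            raise ValueError(
                f"training folds for held-out fold {fold} contain a single class; "
                "use a different seed or fewer folds"
            )
        if test_set.n_pos == 0 or test_set.n_neg == 0:
            raise ValueError(
                f"held-out fold {fold} contains a single class; "
                "use a different seed or fewer folds"
            )
        if fold_cleaning is not None:
            train_set, _ = knn_clean(train_set, fold_cleaning)
        params = fit_normalization(train_set)
        model = train(apply_normalization(train_set, params), svm_config)
        test_norm = apply_normalization(test_set, params)
        pred, scores = predict(model, test_norm.X)
        truth = test_set.y
        counts = ConfusionCounts(
            tp=int(np.sum((truth == 1) & (pred == 1))),
            fn=int(np.sum((truth == 1) & (pred == 0))),
            tn=int(np.sum((truth == 0) & (pred == 0))),
            fp=int(np.sum((truth == 0) & (pred == 1))),
        )
        pooled = pooled + counts
        results.append(
            FoldResult(
                fold=fold,
                counts=counts,
                metrics=compute_metrics(counts),
                roc=roc_curve(scores, truth),
            )
        )
    mean_metrics = Metrics(
        **{
            name: float(np.mean([getattr(fr.metrics, name) for fr in results]))
            for name in _METRIC_NAMES
        }
    )
    aucs = [fr.roc.auc for fr in results]
    grid, mean_tpr = _mean_roc([fr.roc for fr in results])
    return MetricsReport(
        per_fold=results,
        mean_metrics=mean_metrics,
        pooled_counts=pooled,
        pooled_metrics=compute_metrics(pooled),
        auc_per_fold=aucs,
        mean_auc=float(np.mean(aucs)),
        mean_roc_fpr=grid,
        mean_roc_tpr=mean_tpr,
        split=split,
    )


def ablation_run(
    dataset: LabeledDataset,
    subsets: Sequence[str] = ABLATION_MENU,
    n_folds: int = 6,
    seed: int = 0,
    svm_config: SvmConfig = SvmConfig(),
) -> pd.DataFrame:
    """Cross-validate one channel subset at a time, same folds throughout.

    Subsets are names from :data:`CHANNEL_SUBSETS` (e.g. ``"asa"``,
    ``"sspre"``, ``"torsion"``, ``"all"``). Returns one row per subset
    with the five mean metrics and mean AUC.
    """
    if not subsets:
        raise ValueError("ablation requires at least one feature subset")
    unknown = [s for s in subsets if s not in CHANNEL_SUBSETS]
    if unknown:
        raise ValueError(f"unknown subsets {unknown}; valid: {sorted(CHANNEL_SUBSETS)}")
    split = stratified_folds(dataset.y, n_folds, seed)
    rows = []
    for name in subsets:
        sub = select_features(dataset, channels=CHANNEL_SUBSETS[name])
        report = cross_validate(sub, svm_config=svm_config, folds=split)
        rows.append(
            {"subset": name, "n_features": sub.n_features,
             **report.mean_metrics.as_dict(), "mean_auc": report.mean_auc}
        )
    return pd.DataFrame(rows)


def window_scan(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ResidueProfile],
    labels: Sequence[SiteLabel],
    widths: Iterable[int] = range(11, 42, 2),
    n_folds: int = 6,
    seed: int = 0,
    svm_config: SvmConfig = SvmConfig(),
    cleaning: Optional[CleaningConfig] = None,
) -> pd.DataFrame:
    """Full encode -> (clean) -> cross-validate pipeline per window width.

    Widths must be odd and >= 3. Returns one metrics row per width; the
    default sweep covers widths 11 to 41.
    """
    rows = []
    for width in widths:
        spec = WindowSpec.from_width(width)
        dataset = build_dataset(records, profiles, labels, spec)
        dataset = dataset.take(np.flatnonzero(dataset.y >= 0))
        if cleaning is not None:
            dataset, _ = knn_clean(dataset, cleaning)
        report = cross_validate(dataset, n_folds=n_folds, seed=seed, svm_config=svm_config)
        rows.append(
            {"width": width, "n_sites": len(dataset),
             **report.mean_metrics.as_dict(), "mean_auc": report.mean_auc}
        )
    if not rows:
        raise ValueError("window scan requires at least one width")
    return pd.DataFrame(rows)
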