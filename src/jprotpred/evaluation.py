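"""Per-class metrics and the stratified cross-validation driver.

All metrics are one-versus-rest per class *i*:

.. math::
   Sn_i = \\frac{TP_i}{TP_i + FN_i}, \\quad
   Sp_i = \\frac{TN_i}{TN_i + FP_i}, \\quad
   Acc = \\frac{\\sum_i TP_i}{N}, \\quad
   AvgSn = \\frac{1}{4} \\sum_i Sn_i.

With a majority class outnumbering the rarest class fifty-fold, overall
accuracy is dominated by the majority and can look excellent while the
rare classes are never predicted; the unweighted mean sensitivity AvgSn
is the headline figure instead.

Cross-validation is stratified per class: each class is independently
permuted and split into ``n_folds`` near-equal parts, and fold *k* tests
on the union of part *k* of every class.  Metrics are reported both
pooled (all test-fold predictions scored once — stable for tiny classes)
and as the mean of per-fold scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.utils import check_random_state

from .io import ValidationError
from .ensemble import smote_expand


@dataclass
class ConfusionCounts:
    """One-versus-rest confusion counts per class."""

    classes: tuple
    tp: dict
    fn: dict
    fp: dict
    tn: dict
    n: int


@dataclass
class MetricsReport:
    """Per-class sensitivity/specificity plus Acc and AvgSn."""

    sn: dict
    sp: dict
    acc: float
    avg_sn: float
    confusion: ConfusionCounts | None = None
    fold_reports: list["MetricsReport"] = field(default_factory=list)
    fold_mean_avg_sn: float | None = None

    def rounded(self, digits: int = 3) -> dict:
        """Display form with half-up rounding, as in benchmark tables."""
        from decimal import Decimal, ROUND_HALF_UP

        def r(x: float) -> float:
            q = Decimal(1).scaleb(-digits)
            return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

        return {
            "sn": {c: r(v) for c, v in self.sn.items() if v is not None},
            "sp": {c: r(v) for c, v in self.sp.items() if v is not None},
            "acc": r(self.acc),
            "avg_sn": r(self.avg_sn),
        }


def confusion_counts(truth: Sequence, predicted: Sequence) -> ConfusionCounts:
    """One-versus-rest TP/FN/FP/TN per class appearing in truth or predictions."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape[0] != p.shape[0]:
        raise ValidationError("truth and predicted must have equal length")
    classes = tuple(sorted(set(t.tolist()) | set(p.tolist()), key=str))
    n = len(t)
    tp, fn, fp, tn = {}, {}, {}, {}
    for cls in classes:
        tp[cls] = int(np.sum((t == cls) & (p == cls)))
        fn[cls] = int(np.sum((t == cls) & (p != cls)))
        fp[cls] = int(np.sum((t != cls) & (p == cls)))
        tn[cls] = int(np.sum((t != cls) & (p != cls)))
    return ConfusionCounts(classes=classes, tp=tp, fn=fn, fp=fp, tn=tn, n=n)


def average_sensitivity(sn_values: Sequence[float]) -> float:
    """Unweighted mean of per-class sensitivities."""
    vals = [v for v in sn_values if v is not None]
    if not vals:
        raise ValidationError("no defined per-class sensitivities")
    return float(np.mean(vals))


def compute_metrics(truth: Sequence, predicted: Sequence) -> MetricsReport:
    """Per-class Sn/Sp, overall Acc, and AvgSn from truth/prediction vectors.

    A class absent from ``truth`` has undefined sensitivity; it is
    reported as ``None`` and excluded from AvgSn with a warning.
    """
    cm = confusion_counts(truth, predicted)
    sn: dict = {}
    sp: dict = {}
    for cls in cm.classes:
        pos = cm.tp[cls] + cm.fn[cls]
        sn[cls] = cm.tp[cls] / pos if pos else None
        neg = cm.tn[cls] + cm.fp[cls]
        sp[cls] = cm.tn[cls] / neg if neg else None
    undefined = [c for c, v in sn.items() if v is None]
    if undefined:
        warnings.warn(
            f"classes absent from truth, excluded from AvgSn: {undefined}",
            stacklevel=2,
        )
    acc = sum(cm.tp.values()) / cm.n
    return MetricsReport(
        sn=sn, sp=sp, acc=float(acc),
        avg_sn=average_sensitivity(list(sn.values())),
        confusion=cm,
    )


@dataclass
class FoldPlan:
    """Per-class assignment of samples to folds."""

    fold_of: np.ndarray  # fold index (0..n_folds-1) per sample
    n_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def make_fold_plan(
    labels: Sequence, n_folds: int = 10, seed: int = 0
) -> FoldPlan:
    """Per-class random split into ``n_folds`` near-equal parts.

    Every class must have at least ``n_folds`` members so each fold tests
    on at least one sample of each class.
    """
    y = np.asarray(labels)
    rng = check_random_state(seed)
    fold_of = np.empty(len(y), dtype=int)
    for cls in sorted(set(y.tolist()), key=str):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValidationError(
                f"class {cls!r} has {len(idx)} samples, fewer than "
                f"{n_folds} folds"
            )
        perm = rng.permutation(len(idx))
        for k, part in enumerate(np.array_split(perm, n_folds)):
            fold_of[idx[part]] = k
    return FoldPlan(fold_of=fold_of, n_folds=n_folds, seed=seed)


@dataclass
class CVResult:
    """Pooled predictions and metrics from one cross-validation run."""

    report: MetricsReport          # pooled over all test folds
    truth: np.ndarray
    predicted: np.ndarray
    fold_of: np.ndarray
    tallies: np.ndarray | None = None


def cross_validate(
    X: np.ndarray,
    y: Sequence,
    estimator,
    n_folds: int = 10,
    seed: int = 0,
    smote_scope: str = "train_fold_only",
    smote_target: int | None = None,
    smote_k: int = 5,
) -> CVResult:
    """Per-class stratified cross-validation of a classifier.

    ``estimator`` is cloned and refitted for each fold.  With
    ``smote_scope="benchmark_pre_cv"`` the rarest class is
    SMOTE-expanded to ``smote_target`` once, before fold assignment, so
    synthetic samples participate in both training and testing folds (the
    benchmark protocol); ``"train_fold_only"`` leaves expansion to the
    estimator's own fit, confined to training folds.

    Metrics are computed on the pooled test-fold predictions; per-fold
    reports and their AvgSn mean are attached to the returned report.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if smote_scope not in ("benchmark_pre_cv", "train_fold_only"):
        raise ValidationError(f"unknown smote_scope {smote_scope!r}")
    estimator = clone(estimator)
    if smote_scope == "benchmark_pre_cv":
        if smote_target is None:
            smote_target = int(getattr(estimator, "smote_target", 60))
        classes, counts = np.unique(y, return_counts=True)
        rare = classes[np.argmin(counts)]
        if counts.min() < smote_target:
            expanded = smote_expand(
                X[y == rare], smote_target, k=smote_k, seed=seed
            )
            X = np.vstack([X, expanded[counts.min():]])
            y = np.concatenate(
                [y, np.repeat(rare, smote_target - counts.min())]
            )
        # expansion is done; the estimator must not re-expand per fold
        if "apply_smote" in estimator.get_params():
            estimator.set_params(apply_smote=False)

    plan = make_fold_plan(y, n_folds=n_folds, seed=seed)
    predicted = np.empty(len(y), dtype=y.dtype)
    tallies = None
    fold_reports = []
    for k in range(n_folds):
        tr, te = plan.train_indices(k), plan.test_indices(k)
        model = clone(estimator)
        if "random_state" in model.get_params():
            model.set_params(random_state=seed + k)
        model.fit(X[tr], y[tr])
        predicted[te] = model.predict(X[te])
        if hasattr(model, "vote_tallies"):
            if tallies is None:
                tallies = np.zeros(
                    (len(y), len(model.classes_)), dtype=int
                )
            tallies[te] = model.vote_tallies(X[te])
        fold_reports.append(compute_metrics(y[te], predicted[te]))
    report = compute_metrics(y, predicted)
    report.fold_reports = fold_reports
    report.fold_mean_avg_sn = float(
        np.mean([fr.avg_sn for fr in fold_reports])
    )
    return CVResult(
        report=report, truth=y, predicted=predicted,
        fold_of=plan.fold_of, tallies=tallies,
    )
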