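"""Symmetric-uncertainty feature ranking and incremental feature selection.

Symmetric uncertainty (SU) between a feature *f* and the class *C* is the
normalised information gain

.. math:: \\mathrm{SU}(f, C) = \\frac{2\\,[H(C) - H(C \\mid f)]}{H(f) + H(C)},

with all entropies in bits.  SU lies in [0, 1]: 0 under empirical
independence, 1 when feature and class determine each other.  Numeric
features are first discretised with the Fayyad–Irani minimum description
length (MDL) method — recursive binary splits on class-entropy gain,
accepted only when the gain exceeds the MDL coding cost; a feature with
no accepted cut collapses to one bin and scores SU = 0.  An unsupervised
equal-frequency binning is available as a fallback.

Incremental feature selection (IFS) walks prefixes of the SU-ranked list,
evaluates each prefix with a caller-supplied model evaluator (average
per-class sensitivity under cross-validation in the full pipeline), and
keeps the best-scoring prefix, preferring the smaller one on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .io import ValidationError


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits from nonnegative counts; empty cells add 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _class_entropy(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    return _entropy(counts)


def _mdlp_split(values: np.ndarray, y: np.ndarray) -> float | None:
    """Best accepted MDL cut point on a sorted sample, or None.

    Candidate cuts are midpoints between adjacent distinct values; a cut
    is accepted when the information gain exceeds the Fayyad–Irani coding
    cost ``(log2(N-1) + log2(3^k - 2) - k H(S) + k1 H(S1) + k2 H(S2)) / N``.
    """
    n = len(values)
    if n < 2:
        return None
    classes, y_codes = np.unique(y, return_inverse=True)
    k = len(classes)
    if k < 2:
        return None
    h_s = _class_entropy(y_codes)

    # cumulative class counts along the sorted sample
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y_codes] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]

    # candidate boundaries: between adjacent distinct values
    distinct = np.nonzero(np.diff(values) > 0)[0]  # cut after index i
    if len(distinct) == 0:
        return None

    best_gain, best_cut, best_stats = -np.inf, None, None
    for i in distinct:
        left, right = cum[i], total - cum[i]
        n1, n2 = i + 1, n - i - 1
        h1, h2 = _entropy(left), _entropy(right)
        gain = h_s - (n1 * h1 + n2 * h2) / n
        if gain > best_gain:
            best_gain, best_cut = gain, (values[i] + values[i + 1]) / 2.0
            best_stats = (left, right, h1, h2, n1, n2)
    assert best_stats is not None
    left, right, h1, h2, n1, n2 = best_stats
    k1, k2 = int((left > 0).sum()), int((right > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (k * h_s - k1 * h1 - k2 * h2)
    threshold = (np.log2(n - 1.0) + delta) / n
    if best_gain > threshold:
        return best_cut
    return None


def _mdlp_cuts(values: np.ndarray, y: np.ndarray) -> list[float]:
    order = np.argsort(values, kind="mergesort")
    values, y = values[order], y[order]

    cuts: list[float] = []
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop()
        cut = _mdlp_split(values[lo:hi], y[lo:hi])
        if cut is None:
            continue
        cuts.append(cut)
        mid = lo + int(np.searchsorted(values[lo:hi], cut, side="right"))
        stack.append((lo, mid))
        stack.append((mid, hi))
    return sorted(cuts)


def discretize_feature(
    values: Sequence[float],
    labels: Sequence,
    method: str = "mdl",
    n_bins: int = 10,
) -> np.ndarray:
    """Map a numeric feature to integer bin labels.

    ``method="mdl"`` (default) applies supervised Fayyad–Irani MDL
    discretisation; when no cut passes the MDL criterion the whole feature
    falls into a single bin (and will score SU = 0).  ``method="equal-freq"``
    bins by sample quantiles, ignoring the labels.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValidationError("values and labels must have equal length")
    if method == "mdl":
        cuts = _mdlp_cuts(values, labels)
        return np.searchsorted(cuts, values, side="left").astype(int) \
            if cuts else np.zeros(len(values), dtype=int)
    if method == "equal-freq":
        qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(np.unique(qs), values, side="left").astype(int)
    raise ValidationError(f"unknown discretizer {method!r}")


def symmetric_uncertainty(feature_bins: Sequence, labels: Sequence) -> float:
    """SU between a discrete feature and the class labels, in [0, 1].

    Returns 0 when ``H(f) + H(C) == 0`` (both variables constant).
    """
    f = np.asarray(feature_bins)
    y = np.asarray(labels)
    if f.shape[0] != y.shape[0]:
        raise ValidationError("feature and labels must have equal length")
    _, f_codes = np.unique(f, return_inverse=True)
    _, y_codes = np.unique(y, return_inverse=True)
    joint = np.zeros((f_codes.max() + 1, y_codes.max() + 1))
    np.add.at(joint, (f_codes, y_codes), 1.0)
    h_f = _entropy(joint.sum(axis=1))
    h_c = _entropy(joint.sum(axis=0))
    if h_f + h_c == 0:
        return 0.0
    # H(C|f) = sum_j P(f_j) H(C | f = f_j)
    n = joint.sum()
    h_c_given_f = sum(
        (row.sum() / n) * _entropy(row) for row in joint if row.sum() > 0
    )
    ig = h_c - h_c_given_f
    return float(2.0 * ig / (h_f + h_c))


@dataclass
class RankedFeatureList:
    """Feature indices ordered by decreasing SU with the class."""

    order: np.ndarray
    su_scores: np.ndarray  # aligned with ``order``

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.su_scores = np.asarray(self.su_scores, dtype=float)
        if np.any(np.diff(self.su_scores) > 1e-12):
            raise ValidationError("su_scores must be non-increasing")
        if np.any(self.su_scores < -1e-12) or np.any(self.su_scores > 1 + 1e-12):
            raise ValidationError("SU scores must lie in [0, 1]")


def rank_features(
    features: np.ndarray,
    labels: Sequence,
    method: str = "mdl",
) -> RankedFeatureList:
    """Discretise every feature, score it by SU, and rank.

    Sorting is stable with ties broken by the original feature index.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("need at least 2 classes to rank features")
    scores = np.array([
        symmetric_uncertainty(discretize_feature(X[:, j], y, method=method), y)
        for j in range(X.shape[1])
    ])
    order = np.argsort(-scores, kind="stable")
    return RankedFeatureList(order=order, su_scores=scores[order])


@dataclass
class IFSResult:
    """Outcome of the incremental prefix search."""

    sizes: np.ndarray       # evaluated prefix sizes
    curve: np.ndarray       # score per prefix size
    best_size: int
    best_score: float


def incremental_feature_selection(
    ranked: RankedFeatureList,
    evaluator: Callable[[np.ndarray], float],
    n_features: int | None = None,
    step: int = 1,
) -> IFSResult:
    """Evaluate growing prefixes of the ranked list; keep the best.

    ``evaluator`` receives an array of global feature indices and returns
    a score (average per-class sensitivity in the full pipeline).  Prefix
    sizes ``step, 2*step, ...`` up to ``n_features`` are evaluated, the
    final full set always included.  Ties prefer the smaller prefix.
    """
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    if n_features is None:
        n_features = len(ranked.order)
    sizes = list(range(step, n_features + 1, step))
    if not sizes or sizes[-1] != n_features:
        sizes.append(n_features)
    curve = np.array([
        float(evaluator(ranked.order[:size])) for size in sizes
    ])
    best_pos = int(np.argmax(curve))  # argmax returns the first maximum
    return IFSResult(
        sizes=np.asarray(sizes),
        curve=curve,
        best_size=int(sizes[best_pos]),
        best_score=float(curve[best_pos]),
    )


class SymmetricUncertaintyRanker(SelectorMixin, BaseEstimator):
    """Scikit-learn selector keeping the ``k`` top features by SU.

    Fitting discretises each column (Fayyad–Irani MDL by default),
    computes its symmetric uncertainty with the class, and stores the
    ranking; ``transform`` keeps the top ``k`` columns (all columns when
    ``k`` is None, i.e. the estimator only ranks).

    Attributes
    ----------
    ranking_ : RankedFeatureList
        Feature indices by decreasing SU and the aligned scores.
    su_scores_ : ndarray of shape (n_features,)
        SU per original feature index.
    """

    def __init__(self, k: int | None = None, method: str = "mdl") -> None:
        self.k = k
        self.method = method

    def fit(self, X, y) -> "SymmetricUncertaintyRanker":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.ranking_ = rank_features(X, y, method=self.method)
        self.su_scores_ = np.empty(X.shape[1])
        self.su_scores_[self.ranking_.order] = self.ranking_.su_scores
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        k = self.n_features_in_ if self.k is None else self.k
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_.order[:k]] = True
        return mask
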