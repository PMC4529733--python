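"""Complex-prediction quality metrics.

Two families of metrics compare a predicted catalog against a reference one:

* contingency-table statistics — size-weighted best-overlap Sensitivity over
  real complexes, column-weighted best-overlap Positive Predictive Value over
  predicted complexes, and their geometric mean (Accuracy);
* Jaccard-threshold coverage — a benchmark complex counts as covered when its
  Jaccard index with some predicted complex strictly exceeds a threshold t;
  sweeping t over [0, 1] yields a precision-recall curve and its AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .network import ComplexCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "PRCurve",
    "contingency",
    "sensitivity",
    "ppv",
    "accuracy",
    "jaccard",
    "precision_recall_curve",
    "mean_best_match_jaccard",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class ContingencyTable:
    """T[i, j] = |real_i ∩ predicted_j| plus the real complex sizes N_i."""

    T: np.ndarray
    real_sizes: np.ndarray

    def __post_init__(self) -> None:
        if self.T.ndim != 2 or self.T.shape[0] != self.real_sizes.shape[0]:
            raise ValueError("contingency table shape mismatch")

    @property
    def column_sums(self) -> np.ndarray:
        return self.T.sum(axis=0)


@dataclass(frozen=True)
class PRCurve:
    """Threshold-swept (t, recall, precision) points and the area under the curve."""

    points: tuple[tuple[float, float, float], ...]
    auc: float

    @property
    def thresholds(self) -> list[float]:
        return [t for t, _, _ in self.points]

    @property
    def recalls(self) -> list[float]:
        return [r for _, r, _ in self.points]

    @property
    def precisions(self) -> list[float]:
        return [p for _, _, p in self.points]


def contingency(real: ComplexCatalog, predicted: ComplexCatalog) -> ContingencyTable:
    """Protein-overlap contingency table between two catalogs."""
    if len(real) == 0 or len(predicted) == 0:
        raise ValueError("both catalogs must be non-empty")
    real_sets = real.member_sets
    pred_sets = predicted.member_sets
    T = np.zeros((len(real_sets), len(pred_sets)), dtype=int)
    for i, r in enumerate(real_sets):
        for j, p in enumerate(pred_sets):
            T[i, j] = len(r & p)
    return ContingencyTable(T, np.array([len(r) for r in real_sets]))


def sensitivity(ct: ContingencyTable) -> float:
    """Size-weighted average of each real complex's best coverage fraction."""
    N = ct.real_sizes
    if np.any(N < 1):
        raise ValueError("real complex sizes must be >= 1")
    best = ct.T.max(axis=1) if ct.T.shape[1] else np.zeros(len(N))
    return float((best).sum() / N.sum())


def ppv(ct: ContingencyTable) -> float:
    """Column-sum-weighted average of each predicted complex's best purity.

    Columns with zero sum (predicted complexes disjoint from every real one)
    contribute 0 to both numerator and denominator.
    """
    col = ct.column_sums
    total = col.sum()
    if total == 0:
        logger.info("ppv: all contingency columns are zero")
        return 0.0
    best = ct.T.max(axis=0)
    return float(best.sum() / total)


def accuracy(sn: float, ppv_value: float) -> float:
    """Geometric mean of sensitivity and positive predictive value."""
    if not (0.0 <= sn <= 1.0 and 0.0 <= ppv_value <= 1.0):
        raise ValueError("sensitivity and PPV must be in [0, 1]")
    return math.sqrt(sn * ppv_value)


def jaccard(a, b) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b|; both sets empty is an error."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(union)


def _jaccard_matrix(benchmark: ComplexCatalog, predicted: ComplexCatalog) -> np.ndarray:
    J = np.zeros((len(benchmark), len(predicted)))
    for i, b in enumerate(benchmark.member_sets):
        for j, c in enumerate(predicted.member_sets):
            J[i, j] = len(b & c) / len(b | c)
    return J


def precision_recall_curve(
    benchmark: ComplexCatalog,
    predicted: ComplexCatalog,
    thresholds=DEFAULT_THRESHOLDS,
    weighted: bool = False,
) -> PRCurve:
    """Jaccard-coverage precision-recall curve swept over thresholds.

    At threshold t, recall is the fraction of benchmark complexes whose best
    Jaccard against a predicted complex strictly exceeds t, and precision the
    fraction of predicted complexes whose best Jaccard against a benchmark
    strictly exceeds t (``weighted=True`` weights complexes by their size
    instead of counting them).  The AUC is the trapezoidal area under
    precision versus recall over the swept points with recall > 0, with the
    lowest-recall precision extended flat to recall 0.
    """
    if len(benchmark) == 0 or len(predicted) == 0:
        raise ValueError("both catalogs must be non-empty")
    J = _jaccard_matrix(benchmark, predicted)
    best_bench = J.max(axis=1)
    best_pred = J.max(axis=0)
    if weighted:
        wb = np.array([len(s) for s in benchmark.member_sets], dtype=float)
        wp = np.array([len(s) for s in predicted.member_sets], dtype=float)
    else:
        wb = np.ones(len(benchmark))
        wp = np.ones(len(predicted))
    points = []
    for t in sorted(thresholds):
        recall = float(wb[best_bench > t].sum() / wb.sum())
        precision = float(wp[best_pred > t].sum() / wp.sum())
        points.append((float(t), recall, precision))
    auc = _pr_auc(points)
    return PRCurve(tuple(points), auc)


def _pr_auc(points) -> float:
    """Trapezoid over (recall, precision), covered points only, flat to recall 0."""
    covered = [(r, p) for _, r, p in points if r > 0.0]
    if not covered:
        return 0.0
    by_recall: dict[float, list[float]] = {}
    for r, p in covered:
        by_recall.setdefault(r, []).append(p)
    rs = sorted(by_recall)
    ps = [float(np.mean(by_recall[r])) for r in rs]
    rs = [0.0, *rs]
    ps = [ps[0], *ps]
    return float(np.trapezoid(ps, rs))


def mean_best_match_jaccard(truth: ComplexCatalog, predicted: ComplexCatalog) -> float:
    """Mean over reference complexes of their best Jaccard with any prediction."""
    if len(truth) == 0:
        raise ValueError("truth catalog is empty")
    if len(predicted) == 0:
        return 0.0
    J = _jaccard_matrix(truth, predicted)
    return float(J.max(axis=1).mean())
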