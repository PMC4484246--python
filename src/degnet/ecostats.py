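"""Comparative ecology layer: diversity, ordination, cluster testing,
environmental regression, fold-change contrasts and mass-feature filtering.

Every named t-test uses the Welch (unequal-variance) form, two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from degnet.errors import DataError, ValidationError

METRICS = ("bray_curtis", "euclidean_hellinger")


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def shannon(counts: Sequence[float], base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive proportions.

    Natural log by default (``base=None``); pass ``base=2`` for bits.
    """
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise DataError("negative counts")
    total = arr.sum()
    if total <= 0:
        raise DataError("all-zero count vector: Shannon index undefined")
    p = arr[arr > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


# ---------------------------------------------------------------------------
# distances and ordination
# ---------------------------------------------------------------------------


def distance_matrix(table: np.ndarray, metric: str = "bray_curtis") -> np.ndarray:
    """Pairwise distances between samples (rows) of an abundance table.

    ``bray_curtis`` operates on the abundances as given;
    ``euclidean_hellinger`` is the Euclidean distance between
    Hellinger-transformed rows (square roots of row proportions).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValidationError("need a 2-D table with at least 2 samples")
    if np.any(table < 0):
        raise DataError("negative abundances")
    if metric == "bray_curtis":
        d = pdist(table, metric="braycurtis")
    elif metric == "euclidean_hellinger":
        row_sums = table.sum(axis=1, keepdims=True)
        if np.any(row_sums == 0):
            raise DataError("all-zero sample row")
        d = pdist(np.sqrt(table / row_sums), metric="euclidean")
    else:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return squareform(d)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # n_samples x n_retained_axes, MDS1 first
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    percent_explained: np.ndarray  # per retained axis, of the positive-eigenvalue total

    def axis(self, i: int = 0) -> np.ndarray:
        return self.coordinates[:, i]


def pcoa(d: np.ndarray, sample_ids: Sequence[str] | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -0.5 * D^2, takes the eigendecomposition, and keeps axes
    with positive eigenvalues. Negative eigenvalues are reported in
    ``eigenvalues`` but excluded from the percent-explained denominator.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-9 * max(eigvals.max(), 0.0))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    percent = (
        100.0 * eigvals[positive] / pos_sum if pos_sum > 0 else np.zeros(int(positive.sum()))
    )
    return OrdinationResult(
        sample_ids=list(sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        percent_explained=percent,
    )


# ---------------------------------------------------------------------------
# cluster split along an ordination axis
# ---------------------------------------------------------------------------


@dataclass
class ClusterSplit:
    group_a: list[str]  # lower end of the axis
    group_b: list[str]
    axis: int
    t_statistic: float
    p_value: float


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(p):
        # zero within-group variance on both sides: degenerate
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    return t, p


def split_on_axis(ordination: OrdinationResult, axis: int = 0) -> ClusterSplit:
    """Best two-group split of samples along one ordination axis.

    Samples are sorted by their coordinate; every contiguous bipartition
    with at least two samples per side is scored with a Welch t-test on the
    coordinate, and the split with the smallest p-value is returned. Ties
    are broken toward the more balanced split.
    """
    coords = ordination.axis(axis)
    n = len(coords)
    if n < 4:
        raise ValidationError("need at least 4 samples to split")
    order = np.argsort(coords, kind="stable")
    sorted_coords = coords[order]
    best: tuple[float, int, int] | None = None  # (p, imbalance, cut)
    best_tp: tuple[float, float] = (0.0, 1.0)
    for cut in range(2, n - 1):
        t, p = _welch(sorted_coords[:cut], sorted_coords[cut:])
        imbalance = abs(2 * cut - n)
        cand = (p, imbalance, cut)
        if best is None or cand[:2] < best[:2]:
            best = cand
            best_tp = (t, p)
    assert best is not None
    cut = best[2]
    ids = [ordination.sample_ids[i] for i in order]
    return ClusterSplit(
        group_a=ids[:cut],
        group_b=ids[cut:],
        axis=axis,
        t_statistic=best_tp[0],
        p_value=best_tp[1],
    )


# ---------------------------------------------------------------------------
# regression and fold contrasts
# ---------------------------------------------------------------------------


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def regress(y: Sequence[float], x: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of y on x with the two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]):
        raise DataError("constant covariate: slope undefined")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n=len(x),
    )


@dataclass
class FoldTest:
    fold: float  # mean(a) / mean(b)
    p_value: float  # Welch two-sided; nan when either group has < 2 values
    n_a: int
    n_b: int
    infinite: bool = False


def fold_test(a: Sequence[float], b: Sequence[float]) -> FoldTest:
    """Ratio of group means with a Welch t-test on the groups.

    A zero mean in ``b`` yields an infinite-fold flag rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    mean_b = b.mean()
    if mean_b == 0:
        fold, infinite = math.inf, True
    else:
        fold, infinite = float(a.mean() / mean_b), False
    if a.size >= 2 and b.size >= 2:
        _, p = _welch(a, b)
    else:
        p = math.nan
    return FoldTest(fold=fold, p_value=p, n_a=a.size, n_b=b.size, infinite=infinite)


# ---------------------------------------------------------------------------
# mass-feature filtering and validation accounting
# ---------------------------------------------------------------------------


def filter_mass_features(
    matrix: np.ndarray,
    groups: Sequence[str],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[int]:
    """Two-step mass-feature filter.

    Keeps features (rows) detected (nonzero) in every replicate of at least
    one group, then applies a Welch t-test between the two groups and keeps
    p < ``alpha`` (strict). No multiplicity correction by default; set
    ``bh_correct`` for Benjamini-Hochberg on the presence-passing features.
    Returns retained row indices.
    """
    matrix = np.asarray(matrix, dtype=float)
    groups = list(groups)
    if matrix.ndim != 2 or matrix.shape[1] != len(groups):
        raise ValidationError("matrix columns must match the group labels")
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValidationError("exactly two groups are required")
    idx = {g: [j for j, lab in enumerate(groups) if lab == g] for g in labels}
    for g, cols in idx.items():
        if len(cols) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 replicates")
    present = [
        i
        for i in range(matrix.shape[0])
        if any(np.all(matrix[i, cols] != 0) for cols in idx.values())
    ]
    pvals = np.array(
        [_welch(matrix[i, idx[labels[0]]], matrix[i, idx[labels[1]]])[1] for i in present]
    )
    if bh_correct and len(pvals):
        pvals = _bh_adjust(pvals)
    return [i for i, p in zip(present, pvals) if p < alpha]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def validation_summary(
    predicted: set[str], confirmed: set[str], catalog_codes: set[str] | None = None
) -> tuple[int, int, int]:
    """(n_confirmed, n_predicted, integer percent confirmed-of-predicted)."""
    if not predicted:
        raise DataError("empty predicted set: percent undefined")
    if catalog_codes is not None and not confirmed <= catalog_codes:
        raise ValidationError("confirmed chemicals must belong to the catalog")
    n_confirmed = len(predicted & confirmed)
    percent = int(round(100.0 * n_confirmed / len(predicted)))
    return n_confirmed, len(predicted), percent
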