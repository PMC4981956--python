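"""Morphospace construction: regression, PCA and hull-overlap detection.

Body length is regressed on vertebral counts by ordinary least squares
with a t-based 95% confidence band. The VSI component variables (mm,
counts, ratios — incommensurate scales) are ordinated by PCA, by default
on the correlation matrix; extinct/extant morphospace overlap is scored
by convex hulls in a chosen component plane, boundary-inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import ConvexHull

from .errors import RecordError

logger = logging.getLogger(__name__)

#: the eight VSI component variables used for the default morphospace
DEFAULT_VARIABLES = [
    "L_axis1", "L_axis2", "L_head_in_vertebrae", "AR_head",
    "N_PCV", "AR_PCV", "N_CV", "AR_CV",
]


@dataclass
class RegressionResult:
    """OLS fit of y on x with a pointwise 95% confidence band for the mean."""

    slope: float
    intercept: float
    r_squared: float
    se_slope: float
    se_intercept: float
    n: int
    ci95_band: Callable[[np.ndarray], Tuple[np.ndarray, np.ndarray]] = field(repr=False)

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class PCAResult:
    """Eigen-decomposition of a correlation or covariance matrix.

    ``loadings`` columns are orthonormal eigenvectors ordered by
    non-increasing eigenvalue, each oriented so its largest-magnitude
    entry is positive; ``scores`` are the centered (and, in correlation
    mode, standardized) data projected on them.
    """

    variables: List[str]
    taxa: List[str]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    mode: str


@dataclass
class OverlapReport:
    """Taxa lying inside both groups' convex hulls in a component plane."""

    group_a: str
    group_b: str
    overlap_taxa: Set[str]
    plane: Tuple[int, int]


def fit_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with a 95% CI band from the t
    distribution on n - 2 df. Requires n >= 3 and non-constant x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise RecordError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise RecordError(f"regression needs n >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise RecordError("x is constant; slope is unidentifiable")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()

    def ci95_band(xs):
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        pred = fit.get_prediction(sm.add_constant(xs, has_constant="add"))
        lo, hi = pred.conf_int(alpha=0.05).T
        return lo, hi

    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        se_slope=float(fit.bse[1]),
        se_intercept=float(fit.bse[0]),
        n=n,
        ci95_band=ci95_band,
    )


def run_pca(table: pd.DataFrame, mode: str = "correlation") -> PCAResult:
    """PCA of a taxa x variables table.

    Incomplete rows are excluded with a logged warning; at least three
    complete rows and two variables are required. ``mode`` selects the
    correlation (default; variables standardized) or covariance matrix.
    """
    if mode not in ("correlation", "covariance"):
        raise RecordError(f"unknown PCA mode {mode!r}")
    if table.shape[1] < 2:
        raise RecordError("PCA needs >= 2 variables")
    complete = table.dropna(axis=0)
    dropped = sorted(set(table.index) - set(complete.index))
    if dropped:
        logger.warning("PCA: excluding %d incomplete row(s): %s", len(dropped), dropped)
    if complete.shape[0] < 3:
        raise RecordError(
            f"PCA needs >= 3 complete rows, have {complete.shape[0]} "
            f"(excluded: {dropped})"
        )
    X = complete.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if mode == "correlation":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [complete.columns[i] for i in np.flatnonzero(sd == 0)]
            raise RecordError(f"constant variable(s) in correlation-mode PCA: {bad}")
        Xc = Xc / sd
        mat = np.corrcoef(X, rowvar=False)
    else:
        mat = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(mat)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # orient each component so its largest-magnitude loading is positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ evecs
    return PCAResult(
        variables=list(complete.columns),
        taxa=[str(t) for t in complete.index],
        loadings=evecs,
        eigenvalues=evals,
        scores=scores,
        variance_fraction=evals / evals.sum(),
        mode=mode,
    )


def _points_in_hull(points: np.ndarray, hull: ConvexHull, tol: float = 1e-9) -> np.ndarray:
    """Boundary-inclusive membership via the hull's half-plane equations."""
    eq = hull.equations  # rows: [a, b, c] with a*x + b*y + c <= 0 inside
    d = points @ eq[:, :2].T + eq[:, 2]
    return np.all(d <= tol, axis=1)


def morphospace_overlap(
    pca: PCAResult,
    groups: Dict[str, str],
    plane: Tuple[int, int] = (0, 1),
    group_a: str | None = None,
    group_b: str | None = None,
) -> OverlapReport:
    """Convex-hull overlap between two taxon groups in a component plane.

    ``groups`` maps every scored taxon to a label; each group needs at
    least three taxa to define a hull. A taxon counts as overlapping if
    it lies inside (boundary included) the *other* group's hull.
    """
    unlabeled = [t for t in pca.taxa if t not in groups]
    if unlabeled:
        raise RecordError(f"taxa without group labels: {unlabeled}")
    labels = sorted({groups[t] for t in pca.taxa})
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise RecordError(
                f"need exactly two groups (or explicit group_a/group_b); have {labels}"
            )
        group_a, group_b = labels
    pts = {t: pca.scores[i, list(plane)] for i, t in enumerate(pca.taxa)}
    members = {
        g: [t for t in pca.taxa if groups[t] == g] for g in (group_a, group_b)
    }
    hulls = {}
    for g, taxa in members.items():
        if len(taxa) < 3:
            raise RecordError(f"group {g!r} has {len(taxa)} taxa; >= 3 needed for a hull")
        arr = np.array([pts[t] for t in taxa])
        try:
            hulls[g] = ConvexHull(arr)
        except Exception as exc:
            raise RecordError(f"degenerate hull for group {g!r}: {exc}") from exc
    overlap: Set[str] = set()
    for g, other in ((group_a, group_b), (group_b, group_a)):
        arr = np.array([pts[t] for t in members[g]])
        inside = _points_in_hull(arr, hulls[other])
        overlap.update(t for t, ok in zip(members[g], inside) if ok)
    return OverlapReport(group_a=group_a, group_b=group_b, overlap_taxa=overlap, plane=plane)


def plot_morphospace(
    pca: PCAResult,
    groups: Dict[str, str],
    path,
    plane: Tuple[int, int] = (0, 1),
) -> None:
    """Scatter the component plane, one marker style per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = plane
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in sorted(set(groups.values())):
        idx = [k for k, t in enumerate(pca.taxa) if groups[t] == g]
        ax.scatter(pca.scores[idx, i], pca.scores[idx, j], label=g, alpha=0.8)
    ax.set_xlabel(f"PC{i + 1} ({100 * pca.variance_fraction[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * pca.variance_fraction[j]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
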