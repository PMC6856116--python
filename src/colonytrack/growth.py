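"""Classification and predictive analysis of colony growth curves.

Cell numbers per colony span orders of magnitude by day 14, so curves are
square-root transformed before clustering to damp that spread.  Curves are
then grouped by agglomerative hierarchical clustering with complete linkage
(the furthest-neighbour method) on Euclidean distances, the classical
choice for growth-curve classification, and the dendrogram is cut into
``k_groups`` clusters (default 7: two large, four medium and one small
group is the typical structure of a 14-day MSC colony assay).

Predictability of the final yield is quantified by ordinary least squares
of the day-14 cell number per colony on the day-*d* number, reported as the
coefficient of determination R² for each day; R² > 0.7 is conventionally
read as a strong correlation.  The same raw-scale R² (no log transform)
validates phase-contrast counts against reference counts such as
nuclear-stain counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class GrowthCurveSet:
    """Growth-curve matrix with clustering and prediction results."""

    counts: pd.DataFrame  # colony x day, columns day_1..day_N
    k_groups: int = 7
    cluster_labels: pd.Series | None = None
    linkage_matrix: np.ndarray | None = None
    r2_by_day: dict[int, float] = field(default_factory=dict)

    @property
    def sqrt_counts(self) -> pd.DataFrame:
        return np.sqrt(self.counts)

    @property
    def days(self) -> list[int]:
        return [int(c.split("_")[1]) for c in self.counts.columns]


def cluster_curves(
    sqrt_counts: np.ndarray | pd.DataFrame, k_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage clustering of square-root growth curves.

    Returns ``(labels, linkage_matrix)``.  Labels run 1..k and are ordered
    by descending group mean of the final-day value, so group 1 always
    contains the largest colonies; the linkage matrix is the standard
    SciPy agglomeration encoding of the dendrogram.
    """
    x = np.asarray(sqrt_counts, dtype=float)
    n = len(x)
    if k_groups < 1:
        raise ValueError("k_groups must be >= 1")
    if k_groups > n:
        raise ValueError(f"k_groups={k_groups} exceeds number of curves ({n})")
    if n == 1:
        return np.array([1]), np.empty((0, 4))
    z = linkage(x, method="complete", metric="euclidean")
    raw = fcluster(z, t=k_groups, criterion="maxclust")
    # relabel by descending mean final-day value
    finals = x[:, -1]
    means = {g: finals[raw == g].mean() for g in np.unique(raw)}
    order = sorted(means, key=lambda g: -means[g])
    remap = {g: i + 1 for i, g in enumerate(order)}
    labels = np.array([remap[g] for g in raw])
    return labels, z


def predict_day14(counts: pd.DataFrame) -> dict[int, float]:
    """R² of the final-day cell number per colony regressed on each day.

    For every day *d*, ordinary least squares of final-day counts on
    day-*d* counts across colonies (raw scale); the reported value is the
    squared Pearson correlation, so the final day itself gives exactly 1.
    A day with zero variance across colonies has no defined R² and is
    reported as NaN with a warning.
    """
    if len(counts) < 3:
        raise ValueError("need at least 3 colonies")
    days = [int(c.split("_")[1]) for c in counts.columns]
    final_col = counts.columns[-1]
    y = counts[final_col].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("final-day counts have zero variance")
    r2: dict[int, float] = {}
    for d, col in zip(days, counts.columns):
        x = counts[col].to_numpy(dtype=float)
        if np.var(x) == 0:
            warnings.warn(f"day {d}: zero variance in predictor, R^2 undefined")
            r2[d] = float("nan")
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2[d] = float(r**2)
    return r2


@dataclass
class CountValidation:
    r2: float
    slope: float
    intercept: float
    mean_relative_error: float
    n: int


def validate_counts(
    detected_counts: np.ndarray, truth_counts: np.ndarray
) -> CountValidation:
    """Agreement between detected and reference per-colony counts.

    Ordinary least squares on the raw counts (no log transform): R² is the
    squared Pearson correlation of the paired counts, alongside the fitted
    slope/intercept and the mean relative error
    ``mean(|detected - truth| / truth)`` over pairs with nonzero truth.
    """
    det = np.asarray(detected_counts, dtype=float)
    tru = np.asarray(truth_counts, dtype=float)
    if det.shape != tru.shape:
        raise ValueError("detected and truth counts must have the same length")
    if len(det) < 3:
        raise ValueError("need at least 3 paired counts")
    slope, intercept = np.polyfit(tru, det, 1)
    r = np.corrcoef(tru, det)[0, 1]
    nz = tru != 0
    mre = float(np.mean(np.abs(det[nz] - tru[nz]) / tru[nz])) if nz.any() else float("nan")
    return CountValidation(
        r2=float(r**2),
        slope=float(slope),
        intercept=float(intercept),
        mean_relative_error=mre,
        n=len(det),
    )


def analyze_growth(counts: pd.DataFrame, k_groups: int = 7) -> GrowthCurveSet:
    """Cluster the curves and compute per-day prediction R² in one call."""
    gcs = GrowthCurveSet(counts=counts, k_groups=k_groups)
    if len(counts) >= max(k_groups, 1):
        labels, z = cluster_curves(gcs.sqrt_counts.to_numpy(), k_groups)
        gcs.cluster_labels = pd.Series(labels, index=counts.index, name="group")
        gcs.linkage_matrix = z
    else:
        warnings.warn(
            f"only {len(counts)} colonies; skipping clustering (k_groups={k_groups})"
        )
    if len(counts) >= 3 and np.var(counts.iloc[:, -1].to_numpy(dtype=float)) > 0:
        gcs.r2_by_day = predict_day14(counts)
    return gcs
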