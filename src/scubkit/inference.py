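"""Statistical comparisons and multivariate views of codon-usage profiles.

chi-square cross-table tests (no continuity correction), Welch/pooled
two-sample t-tests, coefficient of variation, average-linkage hierarchical
clustering under correlation distance (reported on a 0-100 similarity
scale), and PCA score coefficients with a deterministic sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p: float
    low_expected: bool  # any expected cell < 1; result still reported


def chisq_crosstable(table: Sequence[Sequence[float]]) -> ChisqResult:
    """Pearson chi-square on an r x k count table, upper-tail p, no Yates."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("cross table needs at least 2 columns")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("cross table cells must be finite and non-negative")
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("row and column totals must be positive")
    expected = row @ col / arr.sum()
    statistic = float(((arr - expected) ** 2 / expected).sum())
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return ChisqResult(statistic, df, p, bool((expected < 1).any()))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> TTestResult:
    """Two-sample t-test, Welch by default (``equal_var=True`` for pooled).

    Two zero-variance samples with equal means return t=0, p=1 by
    convention instead of NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        df = len(x) + len(y) - 2
        return TTestResult(0.0, float(df), 1.0)
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def coefficient_of_variation(x: Sequence[float]) -> float:
    """Sample standard deviation divided by the mean."""
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def _drop_incomplete_columns(m: pd.DataFrame) -> pd.DataFrame:
    bad = m.columns[m.isna().any()]
    if len(bad):
        logger.info("dropping %d column(s) with missing values: %s", len(bad), list(bad))
        m = m.drop(columns=bad)
    return m


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray          # scipy linkage matrix, heights = 1 - r
    merge_similarities: list[float]  # 100 * (1 - d/2) per merge
    newick: str


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def build(node: int) -> str:
        if node < n:
            return labels[node]
        left, right, height, _ = z[node - n]
        return f"({build(int(left))}:{height / 2:.6g},{build(int(right))}:{height / 2:.6g})"

    return build(2 * n - 2) + ";"


def cluster_profiles(m: pd.DataFrame) -> ClusterResult:
    """Average-linkage agglomeration under d = 1 - Pearson correlation.

    Merge heights are also reported on the similarity scale 100*(1 - d/2)
    so a perfect correlation merge scores 100 and a perfect anticorrelation
    merge scores 0.  Constant rows (zero variance) are an error.
    """
    m = _drop_incomplete_columns(m)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 complete columns")
    values = m.to_numpy(dtype=float)
    variances = values.var(axis=1)
    for label, var in zip(m.index, variances):
        if var == 0:
            raise ValueError(f"row {label!r} is constant; correlation distance undefined")
    dist = pdist(values, metric="correlation")
    z = hierarchy.linkage(dist, method="average")
    sims = [100.0 * (1.0 - h / 2.0) for h in z[:, 2]]
    labels = [str(ix) for ix in m.index]
    return ClusterResult(labels, z, sims, _linkage_to_newick(z, labels))


@dataclass
class PcaResult:
    scores: pd.DataFrame             # rows x retained components
    explained_variance_ratio: list[float]
    loadings: pd.DataFrame           # features x retained components


def pca_scores(
    m: pd.DataFrame, n_components: int = 2, standardize: bool = False
) -> PcaResult:
    """Scores on the leading principal components of the (centered) matrix.

    Sign convention: each component's loading vector is flipped so that its
    largest-magnitude loading is positive, making outputs reproducible.
    Components beyond the matrix rank are not reported.
    """
    m = _drop_incomplete_columns(m)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    x = m.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
        feature_names = [f for f, k in zip(m.columns, keep) if k]
    else:
        feature_names = list(m.columns)

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    k = min(n_components, rank)

    total_var = float((s**2).sum())
    scores = np.zeros((x.shape[0], k))
    loadings = np.zeros((len(feature_names), k))
    ratios: list[float] = []
    for j in range(k):
        load = vt[j]
        sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
        loadings[:, j] = sign * load
        scores[:, j] = sign * u[:, j] * s[j]
        ratios.append(float(s[j] ** 2 / total_var) if total_var > 0 else 0.0)

    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.index, columns=comp_names),
        explained_variance_ratio=ratios,
        loadings=pd.DataFrame(loadings, index=feature_names, columns=comp_names),
    )
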