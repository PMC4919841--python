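"""Two-group comparison statistics for quantified protein groups.

The analysis chain mirrors common label-free practice: keep protein
groups quantified in >90 % of samples, log10-transform, Welch two-sample
t-test per group with Benjamini-Hochberg correction (q < 0.05 flags a
significant responder), Mann-Whitney for taxon abundances, k-nearest-
neighbour imputation followed by PCA for sample ordination, and
average-linkage (UPGMA) hierarchical clustering on Euclidean distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from sklearn.impute import KNNImputer

#: Presence threshold: with 32 samples this keeps rows valid in >= 29.
DEFAULT_MIN_FRAC = 29 / 32


def presence_filter(matrix: pd.DataFrame, min_frac: float = DEFAULT_MIN_FRAC) -> pd.DataFrame:
    """Keep rows with valid values in at least ``ceil(min_frac * n)`` columns."""
    n = matrix.shape[1]
    need = math.ceil(min_frac * n)
    valid = matrix.notna().sum(axis=1)
    return matrix.loc[valid >= need]


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q(i) = min_{j >= i} p_(j) * m / j`` over the m tested hypotheses,
    clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test, two-sided.

    Zero variance in both groups with equal means returns p = 1; zero
    variance with different means returns p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def ttest_bh(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    group_order: tuple[str, str] | None = None,
    log_transform: bool = True,
    equal_var: bool = False,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-row two-sample t-test with BH correction on log10 intensities.

    The fold change is ``mean(log10 group1) - mean(log10 group2)``
    (anti-symmetric under group swap).  Rows with fewer than two observed
    values in either group are reported with ``tested=False`` and NaN
    statistics.  Fold-change responder tiers are flagged at 2x and 100x.
    """
    groups = pd.Series(groups)
    labels = group_order or tuple(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    g1 = [c for c in matrix.columns if groups.get(c) == labels[0]]
    g2 = [c for c in matrix.columns if groups.get(c) == labels[1]]
    data = np.log10(matrix[g1 + g2]) if log_transform else matrix[g1 + g2]
    rows = []
    for row_id, row in data.iterrows():
        a = row[g1].dropna().to_numpy()
        b = row[g2].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append((row_id, np.nan, np.nan, np.nan, False))
            continue
        fc = float(a.mean() - b.mean())
        if equal_var:
            t, p = sps.ttest_ind(a, b, equal_var=True)
            t, p = float(t), float(p)
            if np.isnan(p):
                t, p = welch_ttest(a, b)
        else:
            t, p = welch_ttest(a, b)
        rows.append((row_id, fc, t, p, True))
    out = pd.DataFrame(rows, columns=["row_id", "log10_fc", "t", "p", "tested"]).set_index(
        "row_id"
    )
    tested = out["tested"].to_numpy()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested] = bh_qvalues(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["significant"] = (out["q"] < q_threshold).fillna(False)
    out["fold_change_2x"] = out["log10_fc"].abs() >= np.log10(2)
    out["fold_change_100x"] = out["log10_fc"].abs() >= 2.0
    return out


def mannwhitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The exact distribution is used for group sizes up to 8 when there are
    no ties; otherwise the normal approximation with tie correction and
    continuity correction applies.  All values tied across both groups
    gives p = 1, as does U exactly at its null mean.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    u_mean = a.size * b.size / 2.0
    if np.ptp(pooled) == 0:
        return u_mean, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u = float(res.statistic)
    p = float(min(res.pvalue, 1.0))
    if u == u_mean:
        p = 1.0
    return u, p


def knn_impute_pca(
    matrix: pd.DataFrame, k: int = 1, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kNN imputation (nearest rows) followed by PCA on samples.

    Missing entries of a row are filled from its ``k`` nearest rows under
    the (NaN-aware) Euclidean distance over shared columns.  PCA runs on
    the column-centred sample-by-row matrix; scores for the first
    ``n_components`` components are returned per sample, along with the
    loadings.  Component signs are fixed so the largest-magnitude loading
    of each component is positive.
    """
    matrix = matrix.dropna(how="all")
    if matrix.isna().any().any():
        imputer = KNNImputer(n_neighbors=k)
        values = imputer.fit_transform(matrix.to_numpy(dtype=float))
    else:
        values = matrix.to_numpy(dtype=float)
    X = values.T  # samples x rows
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, s.size)
    for c in range(n_components):  # deterministic sign convention
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] = -vt[c]
            u[:, c] = -u[:, c]
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components],
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        vt[:n_components].T,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, loadings


def hcluster(matrix: pd.DataFrame) -> dict[str, object]:
    """UPGMA trees for rows and columns on Euclidean distance.

    Returns scipy linkage matrices plus Newick strings; requires at least
    two rows and two columns and no missing values (impute first).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    if matrix.isna().any().any():
        raise ValueError("missing values present; impute before clustering")
    row_link = sch.linkage(matrix.to_numpy(dtype=float), method="average", metric="euclidean")
    col_link = sch.linkage(matrix.to_numpy(dtype=float).T, method="average", metric="euclidean")
    return {
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_newick": linkage_to_newick(row_link, list(matrix.index)),
        "col_newick": linkage_to_newick(col_link, list(matrix.columns)),
    }


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
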