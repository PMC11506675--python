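"""Exploratory analysis on replicate-averaged profiles.

PCA treats the design cells (condition x day x zone combinations) as
observations and proteins as variables; variables are centred but not
scaled by default, matching the common default for this kind of
analysis. K-means clusters per-protein z-scored profiles so clusters
capture abundance *patterns* rather than absolute levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .matrix import AbundanceMatrix, CellMeanMatrix, cell_means

logger = logging.getLogger(__name__)

#: Smallest p-value reported by the chi-squared independence test.
P_FLOOR = np.finfo(float).tiny


def compute_cell_means(matrix: AbundanceMatrix) -> CellMeanMatrix:
    """Average the replicates of each design cell (available-case mean)."""
    return cell_means(matrix)


@dataclass
class PCAResult:
    scores: pd.DataFrame        # cells x components
    loadings: pd.DataFrame      # proteins x components
    variance_frac: pd.Series    # per component, sums to 1
    excluded_proteins: pd.Index


def run_pca(cellmeans: CellMeanMatrix, scale: bool = False) -> PCAResult:
    """PCA of cells in protein space (centred, unscaled by default).

    Proteins with any missing cell mean are excluded (and reported);
    variance fractions are over all non-trivial components and sum to 1.
    """
    complete, excluded = cellmeans.complete()
    if len(excluded):
        logger.info("PCA: %d protein(s) with missing cell means excluded", len(excluded))
    if complete.n_cells < 2:
        raise ValueError("PCA needs at least 2 design cells")
    X = complete.values.to_numpy(dtype=float).T  # cells x proteins
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    # SVD of the centred matrix: scores = U S, loadings = V
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    # deterministic sign: largest-magnitude loading positive
    for k in range(n_comp):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.full(n_comp, np.nan)
    cells_index = pd.Index([f"{c}_{d}_z{z}" for c, d, z in complete.cells], name="cell")
    return PCAResult(
        scores=pd.DataFrame(u * s, index=cells_index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=complete.protein_ids, columns=comp_names),
        variance_frac=pd.Series(frac, index=comp_names, name="variance_frac"),
        excluded_proteins=excluded,
    )


@dataclass
class ClusterAssignment:
    labels: pd.Series           # protein -> cluster in 1..k
    centroids: pd.DataFrame     # k x cells (z-scored profile space)
    inertia: float

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def cluster_proteins(
    cellmeans: CellMeanMatrix,
    k: int = 8,
    seed: int = 0,
    restarts: int = 25,
) -> ClusterAssignment:
    """K-means on z-scored protein profiles; best of several restarts.

    Proteins are sorted by id before fitting so the assignment does not
    depend on input row order; labels are renumbered 1..k in order of
    first appearance for stable output.
    """
    complete, excluded = cellmeans.complete()
    if len(excluded):
        logger.info("clustering: %d protein(s) with missing cell means excluded", len(excluded))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > complete.values.shape[0]:
        raise ValueError(f"k={k} exceeds {complete.values.shape[0]} proteins")
    order = complete.values.index.sort_values()
    X = _zscore_rows(complete.values.loc[order].to_numpy(dtype=float))
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed & 0x7FFFFFFF, algorithm="lloyd")
    raw_labels = km.fit_predict(X)
    relabel: dict[int, int] = {}
    for lab in raw_labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series(
        [relabel[lab] for lab in raw_labels], index=order, name="cluster"
    ).loc[complete.values.index]
    centroid_rows = np.empty((k, X.shape[1]))
    for raw, new in relabel.items():
        centroid_rows[new - 1] = km.cluster_centers_[raw]
    centroids = pd.DataFrame(
        centroid_rows,
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=complete.values.columns,
    )
    return ClusterAssignment(labels=labels, centroids=centroids, inertia=float(km.inertia_))


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p: float
    table: pd.DataFrame


def test_cluster_annotation_independence(
    assignment: ClusterAssignment | pd.Series,
    annotation: pd.Series,
) -> Chi2Result:
    """Pearson chi-squared independence of cluster vs level-1 bin.

    Works on the clusters x bins contingency table (no continuity
    correction, as usual for r x c tables); the p-value is floored at
    the smallest positive float so a vanishing p is reported as a bound
    rather than zero.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    common = labels.index.intersection(annotation.index)
    if len(common) == 0:
        raise ValueError("no proteins shared between assignment and annotation")
    table = pd.crosstab(labels.loc[common], annotation.loc[common])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        zero_rows = list(table.index[table.sum(axis=1) == 0])
        zero_cols = list(table.columns[table.sum(axis=0) == 0])
        raise ValueError(f"degenerate contingency table: zero margin rows={zero_rows} cols={zero_cols}")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"need >=2 clusters and >=2 annotation categories, got {table.shape}"
        )
    stat, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return Chi2Result(statistic=float(stat), df=int(df), p=max(float(p), P_FLOOR), table=table)
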