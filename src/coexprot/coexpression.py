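"""Condition-specific protein co-expression networks.

Within one watering condition the replicate-averaged profiles vary only
with developmental position (day x zone), so a significant Pearson
correlation between two proteins across those design cells indicates
coordinated abundance through ear development. For every unordered
protein pair the correlation is tested with the exact t-transform
(df = m - 2 over m shared cells), p-values are BH-adjusted over all
pairs within the condition, and pairs with adjusted p below alpha
become edges — of either sign; the sign is kept on the edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_bh
from .matrix import AbundanceMatrix, CellMeanMatrix, cell_means

logger = logging.getLogger(__name__)

#: Reporting floor for correlation p-values (avoids zeros downstream).
P_FLOOR = 1e-300

#: Minimum shared cells for a pair to be testable (df >= 2).
MIN_SHARED_CELLS = 4


@dataclass
class CoexpressionNetwork:
    """Edges over a fixed protein universe for one condition.

    ``edges`` has columns protein_a, protein_b (a < b), r, p, p_adj.
    The density denominator uses the full node universe P(P-1)/2, not
    just connected nodes.
    """

    condition: str
    nodes: pd.Index
    edges: pd.DataFrame
    n_excluded_pairs: int = 0
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        if len(self.edges):
            a = self.edges["protein_a"]
            b = self.edges["protein_b"]
            if (a == b).any():
                raise ValueError("self-edge in network")
            if (a >= b).any():
                raise ValueError("edges must be stored with protein_a < protein_b")
            pairs = pd.MultiIndex.from_frame(self.edges[["protein_a", "protein_b"]])
            if pairs.has_duplicates:
                raise ValueError("duplicated edge")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_possible(self) -> int:
        p = self.n_nodes
        return p * (p - 1) // 2

    @property
    def density(self) -> float:
        return network_density(self)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["protein_a"], self.edges["protein_b"]))

    def degrees(self) -> pd.Series:
        counts = pd.concat([self.edges["protein_a"], self.edges["protein_b"]]).value_counts()
        return counts.reindex(self.nodes, fill_value=0).rename("degree")


def condition_cell_means(matrix: AbundanceMatrix, condition: str) -> CellMeanMatrix:
    """Replicate-averaged profiles restricted to one condition.

    On the study design WW yields 10 cells (2 days x 5 zones) and WD 9
    (the aborted SE5/zone-5 cell is absent).
    """
    mask = matrix.design["condition"] == condition
    if not mask.any():
        raise ValueError(f"condition {condition!r} absent from design")
    return cell_means(matrix.subset_samples(matrix.design.index[mask]))


def correlation_pvalue(r, m) -> np.ndarray:
    """Two-sided p for Pearson r over m observations via the t-transform."""
    r = np.asarray(r, dtype=float)
    m = np.asarray(m, dtype=float)
    df = m - 2
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(df / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rr) >= 1.0, 0.0, p)
    return np.clip(p, P_FLOOR, 1.0)


def correlation_edges(
    cellmeans: CellMeanMatrix,
    alpha: float = 0.05,
    condition: str = "",
) -> CoexpressionNetwork:
    """Test all protein pairs and keep BH-significant correlations.

    Pairs are evaluated on pairwise-complete cells; pairs sharing fewer
    than four cells, and pairs involving a zero-variance profile, are
    excluded from testing (counted, not edges). All proteins remain
    network nodes regardless.
    """
    if cellmeans.n_cells < MIN_SHARED_CELLS:
        raise ValueError(f"need >= {MIN_SHARED_CELLS} cells, got {cellmeans.n_cells}")
    values = cellmeans.values.to_numpy(dtype=float)
    nodes = cellmeans.protein_ids
    n = len(nodes)

    finite = np.isfinite(values)
    shared = finite.astype(np.int64) @ finite.T.astype(np.int64)
    sd = np.nanstd(values, axis=1)
    zero_var = sd == 0
    n_zero_var = int(zero_var.sum())
    if n_zero_var:
        logger.info("%d zero-variance protein(s) excluded from correlation testing", n_zero_var)

    with np.errstate(invalid="ignore", divide="ignore"):
        if finite.all():
            corr = np.corrcoef(values)
        else:
            corr = pd.DataFrame(values.T).corr(min_periods=MIN_SHARED_CELLS).to_numpy()

    iu, ju = np.triu_indices(n, k=1)
    r = corr[iu, ju]
    m = shared[iu, ju]
    testable = np.isfinite(r) & (m >= MIN_SHARED_CELLS) & ~zero_var[iu] & ~zero_var[ju]
    n_excluded = int((~testable).sum())

    p = np.full(r.shape, np.nan)
    p[testable] = correlation_pvalue(r[testable], m[testable])
    p_adj = np.full(r.shape, np.nan)
    p_adj[testable] = adjust_bh(p[testable])

    keep = testable & (p_adj < alpha)
    edges = pd.DataFrame(
        {
            "protein_a": nodes[iu[keep]],
            "protein_b": nodes[ju[keep]],
            "r": r[keep],
            "p": p[keep],
            "p_adj": p_adj[keep],
        }
    )
    # canonical order: a < b lexicographically, rows sorted
    swap = edges["protein_a"] > edges["protein_b"]
    edges.loc[swap, ["protein_a", "protein_b"]] = edges.loc[
        swap, ["protein_b", "protein_a"]
    ].to_numpy()
    edges = edges.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)
    net = CoexpressionNetwork(
        condition=condition,
        nodes=nodes,
        edges=edges,
        n_excluded_pairs=n_excluded,
        n_zero_variance=n_zero_var,
    )
    logger.info(
        "%s network: %d edges / %d possible pairs (density %.5f), %d pair(s) untestable",
        condition or "unlabelled", net.n_edges, net.n_possible, net.density, n_excluded,
    )
    return net


def build_network(
    matrix: AbundanceMatrix,
    condition: str,
    alpha: float = 0.05,
) -> CoexpressionNetwork:
    """Cell means for one condition, then significant correlation edges."""
    return correlation_edges(condition_cell_means(matrix, condition), alpha, condition)


def network_density(network: CoexpressionNetwork) -> float:
    """Observed edges over all possible unordered pairs P(P-1)/2."""
    if network.n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return network.n_edges / network.n_possible


def write_edges(network: CoexpressionNetwork, path) -> None:
    out = network.edges.copy()
    out["condition"] = network.condition
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def network_from_edges(
    nodes, edge_pairs, condition: str = ""
) -> CoexpressionNetwork:
    """Build a network from explicit pairs (r/p fields filled with NaN)."""
    rows = []
    for a, b in edge_pairs:
        a, b = (a, b) if a < b else (b, a)
        rows.append((a, b))
    edges = pd.DataFrame(sorted(set(rows)), columns=["protein_a", "protein_b"]) \
        if rows else pd.DataFrame(columns=["protein_a", "protein_b"])
    edges["r"] = np.nan
    edges["p"] = np.nan
    edges["p_adj"] = np.nan
    return CoexpressionNetwork(condition=condition, nodes=pd.Index(nodes), edges=edges)
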