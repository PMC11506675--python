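"""Cross-network statistics and annotation-level connectivity tests.

Covers: overlap of two condition networks against an independence null
(expected common edges = n_A * n_B / n_possible, one-sided binomial
tail), hypergeometric enrichment of edges within/between level-1
process pairs inside one network, 2x2 chi-squared tests of WW-vs-WD
connectivity change per process pair, bookkeeping of edges by how many
differentially expressed endpoints they carry, and per-protein degree
gains/losses between conditions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CoexpressionNetwork, P_FLOOR
from .differential import adjust_bh

logger = logging.getLogger(__name__)

#: Conventional reporting floor for vanishing p-values.
REPORT_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    """Render a p-value, using the conventional "<2.2e-16" floor."""
    if p < REPORT_FLOOR:
        return "<2.2e-16"
    return f"{p:.4g}"


def expected_common_edges(n_A: int, n_B: int, P: int) -> float:
    """Expected shared edges if the two networks were independent.

    With densities p_A = n_A / C and p_B = n_B / C over the C = P(P-1)/2
    possible pairs, independence gives p_A * p_B * C = n_A * n_B / C.
    """
    if P < 2:
        raise ValueError("need at least 2 nodes")
    n_possible = P * (P - 1) // 2
    for name, n in (("n_A", n_A), ("n_B", n_B)):
        if not 0 <= n <= n_possible:
            raise ValueError(f"{name}={n} outside [0, {n_possible}]")
    return n_A * n_B / n_possible


@dataclass
class OverlapResult:
    n_A: int
    n_B: int
    n_common: int
    n_union: int
    n_possible: int
    expected_common: float
    p: float

    def to_dict(self) -> dict:
        return {
            "n_A": self.n_A, "n_B": self.n_B, "n_common": self.n_common,
            "n_union": self.n_union, "n_possible": self.n_possible,
            "expected_common": self.expected_common,
            "p": self.p, "p_reported": format_p(self.p),
        }


def test_overlap(observed_common: int, n_A: int, n_B: int, P: int) -> OverlapResult:
    """One-sided binomial tail for the observed number of shared edges.

    Null: each of the C possible pairs is a shared edge independently
    with probability p_A * p_B; p = P(X >= observed).
    """
    if observed_common > min(n_A, n_B):
        raise ValueError("observed_common exceeds min(n_A, n_B)")
    n_possible = P * (P - 1) // 2
    expected = expected_common_edges(n_A, n_B, P)
    prob = (n_A / n_possible) * (n_B / n_possible)
    p = float(stats.binom.sf(observed_common - 1, n_possible, prob))
    return OverlapResult(
        n_A=n_A, n_B=n_B, n_common=observed_common,
        n_union=n_A + n_B - observed_common,
        n_possible=n_possible, expected_common=expected,
        p=max(p, P_FLOOR),
    )


def overlap(net_A: CoexpressionNetwork, net_B: CoexpressionNetwork) -> OverlapResult:
    """Overlap test computed directly from two networks."""
    _check_universe(net_A, net_B)
    common = len(net_A.edge_set() & net_B.edge_set())
    return test_overlap(common, net_A.n_edges, net_B.n_edges, net_A.n_nodes)


def _check_universe(net_A: CoexpressionNetwork, net_B: CoexpressionNetwork) -> None:
    if set(net_A.nodes) != set(net_B.nodes):
        raise ValueError("networks must share the same node universe")


def _term_pair_possible(k_A: int, k_B: int, same: bool) -> int:
    return k_A * (k_A - 1) // 2 if same else k_A * k_B


def _edge_term_counts(network: CoexpressionNetwork, bins: pd.Series) -> dict[tuple[str, str], int]:
    """Edges per unordered term pair; each edge counts for exactly one pair."""
    counts: dict[tuple[str, str], int] = {}
    ta = bins.loc[network.edges["protein_a"]].to_numpy()
    tb = bins.loc[network.edges["protein_b"]].to_numpy()
    for a, b in zip(ta, tb):
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    return counts


def term_pair_enrichment(
    network: CoexpressionNetwork,
    annotation: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over/under-connectivity of process pairs.

    Under the no-preferential-connection null, the network's n_edges
    are a uniform draw from the C = P(P-1)/2 possible pairs, of which
    K(A,B) belong to the term pair; the observed count is then
    hypergeometric. Both one-sided tails are reported and BH-adjusted
    (each tail across all term pairs).
    """
    bins = annotation.loc[network.nodes]
    sizes = bins.value_counts()
    terms = sorted(sizes.index[sizes > 0])
    observed = _edge_term_counts(network, bins)
    M = network.n_possible
    N = network.n_edges

    rows = []
    for a, b in itertools.combinations_with_replacement(terms, 2):
        K = _term_pair_possible(sizes[a], sizes[b], a == b)
        if K == 0:
            continue
        obs = observed.get((a, b), 0)
        p_over = float(stats.hypergeom.sf(obs - 1, M, K, N))
        p_under = float(stats.hypergeom.cdf(obs, M, K, N))
        expected = N * K / M
        rows.append((a, b, K, obs, expected, p_over, p_under))
    table = pd.DataFrame(
        rows,
        columns=["term_a", "term_b", "n_pairs_possible", "observed",
                 "expected", "p_over", "p_under"],
    )
    table["p_over_adj"] = adjust_bh(table["p_over"])
    table["p_under_adj"] = adjust_bh(table["p_under"])
    table["direction"] = np.select(
        [table["p_over_adj"] < alpha, table["p_under_adj"] < alpha],
        ["over", "under"], default="ns",
    )
    return table


def compare_term_pair_connectivity(
    net_A: CoexpressionNetwork,
    net_B: CoexpressionNetwork,
    annotation: pd.Series,
    yates: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """2x2 chi-squared test of connectivity change per process pair.

    For a term pair, the table is [[x_A, n_A - x_A], [x_B, n_B - x_B]]
    where x is the number of edges with exactly one endpoint in each
    term (both in the term for intra-pairs) and n the network's edge
    total. Yates continuity correction is applied by default. Pairs
    with a zero table margin are skipped with a reason. The direction
    is the sign of the proportion change in B relative to A.
    """
    _check_universe(net_A, net_B)
    bins = annotation.loc[net_A.nodes]
    sizes = bins.value_counts()
    terms = sorted(sizes.index[sizes > 0])
    counts_A = _edge_term_counts(net_A, bins)
    counts_B = _edge_term_counts(net_B, bins)
    n_A, n_B = net_A.n_edges, net_B.n_edges

    rows, skipped = [], []
    for a, b in itertools.combinations_with_replacement(terms, 2):
        if _term_pair_possible(sizes[a], sizes[b], a == b) == 0:
            continue
        x_A = counts_A.get((a, b), 0)
        x_B = counts_B.get((a, b), 0)
        table = np.array([[x_A, n_A - x_A], [x_B, n_B - x_B]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            skipped.append((a, b, "zero margin"))
            continue
        if x_A == x_B and n_A == n_B:
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
        diff = x_B / n_B - x_A / n_A
        rows.append((a, b, x_A, n_A, x_B, n_B, float(stat), float(p), np.sign(diff)))
    result = pd.DataFrame(
        rows,
        columns=["term_a", "term_b", "x_A", "n_A", "x_B", "n_B",
                 "chi2", "p", "direction"],
    )
    result["p_adj"] = adjust_bh(result["p"])
    result["significant"] = result["p_adj"] < alpha
    if skipped:
        logger.info("connectivity change: %d term pair(s) skipped (%s ...)",
                    len(skipped), skipped[0])
    result.attrs["skipped"] = skipped
    return result


def classify_edges_by_dep(
    network: CoexpressionNetwork, dep_set: set[str]
) -> tuple[int, int, int]:
    """Count edges with 0, 1 or 2 differentially expressed endpoints."""
    unknown = dep_set - set(network.nodes)
    if unknown:
        raise ValueError(f"DEP proteins outside node universe: {sorted(unknown)[:5]}")
    counts = [0, 0, 0]
    for a, b in network.edge_set():
        counts[(a in dep_set) + (b in dep_set)] += 1
    return tuple(counts)


def dep_breakdown_table(
    counts_A: tuple[int, int, int],
    counts_B: tuple[int, int, int],
    counts_common: tuple[int, int, int],
    labels: tuple[str, str] = ("WW", "WD"),
) -> pd.DataFrame:
    """DEP-class bookkeeping rows: common, each network, and the union.

    The union row is A + B - common per class; row totals close the
    table.
    """
    a = np.asarray(counts_A, dtype=int)
    b = np.asarray(counts_B, dtype=int)
    c = np.asarray(counts_common, dtype=int)
    if (c > np.minimum(a, b)).any():
        raise ValueError("common class counts exceed a network's counts")
    union = a + b - c
    frame = pd.DataFrame(
        [c, a, b, union],
        index=pd.Index(
            [f"common ({labels[0]} and {labels[1]})",
             f"{labels[0]} network", f"{labels[1]} network", "union"],
            name="edge_set",
        ),
        columns=["no_dep", "one_dep", "two_dep"],
    )
    frame["total"] = frame.sum(axis=1)
    return frame


def edge_set_algebra(
    net_A: CoexpressionNetwork,
    net_B: CoexpressionNetwork,
    dep_set: set[str],
) -> pd.DataFrame:
    """DEP breakdown for two networks, their intersection and union."""
    _check_universe(net_A, net_B)
    common_edges = net_A.edge_set() & net_B.edge_set()
    common = CoexpressionNetwork(
        condition="common",
        nodes=net_A.nodes,
        edges=pd.DataFrame(sorted(common_edges), columns=["protein_a", "protein_b"])
        if common_edges else pd.DataFrame(columns=["protein_a", "protein_b"]),
    )
    labels = (net_A.condition or "A", net_B.condition or "B")
    return dep_breakdown_table(
        classify_edges_by_dep(net_A, dep_set),
        classify_edges_by_dep(net_B, dep_set),
        classify_edges_by_dep(common, dep_set),
        labels=labels,
    )


def node_degree_delta(
    net_A: CoexpressionNetwork,
    net_B: CoexpressionNetwork,
    annotation: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-protein edge gains and losses between two networks.

    An edge "lost" is present in A but not B; "gained" the reverse.
    When an annotation is given, per-node tallies of the partner
    protein's process are included (serialised as "term:count;...").
    Rows are sorted by total rewiring (losses + gains), descending.
    """
    _check_universe(net_A, net_B)
    edges_A, edges_B = net_A.edge_set(), net_B.edge_set()
    lost, gained = edges_A - edges_B, edges_B - edges_A

    def tally(edge_set):
        per_node: dict[str, dict[str, int]] = {}
        for a, b in edge_set:
            for node, partner in ((a, b), (b, a)):
                d = per_node.setdefault(node, {})
                key = annotation.loc[partner] if annotation is not None else "all"
                d[key] = d.get(key, 0) + 1
        return per_node

    lost_t, gained_t = tally(lost), tally(gained)
    deg_A, deg_B = net_A.degrees(), net_B.degrees()

    def serialise(d: dict[str, int]) -> str:
        return ";".join(f"{k}:{v}" for k, v in sorted(d.items()))

    rows = []
    for node in net_A.nodes:
        ls, gs = lost_t.get(node, {}), gained_t.get(node, {})
        n_lost, n_gained = sum(ls.values()), sum(gs.values())
        rows.append((node, int(deg_A.loc[node]), int(deg_B.loc[node]),
                     n_lost, n_gained, serialise(ls), serialise(gs)))
    frame = pd.DataFrame(
        rows,
        columns=["protein_id", "degree_A", "degree_B",
                 "n_lost", "n_gained", "lost_partners", "gained_partners"],
    )
    frame["rewiring"] = frame["n_lost"] + frame["n_gained"]
    return frame.sort_values(
        ["rewiring", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)
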