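import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coexprot import compare as cmp
from coexprot.coexpression import network_from_edges


def random_network(rng, nodes, density, condition=""):
    pairs = list(itertools.combinations(nodes, 2))
    chosen = [p for p in pairs if rng.random() < density]
    return network_from_edges(nodes, chosen, condition=condition)


class TestExpectedCommonEdges:
    def test_printed_counts_give_expected_68(self):
        expected = cmp.expected_common_edges(7824, 2768, 800)
        assert expected == pytest.approx(7824 * 2768 / 319600)
        assert expected == pytest.approx(67.76, abs=0.005)
        assert round(expected) == 68

    def test_empty_network_expects_zero(self):
        assert cmp.expected_common_edges(5000, 0, 800) == 0.0

    def test_two_complete_networks_expect_everything(self):
        n_possible = 10 * 9 // 2
        assert cmp.expected_common_edges(n_possible, n_possible, 10) == n_possible

    def test_tiny_node_count_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cmp.expected_common_edges(0, 0, 1)

    def test_count_above_possible_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cmp.expected_common_edges(100, 0, 5)


class TestOverlap:
    def test_tail_matches_binomial_enumeration(self):
        """Toy P=6: tail probability equals an explicit sum of binomial
        pmf terms over Binomial(15, 9/225)."""
        n_possible, prob = 15, (3 / 15) * (3 / 15)
        res = cmp.test_overlap(2, 3, 3, 6)
        oracle = sum(
            math.comb(n_possible, k) * prob**k * (1 - prob) ** (n_possible - k)
            for k in range(2, n_possible + 1)
        )
        assert res.p == pytest.approx(oracle, rel=1e-12)
        assert res.expected_common == pytest.approx(9 / 15)

    def test_no_edges_gives_p_one(self):
        res = cmp.test_overlap(0, 0, 5, 6)
        assert res.p == pytest.approx(1.0)

    def test_study_scale_overlap_is_floored(self):
        res = cmp.test_overlap(624, 7824, 2768, 800)
        assert res.p < 2.2e-16
        assert cmp.format_p(res.p) == "<2.2e-16"
        assert res.n_union == 7824 + 2768 - 624

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cmp.test_overlap(10, 5, 20, 10)

    def test_union_identity_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            P = int(rng.integers(3, 30))
            n_possible = P * (P - 1) // 2
            n_a = int(rng.integers(0, n_possible + 1))
            n_b = int(rng.integers(0, n_possible + 1))
            common = int(rng.integers(0, min(n_a, n_b) + 1))
            res = cmp.test_overlap(common, n_a, n_b, P)
            assert res.n_union == n_a + n_b - common
            assert res.expected_common <= min(n_a, n_b) + 1e-9


def hypergeom_pmf(k, M, K, N):
    return math.comb(K, k) * math.comb(M - K, N - k) / math.comb(M, N)


class TestTermPairEnrichment:
    @staticmethod
    def annotation(mapping):
        return pd.Series(mapping, name="bin").rename_axis("protein_id")

    def test_complete_network_has_p_over_one(self):
        nodes = list("abcd")
        net = network_from_edges(nodes, itertools.combinations(nodes, 2))
        ann = self.annotation({"a": "X", "b": "X", "c": "Y", "d": "Y"})
        table = cmp.term_pair_enrichment(net, ann)
        np.testing.assert_allclose(table["p_over"], 1.0)

    def test_empty_network_has_p_under_one(self):
        net = network_from_edges(list("abcd"), [])
        ann = self.annotation({"a": "X", "b": "X", "c": "Y", "d": "Y"})
        table = cmp.term_pair_enrichment(net, ann)
        assert (table["observed"] == 0).all()
        np.testing.assert_allclose(table["p_under"], 1.0)

    def test_intra_term_tail_matches_pmf_summation(self):
        """P=6 in two terms of 3; 4 edges, 3 of them inside term A."""
        nodes = ["a1", "a2", "a3", "b1", "b2", "b3"]
        edges = [("a1", "a2"), ("a1", "a3"), ("a2", "a3"), ("b1", "b2")]
        net = network_from_edges(nodes, edges)
        ann = self.annotation({n: n[0].upper() for n in nodes})
        table = cmp.term_pair_enrichment(net, ann).set_index(["term_a", "term_b"])
        M, N, K = 15, 4, 3  # possible pairs, drawn edges, intra-A pairs
        oracle = sum(hypergeom_pmf(k, M, K, N) for k in range(3, K + 1))
        assert table.loc[("A", "A"), "observed"] == 3
        assert table.loc[("A", "A"), "p_over"] == pytest.approx(oracle, rel=1e-12)

    def test_pair_decomposition_covers_all_pairs(self):
        """When the annotation partitions the nodes, term-pair possible
        counts add up to P(P-1)/2 and every edge lands in one pair."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            P = int(rng.integers(4, 25))
            nodes = [f"n{i}" for i in range(P)]
            ann = self.annotation(
                {n: f"T{rng.integers(0, 4)}" for n in nodes}
            )
            net = random_network(rng, nodes, 0.3)
            table = cmp.term_pair_enrichment(net, ann)
            assert table["n_pairs_possible"].sum() == P * (P - 1) // 2
            assert table["observed"].sum() == net.n_edges

    def test_small_network_tails_match_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            nodes = [f"n{i}" for i in range(int(rng.integers(4, 7)))]
            net = random_network(rng, nodes, 0.4)
            ann = self.annotation({n: f"T{rng.integers(0, 2)}" for n in nodes})
            if ann.nunique() < 2:
                continue
            table = cmp.term_pair_enrichment(net, ann)
            M, N = net.n_possible, net.n_edges
            for _, row in table.iterrows():
                K, obs = int(row["n_pairs_possible"]), int(row["observed"])
                over = sum(hypergeom_pmf(k, M, K, N)
                           for k in range(obs, min(K, N) + 1))
                under = sum(hypergeom_pmf(k, M, K, N)
                            for k in range(max(0, N - (M - K)), obs + 1))
                assert row["p_over"] == pytest.approx(over, rel=1e-10, abs=1e-12)
                assert row["p_under"] == pytest.approx(under, rel=1e-10, abs=1e-12)


def yates_chi2(table):
    """Hand formula for the corrected 2x2 statistic."""
    (a, b), (c, d) = table
    n = a + b + c + d
    num = n * (max(abs(a * d - b * c) - n / 2, 0)) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def pearson_chi2(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestConnectivityChange:
    @staticmethod
    def annotation(nodes, rng, n_terms=3):
        return pd.Series({n: f"T{rng.integers(0, n_terms)}" for n in nodes},
                         name="bin").rename_axis("protein_id")

    def test_identical_networks_give_zero_statistic(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(12)]
        net = random_network(rng, nodes, 0.4, condition="WW")
        ann = self.annotation(nodes, rng)
        table = cmp.compare_term_pair_connectivity(net, net, ann)
        assert (table["chi2"] == 0).all()
        np.testing.assert_allclose(table["p"], 1.0)

    def test_statistics_match_hand_formula(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(15)]
        net_a = random_network(rng, nodes, 0.5, condition="WW")
        net_b = random_network(rng, nodes, 0.2, condition="WD")
        ann = self.annotation(nodes, rng)
        for yates in (True, False):
            table = cmp.compare_term_pair_connectivity(net_a, net_b, ann, yates=yates)
            for _, row in table.iterrows():
                t = [[row["x_A"], row["n_A"] - row["x_A"]],
                     [row["x_B"], row["n_B"] - row["x_B"]]]
                expect = yates_chi2(t) if yates else pearson_chi2(t)
                assert row["chi2"] == pytest.approx(expect, rel=1e-10, abs=1e-12)

    def test_reference_table_matches_scipy_and_hand_value(self):
        # [[10, 90], [40, 60]]: n(ad-bc)^2 / (r1 r2 c1 c2)
        #   = 200 * 3000^2 / (100 * 100 * 50 * 150) = 24.0 uncorrected
        from scipy import stats
        assert pearson_chi2([[10, 90], [40, 60]]) == pytest.approx(24.0)
        stat, _, dof, _ = stats.chi2_contingency([[10, 90], [40, 60]], correction=False)
        assert stat == pytest.approx(24.0) and dof == 1
        stat_y, _, _, _ = stats.chi2_contingency([[10, 90], [40, 60]], correction=True)
        assert stat_y == pytest.approx(yates_chi2([[10, 90], [40, 60]]))

    def test_zero_margin_pairs_skipped(self):
        nodes = ["a1", "a2", "b1", "b2", "c1", "c2"]
        ann = pd.Series({n: n[0].upper() for n in nodes}, name="bin").rename_axis("protein_id")
        net_a = network_from_edges(nodes, [("a1", "a2"), ("a1", "b1")], condition="WW")
        net_b = network_from_edges(nodes, [("a1", "a2"), ("b1", "b2")], condition="WD")
        table = cmp.compare_term_pair_connectivity(net_a, net_b, ann)
        # every pair involving term C has zero edges in both networks
        pairs = set(zip(table["term_a"], table["term_b"]))
        assert not any("C" in p for p in pairs)
        assert len(table.attrs["skipped"]) == 3


class TestDepBookkeeping:
    def test_edge_classification_by_endpoint_count(self):
        net = network_from_edges(list("abc"), [("a", "b"), ("a", "c"), ("b", "c")])
        assert cmp.classify_edges_by_dep(net, {"a", "b"}) == (0, 2, 1)
        assert cmp.classify_edges_by_dep(net, set()) == (3, 0, 0)
        assert cmp.classify_edges_by_dep(net, {"a"}) == (1, 2, 0)

    def test_dep_outside_universe_rejected(self):
        net = network_from_edges(list("ab"), [("a", "b")])
        with pytest.raises(ValueError, match="outside"):
            cmp.classify_edges_by_dep(net, {"z"})

    def test_union_row_from_study_counts(self):
        """The union row follows from per-network and common class
        counts by inclusion-exclusion."""
        table = cmp.dep_breakdown_table(
            counts_A=(1584, 3837, 2403),
            counts_B=(638, 1341, 789),
            counts_common=(188, 289, 147),
        )
        union = table.loc["union"]
        assert list(union[["no_dep", "one_dep", "two_dep"]]) == [2034, 4889, 3045]
        assert union["total"] == 9968
        assert table.loc["WW network", "total"] == 7824
        assert table.loc["WD network", "total"] == 2768
        assert table.loc["common (WW and WD)", "total"] == 624

    def test_disjoint_edge_sets_union_is_sum(self):
        nodes = list("abcd")
        net_a = network_from_edges(nodes, [("a", "b")], condition="WW")
        net_b = network_from_edges(nodes, [("c", "d")], condition="WD")
        table = cmp.edge_set_algebra(net_a, net_b, {"a"})
        assert table.loc["union", "total"] == 2
        assert table.loc["common (WW and WD)", "total"] == 0

    def test_identical_edge_sets_union_equals_either(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(10)]
        net = random_network(rng, nodes, 0.4, condition="WW")
        twin = network_from_edges(nodes, net.edge_set(), condition="WD")
        table = cmp.edge_set_algebra(net, twin, {"n0", "n1"})
        assert (table.loc["union"] == table.loc["WW network"]).all()
        assert (table.loc["common (WW and WD)"] == table.loc["WW network"]).all()

    def test_union_identity_for_random_partitions(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            nodes = [f"n{i}" for i in range(int(rng.integers(5, 15)))]
            net_a = random_network(rng, nodes, 0.5, condition="A")
            net_b = random_network(rng, nodes, 0.5, condition="B")
            dep = {n for n in nodes if rng.random() < 0.4}
            table = cmp.edge_set_algebra(net_a, net_b, dep)
            for cls in ("no_dep", "one_dep", "two_dep"):
                assert (table.loc["union", cls]
                        == table.loc["A network", cls] + table.loc["B network", cls]
                        - table.loc[f"common (A and B)", cls])
            assert table.loc["A network", "total"] == net_a.n_edges
            assert table.loc["B network", "total"] == net_b.n_edges


class TestNodeDegreeDelta:
    def test_identical_networks_have_no_rewiring(self):
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(8)]
        net = random_network(rng, nodes, 0.4)
        delta = cmp.node_degree_delta(net, net)
        assert (delta["n_lost"] == 0).all()
        assert (delta["n_gained"] == 0).all()

    def test_hub_losing_all_edges_to_one_process(self):
        """A hub connected to 31 partners of one process in A and none
        in B loses 31 edges, all to that process."""
        partners = [f"t{i}" for i in range(31)]
        nodes = ["hub"] + partners
        net_a = network_from_edges(nodes, [("hub", p) for p in partners], condition="WW")
        net_b = network_from_edges(nodes, [], condition="WD")
        ann = pd.Series({"hub": "RNA processing", **{p: "Protein biosynthesis" for p in partners}},
                        name="bin").rename_axis("protein_id")
        delta = cmp.node_degree_delta(net_a, net_b, ann).set_index("protein_id")
        assert delta.loc["hub", "n_lost"] == 31
        assert delta.loc["hub", "lost_partners"] == "Protein biosynthesis:31"
        assert delta.loc["hub", "n_gained"] == 0
        # the hub tops the rewiring ordering
        assert cmp.node_degree_delta(net_a, net_b, ann)["protein_id"].iloc[0] == "hub"

    def test_handshake_identity_for_losses_and_gains(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(12)]
        net_a = random_network(rng, nodes, 0.5)
        net_b = random_network(rng, nodes, 0.5)
        delta = cmp.node_degree_delta(net_a, net_b)
        lost = net_a.edge_set() - net_b.edge_set()
        gained = net_b.edge_set() - net_a.edge_set()
        assert delta["n_lost"].sum() == 2 * len(lost)
        assert delta["n_gained"].sum() == 2 * len(gained)
        assert (delta["degree_A"] - delta["degree_B"]
                == delta["n_lost"] - delta["n_gained"]).all()
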