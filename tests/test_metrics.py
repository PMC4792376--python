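"""Contact-network construction and the weighted-network statistics."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

import schoolnet as sn
from schoolnet.ingest import Contact, Encounter


def contact(a, b, minutes):
    recordings = int(round(minutes * 3))
    return Contact((a, b), recordings, minutes, 1)


class TestBuildNetwork:
    def test_threshold_is_strict(self, small_roster):
        contacts = [
            contact("n00", "n01", 4.9),
            contact("n00", "n02", 5.0),
            contact("n01", "n02", 5.1),
        ]
        net = sn.build_network(contacts, small_roster, 5.0)
        assert set(net.edges) == {("n01", "n02")}
        assert set(net.nodes) == {"n01", "n02"}

    def test_zero_threshold_keeps_all_positive_contacts(self, small_roster):
        contacts = [contact("n00", "n01", 0.5), contact("n01", "n02", 9.0)]
        net = sn.build_network(contacts, small_roster, 0.0)
        assert net.number_of_edges() == 2

    def test_unknown_id_raises(self, small_roster):
        with pytest.raises(sn.ConsistencyError):
            sn.build_network([contact("n00", "zz", 9.0)], small_roster)

    def test_staff_and_stationary_edges_are_excluded(self, small_roster):
        contacts = [contact("n00", "staff0", 30.0),
                    contact("n01", "x00", 30.0),
                    contact("n00", "n01", 30.0)]
        net = sn.build_network(contacts, small_roster)
        assert set(net.edges) == {("n00", "n01")}

    def test_node_attributes_come_from_roster(self, small_roster):
        net = sn.build_network([contact("n00", "n07", 10.0)], small_roster)
        assert net.nodes["n00"]["grade"] == "G1"
        assert net.nodes["n07"]["grade"] == "G2"


class TestDensity:
    def test_complete_graph_has_density_one(self):
        assert sn.density(nx.complete_graph(4)) == pytest.approx(1.0)

    def test_formula_on_reported_scale(self):
        # arithmetic check of δ = 2m/(n(n−1)) at n=141, m=1946
        g = nx.gnm_random_graph(141, 1946, seed=0)
        assert sn.density(g) == pytest.approx(2 * 1946 / (141 * 140))

    def test_undefined_below_two_nodes(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(sn.UndefinedError):
            sn.density(g)


class TestDegreeStrength:
    def test_star_center(self):
        g = nx.Graph()
        for node, w in (("b", 10), ("c", 20), ("d", 30)):
            g.add_edge("a", node, weight=w)
        df = sn.degree_and_strength(g)
        assert df.loc["a", "degree"] == 3
        assert df.loc["a", "strength"] == 60
        assert df.loc["a", "mean_duration"] == pytest.approx(20)

    def test_degree_sum_and_strength_sum_identities(self, cohort_run):
        net = cohort_run.net
        df = sn.degree_and_strength(net)
        assert df["degree"].sum() == 2 * net.number_of_edges()
        total_w = sum(w for _, _, w in net.edges(data="weight"))
        assert df["strength"].sum() == pytest.approx(2 * total_w)


class TestClustering:
    def test_triangle_and_star(self):
        tri = nx.complete_graph(3)
        cc, avg = sn.clustering_coefficient(tri)
        assert avg == pytest.approx(1.0) and all(v == 1.0 for v in cc.values())
        star = nx.star_graph(4)
        _, avg_star = sn.clustering_coefficient(star)
        assert avg_star == pytest.approx(0.0)


class TestOverlap:
    def test_triangle_edge_has_full_overlap(self):
        assert sn.overlap(nx.complete_graph(3), 0, 1) == pytest.approx(1.0)

    def test_pendant_edge_defined_zero(self):
        g = nx.Graph([("a", "b")])
        assert sn.overlap(g, "a", "b") == 0.0

    def test_shared_cliques_with_private_neighbors(self):
        # four common contacts plus one private contact each:
        # k_i = k_j = 6, n_ij = 4 → O = 4 / (5 + 5 − 4) = 2/3
        g = nx.Graph()
        for c in ("c1", "c2", "c3", "c4"):
            g.add_edge("i", c)
            g.add_edge("j", c)
        g.add_edge("i", "j")
        g.add_edge("i", "u")
        g.add_edge("j", "v")
        assert g.degree("i") == g.degree("j") == 6
        assert sn.overlap(g, "i", "j") == pytest.approx(2 / 3)

    def test_clique_sharing_an_edge_has_full_overlap(self):
        # when every other neighbor is common, the ratio collapses to 1
        g = nx.Graph()
        for pair in itertools.combinations(["i", "j", "a", "b"], 2):
            g.add_edge(*pair)
        assert sn.overlap(g, "i", "j") == pytest.approx(1.0)

    def test_non_edge_raises(self):
        g = nx.path_graph(3)
        with pytest.raises(sn.UndefinedError):
            sn.overlap(g, 0, 2)

    def test_brute_force_neighbor_intersection_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1 << 30)))
            for i, j in g.edges:
                common = sum(
                    1
                    for v in g.nodes
                    if v not in (i, j) and g.has_edge(i, v) and g.has_edge(j, v)
                )
                denom = g.degree(i) - 1 + g.degree(j) - 1 - common
                expected = common / denom if denom else 0.0
                assert sn.overlap(g, i, j) == pytest.approx(expected)


class TestOverlapCurve:
    def test_single_bin_equals_global_mean(self):
        g = nx.complete_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        curve = sn.overlap_vs_weight_curve(g, [0.0, 2.0])
        mean_overlap = np.mean([sn.overlap(g, u, v) for u, v in g.edges])
        assert curve.mean_overlap.iloc[0] == pytest.approx(mean_overlap)

    def test_cohort_school_overlap_rises_with_weight(self, cohort_run):
        """Long-duration contacts sit in clique-like classroom cores, so mean
        overlap trends upward with weight over the upper half of the range."""
        net = cohort_run.net
        w = [d for _, _, d in net.edges(data="weight")]
        bins = np.linspace(min(w), max(w) + 1e-9, 11)
        curve = sn.overlap_vs_weight_curve(net, bins)
        upper = curve.mean_overlap.to_numpy()[5:]
        upper = upper[~np.isnan(upper)]
        slope = np.polyfit(np.arange(len(upper)), upper, 1)[0]
        assert slope >= 0
        assert upper[-1] > curve.mean_overlap.iloc[0]

    def test_empty_bins_are_flagged(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        curve = sn.overlap_vs_weight_curve(g, [0.0, 2.0, 4.0])
        assert not curve.is_empty.iloc[0]
        assert curve.is_empty.iloc[1]


class TestContactMatrix:
    def _net(self, edges, groups):
        g = nx.Graph()
        g.add_edges_from(edges)
        for n, grp in groups.items():
            g.add_node(n, grade=grp)
        return g

    def test_no_cross_edges_gives_zero_off_diagonal(self):
        g = self._net(
            [("a", "b"), ("c", "d")],
            {"a": "G1", "b": "G1", "c": "G2", "d": "G2"},
        )
        m = sn.contact_matrix(g, "grade")
        assert m.loc["G1", "G2"] == 0.0 and m.loc["G2", "G1"] == 0.0

    def test_complete_group_diagonal_is_one(self):
        g = self._net(
            [("a", "b"), ("a", "c"), ("b", "c")],
            {"a": "G1", "b": "G1", "c": "G1"},
        )
        assert sn.contact_matrix(g, "grade").loc["G1", "G1"] == pytest.approx(1)

    def test_unlabeled_node_raises(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(sn.ConsistencyError):
            sn.contact_matrix(g, "grade")

    def test_cohort_school_diagonal_dominates_rows(self, cohort_run):
        m = sn.contact_matrix(cohort_run.net, "grade")
        vals = m.to_numpy()
        for i in range(vals.shape[0]):
            off = np.delete(vals[i], i)
            assert vals[i, i] > off.max()

    def test_cell_counts_reconstruct_edge_total(self, cohort_run):
        net = cohort_run.net
        m = sn.contact_matrix(net, "grade")
        sizes = {}
        for _, d in net.nodes(data=True):
            sizes[d["grade"]] = sizes.get(d["grade"], 0) + 1
        total = 0.0
        groups = list(m.index)
        for gi, g in enumerate(groups):
            for h in groups[gi:]:
                pairs = (
                    sizes[g] * (sizes[g] - 1) / 2
                    if g == h
                    else sizes[g] * sizes[h]
                )
                total += m.loc[g, h] * pairs
        assert total == pytest.approx(net.number_of_edges())


class TestTimeBinnedDegree:
    def test_constant_pair_has_degree_one_everywhere(self):
        encs = [Encounter(("a", "b"), 0, 26, 27, 20)]  # 9 min continuous
        series = sn.time_binned_degree(encs, bin_seconds=180, tick_seconds=20)
        assert len(series) == 3
        assert np.allclose(series.to_numpy(), 1.0)

    def test_empty_bin_has_zero_mean_degree(self):
        encs = [
            Encounter(("a", "b"), 0, 2, 3, 20),
            Encounter(("a", "b"), 27, 29, 3, 20),  # bins 0 and 3, 1–2 empty
        ]
        series = sn.time_binned_degree(encs, 180, 20)
        assert series.iloc[1] == 0.0 and series.iloc[2] == 0.0

    def test_break_bins_busier_than_class_bins_in_high_school(
        self, individualized_run
    ):
        run = individualized_run
        series = sn.time_binned_degree(
            run.encounters,
            tick_seconds=run.config.tick_seconds,
            students=set(run.result.roster.student_ids()),
        )
        by_kind: dict[str, list[float]] = {"class": [], "break": []}
        for sec, v in series.items():
            for p in run.config.resolved_periods():
                if p.start <= sec < p.end and p.kind in by_kind:
                    by_kind[p.kind].append(v)
        assert np.mean(by_kind["break"]) > np.mean(by_kind["class"])


def test_small_graph_metrics_match_brute_force():
    """Density, clustering and degree on all-pairs enumeration for ≤8 nodes."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
        if g.number_of_nodes() < 2:
            continue
        pairs = n * (n - 1) / 2
        assert sn.density(g) == pytest.approx(g.number_of_edges() / pairs)
        cc, avg = sn.clustering_coefficient(g)
        brute = {}
        for v in g.nodes:
            nbrs = list(g.neighbors(v))
            k = len(nbrs)
            if k < 2:
                brute[v] = 0.0
                continue
            links = sum(
                1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
            )
            brute[v] = 2 * links / (k * (k - 1))
        for v in g.nodes:
            assert cc[v] == pytest.approx(brute[v])
        assert avg == pytest.approx(np.mean(list(brute.values())))


def test_summary_bounds_and_schema(cohort_run):
    summary = sn.summarize(cohort_run.net)
    assert 0 <= summary.density <= 1
    assert 0 <= summary.clustering_mean <= 1
    assert summary.degree_mean <= summary.n - 1
    row = summary.as_row()
    assert list(row) == ["n", "delta", "d", "d_sd", "d_se", "s", "s_sd",
                         "s_se", "CC", "CC_sd", "CC_se"]
    assert row["d_se"] == pytest.approx(row["d_sd"] / np.sqrt(row["n"]))
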