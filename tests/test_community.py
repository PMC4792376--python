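"""Weighted modularity against external partitions and threshold sweeps."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

import schoolnet as sn
from schoolnet.ingest import Contact


def part(mapping, level="custom"):
    return sn.Partition(dict(mapping), level)


def brute_force_modularity(net, mapping, weighted=True):
    """Direct evaluation of Q = (1/2W) Σ_ij (w_ij − s_i s_j / 2W) δ(c_i, c_j)
    over every ordered node pair."""
    nodes = list(net.nodes)
    w = {(u, v): 0.0 for u in nodes for v in nodes}
    for u, v, data in net.edges(data=True):
        wt = float(data.get("weight", 1.0)) if weighted else 1.0
        w[(u, v)] += wt
        w[(v, u)] += wt
    s = {u: sum(w[(u, v)] for v in nodes) for u in nodes}
    two_w = sum(s.values())
    q = 0.0
    for u in nodes:
        for v in nodes:
            if mapping[u] == mapping[v]:
                q += w[(u, v)] - s[u] * s[v] / two_w
    return q / two_w


class TestModularity:
    def test_single_community_is_zero(self):
        g = nx.gnp_random_graph(10, 0.4, seed=1)
        nx.set_edge_attributes(g, 2.5, "weight")
        q = sn.modularity(g, part({n: "all" for n in g.nodes}))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_give_half(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        mapping = {n: ("a" if n < 4 else "b") for n in g.nodes}
        q = sn.modularity(g, part(mapping), weighted=False)
        assert q == pytest.approx(0.5)

    def test_empty_network_raises(self):
        with pytest.raises(sn.UndefinedError):
            sn.modularity(nx.Graph(), part({}))

    def test_uncovered_node_raises(self):
        g = nx.path_graph(3)
        with pytest.raises(sn.ConsistencyError):
            sn.modularity(g, part({0: "a", 1: "a"}))

    def test_equal_weights_match_unweighted(self):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        nx.set_edge_attributes(g, 7.0, "weight")
        mapping = {n: n % 3 for n in g.nodes}
        qw = sn.modularity(g, part(mapping), weighted=True)
        qb = sn.modularity(g, part(mapping), weighted=False)
        assert qw == pytest.approx(qb, abs=1e-12)

    def test_matches_brute_force_on_small_graphs(self):
        """Oracle: exhaustive evaluation of the defining sum, ≤ 8 nodes,
        random weights and random partitions."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.5, 10))
            mapping = {v: int(rng.integers(0, 3)) for v in g.nodes}
            q = sn.modularity(g, part(mapping))
            assert q == pytest.approx(
                brute_force_modularity(g, mapping), abs=1e-12
            )

    def test_matches_networkx_weighted_modularity(self):
        """Independent cross-check against the networkx implementation."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.5, 10))
            mapping = {v: int(rng.integers(0, 4)) for v in g.nodes}
            communities = [
                {v for v in g.nodes if mapping[v] == c} for c in range(4)
            ]
            communities = [c for c in communities if c]
            expected = nx.community.modularity(g, communities, weight="weight")
            assert sn.modularity(g, part(mapping)) == pytest.approx(expected)

    def test_q_bounded(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            mapping = {v: int(rng.integers(0, 4)) for v in g.nodes}
            q = sn.modularity(g, part(mapping), weighted=False)
            assert -0.5 <= q < 1


def _two_block_contacts():
    """12-node planted two-block weighted contact list: every inter-block
    weight strictly below every intra-block weight."""
    roster_entries = [
        sn.RosterEntry(f"n{i:02d}", "G1" if i < 6 else "G2",
                       "G1C1" if i < 6 else "G2C1", "student")
        for i in range(12)
    ]
    roster = sn.Roster(tuple(roster_entries))
    contacts = []
    for block in (range(0, 6), range(6, 12)):
        for a, b in itertools.combinations(block, 2):
            recordings = 60 + (a + b) % 5 * 10  # intra: 60..100 recordings
            contacts.append(
                Contact((f"n{a:02d}", f"n{b:02d}"), recordings,
                        recordings / 3, 1)
            )
    for a in range(0, 6):
        b = a + 6
        recordings = 10 + a  # inter: 10..15 recordings, all below intra
        contacts.append(
            Contact((f"n{a:02d}", f"n{b:02d}"), recordings, recordings / 3, 1)
        )
    return contacts, roster


class TestModularityVsThreshold:
    def test_threshold_zero_matches_unthresholded_network(self, cohort_run):
        curve = sn.modularity_vs_threshold(
            cohort_run.contacts, cohort_run.result.roster, "grade"
        )
        net0 = sn.build_network(
            cohort_run.contacts, cohort_run.result.roster,
            threshold_recordings=0,
        )
        p0 = sn.Partition.from_roster(
            cohort_run.result.roster, "grade"
        ).restricted_to(net0.nodes)
        assert curve.thresholds_recordings[0] == 0
        assert curve.q[0] == pytest.approx(sn.modularity(net0, p0))

    def test_planted_two_block_q_non_decreasing_under_inter_block_pruning(self):
        """While only inter-block edges are being removed, Q never drops;
        verified against brute-force evaluation at every step."""
        contacts, roster = _two_block_contacts()
        curve = sn.modularity_vs_threshold(
            contacts, roster, "grade", step_recordings=5, max_threshold=55
        )
        # all thresholds < 60 only ever remove inter-block contacts
        assert all(t < 60 for t in curve.thresholds_recordings)
        qs = np.array(curve.q)
        assert np.all(np.diff(qs) >= -1e-12)
        for t, q in zip(curve.thresholds_recordings, curve.q):
            net = sn.build_network(contacts, roster, threshold_recordings=t)
            mapping = {n: net.nodes[n]["grade"] for n in net.nodes}
            assert q == pytest.approx(brute_force_modularity(net, mapping))

    def test_cohort_school_curve_rises_then_declines(self, cohort_run):
        """Deleting weak inter-classroom links first raises Q; once the
        threshold eats into intra-classroom contacts Q falls back."""
        curve = sn.modularity_vs_threshold(
            cohort_run.contacts, cohort_run.result.roster, "grade"
        )
        q = np.array(curve.q)
        rel = np.array(curve.reliable)
        peak = np.nanmax(q[rel])
        assert peak > q[0]
        last_reliable = q[rel][-1]
        assert last_reliable < peak

    def test_unreliable_points_are_flagged(self):
        contacts, roster = _two_block_contacts()
        curve = sn.modularity_vs_threshold(
            contacts, roster, "grade", step_recordings=20
        )
        # beyond the largest intra-block weight nothing survives
        assert not curve.reliable[-1]


class TestPlantedStructureContrast:
    def test_cohort_vs_individualized_grade_modularity(
        self, cohort_run, individualized_run
    ):
        """Fixed cohort schedules produce strongly grade-assortative networks;
        free individualized schedules do not (mirroring the elementary vs
        high-school contrast)."""
        pg_c = sn.Partition.from_roster(
            cohort_run.result.roster, "grade"
        ).restricted_to(cohort_run.net.nodes)
        q_cohort = sn.modularity(cohort_run.net, pg_c)
        pg_i = sn.Partition.from_roster(
            individualized_run.result.roster, "grade"
        ).restricted_to(individualized_run.net.nodes)
        q_indiv = sn.modularity(individualized_run.net, pg_i)
        assert q_cohort >= 0.5
        assert q_indiv <= 0.3
        assert q_cohort - q_indiv >= 0.2
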