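"""Weighted contact-network construction and descriptive statistics.

The contact network is an undirected graph on tagged students; the weight of
an edge is the pair's cumulative contact time in minutes over the deployment
day.  Contacts with small total duration (≤ 5 minutes by default) are dropped
before computing statistics, since many network measures are very sensitive to
the large number of short-duration contacts.

Statistics follow the standard weighted-network vocabulary: degree k_i (number
of contacts), strength (total contact minutes), density δ = 2m / (n(n−1)),
binary local clustering CC_i, and the edge overlap ratio
O_ij = n_ij / (k_i − 1 + k_j − 1 − n_ij) where n_ij counts common contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConsistencyError, UndefinedError
from .ingest import Contact, Encounter
from .synthetic import Roster

__all__ = [
    "NetworkSummary",
    "build_network",
    "density",
    "degree_and_strength",
    "clustering_coefficient",
    "overlap",
    "overlap_vs_weight_curve",
    "contact_matrix",
    "time_binned_degree",
    "summarize",
    "DEFAULT_CONTACT_THRESHOLD_MINUTES",
]

DEFAULT_CONTACT_THRESHOLD_MINUTES = 5.0


def build_network(
    contacts: Sequence[Contact],
    roster: Roster,
    threshold_minutes: float = DEFAULT_CONTACT_THRESHOLD_MINUTES,
    threshold_recordings: int | None = None,
) -> nx.Graph:
    """Student contact network keeping edges strictly above the threshold.

    The comparison is strict (weight > threshold survives): "contacts with
    total duration less than 5 minutes are ignored" leaves ties at exactly
    5.0 minutes ambiguous, and with 20-second ticks the tie occurs (15
    recordings); dropping ties gives clean semantics under threshold sweeps.
    Nodes are the students left with at least one surviving edge.  A
    recording-count threshold can be given instead of minutes (used by the
    modularity sweep).
    """
    if threshold_minutes < 0:
        raise ValueError("threshold_minutes must be >= 0")
    entries = roster.by_id()
    g = nx.Graph()
    for c in contacts:
        a, b = c.pair
        for nid in (a, b):
            if nid not in entries:
                raise ConsistencyError(f"contact references unknown id {nid!r}")
        if entries[a].role != "student" or entries[b].role != "student":
            continue
        if threshold_recordings is not None:
            if not c.total_recordings > threshold_recordings:
                continue
        elif not c.cumulative_minutes > threshold_minutes:
            continue
        g.add_edge(
            a,
            b,
            weight=c.cumulative_minutes,
            recordings=c.total_recordings,
            encounters=c.n_encounters,
        )
    for nid in g.nodes:
        e = entries[nid]
        g.nodes[nid].update(grade=e.grade, classroom=e.classroom, role=e.role)
    return g


def density(net: nx.Graph) -> float:
    """δ = 2m / (n(n−1)): contacts present over contacts possible."""
    n = net.number_of_nodes()
    if n < 2:
        raise UndefinedError("density undefined for networks with n < 2")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def degree_and_strength(net: nx.Graph) -> pd.DataFrame:
    """Per-student degree, strength, and mean minutes per contact.

    Degree is the number of distinct contacts; strength the total contact
    minutes; their ratio is the student's average duration per contact.
    """
    rows = []
    for node in net.nodes:
        k = net.degree(node)
        s = sum(d["weight"] for _, _, d in net.edges(node, data=True))
        rows.append((node, k, s, s / k if k else float("nan")))
    return pd.DataFrame(
        rows, columns=["node_id", "degree", "strength", "mean_duration"]
    ).set_index("node_id")


def clustering_coefficient(net: nx.Graph) -> tuple[dict[str, float], float]:
    """Binary local clustering per node and its average over nodes.

    Computed on the thresholded graph ignoring weights; CC_i = 0 for nodes of
    degree < 2.
    """
    cc = nx.clustering(net)  # unweighted
    avg = float(np.mean(list(cc.values()))) if cc else float("nan")
    return cc, avg


def overlap(net: nx.Graph, i: str, j: str) -> float:
    """Overlap ratio O_ij of the edge (i, j).

    O_ij = n_ij / (k_i − 1 + k_j − 1 − n_ij) with n_ij the number of common
    contacts; defined as 0 for a pendant pair (denominator 0).
    """
    if not net.has_edge(i, j):
        raise UndefinedError(f"({i!r}, {j!r}) is not an edge")
    ni = set(net.neighbors(i))
    nj = set(net.neighbors(j))
    n_ij = len((ni & nj) - {i, j})
    denom = net.degree(i) - 1 + net.degree(j) - 1 - n_ij
    return n_ij / denom if denom > 0 else 0.0


def overlap_vs_weight_curve(
    net: nx.Graph, weight_bins: Sequence[float]
) -> pd.DataFrame:
    """Mean edge overlap ratio per contact-duration (weight) bin.

    ``weight_bins`` are bin edges; each edge falls in the bin containing its
    weight (right-closed last bin).  Empty bins are kept and flagged.
    """
    edges = list(net.edges(data="weight"))
    bins = np.asarray(weight_bins, dtype=float)
    if len(bins) < 2:
        raise ValueError("need at least two bin edges")
    weights = np.array([w for _, _, w in edges], dtype=float)
    if len(weights) and (
        weights.min() < bins[0] or weights.max() > bins[-1]
    ):
        raise ValueError("weight_bins do not cover observed edge weights")
    ov = np.array([overlap(net, u, v) for u, v, _ in edges])
    idx = np.clip(np.digitize(weights, bins) - 1, 0, len(bins) - 2)
    rows = []
    for b in range(len(bins) - 1):
        mask = idx == b
        n = int(mask.sum())
        rows.append(
            (
                bins[b],
                bins[b + 1],
                float(ov[mask].mean()) if n else float("nan"),
                n,
                n == 0,
            )
        )
    return pd.DataFrame(
        rows, columns=["bin_left", "bin_right", "mean_overlap", "n_edges", "is_empty"]
    )


def contact_matrix(
    net: nx.Graph, grouping: Literal["grade", "classroom"] = "grade"
) -> pd.DataFrame:
    """Mixing matrix: contacts between groups per pair of students.

    M[g, h] = (#edges between g and h) / (n_g · n_h) for g ≠ h and
    M[g, g] = (#edges within g) / (n_g (n_g − 1) / 2); symmetric.
    """
    labels = {}
    for node, data in net.nodes(data=True):
        if grouping not in data:
            raise ConsistencyError(f"node {node!r} lacks a {grouping} label")
        labels[node] = data[grouping]
    groups = sorted(set(labels.values()))
    sizes = {g: sum(1 for v in labels.values() if v == g) for g in groups}
    counts = pd.DataFrame(0.0, index=groups, columns=groups)
    for u, v in net.edges:
        gu, gv = labels[u], labels[v]
        counts.loc[gu, gv] += 1
        if gu != gv:
            counts.loc[gv, gu] += 1
    for g in groups:
        for h in groups:
            if g == h:
                pairs = sizes[g] * (sizes[g] - 1) / 2
            else:
                pairs = sizes[g] * sizes[h]
            counts.loc[g, h] = counts.loc[g, h] / pairs if pairs else float("nan")
    return counts


def time_binned_degree(
    encounters: Sequence[Encounter],
    bin_seconds: int = 180,
    tick_seconds: int = 20,
    students: Iterable[str] | None = None,
    t0: int | None = None,
) -> pd.Series:
    """Mean number of distinct contacts per student in fixed time bins.

    For each bin (default 3 minutes), a student's bin-degree is the number of
    distinct partners with at least one pair-tick in the bin; the series
    averages over all tagged students (``students``; defaults to everyone seen
    in the encounter list).  Bins are indexed from ``t0`` (default: the first
    encounter's start, floored to a bin boundary).
    """
    if bin_seconds <= 0 or bin_seconds % tick_seconds:
        raise ValueError("bin must be a positive multiple of tick_seconds")
    ticks_per_bin = bin_seconds // tick_seconds
    if students is None:
        students = {n for e in encounters for n in e.pair}
    students = sorted(set(students))
    if not encounters or not students:
        return pd.Series(dtype=float, name="mean_degree")
    start_tick = min(e.start_tick for e in encounters)
    if t0 is not None:
        start_tick = t0 // tick_seconds
    end_tick = max(e.start_tick + e.n_ticks for e in encounters)
    first_bin = start_tick // ticks_per_bin
    last_bin = (end_tick - 1) // ticks_per_bin
    partners: dict[int, set[tuple[str, str]]] = {
        b: set() for b in range(first_bin, last_bin + 1)
    }
    student_set = set(students)
    for e in encounters:
        a, b = e.pair
        if a not in student_set or b not in student_set:
            continue
        for t in range(e.start_tick, e.start_tick + e.n_ticks):
            partners[t // ticks_per_bin].add((a, b))
    out = {}
    n = len(students)
    for b in range(first_bin, last_bin + 1):
        deg = 2 * len(partners[b]) / n  # each pair grants both students one
        out[b * bin_seconds] = deg
    return pd.Series(out, name="mean_degree")


@dataclass(frozen=True)
class NetworkSummary:
    """The per-school summary row: n, δ, and mean ± sd (se) of degree,
    per-contact duration (minutes) and clustering over students."""

    n: int
    density: float
    degree_mean: float
    degree_sd: float
    degree_se: float
    duration_mean: float
    duration_sd: float
    duration_se: float
    clustering_mean: float
    clustering_sd: float
    clustering_se: float
    strength_mean: float
    strength_sd: float

    def as_row(self) -> dict[str, float]:
        return {
            "n": self.n,
            "delta": self.density,
            "d": self.degree_mean,
            "d_sd": self.degree_sd,
            "d_se": self.degree_se,
            "s": self.duration_mean,
            "s_sd": self.duration_sd,
            "s_se": self.duration_se,
            "CC": self.clustering_mean,
            "CC_sd": self.clustering_sd,
            "CC_se": self.clustering_se,
        }


def _mss(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd, sd / math.sqrt(len(values))


def summarize(net: nx.Graph) -> NetworkSummary:
    """Aggregate the per-student statistics into one summary row.

    The duration column is the across-student mean of each student's mean
    minutes per contact (strength / degree), not the total strength; total
    strength statistics are carried alongside.
    """
    if net.number_of_nodes() < 2:
        raise UndefinedError("summary undefined for networks with n < 2")
    df = degree_and_strength(net)
    cc_map, _ = clustering_coefficient(net)
    cc = np.array(list(cc_map.values()), dtype=float)
    d_m, d_sd, d_se = _mss(df["degree"].to_numpy(dtype=float))
    s_m, s_sd, s_se = _mss(df["mean_duration"].to_numpy(dtype=float))
    c_m, c_sd, c_se = _mss(cc)
    st_m, st_sd, _ = _mss(df["strength"].to_numpy(dtype=float))
    return NetworkSummary(
        n=net.number_of_nodes(),
        density=density(net),
        degree_mean=d_m,
        degree_sd=d_sd,
        degree_se=d_se,
        duration_mean=s_m,
        duration_sd=s_sd,
        duration_se=s_se,
        clustering_mean=c_m,
        clustering_sd=c_sd,
        clustering_se=c_se,
        strength_mean=st_m,
        strength_sd=st_sd,
    )
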