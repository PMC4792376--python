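"""Modularity of a contact network against an externally given partition.

The partition (grade or classroom membership) comes from the roster, never
from community detection: the question is how well the observed contact
structure lines up with the school's organisational divisions.

Weighted Newman–Girvan modularity:

    Q = (1 / 2W) Σ_ij (w_ij − s_i s_j / 2W) 𝟙[c_i = c_j]

with s_i the strength of node i and W the total edge weight; on a binarized
network this reduces to the familiar unweighted form.  Q compares the weight
actually inside communities with the weight expected if edges were placed at
random preserving strengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx

from .errors import ConsistencyError, UndefinedError
from .ingest import Contact
from .metrics import build_network
from .synthetic import Roster

__all__ = ["Partition", "ModularityCurve", "modularity", "modularity_vs_threshold"]


@dataclass(frozen=True)
class Partition:
    """Node → community label, externally specified (never inferred)."""

    mapping: dict[str, str]
    level: Literal["grade", "classroom", "custom"] = "custom"

    @classmethod
    def from_roster(
        cls, roster: Roster, level: Literal["grade", "classroom"]
    ) -> "Partition":
        return cls(roster.labels(level), level)

    def restricted_to(self, nodes) -> "Partition":
        return Partition(
            {n: self.mapping[n] for n in nodes if n in self.mapping}, self.level
        )

    def n_communities(self) -> int:
        return len(set(self.mapping.values()))


def modularity(
    net: nx.Graph, partition: Partition, weighted: bool = True
) -> float:
    """Newman–Girvan modularity of ``net`` against ``partition``.

    ``weighted=False`` binarizes the (already thresholded) network first.
    Raises if the network has no edges or the partition misses a node.
    """
    if net.number_of_edges() == 0:
        raise UndefinedError("modularity undefined for an empty network")
    missing = [n for n in net.nodes if n not in partition.mapping]
    if missing:
        raise ConsistencyError(
            f"partition does not cover nodes {missing[:5]!r}..."
            if len(missing) > 5
            else f"partition does not cover nodes {missing!r}"
        )
    strength: dict[str, float] = {n: 0.0 for n in net.nodes}
    two_w = 0.0
    w_in: dict[str, float] = {}
    for u, v, data in net.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        strength[u] += w
        strength[v] += w
        two_w += 2.0 * w
        cu, cv = partition.mapping[u], partition.mapping[v]
        if cu == cv:
            w_in[cu] = w_in.get(cu, 0.0) + w
    s_c: dict[str, float] = {}
    for n, s in strength.items():
        c = partition.mapping[n]
        s_c[c] = s_c.get(c, 0.0) + s
    q = 0.0
    for c, s in s_c.items():
        q += 2.0 * w_in.get(c, 0.0) / two_w - (s / two_w) ** 2
    return q


@dataclass(frozen=True)
class ModularityCurve:
    """Modularity as a function of the contact-duration threshold.

    Thresholds are in recordings (ticks); ``thresholds_minutes`` is the same
    axis divided by 3 for 20-second ticks.  Points where fewer than two
    communities survive, or no edges do, are flagged unreliable (the score is
    reported but should not be interpreted).
    """

    thresholds_recordings: tuple[int, ...]
    thresholds_minutes: tuple[float, ...]
    q: tuple[float, ...]
    n_nodes: tuple[int, ...]
    n_edges: tuple[int, ...]
    reliable: tuple[bool, ...]

    def __post_init__(self) -> None:
        t = self.thresholds_recordings
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")


def modularity_vs_threshold(
    contacts: Sequence[Contact],
    roster: Roster,
    level: Literal["grade", "classroom"],
    step_recordings: int = 10,
    max_threshold: int | None = None,
    weighted: bool = True,
    tick_seconds: int = 20,
) -> ModularityCurve:
    """Sweep the contact threshold and recompute modularity at each step.

    At threshold t the network keeps contacts with total_recordings > t (so
    t = 0 is the unthresholded network); students isolated by the cut drop
    out, and the partition is restricted to the survivors.  The default step
    of 10 recordings corresponds to 3 minutes 20 seconds of contact.
    """
    if step_recordings < 1:
        raise ValueError("step_recordings must be >= 1")
    partition = Partition.from_roster(roster, level)
    if max_threshold is None:
        max_threshold = max((c.total_recordings for c in contacts), default=0)
    thresholds = list(range(0, max_threshold + 1, step_recordings))
    qs, nn, ne, ok = [], [], [], []
    for t in thresholds:
        net = build_network(contacts, roster, threshold_recordings=t)
        n, m = net.number_of_nodes(), net.number_of_edges()
        part = partition.restricted_to(net.nodes)
        reliable = m > 0 and part.n_communities() >= 2
        q = modularity(net, part, weighted=weighted) if m > 0 else float("nan")
        qs.append(q)
        nn.append(n)
        ne.append(m)
        ok.append(reliable)
    minutes = tuple(t * tick_seconds / 60.0 for t in thresholds)
    return ModularityCurve(
        tuple(thresholds), minutes, tuple(qs), tuple(nn), tuple(ne), tuple(ok)
    )
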