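"""File formats and the end-to-end pipeline.

Plain-text formats only:

* beacon log CSV — ``receiver_id,sender_id,timestamp,rssi``
* roster CSV — ``node_id,grade,classroom,role``
* contact edge list CSV — ``id_a,id_b,recordings,minutes,encounters``
* networks — edge-list CSV (``id_a,id_b,weight``), Pajek ``.net`` (with
  companion ``.clu`` partition files), GraphML with node attributes
* partitions — Pajek ``.clu`` aligned to the ``.net`` vertex order, or CSV
  ``node_id,label``
* configuration — YAML mirroring :class:`~schoolnet.synthetic.SchoolConfig`
  and :class:`RunConfig`
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import community as community_mod
from . import distributions as dist_mod
from . import ingest as ingest_mod
from . import metrics as metrics_mod
from .errors import ConfigError, FitError, FormatError
from .ingest import BeaconRecord, Contact
from .synthetic import (
    Period,
    Roster,
    RosterEntry,
    SchoolConfig,
    hhmm,
    simulate_school_day,
)

logger = logging.getLogger("schoolnet")

__all__ = [
    "RunConfig",
    "read_beacon_log",
    "write_beacon_log",
    "read_roster",
    "write_roster",
    "read_contacts",
    "write_contacts",
    "read_network",
    "write_network",
    "read_partition_csv",
    "write_partition_csv",
    "read_partition_clu",
    "write_partition_clu",
    "load_school_config",
    "save_school_config",
    "load_run_config",
    "run_pipeline",
]


# ---------------------------------------------------------------- tabular IO

def write_beacon_log(records: Sequence[BeaconRecord], path) -> None:
    pd.DataFrame(
        [(r.receiver_id, r.sender_id, r.timestamp, r.rssi) for r in records],
        columns=["receiver_id", "sender_id", "timestamp", "rssi"],
    ).to_csv(path, index=False)


def read_beacon_log(path) -> list[BeaconRecord]:
    try:
        df = pd.read_csv(path, dtype={"receiver_id": str, "sender_id": str})
        return [
            BeaconRecord(r.receiver_id, r.sender_id, int(r.timestamp),
                         float(r.rssi))
            for r in df.itertuples(index=False)
        ]
    except (KeyError, ValueError, AttributeError) as exc:
        raise FormatError(f"malformed beacon log {path}: {exc}") from exc


def write_roster(roster: Roster, path) -> None:
    pd.DataFrame(
        [(e.node_id, e.grade, e.classroom, e.role) for e in roster.entries],
        columns=["node_id", "grade", "classroom", "role"],
    ).to_csv(path, index=False)


def read_roster(path) -> Roster:
    try:
        df = pd.read_csv(path, dtype=str)
        return Roster(
            tuple(
                RosterEntry(r.node_id, r.grade, r.classroom, r.role)
                for r in df.itertuples(index=False)
            )
        )
    except (KeyError, AttributeError, ValueError) as exc:
        raise FormatError(f"malformed roster {path}: {exc}") from exc


def write_contacts(contacts: Sequence[Contact], path) -> None:
    pd.DataFrame(
        [
            (c.pair[0], c.pair[1], c.total_recordings, c.cumulative_minutes,
             c.n_encounters)
            for c in contacts
        ],
        columns=["id_a", "id_b", "recordings", "minutes", "encounters"],
    ).to_csv(path, index=False)


def read_contacts(path) -> list[Contact]:
    try:
        df = pd.read_csv(path, dtype={"id_a": str, "id_b": str})
        return [
            Contact(
                tuple(sorted((r.id_a, r.id_b))),
                int(r.recordings),
                float(r.minutes),
                int(r.encounters),
            )
            for r in df.itertuples(index=False)
        ]
    except (KeyError, AttributeError, ValueError) as exc:
        raise FormatError(f"malformed contact list {path}: {exc}") from exc


# ---------------------------------------------------------------- network IO

NetworkFormat = Literal["edge_csv", "pajek", "graphml"]

_SUFFIX_FORMAT = {".csv": "edge_csv", ".net": "pajek", ".graphml": "graphml"}


def _infer_format(path, fmt: NetworkFormat | None) -> NetworkFormat:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix not in _SUFFIX_FORMAT:
        raise FormatError(f"cannot infer network format from {path}")
    return _SUFFIX_FORMAT[suffix]


def read_network(
    path, format: NetworkFormat | None = None, roster: Roster | None = None
) -> nx.Graph:
    """Read a weighted undirected network from any supported format.

    Duplicate edges are merged by summing weights (with a warning); node
    attributes are attached from ``roster`` when given, else from attributes
    embedded in the file (GraphML).
    """
    fmt = _infer_format(path, format)
    try:
        if fmt == "edge_csv":
            df = pd.read_csv(path, dtype={"id_a": str, "id_b": str})
            wcol = "weight" if "weight" in df.columns else "minutes"
            if wcol not in df.columns:
                raise FormatError(
                    f"{path}: edge CSV needs a 'weight' or 'minutes' column"
                )
            raw = nx.MultiGraph()
            for r in df.itertuples(index=False):
                raw.add_edge(str(r.id_a), str(r.id_b),
                             weight=float(getattr(r, wcol)))
        elif fmt == "pajek":
            head = Path(path).read_text().lower()
            if "*vertices" not in head:
                raise FormatError(
                    f"{path}: no *Vertices section — not a Pajek file"
                )
            raw = nx.read_pajek(path)
        else:
            raw = nx.read_graphml(path)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    g = nx.Graph()
    duplicates = 0
    for u, v, data in raw.edges(data=True):
        w = float(data.get("weight", 1.0))
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
            duplicates += 1
        else:
            g.add_edge(u, v, weight=w)
    if duplicates:
        logger.warning("%s: merged %d duplicate edges by weight sum",
                       path, duplicates)
    for node, data in raw.nodes(data=True):
        if node not in g:
            g.add_node(node)
        for key in ("grade", "classroom", "role"):
            if key in data:
                g.nodes[node][key] = data[key]
    if roster is not None:
        entries = roster.by_id()
        for node in g.nodes:
            if node in entries:
                e = entries[node]
                g.nodes[node].update(
                    grade=e.grade, classroom=e.classroom, role=e.role
                )
    return g


def write_network(
    net: nx.Graph, path, format: NetworkFormat | None = None
) -> None:
    """Write a network; for Pajek, grade/classroom ``.clu`` companions are
    written alongside when those node attributes are present."""
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "edge_csv":
        rows = sorted(
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in net.edges(data=True)
        )
        pd.DataFrame(rows, columns=["id_a", "id_b", "weight"]).to_csv(
            path, index=False
        )
    elif fmt == "pajek":
        order = sorted(net.nodes)
        with open(path, "w") as fh:
            fh.write(f"*Vertices {len(order)}\n")
            for i, node in enumerate(order, start=1):
                fh.write(f'{i} "{node}"\n')
            index = {node: i for i, node in enumerate(order, start=1)}
            fh.write("*Edges\n")
            for u, v, d in sorted(net.edges(data=True)):
                a, b = sorted((index[u], index[v]))
                fh.write(f"{a} {b} {d['weight']:g}\n")
        for level in ("grade", "classroom"):
            if all(level in net.nodes[n] for n in order) and order:
                labels = [net.nodes[n][level] for n in order]
                codes = {lab: i + 1 for i, lab in
                         enumerate(sorted(set(labels)))}
                clu = path.with_suffix(f".{level}.clu")
                with open(clu, "w") as fh:
                    fh.write(f"*Vertices {len(order)}\n")
                    for lab in labels:
                        fh.write(f"{codes[lab]}\n")
    else:
        nx.write_graphml(net, path)


# -------------------------------------------------------------- partition IO

def write_partition_csv(partition: community_mod.Partition, path) -> None:
    pd.DataFrame(
        sorted(partition.mapping.items()), columns=["node_id", "label"]
    ).to_csv(path, index=False)


def read_partition_csv(path, level="custom") -> community_mod.Partition:
    try:
        df = pd.read_csv(path, dtype=str)
        return community_mod.Partition(
            dict(zip(df["node_id"], df["label"])), level
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed partition {path}: {exc}") from exc


def write_partition_clu(
    partition: community_mod.Partition, node_order: Sequence[str], path
) -> None:
    """Pajek .clu: integer community codes, one per vertex in ``node_order``."""
    labels = sorted(set(partition.mapping.values()))
    codes = {lab: i + 1 for i, lab in enumerate(labels)}
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(node_order)}\n")
        for node in node_order:
            fh.write(f"{codes[partition.mapping[node]]}\n")


def read_partition_clu(
    path, node_order: Sequence[str], level="custom"
) -> community_mod.Partition:
    try:
        lines = Path(path).read_text().strip().splitlines()
        if not lines[0].lower().startswith("*vertices"):
            raise FormatError(f"{path}: line 1: expected *Vertices header")
        values = [ln.strip() for ln in lines[1:] if ln.strip()]
        if len(values) != len(node_order):
            raise FormatError(
                f"{path}: {len(values)} entries for {len(node_order)} vertices"
            )
        return community_mod.Partition(dict(zip(node_order, values)), level)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc


# ------------------------------------------------------------ configuration

def save_school_config(config: SchoolConfig, path) -> None:
    data = dataclasses.asdict(config)
    if config.periods is not None:
        data["periods"] = [[p.start, p.end, p.kind] for p in config.periods]
    if config.lunch_groups is not None:
        data["lunch_groups"] = [list(g) for g in config.lunch_groups]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_school_config(path) -> SchoolConfig:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot read config {path}: {exc}") from exc
    known = {f.name for f in dataclasses.fields(SchoolConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("day_start", "day_end"):
        if key in data:
            data[key] = hhmm(data[key])
    if data.get("periods") is not None:
        data["periods"] = tuple(
            Period(hhmm(s), hhmm(e), k) for s, e, k in data["periods"]
        )
    if data.get("lunch_groups") is not None:
        data["lunch_groups"] = tuple(tuple(g) for g in data["lunch_groups"])
    config = SchoolConfig(**data)
    config.validate()
    return config


@dataclass
class RunConfig:
    """One pipeline run: where inputs come from and which rules to apply.

    Defaults reproduce the deployment's stated settings without any flags:
    −80 dB proximity cut, 20-second ticks, 5-minute contact threshold, union
    pair rule, 10-recording sweep step.
    """

    out_dir: str = "schoolnet_out"
    beacon_log: str | None = None
    roster: str | None = None
    network: str | None = None  # prebuilt network: skips ingest
    simulate: SchoolConfig | None = None
    rssi_threshold: float = -80.0
    tick_seconds: int = 20
    contact_threshold_minutes: float = 5.0
    pair_rule: str = "union"
    max_gap_ticks: int = 0
    sweep_step_recordings: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_log = self.beacon_log is not None and self.roster is not None
        if not (has_log or self.network is not None or self.simulate):
            raise ConfigError(
                "need a beacon log + roster, a prebuilt network, or a "
                "simulation config"
            )
        if self.pair_rule not in ("union", "mutual"):
            raise ConfigError(f"unknown pair rule {self.pair_rule!r}")


def load_run_config(path) -> RunConfig:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot read config {path}: {exc}") from exc
    if isinstance(data.get("simulate"), dict):
        sim = data["simulate"]
        for key in ("day_start", "day_end"):
            if key in sim:
                sim[key] = hhmm(sim[key])
        if sim.get("periods") is not None:
            sim["periods"] = tuple(
                Period(hhmm(s), hhmm(e), k) for s, e, k in sim["periods"]
            )
        if sim.get("lunch_groups") is not None:
            sim["lunch_groups"] = tuple(tuple(g) for g in sim["lunch_groups"])
        data["simulate"] = SchoolConfig(**sim)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


# ------------------------------------------------------------------ pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Simulate (optionally) → ingest → metrics → modularity → distributions.

    Writes every table the analysis produces into ``config.out_dir`` and
    returns the key numbers as a dict.  Deterministic given the same config
    and seed.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    roster = None
    records = None
    encounters = None
    contacts = None
    net = None

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        logger.info("simulating school day (mode=%s, seed=%d)",
                    sim_cfg.schedule_mode, config.seed)
        result = simulate_school_day(sim_cfg)
        roster = result.roster
        records = list(result.records)
        write_beacon_log(records, out / "beacon_log.csv")
        write_roster(roster, out / "roster.csv")
    elif config.beacon_log is not None:
        records = read_beacon_log(config.beacon_log)
        roster = read_roster(config.roster)
    elif config.roster is not None:
        roster = read_roster(config.roster)

    if records is not None:
        logger.info("ingest: %d records, rssi threshold %.1f dB, rule=%s",
                    len(records), config.rssi_threshold, config.pair_rule)
        kept = ingest_mod.filter_by_rssi(records, config.rssi_threshold)
        kept = ingest_mod.filter_students(kept, roster.student_ids())
        pair_ticks = ingest_mod.records_to_pair_ticks(
            kept, config.tick_seconds, config.pair_rule
        )
        encounters = ingest_mod.pair_ticks_to_encounters(
            pair_ticks, config.tick_seconds, config.max_gap_ticks
        )
        contacts = ingest_mod.encounters_to_contacts(encounters)
        write_contacts(contacts, out / "contacts.csv")
        logger.info("ingest: %d pair-ticks, %d encounters, %d contacts",
                    len(pair_ticks), len(encounters), len(contacts))
        net = metrics_mod.build_network(
            contacts, roster, config.contact_threshold_minutes
        )
    elif config.network is not None:
        net = read_network(config.network, roster=roster)
        # apply the duration threshold to the prebuilt weights
        drop = [
            (u, v)
            for u, v, w in net.edges(data="weight")
            if not w > config.contact_threshold_minutes
        ]
        net.remove_edges_from(drop)
        net.remove_nodes_from([n for n in list(net) if net.degree(n) == 0])

    report.update(_metrics_stage(net, out))
    report.update(_community_stage(net, contacts, roster, config, out))
    if encounters is not None:
        report.update(
            _distributions_stage(encounters, contacts, records, config, out)
        )
        tbd = metrics_mod.time_binned_degree(
            encounters,
            tick_seconds=config.tick_seconds,
            students=set(roster.student_ids()),
        )
        tbd.rename_axis("t_seconds").to_csv(out / "time_binned_degree.csv")
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    return report


def _metrics_stage(net, out: Path) -> dict:
    logger.info("metrics: n=%d m=%d", net.number_of_nodes(),
                net.number_of_edges())
    summary = metrics_mod.summarize(net)
    pd.DataFrame([summary.as_row()]).to_csv(out / "summary.csv", index=False)
    write_network(net, out / "network.csv")
    write_network(net, out / "network.net")
    write_network(net, out / "network.graphml")
    dist_mod.degree_distribution(net).to_csv(out / "degree_distribution.csv")
    have_labels = all(
        "grade" in net.nodes[n] and "classroom" in net.nodes[n]
        for n in net.nodes
    )
    if have_labels:
        for level in ("grade", "classroom"):
            metrics_mod.contact_matrix(net, level).to_csv(
                out / f"contact_matrix_{level}.csv"
            )
    weights = [w for _, _, w in net.edges(data="weight")]
    if weights:
        bins = np.linspace(min(weights), max(weights) + 1e-9, 11)
        metrics_mod.overlap_vs_weight_curve(net, bins).to_csv(
            out / "overlap_vs_weight.csv", index=False
        )
    return {
        "n": int(summary.n),
        "density": float(round(summary.density, 6)),
        "mean_degree": float(round(summary.degree_mean, 4)),
        "mean_duration_per_contact": float(round(summary.duration_mean, 4)),
        "mean_clustering": float(round(summary.clustering_mean, 4)),
    }


def _community_stage(net, contacts, roster, config: RunConfig, out: Path) -> dict:
    have_labels = all(
        "grade" in net.nodes[n] and "classroom" in net.nodes[n]
        for n in net.nodes
    )
    if not have_labels:
        logger.warning("community: no grade/classroom labels; skipping")
        return {}
    rows = {}
    result = {}
    for level in ("grade", "classroom"):
        part = community_mod.Partition(
            {n: net.nodes[n][level] for n in net.nodes}, level
        )
        qw = community_mod.modularity(net, part, weighted=True)
        qb = community_mod.modularity(net, part, weighted=False)
        rows[f"Q_{level}"] = float(round(qw, 6))
        rows[f"Q_{level}_binary"] = float(round(qb, 6))
        result[f"modularity_{level}"] = float(round(qw, 6))
        logger.info("modularity (%s): weighted %.3f, binary %.3f",
                    level, qw, qb)
    pd.DataFrame([rows]).to_csv(out / "modularity.csv", index=False)
    if contacts is not None and roster is not None:
        for level in ("grade", "classroom"):
            curve = community_mod.modularity_vs_threshold(
                contacts, roster, level,
                step_recordings=config.sweep_step_recordings,
                tick_seconds=config.tick_seconds,
            )
            pd.DataFrame(
                {
                    "threshold_recordings": curve.thresholds_recordings,
                    "threshold_minutes": curve.thresholds_minutes,
                    "Q": curve.q,
                    "n_nodes": curve.n_nodes,
                    "n_edges": curve.n_edges,
                    "reliable": curve.reliable,
                }
            ).to_csv(out / f"modularity_vs_threshold_{level}.csv", index=False)
    return result


def _distributions_stage(encounters, contacts, records, config: RunConfig,
                         out: Path) -> dict:
    result: dict = {}
    fit_lines = []
    samples = {
        "encounter_duration": dist_mod.collect_durations(
            encounters, "encounter_duration"
        ),
        "inter_encounter_gap": dist_mod.collect_durations(
            encounters, "inter_encounter_gap"
        ),
        "encounters_per_pair": dist_mod.collect_durations(
            encounters, "encounters_per_pair"
        ),
        "contact_duration": dist_mod.collect_durations(
            contacts, "contact_duration"
        ),
    }
    for name, sample in samples.items():
        sample.relative_frequencies().to_csv(
            out / f"dist_{name}.csv", index=False
        )
    for name in ("encounter_duration", "contact_duration"):
        try:
            fit = dist_mod.fit_power_law(samples[name])
            fit_lines.append(f"{name}: {fit.report()}")
            result[f"beta_{name}"] = float(round(fit.beta, 4))
        except FitError as exc:
            fit_lines.append(f"{name}: fit failed ({exc})")
    contact_minutes = samples["contact_duration"]
    result["fraction_le_1min"] = float(round(
        dist_mod.fraction_within(contact_minutes, 1.0, "le"), 4)
    )
    result["fraction_le_5min"] = float(round(
        dist_mod.fraction_within(contact_minutes, 5.0, "le"), 4)
    )
    result["fraction_gt_30min"] = float(round(
        dist_mod.fraction_within(contact_minutes, 30.0, "gt"), 4)
    )
    if records:
        rate = dist_mod.rssi_exponential_rate(records)
        fit_lines.append(f"rssi |magnitude| exponential rate: {rate:.5f}")
    (out / "fits.txt").write_text("\n".join(fit_lines) + "\n")
    return result
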