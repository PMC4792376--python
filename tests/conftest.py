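"""Shared fixtures: one simulated cohort school and one individualized school,
ingested end-to-end once per session."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pytest

import schoolnet as sn


@dataclass
class SchoolRun:
    """A simulated school day pushed through the full ingest chain."""

    config: sn.SchoolConfig
    result: sn.SimulationResult
    pair_ticks: set
    encounters: list
    contacts: list
    net: nx.Graph


def _run_school(config: sn.SchoolConfig) -> SchoolRun:
    result = sn.simulate_school_day(config)
    records = sn.filter_by_rssi(list(result.records))
    records = sn.filter_students(records, result.roster.student_ids())
    pair_ticks = sn.records_to_pair_ticks(records, config.tick_seconds)
    encounters = sn.pair_ticks_to_encounters(pair_ticks, config.tick_seconds)
    contacts = sn.encounters_to_contacts(encounters)
    net = sn.build_network(contacts, result.roster)
    return SchoolRun(config, result, pair_ticks, encounters, contacts, net)


@pytest.fixture(scope="session")
def cohort_run() -> SchoolRun:
    """Elementary-style school: classrooms stay together all day."""
    return _run_school(sn.elementary_config(seed=1))


@pytest.fixture(scope="session")
def individualized_run() -> SchoolRun:
    """High-school-style school: per-period room reassignment across grades."""
    return _run_school(sn.high_school_config(seed=1))


@pytest.fixture()
def small_roster() -> sn.Roster:
    """Hand-sized roster for constructed-contact tests."""
    entries = []
    for i in range(12):
        grade = f"G{i // 6 + 1}"
        classroom = f"{grade}C{i % 6 // 3 + 1}"
        entries.append(sn.RosterEntry(f"n{i:02d}", grade, classroom, "student"))
    entries.append(sn.RosterEntry("staff0", "-", "-", "staff"))
    entries.append(sn.RosterEntry("x00", "-", "-", "stationary"))
    return sn.Roster(tuple(entries))
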