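"""From raw beacon records to encounters and cumulative contacts.

Proximity motes broadcast a beacon every tick (20 s by default) and log every
beacon they hear as ``(receiver, sender, timestamp, rssi)``.  This module turns
those directed radio observations into the objects the network analysis is
built on:

* a **pair-tick** — evidence that an unordered pair of motes was in proximity
  during one beacon interval;
* an **encounter** — a maximal run of consecutive pair-ticks, i.e. one
  uninterrupted proximal interaction;
* a **contact** — a pair's encounters accumulated over the deployment day.

Each recording (pair-tick) stands for a continuous 20-second contact, so
``x`` recordings between two students denote ``x/3`` minutes of aggregated
contact time.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import ConsistencyError

__all__ = [
    "BeaconRecord",
    "Encounter",
    "Contact",
    "filter_by_rssi",
    "filter_students",
    "records_to_pair_ticks",
    "pair_ticks_to_encounters",
    "encounters_to_contacts",
    "DEFAULT_RSSI_THRESHOLD",
    "DEFAULT_TICK_SECONDS",
]

DEFAULT_RSSI_THRESHOLD = -80.0  # dB; ~3 m face-to-face separation
DEFAULT_TICK_SECONDS = 20

PairRule = Literal["union", "mutual"]


@dataclass(frozen=True)
class BeaconRecord:
    """One directed radio observation: ``receiver_id`` heard ``sender_id``."""

    receiver_id: str
    sender_id: str
    timestamp: int  # seconds (shared school-wide clock)
    rssi: float  # dB, negative

    def __post_init__(self) -> None:
        if self.receiver_id == self.sender_id:
            raise ConsistencyError(
                f"record with receiver == sender ({self.receiver_id!r})"
            )
        if self.timestamp < 0:
            raise ConsistencyError(f"negative timestamp {self.timestamp}")


@dataclass(frozen=True)
class Encounter:
    """A maximal run of ticks during which one pair stayed in proximity.

    ``n_ticks`` counts the ticks actually recorded, which can be fewer than the
    tick span when a gap tolerance was used in segmentation; duration is
    ``n_ticks * tick_seconds``.
    """

    pair: tuple[str, str]  # sorted, unordered
    start_tick: int
    end_tick: int  # last tick index in the run (inclusive)
    n_ticks: int
    tick_seconds: int = DEFAULT_TICK_SECONDS

    @property
    def start(self) -> int:
        """Start time in seconds on the shared clock."""
        return self.start_tick * self.tick_seconds

    @property
    def duration(self) -> int:
        """Duration in seconds (ticks counted, not span)."""
        return self.n_ticks * self.tick_seconds


@dataclass(frozen=True)
class Contact:
    """A pair's cumulative contact over one deployment day."""

    pair: tuple[str, str]
    total_recordings: int  # number of pair-ticks, x
    cumulative_minutes: float  # x / 3 for 20-s ticks
    n_encounters: int


def filter_by_rssi(
    records: Iterable[BeaconRecord],
    rssi_threshold: float = DEFAULT_RSSI_THRESHOLD,
) -> list[BeaconRecord]:
    """Keep records at least as strong as ``rssi_threshold`` (order preserved).

    The default −80 dB corresponds to roughly 3 m face-to-face separation, the
    proximity relevant to droplet transmission.
    """
    return [r for r in records if r.rssi >= rssi_threshold]


def filter_students(
    records: Iterable[BeaconRecord], student_ids: Iterable[str]
) -> list[BeaconRecord]:
    """Drop records where either endpoint is not a tagged student.

    Staff and stationary motes are excluded from the student networks.
    """
    students = set(student_ids)
    return [
        r
        for r in records
        if r.receiver_id in students and r.sender_id in students
    ]


def records_to_pair_ticks(
    records: Iterable[BeaconRecord],
    tick_seconds: int = DEFAULT_TICK_SECONDS,
    rule: PairRule = "union",
) -> set[tuple[tuple[str, str], int]]:
    """Collapse directed records into unordered ``(pair, tick_index)`` events.

    A record at time ``t`` belongs to tick ``floor(t / tick_seconds)``.  Under
    the ``union`` rule a pair-tick exists if either direction was recorded in
    that tick; under ``mutual`` both directions are required.  Duplicates
    collapse: a pair-tick is counted once no matter how many records support it.
    """
    if rule not in ("union", "mutual"):
        raise ValueError(f"unknown pair rule {rule!r}")
    directed: set[tuple[str, str, int]] = set()
    for r in records:
        tick = r.timestamp // tick_seconds
        directed.add((r.receiver_id, r.sender_id, tick))
    out: set[tuple[tuple[str, str], int]] = set()
    for recv, send, tick in directed:
        pair = (recv, send) if recv < send else (send, recv)
        if rule == "union" or (send, recv, tick) in directed:
            out.add((pair, tick))
    return out


def pair_ticks_to_encounters(
    pair_ticks: Iterable[tuple[tuple[str, str], int]],
    tick_seconds: int = DEFAULT_TICK_SECONDS,
    max_gap_ticks: int = 0,
) -> list[Encounter]:
    """Segment each pair's ticks into maximal runs of continuous contact.

    With the default ``max_gap_ticks=0`` two ticks belong to the same
    encounter only if strictly consecutive; a positive tolerance bridges gaps
    of up to that many missing ticks.  Duration counts recorded ticks, not the
    bridged span.
    """
    if max_gap_ticks < 0:
        raise ValueError("max_gap_ticks must be >= 0")
    by_pair: dict[tuple[str, str], list[int]] = defaultdict(list)
    for pair, tick in pair_ticks:
        by_pair[pair].append(tick)
    encounters: list[Encounter] = []
    for pair in sorted(by_pair):
        ticks = sorted(set(by_pair[pair]))
        start = prev = ticks[0]
        count = 1
        for t in ticks[1:]:
            if t - prev <= max_gap_ticks + 1:
                count += 1
            else:
                encounters.append(
                    Encounter(pair, start, prev, count, tick_seconds)
                )
                start = t
                count = 1
            prev = t
        encounters.append(Encounter(pair, start, prev, count, tick_seconds))
    return encounters


def encounters_to_contacts(encounters: Sequence[Encounter]) -> list[Contact]:
    """Accumulate each pair's encounters into one cumulative contact.

    ``total_recordings`` is the pair's total pair-tick count ``x``;
    ``cumulative_minutes`` is ``x * tick_seconds / 60`` — exactly ``x/3`` for
    the standard 20-second tick.
    """
    recs: dict[tuple[str, str], int] = defaultdict(int)
    runs: dict[tuple[str, str], int] = defaultdict(int)
    tick_s: dict[tuple[str, str], int] = {}
    for e in encounters:
        recs[e.pair] += e.n_ticks
        runs[e.pair] += 1
        tick_s[e.pair] = e.tick_seconds
    return [
        Contact(
            pair=pair,
            total_recordings=recs[pair],
            cumulative_minutes=recs[pair] * tick_s[pair] / 60.0,
            n_encounters=runs[pair],
        )
        for pair in sorted(recs)
    ]
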