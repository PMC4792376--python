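"""Synthetic school-day generator.

Emulates a one-day proximity-mote deployment in a school: a roster of students
organised into grades and classrooms, a bell schedule of class periods, breaks
and lunch, and the beacon log the motes would have produced.  Two schedule
regimes are supported:

* ``cohort`` — every classroom stays together all day (elementary / middle
  school style); contact networks come out strongly modular by grade and
  classroom.
* ``individualized`` — each student is independently re-assigned to a room
  every class period, mixing grades (high-school style); modularity against
  the grade partition is low.

Pair interactions inside a room follow a start-hazard / heavy-tailed-duration
process: an idle co-located pair starts an encounter with probability
``p_encounter`` per tick, and the encounter length in ticks is drawn from a
discrete power law (pmf ∝ d**duration_exponent, d ≥ min_encounter_ticks)
truncated at the period boundary.  During breaks and lunch, any pair not
sharing a room additionally gets a minimum-length "background" encounter with
probability ``p_background`` per tick — the occasional hallway brush between
students of different classrooms or grades.

Every in-range pair-tick emits two directed beacon records (both directions)
with RSSI drawn from the near-field model; optionally, out-of-range pairs emit
sparse far-field records so that the RSSI threshold rule has something to
reject.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigError
from .ingest import BeaconRecord, Encounter

__all__ = [
    "Period",
    "SchoolConfig",
    "RosterEntry",
    "Roster",
    "Schedule",
    "SimulationResult",
    "default_periods",
    "elementary_config",
    "high_school_config",
    "generate_roster",
    "generate_schedule",
    "simulate_beacon_log",
    "simulate_school_day",
    "hhmm",
]


def hhmm(text: str | int) -> int:
    """Clock time as seconds from midnight ('08:30' → 30600)."""
    if isinstance(text, int):
        return text
    h, m = text.split(":")
    return int(h) * 3600 + int(m) * 60


@dataclass(frozen=True)
class Period:
    start: int  # seconds from midnight
    end: int
    kind: Literal["class", "break", "lunch"]

    @property
    def is_common(self) -> bool:
        return self.kind in ("break", "lunch")


def default_periods(day_start: int, day_end: int) -> tuple[Period, ...]:
    """A plausible bell schedule tiling [day_start, day_end].

    Seven ~45-minute class periods, three 10-minute breaks and a 35-minute
    lunch block, matching a typical US school day.
    """
    spec = [
        (45, "class"),
        (10, "break"),
        (45, "class"),
        (45, "class"),
        (10, "break"),
        (45, "class"),
        (35, "lunch"),
        (45, "class"),
        (10, "break"),
        (45, "class"),
    ]
    periods = []
    t = day_start
    for minutes, kind in spec:
        periods.append(Period(t, t + minutes * 60, kind))
        t += minutes * 60
    # stretch the final class period to close the day exactly
    if t != day_end:
        last = periods[-1]
        periods[-1] = Period(last.start, day_end, last.kind)
    return tuple(periods)


@dataclass(frozen=True)
class SchoolConfig:
    """Generative parameters for one synthetic school day.

    Defaults describe a scaled-down school of 4 grades × 2 classrooms × 20
    students on an 08:30–15:00 day with 20-second beacon ticks; the RSSI model
    puts in-range pairs well above and out-of-range pairs well below the
    −80 dB proximity cut.
    """

    n_grades: int = 4
    classrooms_per_grade: int = 2
    class_size: int = 20
    n_stationary: int = 2
    tick_seconds: int = 20
    day_start: int = hhmm("08:30")
    day_end: int = hhmm("15:00")
    periods: tuple[Period, ...] | None = None  # None → default_periods
    schedule_mode: Literal["cohort", "individualized"] = "cohort"
    p_encounter: float = 0.02  # per-tick start hazard for an idle in-room pair
    p_background: float = 0.002  # per-tick cross-room encounter rate at break
    duration_exponent: float = -1.2  # discrete power-law exponent (< -0.5)
    min_encounter_ticks: int = 1
    rssi_mean_near: float = -65.0  # dB
    rssi_mean_far: float = -92.0
    rssi_sd: float = 3.0
    record_out_of_range: bool = False
    p_far_record: float = 0.01  # per pair-tick, only if record_out_of_range
    p_drop: float = 0.0  # independent per-record loss
    lunch_groups: tuple[tuple[int, ...], ...] | None = None  # grade indices
    seed: int = 0

    def resolved_periods(self) -> tuple[Period, ...]:
        return (
            self.periods
            if self.periods is not None
            else default_periods(self.day_start, self.day_end)
        )

    def resolved_lunch_groups(self) -> tuple[tuple[int, ...], ...]:
        """Which grades share a lunch room; default pairs consecutive grades."""
        if self.lunch_groups is not None:
            return self.lunch_groups
        grades = list(range(self.n_grades))
        return tuple(tuple(grades[i : i + 2]) for i in range(0, len(grades), 2))

    def validate(self) -> None:
        if self.n_grades < 1 or self.classrooms_per_grade < 1:
            raise ConfigError("need at least one grade and one classroom")
        if self.class_size < 2:
            raise ConfigError("class_size must be >= 2")
        if self.tick_seconds <= 0:
            raise ConfigError("tick_seconds must be positive")
        if not self.duration_exponent < -0.5:
            raise ConfigError("duration_exponent must be < -0.5")
        if self.min_encounter_ticks < 1:
            raise ConfigError("min_encounter_ticks must be >= 1")
        for p in (self.p_encounter, self.p_background, self.p_drop,
                  self.p_far_record):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        periods = self.resolved_periods()
        if not periods:
            raise ConfigError("no periods")
        t = self.day_start
        for p in periods:
            if p.start != t or p.end <= p.start:
                raise ConfigError("periods must tile the day without overlap")
            if p.start % self.tick_seconds or p.end % self.tick_seconds:
                raise ConfigError(
                    "period boundaries must fall on the beacon tick grid"
                )
            t = p.end
        if t != self.day_end:
            raise ConfigError("periods must end exactly at day_end")
        groups = self.resolved_lunch_groups()
        seen = [g for grp in groups for g in grp]
        if sorted(seen) != list(range(self.n_grades)):
            raise ConfigError("lunch_groups must cover every grade exactly once")


def elementary_config(**overrides) -> SchoolConfig:
    """Cohort-scheduled school: classrooms stay together, high modularity."""
    return replace(SchoolConfig(schedule_mode="cohort"), **overrides)


def high_school_config(**overrides) -> SchoolConfig:
    """Individualized schedules mixing grades every period, low modularity."""
    return replace(SchoolConfig(schedule_mode="individualized"), **overrides)


@dataclass(frozen=True)
class RosterEntry:
    node_id: str
    grade: str
    classroom: str
    role: Literal["student", "staff", "stationary"]


@dataclass(frozen=True)
class Roster:
    entries: tuple[RosterEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.node_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate node ids in roster")

    @property
    def students(self) -> tuple[RosterEntry, ...]:
        return tuple(e for e in self.entries if e.role == "student")

    def student_ids(self) -> list[str]:
        return [e.node_id for e in self.students]

    def by_id(self) -> dict[str, RosterEntry]:
        return {e.node_id: e for e in self.entries}

    def labels(self, level: Literal["grade", "classroom"]) -> dict[str, str]:
        attr = "grade" if level == "grade" else "classroom"
        return {e.node_id: getattr(e, attr) for e in self.students}


# per-student room assignment for each period, in period order
Schedule = dict[str, tuple[str, ...]]


def generate_roster(config: SchoolConfig) -> Roster:
    """Enumerate students (and stationary motes) for the configured school."""
    config.validate()
    entries: list[RosterEntry] = []
    sid = 0
    for g in range(config.n_grades):
        grade = f"G{g + 1}"
        for c in range(config.classrooms_per_grade):
            classroom = f"{grade}C{c + 1}"
            for _ in range(config.class_size):
                entries.append(
                    RosterEntry(f"s{sid:04d}", grade, classroom, "student")
                )
                sid += 1
    for k in range(config.n_stationary):
        entries.append(RosterEntry(f"x{k:02d}", "-", "-", "stationary"))
    return Roster(tuple(entries))


def _classroom_names(config: SchoolConfig) -> list[str]:
    return [
        f"G{g + 1}C{c + 1}"
        for g in range(config.n_grades)
        for c in range(config.classrooms_per_grade)
    ]


def _grade_of(entry: RosterEntry) -> int:
    return int(entry.grade[1:]) - 1


def generate_schedule(config: SchoolConfig, roster: Roster) -> Schedule:
    """Assign every student a room for every period.

    Cohort mode keeps each classroom together for every class period; break
    rooms are shared per grade and lunch rooms per lunch group.  Individualized
    mode re-draws each student's room uniformly over all classrooms every
    class period and sends the whole school to one common space at breaks
    (lunch still runs in lunch-group shifts).  Stationary motes sit in fixed
    rooms all day.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    periods = config.resolved_periods()
    rooms = _classroom_names(config)
    groups = config.resolved_lunch_groups()
    grade_to_lunch = {
        g: f"COMMON-LUNCH-{i}" for i, grp in enumerate(groups) for g in grp
    }
    schedule: dict[str, list[str]] = {}
    students = roster.students
    for e in students:
        schedule[e.node_id] = []
    for p_idx, period in enumerate(periods):
        if period.kind == "class":
            if config.schedule_mode == "cohort":
                for e in students:
                    schedule[e.node_id].append(e.classroom)
            else:
                draw = rng.integers(0, len(rooms), size=len(students))
                for e, r in zip(students, draw):
                    schedule[e.node_id].append(rooms[r])
        elif period.kind == "lunch":
            for e in students:
                schedule[e.node_id].append(grade_to_lunch[_grade_of(e)])
        else:  # break
            for e in students:
                room = (
                    f"COMMON-BREAK-{e.grade}"
                    if config.schedule_mode == "cohort"
                    else "COMMON-BREAK-ALL"
                )
                schedule[e.node_id].append(room)
    stationary = [e for e in roster.entries if e.role == "stationary"]
    for k, e in enumerate(stationary):
        schedule[e.node_id] = [rooms[k % len(rooms)]] * len(periods)
    return {nid: tuple(rs) for nid, rs in schedule.items()}


_zipf_cdf_cache: dict[tuple[float, int, int], np.ndarray] = {}


def _sample_truncated_zipf(
    rng: np.random.Generator, exponent: float, lo: int, hi: int
) -> int:
    """One draw from pmf ∝ d**exponent on integers [lo, hi] (inverse CDF)."""
    if hi <= lo:
        return lo
    key = (exponent, lo, hi)
    cdf = _zipf_cdf_cache.get(key)
    if cdf is None:
        w = np.arange(lo, hi + 1, dtype=float) ** exponent
        cdf = np.cumsum(w / w.sum())
        _zipf_cdf_cache[key] = cdf
    return lo + int(np.searchsorted(cdf, rng.random()))


def _pair_process(
    rng: np.random.Generator,
    n_ticks: int,
    p_start: float,
    exponent: float,
    min_ticks: int,
) -> list[tuple[int, int]]:
    """Encounter intervals (start, length) for one co-located pair-period.

    Idle→active waits are geometric with hazard ``p_start``; lengths are
    discrete power-law on [min_ticks, period length], clipped at the period
    boundary (the bell ends the interaction).
    """
    out = []
    t = 0
    while t < n_ticks:
        gap = int(rng.geometric(p_start))  # ticks until next start, >= 1
        t += gap - 1
        if t >= n_ticks:
            break
        length = _sample_truncated_zipf(rng, exponent, min_ticks, n_ticks)
        length = min(length, n_ticks - t)
        out.append((t, length))
        t += length
    return out


@dataclass(frozen=True)
class SimulationResult:
    config: SchoolConfig
    roster: Roster
    schedule: Schedule
    records: tuple[BeaconRecord, ...]
    true_encounters: tuple[Encounter, ...]  # planted ground truth

    def true_pair_ticks(
        self, students_only: bool = True
    ) -> set[tuple[tuple[str, str], int]]:
        """The planted in-range pair-ticks (for recovery checks)."""
        student_ids = set(self.roster.student_ids())
        out = set()
        for e in self.true_encounters:
            if students_only and not (
                e.pair[0] in student_ids and e.pair[1] in student_ids
            ):
                continue
            for t in range(e.start_tick, e.start_tick + e.n_ticks):
                out.add((e.pair, t))
        return out


def simulate_beacon_log(
    config: SchoolConfig, roster: Roster, schedule: Schedule
) -> list[BeaconRecord]:
    """Simulate one day of beacon records (see :func:`simulate_school_day`)."""
    return list(_simulate(config, roster, schedule).records)


def simulate_school_day(
    config: SchoolConfig,
    roster: Roster | None = None,
    schedule: Schedule | None = None,
    emit_records: bool = True,
) -> SimulationResult:
    """Roster → schedule → beacon log, with planted ground truth attached.

    Deterministic given ``config.seed``: the same configuration always yields
    byte-identical logs.  ``emit_records=False`` skips the beacon log and
    returns only the planted encounters (useful for large calibration runs).
    """
    if roster is None:
        roster = generate_roster(config)
    if schedule is None:
        schedule = generate_schedule(config, roster)
    return _simulate(config, roster, schedule, emit_records)


def _simulate(
    config: SchoolConfig,
    roster: Roster,
    schedule: Schedule,
    emit_records: bool = True,
) -> SimulationResult:
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    periods = config.resolved_periods()
    tick = config.tick_seconds
    nodes = sorted(schedule)
    encounters: list[Encounter] = []

    for p_idx, period in enumerate(periods):
        tick0 = period.start // tick  # absolute tick on the shared clock
        n_ticks = (period.end - period.start) // tick
        rooms: dict[str, list[str]] = {}
        for nid in nodes:
            rooms.setdefault(schedule[nid][p_idx], []).append(nid)
        in_room_pairs: set[tuple[str, str]] = set()
        for room in sorted(rooms):
            occupants = sorted(rooms[room])
            for a, b in itertools.combinations(occupants, 2):
                in_room_pairs.add((a, b))
                for start, length in _pair_process(
                    rng,
                    n_ticks,
                    config.p_encounter,
                    config.duration_exponent,
                    config.min_encounter_ticks,
                ):
                    encounters.append(
                        Encounter(
                            (a, b),
                            tick0 + start,
                            tick0 + start + length - 1,
                            length,
                            tick,
                        )
                    )
        if period.is_common and config.p_background > 0:
            cross = [
                (a, b)
                for a, b in itertools.combinations(sorted(nodes), 2)
                if (a, b) not in in_room_pairs
            ]
            if cross:
                counts = rng.binomial(n_ticks, config.p_background, len(cross))
                for (a, b), k in zip(cross, counts):
                    starts = rng.integers(0, n_ticks, size=k)
                    for s in starts:
                        length = min(config.min_encounter_ticks, n_ticks - s)
                        encounters.append(
                            Encounter(
                                (a, b),
                                tick0 + int(s),
                                tick0 + int(s) + length - 1,
                                length,
                                tick,
                            )
                        )

    records = (
        _emit_records(config, rng, encounters, periods) if emit_records else []
    )
    return SimulationResult(
        config, roster, schedule, tuple(records), tuple(encounters)
    )


def _emit_records(
    config: SchoolConfig,
    rng: np.random.Generator,
    encounters: Sequence[Encounter],
    periods: Sequence[Period],
) -> list[BeaconRecord]:
    tick = config.tick_seconds
    # planted pair-ticks, deduplicated (overlapping background draws collapse)
    pair_ticks = sorted(
        {
            (e.pair, t)
            for e in encounters
            for t in range(e.start_tick, e.start_tick + e.n_ticks)
        }
    )
    records: list[BeaconRecord] = []
    n = len(pair_ticks)
    rssi = rng.normal(config.rssi_mean_near, config.rssi_sd, size=(n, 2))
    keep = (
        rng.random(size=(n, 2)) >= config.p_drop
        if config.p_drop > 0
        else np.ones((n, 2), dtype=bool)
    )
    for i, ((a, b), t) in enumerate(pair_ticks):
        ts = t * tick
        if keep[i, 0]:
            records.append(BeaconRecord(a, b, ts, float(rssi[i, 0])))
        if keep[i, 1]:
            records.append(BeaconRecord(b, a, ts, float(rssi[i, 1])))
    if config.record_out_of_range:
        records.extend(_far_records(config, rng, set(pair_ticks), periods))
    records.sort(key=lambda r: (r.timestamp, r.receiver_id, r.sender_id))
    return records


def _far_records(
    config: SchoolConfig,
    rng: np.random.Generator,
    planted: set,
    periods: Sequence[Period],
) -> list[BeaconRecord]:
    """Sparse weak-signal records from pairs that were not in proximity."""
    tick = config.tick_seconds
    first_tick = config.day_start // tick
    total_ticks = (config.day_end - config.day_start) // tick
    ids = sorted({p[0] for p, _ in planted} | {p[1] for p, _ in planted})
    out: list[BeaconRecord] = []
    n_samples = rng.binomial(
        max(len(ids) * (len(ids) - 1) // 2, 1) * total_ticks,
        config.p_far_record,
    )
    for _ in range(n_samples):
        a, b = rng.choice(len(ids), size=2, replace=False)
        a, b = sorted((ids[int(a)], ids[int(b)]))
        t = first_tick + int(rng.integers(0, total_ticks))
        if ((a, b), t) in planted:
            continue
        ts = t * tick
        r = float(rng.normal(config.rssi_mean_far, config.rssi_sd))
        out.append(BeaconRecord(a, b, ts, r))
    return out
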