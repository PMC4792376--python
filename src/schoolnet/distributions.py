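"""Duration distributions and heavy-tail fitting.

Encounter durations, the gaps between a pair's encounters, per-pair encounter
counts and cumulative contact durations are all strongly right-skewed; the
contact-duration density is summarised by a power-law fit P(w) ~ w**β with
β < 0.

The fit follows the Clauset–Shalizi–Newman recipe: maximum-likelihood exponent
for the tail above a cutoff x_min, with x_min chosen to minimise the
Kolmogorov–Smirnov distance between the tail data and the fitted model.  Both
the continuous MLE (exact closed form) and the discrete MLE (zeta-function
likelihood, optionally upper-truncated for tick-quantised durations with a
hard ceiling) are provided.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import FitError
from .ingest import BeaconRecord, Contact, Encounter

__all__ = [
    "DurationSample",
    "PowerLawFit",
    "collect_durations",
    "fit_power_law",
    "fraction_within",
    "degree_distribution",
    "rssi_exponential_rate",
]

Kind = Literal[
    "encounter_duration",
    "inter_encounter_gap",
    "encounters_per_pair",
    "contact_duration",
]


@dataclass(frozen=True)
class DurationSample:
    """Positive durations (seconds for encounter-level kinds, minutes for
    cumulative contacts) or per-pair counts."""

    values: np.ndarray
    kind: Kind

    def relative_frequencies(self) -> pd.DataFrame:
        """Raw (value, relative frequency) table, unbinned."""
        vals, counts = np.unique(self.values, return_counts=True)
        return pd.DataFrame(
            {"value": vals, "rel_freq": counts / counts.sum()}
        )


def collect_durations(
    items: Sequence[Encounter] | Sequence[Contact], kind: Kind
) -> DurationSample:
    """Extract one empirical duration distribution.

    * ``encounter_duration`` — per-encounter seconds;
    * ``inter_encounter_gap`` — for each pair, the seconds between the end of
      one encounter and the start of the next (exclusive of both);
    * ``encounters_per_pair`` — how many separate encounters each pair had;
    * ``contact_duration`` — per-pair cumulative minutes (from contacts).
    """
    if kind == "contact_duration":
        if not all(isinstance(c, Contact) for c in items):
            raise ValueError("contact_duration needs Contact inputs")
        return DurationSample(
            np.array([c.cumulative_minutes for c in items], dtype=float), kind
        )
    if not all(isinstance(e, Encounter) for e in items):
        raise ValueError(f"{kind} needs Encounter inputs")
    if kind == "encounter_duration":
        vals = [e.duration for e in items]
    elif kind == "encounters_per_pair":
        counts: dict[tuple[str, str], int] = defaultdict(int)
        for e in items:
            counts[e.pair] += 1
        vals = sorted(counts.values())
    elif kind == "inter_encounter_gap":
        by_pair: dict[tuple[str, str], list[Encounter]] = defaultdict(list)
        for e in items:
            by_pair[e.pair].append(e)
        vals = []
        for pair in sorted(by_pair):
            es = sorted(by_pair[pair], key=lambda e: e.start_tick)
            for prev, nxt in zip(es, es[1:]):
                gap_ticks = nxt.start_tick - prev.end_tick - 1
                vals.append(gap_ticks * prev.tick_seconds)
    else:
        raise ValueError(f"unknown duration kind {kind!r}")
    return DurationSample(np.array(vals, dtype=float), kind)


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a power-law tail fit: P(x) ~ x**beta for x ≥ x_min."""

    beta: float  # negative density exponent (beta = -alpha)
    x_min: float
    ks: float  # Kolmogorov–Smirnov distance on the fitted tail
    n_tail: int
    discrete: bool

    @property
    def alpha(self) -> float:
        return -self.beta

    def report(self) -> str:
        kind = "discrete" if self.discrete else "continuous"
        return (
            f"power-law fit ({kind}): beta = {self.beta:.4f}, "
            f"x_min = {self.x_min:g}, KS = {self.ks:.4f}, n_tail = {self.n_tail}"
        )


MIN_TAIL = 50


def _continuous_mle(x: np.ndarray, x_min: float) -> float:
    return 1.0 + len(x) / np.sum(np.log(x / x_min))


def _continuous_ks(x: np.ndarray, x_min: float, alpha: float) -> float:
    xs = np.sort(x)
    cdf = 1.0 - (xs / x_min) ** (1.0 - alpha)
    emp_hi = np.arange(1, len(xs) + 1) / len(xs)
    emp_lo = np.arange(0, len(xs)) / len(xs)
    return float(max(np.max(np.abs(emp_hi - cdf)), np.max(np.abs(emp_lo - cdf))))


def _discrete_logpmf(k: np.ndarray, alpha: float, x_min: int,
                     x_max: int | None) -> np.ndarray:
    if x_max is None:
        log_z = np.log(special.zeta(alpha, x_min))
    else:
        support = np.arange(x_min, x_max + 1, dtype=float)
        log_z = np.log(np.sum(support ** -alpha))
    return -alpha * np.log(k) - log_z


def _discrete_mle(x: np.ndarray, x_min: int, x_max: int | None) -> float:
    mean_log = np.mean(np.log(x))

    def nll(alpha: float) -> float:
        if x_max is None:
            log_z = np.log(special.zeta(alpha, x_min))
        else:
            support = np.arange(x_min, x_max + 1, dtype=float)
            log_z = np.log(np.sum(support ** -alpha))
        return alpha * mean_log + log_z

    res = optimize.minimize_scalar(
        nll, bounds=(1.000001 if x_max is None else 0.01, 10.0),
        method="bounded",
    )
    return float(res.x)


def _discrete_ks(x: np.ndarray, x_min: int, x_max: int | None,
                 alpha: float) -> float:
    hi = int(x.max())
    support = np.arange(x_min, hi + 1, dtype=float)
    pmf = np.exp(_discrete_logpmf(support, alpha, x_min, x_max))
    cdf = np.cumsum(pmf)
    counts = np.bincount(x.astype(int), minlength=hi + 1)[x_min:]
    emp = np.cumsum(counts) / len(x)
    return float(np.max(np.abs(emp - cdf)))


def fit_power_law(
    sample: DurationSample | np.ndarray | Sequence[float],
    discrete: bool | None = None,
    x_min: float | None = None,
    x_max: int | None = None,
    unit: float = 1.0,
) -> PowerLawFit:
    """Maximum-likelihood power-law fit with KS-optimal x_min.

    If ``x_min`` is given, only the exponent is estimated; otherwise every
    distinct observed value (thinned to at most 100 candidates) is tried and
    the one minimising the KS distance of its tail fit wins.  ``discrete``
    defaults to True for tick-quantised kinds (encounter durations, gaps,
    counts) and False for continuous contact minutes; discrete data are
    rescaled by ``unit`` (e.g. the tick length in seconds) to an integer grid.
    ``x_max`` fits an upper-truncated discrete power law, appropriate when a
    hard ceiling (the school day) cuts the tail.
    """
    if isinstance(sample, DurationSample):
        values = sample.values
        if discrete is None:
            discrete = sample.kind != "contact_duration"
            if sample.kind in ("encounter_duration", "inter_encounter_gap") \
                    and unit == 1.0:
                diffs = np.unique(values)
                if len(diffs) > 1:
                    unit = float(np.gcd.reduce(diffs.astype(int)))
    else:
        values = np.asarray(sample, dtype=float)
        if discrete is None:
            discrete = bool(np.allclose(values, np.round(values)))
    values = values[values > 0]
    if len(values) < MIN_TAIL:
        raise FitError(f"need >= {MIN_TAIL} positive values, got {len(values)}")
    if np.ptp(values) == 0:
        raise FitError("degenerate sample: all values equal")
    if discrete:
        scaled = values / unit
        if not np.allclose(scaled, np.round(scaled)):
            raise FitError("discrete fit requires values on an integer grid")
        x = np.round(scaled).astype(int)
    else:
        x = values

    def tail_fit(xm) -> PowerLawFit | None:
        tail = x[x >= xm]
        if len(tail) < MIN_TAIL or np.ptp(tail) == 0:
            return None
        if discrete:
            alpha = _discrete_mle(tail, int(xm), x_max)
            ks = _discrete_ks(tail, int(xm), x_max, alpha)
        else:
            alpha = _continuous_mle(tail, float(xm))
            ks = _continuous_ks(tail, float(xm), alpha)
        return PowerLawFit(-alpha, float(xm) * (unit if discrete else 1.0),
                           ks, len(tail), discrete)

    if x_min is not None:
        xm = x_min / unit if discrete else x_min
        fit = tail_fit(int(round(xm)) if discrete else xm)
        if fit is None:
            raise FitError(f"fewer than {MIN_TAIL} values above x_min")
        return fit

    candidates = np.unique(x)[:-1]  # the max alone cannot form a tail
    if len(candidates) > 100:
        qs = np.linspace(0, 1, 100)
        candidates = np.unique(np.quantile(candidates, qs, method="nearest"))
    best: PowerLawFit | None = None
    for xm in candidates:
        fit = tail_fit(int(xm) if discrete else float(xm))
        if fit is not None and (best is None or fit.ks < best.ks):
            best = fit
    if best is None:
        raise FitError("no candidate x_min leaves a fittable tail")
    return best


def fraction_within(
    sample: DurationSample | np.ndarray | Sequence[float],
    bound: float,
    side: Literal["le", "gt"] = "le",
) -> float:
    """Fraction of values ≤ bound (``le``) or > bound (``gt``).

    Computed on the full, unthresholded sample — e.g. the proportion of all
    contacts lasting at most 5 minutes.
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    values = sample.values if isinstance(sample, DurationSample) else \
        np.asarray(sample, dtype=float)
    if len(values) == 0:
        raise ValueError("empty sample")
    if side == "le":
        return float(np.mean(values <= bound))
    if side == "gt":
        return float(np.mean(values > bound))
    raise ValueError(f"unknown side {side!r}")


def degree_distribution(net: nx.Graph) -> pd.Series:
    """Exact histogram N_k: the number of students with k contacts."""
    degrees = [d for _, d in net.degree()]
    if not degrees:
        return pd.Series(dtype=int, name="N_k")
    counts = np.bincount(degrees)
    ks = np.nonzero(counts)[0]
    return pd.Series(counts[ks], index=pd.Index(ks, name="k"), name="N_k")


def rssi_exponential_rate(
    records: Sequence[BeaconRecord] | np.ndarray | Sequence[float],
) -> float:
    """Exponential-rate MLE for the signal-strength magnitudes |rssi|.

    Beacon signal strengths are empirically exponential in magnitude; the MLE
    rate is 1 / mean(|rssi|).  Descriptive only — no threshold decisions
    depend on it.
    """
    if len(records) == 0:
        raise ValueError("empty input")
    if isinstance(records[0], BeaconRecord):
        mags = np.array([abs(r.rssi) for r in records], dtype=float)
    else:
        mags = np.abs(np.asarray(records, dtype=float))
    mean = float(np.mean(mags))
    if mean == 0:
        raise FitError("degenerate: all magnitudes zero")
    return 1.0 / mean
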