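"""Agonistic event logs and win/loss sociomatrices.

Observers score group-housed mice by all-occurrence sampling, recording the
winner and loser of every agonistic interaction together with a behavior
label from a five-value ethogram (fighting, chasing, mounting, subordinate
posture, induced flee).  The winner of an encounter is the animal that
chased, bit, mounted, or forced the other to display subordinate behavior;
for subordinate-posture and induced-flee events the *actor* is therefore the
individual that forced the display, not the displaying animal.

This module provides the event data model, CSV I/O, the two-second
co-occurrence priority rule, and construction of winner-by-loser frequency
sociomatrices from event streams.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Behavior",
    "PRIORITY_ORDER",
    "AgonisticEvent",
    "ObservationSchedule",
    "WinLossMatrix",
    "SchemaError",
    "EventValidationError",
    "read_event_log",
    "write_event_log",
    "apply_priority_rule",
    "build_win_loss_matrix",
    "cumulative_matrix_through_day",
    "hourly_rates",
]


class Behavior(str, enum.Enum):
    """The five-behavior agonistic ethogram."""

    FIGHTING = "fighting"
    CHASING = "chasing"
    MOUNTING = "mounting"
    SUBORDINATE_POSTURE = "subordinate_posture"
    INDUCED_FLEE = "induced_flee"

    @classmethod
    def coerce(cls, value: "Behavior | str") -> "Behavior":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            valid = ", ".join(b.value for b in cls)
            raise ValueError(
                f"unknown behavior {value!r}; expected one of: {valid}"
            ) from None


#: Resolution order for co-occurring behaviors, most to least dominant.
PRIORITY_ORDER: tuple[Behavior, ...] = (
    Behavior.FIGHTING,
    Behavior.CHASING,
    Behavior.MOUNTING,
    Behavior.SUBORDINATE_POSTURE,
    Behavior.INDUCED_FLEE,
)

_PRIORITY_RANK = {b: i for i, b in enumerate(PRIORITY_ORDER)}


class SchemaError(ValueError):
    """An input table is missing a required column."""


class EventValidationError(ValueError):
    """A row of an event log violates the event invariants."""


@dataclass(frozen=True)
class AgonisticEvent:
    """One timed winner/loser interaction.

    Parameters
    ----------
    cohort : str
        Social-group label.
    day : int
        1-based observation day.
    actor : str
        The winner of the encounter.
    recipient : str
        The loser of the encounter.
    behavior : Behavior
        Ethogram label.
    time_s : float, optional
        Seconds from the start of that day's observation session.  Only
        required when the co-occurrence priority rule is applied.
    """

    cohort: str
    day: int
    actor: str
    recipient: str
    behavior: Behavior
    time_s: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "behavior", Behavior.coerce(self.behavior))
        if self.actor == self.recipient:
            raise EventValidationError(
                f"actor and recipient are both {self.actor!r}"
            )
        if self.day < 1:
            raise EventValidationError(f"day must be >= 1, got {self.day}")
        if self.time_s is not None and self.time_s < 0:
            raise EventValidationError(f"time_s must be >= 0, got {self.time_s}")


@dataclass(frozen=True)
class ObservationSchedule:
    """Observation effort: hours watched per day.

    ``hours_per_day`` may be a scalar (the standard protocol observes each
    group 2 h per day) or a mapping from day to hours for uneven effort.
    """

    hours_per_day: float | Mapping[int, float] = 2.0
    n_days: int = 14

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for d in self.days():
            if self.hours_for(d) <= 0:
                raise ValueError(f"hours for day {d} must be > 0")

    def days(self) -> range:
        return range(1, self.n_days + 1)

    def hours_for(self, day: int) -> float:
        if not 1 <= day <= self.n_days:
            raise KeyError(f"day {day} outside schedule 1..{self.n_days}")
        if isinstance(self.hours_per_day, Mapping):
            try:
                return float(self.hours_per_day[day])
            except KeyError:
                raise KeyError(f"day {day} not in schedule mapping") from None
        return float(self.hours_per_day)

    @property
    def total_hours(self) -> float:
        return sum(self.hours_for(d) for d in self.days())


@dataclass
class WinLossMatrix:
    """N x N frequency sociomatrix of wins.

    Entry ``counts[i, j]`` is the total number of wins of individual
    ``ids[i]`` over individual ``ids[j]`` (rows are winners, matching the
    conventional sociomatrix orientation).  The diagonal is structurally
    zero.
    """

    ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids")
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {n} ids"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diagonal(self.counts).any():
            raise ValueError("diagonal must be zero")

    # -- basic quantities -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())

    def dyadic_totals(self) -> np.ndarray:
        """n_ij = s_ij + s_ji, the total interactions per ordered dyad."""
        return self.counts + self.counts.T

    def wins(self) -> np.ndarray:
        """Total wins per individual (row sums)."""
        return self.counts.sum(axis=1)

    def losses(self) -> np.ndarray:
        """Total losses per individual (column sums)."""
        return self.counts.sum(axis=0)

    def permuted(self, order: Sequence[int]) -> "WinLossMatrix":
        """Simultaneously reorder rows, columns and ids."""
        idx = np.asarray(order)
        if sorted(idx.tolist()) != list(range(self.n)):
            raise ValueError("order must be a permutation of 0..N-1")
        return WinLossMatrix(
            ids=[self.ids[i] for i in idx],
            counts=self.counts[np.ix_(idx, idx)],
        )

    def reordered_by_ids(self, ids: Sequence[str]) -> "WinLossMatrix":
        pos = {v: k for k, v in enumerate(self.ids)}
        return self.permuted([pos[str(i)] for i in ids])

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        """Write a square CSV, rows = winners, with an id header row/column."""
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "WinLossMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("matrix CSV row and column ids differ")
        return cls(ids=list(df.index), counts=df.to_numpy())


_DEFAULT_SCHEMA = {
    "cohort": "cohort",
    "day": "day",
    "time_s": "time_s",
    "actor": "actor",
    "recipient": "recipient",
    "behavior": "behavior",
}


def read_event_log(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[AgonisticEvent]:
    """Read an agonistic event log from CSV.

    Required columns: cohort, day, actor, recipient, behavior; ``time_s`` is
    optional and only needed for the priority rule.  ``schema`` maps those
    canonical names to the file's actual column names.  Events are returned
    stably sorted by (cohort, day, time_s) where time is present.

    Raises
    ------
    SchemaError
        If a required column is missing.
    EventValidationError
        If a row has an unknown behavior or actor == recipient; the message
        carries the 1-based data row number.
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canonical in ("cohort", "day", "actor", "recipient", "behavior"):
        if colmap[canonical] not in df.columns:
            raise SchemaError(
                f"event log is missing required column {colmap[canonical]!r}"
            )
    has_time = colmap["time_s"] in df.columns

    events: list[AgonisticEvent] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        time_raw = rec.get(colmap["time_s"], "") if has_time else ""
        try:
            events.append(
                AgonisticEvent(
                    cohort=rec[colmap["cohort"]],
                    day=int(rec[colmap["day"]]),
                    time_s=float(time_raw) if time_raw != "" else None,
                    actor=rec[colmap["actor"]],
                    recipient=rec[colmap["recipient"]],
                    behavior=rec[colmap["behavior"]],
                )
            )
        except (EventValidationError, ValueError) as exc:
            raise EventValidationError(f"row {row_number}: {exc}") from None
    events.sort(
        key=lambda e: (e.cohort, e.day, e.time_s if e.time_s is not None else -1.0)
    )
    return events


def write_event_log(events: Iterable[AgonisticEvent], path: str | Path) -> None:
    """Write events to the standard CSV layout."""
    df = events_to_frame(events)
    df.to_csv(path, index=False)


def events_to_frame(events: Iterable[AgonisticEvent]) -> pd.DataFrame:
    rows = [
        {
            "cohort": e.cohort,
            "day": e.day,
            "time_s": e.time_s,
            "actor": e.actor,
            "recipient": e.recipient,
            "behavior": e.behavior.value,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows, columns=["cohort", "day", "time_s", "actor", "recipient", "behavior"]
    )


def apply_priority_rule(
    events: Sequence[AgonisticEvent], window_s: float = 2.0
) -> list[AgonisticEvent]:
    """Resolve co-occurring same-dyad behaviors to the highest-priority one.

    Scoring protocols record behaviors between the same two females that
    co-occur within ``window_s`` seconds as a single event, keeping the
    highest-priority behavior (fighting > chasing > mounting > subordinate
    posture > induced flee).  Clusters are anchored at the earliest event of
    a run: every same-dyad event within ``window_s`` of the cluster's first
    member joins the cluster, and the whole cluster collapses to one event.
    The operation is idempotent and order-independent.
    """
    if window_s < 0:
        raise ValueError("window_s must be >= 0")
    missing = [e for e in events if e.time_s is None]
    if missing:
        raise ValueError(
            "events lack time_s; the priority rule needs within-session times "
            "— skip the rule for untimed logs"
        )

    def dyad_key(e: AgonisticEvent) -> tuple:
        return (e.cohort, e.day, frozenset((e.actor, e.recipient)))

    groups: dict[tuple, list[AgonisticEvent]] = {}
    for e in events:
        groups.setdefault(dyad_key(e), []).append(e)

    kept: list[AgonisticEvent] = []
    for members in groups.values():
        members.sort(key=lambda e: e.time_s)  # type: ignore[arg-type]
        cluster: list[AgonisticEvent] = []
        for e in members:
            if cluster and e.time_s - cluster[0].time_s <= window_s:  # type: ignore[operator]
                cluster.append(e)
            else:
                if cluster:
                    kept.append(_resolve_cluster(cluster))
                cluster = [e]
        if cluster:
            kept.append(_resolve_cluster(cluster))
    # fully deterministic order, independent of input arrangement
    kept.sort(
        key=lambda e: (e.cohort, e.day, e.time_s, e.actor, e.recipient,
                       _PRIORITY_RANK[e.behavior])
    )
    return kept


def _resolve_cluster(cluster: list[AgonisticEvent]) -> AgonisticEvent:
    # highest priority wins; ties broken by earliest time (cluster is sorted).
    # The kept event takes the cluster's onset time so that consecutive kept
    # events stay > window apart, making the rule idempotent.
    best = min(cluster, key=lambda e: _PRIORITY_RANK[e.behavior])
    if best.time_s == cluster[0].time_s:
        return best
    return dataclasses.replace(best, time_s=cluster[0].time_s)


def build_win_loss_matrix(
    events: Iterable[AgonisticEvent],
    behaviors: Iterable[Behavior | str] | None = None,
    ids: Sequence[str] | None = None,
) -> WinLossMatrix:
    """Aggregate events into a winner-by-loser frequency sociomatrix.

    Parameters
    ----------
    events
        Retained agonistic events (a single cohort is assumed; mixing
        cohorts simply pools their counts).
    behaviors
        Ethogram subset to count; default all five behaviors.
    ids
        Optional fixed individual ordering.  Individuals with zero events
        still appear; an event naming an id outside the list is an error.
    """
    wanted = (
        {Behavior.coerce(b) for b in behaviors}
        if behaviors is not None
        else set(Behavior)
    )
    events = [e for e in events if e.behavior in wanted]
    if ids is None:
        seen: dict[str, None] = {}
        for e in events:
            seen.setdefault(e.actor)
            seen.setdefault(e.recipient)
        id_list = sorted(seen)
    else:
        id_list = [str(i) for i in ids]
        known = set(id_list)
        for e in events:
            if e.actor not in known or e.recipient not in known:
                raise ValueError(
                    f"event individuals ({e.actor}, {e.recipient}) not in the "
                    "fixed id list"
                )
    pos = {v: k for k, v in enumerate(id_list)}
    counts = np.zeros((len(id_list), len(id_list)), dtype=np.int64)
    for e in events:
        counts[pos[e.actor], pos[e.recipient]] += 1
    return WinLossMatrix(ids=id_list, counts=counts)


def cumulative_matrix_through_day(
    events: Iterable[AgonisticEvent],
    d: int,
    behaviors: Iterable[Behavior | str] | None = None,
    ids: Sequence[str] | None = None,
) -> WinLossMatrix:
    """Sociomatrix from all events with day <= d (hierarchy-emergence use)."""
    if d < 1:
        raise ValueError(f"day must be >= 1, got {d}")
    return build_win_loss_matrix(
        [e for e in events if e.day <= d], behaviors=behaviors, ids=ids
    )


def hourly_rates(
    events: Iterable[AgonisticEvent],
    schedule: ObservationSchedule,
    group_by: str = "individual",
    direction: str = "given",
    ranking: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Events per observed hour, grouped by individual, rank, day or behavior.

    ``direction`` selects whether an event is attributed to its winner
    ("given") or its loser ("received").  Zero-event cells are reported as 0
    rather than dropped; for ``group_by="rank"`` a full ``ranking`` (rank 1 =
    most dominant) must be supplied.

    Returns a DataFrame with the grouping column(s), ``count``, ``hours``
    and ``rate``.
    """
    if direction not in ("given", "received"):
        raise ValueError("direction must be 'given' or 'received'")
    if group_by not in ("individual", "rank", "day", "behavior"):
        raise ValueError("group_by must be individual, rank, day or behavior")
    if group_by == "rank" and ranking is None:
        raise ValueError("group_by='rank' requires a ranking")

    events = list(events)
    for e in events:
        if not 1 <= e.day <= schedule.n_days:
            raise KeyError(
                f"event on day {e.day} outside the observation schedule"
            )

    def owner(e: AgonisticEvent) -> str:
        return e.actor if direction == "given" else e.recipient

    total_hours = schedule.total_hours
    if group_by == "day":
        counts = {d: 0 for d in schedule.days()}
        for e in events:
            counts[e.day] += 1
        rows = [
            {"day": d, "count": c, "hours": schedule.hours_for(d)}
            for d, c in counts.items()
        ]
    elif group_by == "behavior":
        counts = {b.value: 0 for b in Behavior}
        for e in events:
            counts[e.behavior.value] += 1
        rows = [
            {"behavior": b, "count": c, "hours": total_hours}
            for b, c in counts.items()
        ]
    else:
        if group_by == "rank":
            individuals = [str(i) for i in ranking]  # type: ignore[union-attr]
        else:
            individuals = sorted({x for e in events for x in (e.actor, e.recipient)})
        counts = {i: 0 for i in individuals}
        for e in events:
            who = owner(e)
            if who not in counts:
                raise ValueError(f"individual {who!r} not covered by the ranking")
            counts[who] += 1
        rows = [
            {"individual": i, "count": c, "hours": total_hours}
            for i, c in counts.items()
        ]
        if group_by == "rank":
            for rank, row in enumerate(rows, start=1):
                row["rank"] = rank
    df = pd.DataFrame(rows)
    df["rate"] = df["count"] / df["hours"]
    return df
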