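"""Event-by-event Glicko ratings for dominance trajectories.

The Glicko system tracks a rating r and a rating deviation RD (an
uncertainty) per individual.  Here every behavioral interaction is one
rating period: all individuals' deviations inflate by the constant c
(capped), then the winner and loser update by the standard Glicko
equations; bystanders keep their inflated deviation and unchanged rating.
All individuals start at rating 2200, and points move from loser to winner
in proportion to how surprising the outcome was given the rating gap.

Plotting each individual's rating against successive events visualizes how
dominance ranks emerge and stabilize over the housing period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .events import AgonisticEvent

if TYPE_CHECKING:
    from .metrics import DavidsScoreSet

__all__ = [
    "GlickoConfig",
    "GlickoState",
    "GlickoTrajectory",
    "init_states",
    "update_event",
    "run_trajectory",
    "select_dom_sub",
]


@dataclass(frozen=True)
class GlickoConfig:
    """Glicko parameters.

    ``initial_rating`` 2200 and per-period inflation constant ``c`` = 3
    follow the dominance-hierarchy protocol; the initial deviation 300 and
    cap 350 are the system's common defaults.  ``q = ln(10)/400`` is the
    Glicko scale constant.
    """

    initial_rating: float = 2200.0
    initial_deviation: float = 300.0
    c: float = 3.0
    deviation_cap: float = 350.0
    q: float = math.log(10) / 400

    def __post_init__(self) -> None:
        if min(self.initial_rating, self.initial_deviation, self.q) <= 0:
            raise ValueError("Glicko parameters must be positive")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if self.initial_deviation > self.deviation_cap:
            raise ValueError("initial_deviation must not exceed deviation_cap")


@dataclass
class GlickoState:
    """One individual's current (rating, deviation)."""

    rating: float
    deviation: float


def init_states(
    ids: Sequence[str], config: GlickoConfig = GlickoConfig()
) -> dict[str, GlickoState]:
    """Fresh states: every individual at the initial rating and deviation."""
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids")
    return {
        i: GlickoState(config.initial_rating, config.initial_deviation)
        for i in ids
    }


def _g(rd: float, q: float) -> float:
    return 1.0 / math.sqrt(1.0 + 3.0 * q * q * rd * rd / math.pi**2)


def update_event(
    states: Mapping[str, GlickoState],
    winner: str,
    loser: str,
    config: GlickoConfig = GlickoConfig(),
) -> dict[str, GlickoState]:
    """One rating period: inflate all deviations, update the two contestants.

    Every individual's deviation first inflates to
    ``min(sqrt(RD^2 + c^2), cap)``.  The winner (score 1) and loser
    (score 0) then update by the Glicko equations: with g(RD) =
    1/sqrt(1 + 3 q^2 RD^2 / pi^2) and expected score
    E = 1/(1 + 10^(-g(RD_opp)(r - r_opp)/400)),

        r'  = r + q/(1/RD^2 + 1/d^2) * g(RD_opp) * (score - E)
        RD' = sqrt(1/(1/RD^2 + 1/d^2)),  1/d^2 = q^2 g(RD_opp)^2 E(1-E).

    Returns a new state dict; the input is not mutated.
    """
    if winner == loser:
        raise ValueError("winner and loser must differ")
    for who in (winner, loser):
        if who not in states:
            raise KeyError(f"unknown individual {who!r}")
    q = config.q
    inflated = {
        i: GlickoState(
            st.rating,
            min(math.sqrt(st.deviation**2 + config.c**2), config.deviation_cap),
        )
        for i, st in states.items()
    }

    def updated(me: GlickoState, opp: GlickoState, score: float) -> GlickoState:
        g_opp = _g(opp.deviation, q)
        e = 1.0 / (1.0 + 10.0 ** (-g_opp * (me.rating - opp.rating) / 400.0))
        d2_inv = q * q * g_opp * g_opp * e * (1.0 - e)
        denom = 1.0 / me.deviation**2 + d2_inv
        return GlickoState(
            rating=me.rating + q / denom * g_opp * (score - e),
            deviation=math.sqrt(1.0 / denom),
        )

    w, l = inflated[winner], inflated[loser]
    inflated[winner] = updated(w, l, 1.0)
    inflated[loser] = updated(l, w, 0.0)
    return inflated


@dataclass
class GlickoTrajectory:
    """Per-event rating history for a cohort.

    ``history`` holds one row per (event index, individual):
    event_index 0 is the initial state; ranks are dense 1..N by descending
    rating with ties broken by total wins so far, then label.
    """

    ids: list[str]
    history: pd.DataFrame = field(repr=False)
    final_states: dict[str, GlickoState] = field(default_factory=dict)

    def final_order(self) -> list[str]:
        """Ids from highest to lowest final rating (stable tie-breaks)."""
        last = self.history[self.history.event_index == self.history.event_index.max()]
        return list(last.sort_values("rank")["individual"])

    def to_csv(self, path) -> None:
        self.history.to_csv(path, index=False)


def run_trajectory(
    events: Iterable[AgonisticEvent],
    ids: Sequence[str] | None = None,
    config: GlickoConfig = GlickoConfig(),
) -> GlickoTrajectory:
    """Sequentially apply :func:`update_event` over an ordered event log.

    ``ids`` fixes the individual set (individuals with no events keep the
    initial rating); by default the ids present in the log are used.  The
    trajectory records every individual's (rating, deviation, rank) after
    every event, with event index 0 for the initial state.
    """
    events = list(events)
    if ids is None:
        seen: dict[str, None] = {}
        for e in events:
            seen.setdefault(e.actor)
            seen.setdefault(e.recipient)
        ids = sorted(seen)
    states = init_states(ids, config)
    wins = {i: 0 for i in states}

    rows: list[dict] = []

    def snapshot(idx: int) -> None:
        order = sorted(
            states, key=lambda i: (-states[i].rating, -wins[i], i)
        )
        rank = {i: k + 1 for k, i in enumerate(order)}
        for i, st in states.items():
            rows.append(
                {
                    "event_index": idx,
                    "individual": i,
                    "rating": st.rating,
                    "deviation": st.deviation,
                    "rank": rank[i],
                }
            )

    snapshot(0)
    for idx, e in enumerate(events, start=1):
        states = update_event(states, e.actor, e.recipient, config)
        wins[e.actor] += 1
        snapshot(idx)
    history = pd.DataFrame(
        rows, columns=["event_index", "individual", "rating", "deviation", "rank"]
    )
    return GlickoTrajectory(
        ids=list(ids), history=history, final_states=dict(states)
    )


def select_dom_sub(
    trajectory: GlickoTrajectory,
    ds: "DavidsScoreSet",
    k: int = 2,
) -> tuple[list[str], list[str], bool]:
    """Most dominant / most subordinate individuals by Glicko, checked
    against David's scores.

    Returns (top-k, bottom-k) by final Glicko rating plus a flag that is
    True iff the David's-score ordering selects the same two sets.  On
    disagreement the Glicko sets are returned and the caller can consult
    ``ds.order()`` for the alternative.
    """
    n = len(trajectory.ids)
    if k < 0 or 2 * k > n:
        raise ValueError(f"k must satisfy 0 <= 2k <= N, got k={k}, N={n}")
    if k == 0:
        return [], [], True
    glicko_order = trajectory.final_order()
    ds_order = ds.order()
    top = glicko_order[:k]
    bottom = glicko_order[-k:]
    agree = set(top) == set(ds_order[:k]) and set(bottom) == set(ds_order[-k:])
    return top, bottom, agree
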