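"""Hierarchy emergence over days and estrus-state descriptive summaries.

Group-housed female mice can form significantly linear hierarchies within a
day or two of introduction.  :func:`emergence_by_day` recomputes linearity
(Landau's modified h') and triangle transitivity with their randomization
p-values on the cumulative win/loss data up to each observation day, flags
significance at a chosen alpha, and reports the earliest day from which
linearity holds through the end of the study.

Estrus state is scored daily by vaginal cytology into proestrus, estrus,
metestrus, diestrus (plus undetermined smears).  The summaries here are
purely descriptive: per-individual state proportions, rank-by-state
day-count crosstabs, and hourly agonistic rates split by the day's estrus
state (medians and IQRs; no model fitting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import AgonisticEvent, Behavior, ObservationSchedule
from .events import cumulative_matrix_through_day
from .metrics import landaus_h_prime, triangle_transitivity
from .significance import NullScheme, randomization_p

__all__ = [
    "ESTRUS_STATES",
    "EstrusRecord",
    "EmergenceTable",
    "emergence_by_day",
    "read_estrus_log",
    "estrus_proportions",
    "estrus_rank_crosstab",
    "rates_by_estrus_state",
]

#: The four determinable cycle states, in cycle order, plus the
#: undetermined-smear label.
ESTRUS_STATES = ("proestrus", "estrus", "metestrus", "diestrus")
UNDETERMINED = "undetermined"
_ALL_STATES = ESTRUS_STATES + (UNDETERMINED,)


@dataclass(frozen=True)
class EstrusRecord:
    """One daily smear call for one individual."""

    cohort: str
    individual: str
    day: int
    state: str

    def __post_init__(self) -> None:
        if self.state not in _ALL_STATES:
            raise ValueError(
                f"unknown estrus state {self.state!r}; expected one of {_ALL_STATES}"
            )
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")


def read_estrus_log(path) -> list[EstrusRecord]:
    """Read an estrus CSV with columns cohort,individual,day,state."""
    df = pd.read_csv(path, dtype=str)
    for col in ("cohort", "individual", "day", "state"):
        if col not in df.columns:
            raise ValueError(f"estrus log missing required column {col!r}")
    return [
        EstrusRecord(
            cohort=r.cohort, individual=r.individual, day=int(r.day), state=r.state
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class EmergenceTable:
    """Per-day cumulative linearity metrics for one cohort.

    ``table`` has one row per day: h_prime, p_h, ttri, p_ttri, the
    significance flags at ``alpha``, and event counts.  ``first_stable_day``
    is the earliest day from which the h' significance flag holds on every
    subsequent day through the final day (None if never); a transiently
    significant day that later loses significance does not qualify.
    """

    cohort: str
    table: pd.DataFrame
    alpha: float
    first_stable_day: int | None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def emergence_by_day(
    events: Sequence[AgonisticEvent],
    n_days: int | None = None,
    ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    n_randomizations: int = 1000,
    n_resolutions: int = 1000,
    seed: int | None = None,
    cohort: str | None = None,
) -> EmergenceTable:
    """Cumulative h' and ttri with randomization p-values for each day.

    For each day d the win/loss matrix over events with day <= d is built
    and h' and ttri computed together with one-sided randomization
    p-values under the uniform-tournament null.  Days whose cumulative
    matrix supports no statistic (fewer than 3 interacting individuals, or
    no complete triad for ttri) are reported as NaN with flag False.
    """
    events = list(events)
    if not events and n_days is None:
        raise ValueError("no events and no n_days given")
    if n_days is None:
        n_days = max(e.day for e in events)
    if cohort is None:
        cohorts = {e.cohort for e in events}
        cohort = cohorts.pop() if len(cohorts) == 1 else "+".join(sorted(cohorts))
    rng = np.random.default_rng(seed)

    rows = []
    for d in range(1, n_days + 1):
        W = cumulative_matrix_through_day(events, d, ids=ids)
        row = {
            "cohort": cohort,
            "day": d,
            "n_events": W.n_events,
            "h_prime": math.nan,
            "p_h": math.nan,
            "sig_h": False,
            "ttri": math.nan,
            "p_ttri": math.nan,
            "sig_ttri": False,
        }
        if W.n >= 3 and W.n_events > 0:
            sub = int(rng.integers(0, 2**31 - 1))
            row["h_prime"] = landaus_h_prime(
                W, n_resolutions=n_resolutions, seed=sub
            )
            row["p_h"] = randomization_p(
                W,
                "h_prime",
                NullScheme(m=n_randomizations, seed=int(rng.integers(0, 2**31 - 1))),
                n_resolutions=min(n_resolutions, 100),
            )
            row["sig_h"] = row["p_h"] <= alpha
            _, tt = triangle_transitivity(W)
            if not math.isnan(tt):
                row["ttri"] = tt
                row["p_ttri"] = randomization_p(
                    W,
                    "ttri",
                    NullScheme(
                        m=n_randomizations, seed=int(rng.integers(0, 2**31 - 1))
                    ),
                )
                row["sig_ttri"] = row["p_ttri"] <= alpha
        rows.append(row)
    table = pd.DataFrame(rows)

    first_stable: int | None = None
    flags = list(table["sig_h"])
    for d in range(n_days, 0, -1):
        if flags[d - 1]:
            first_stable = d
        else:
            break
    return EmergenceTable(
        cohort=cohort, table=table, alpha=alpha, first_stable_day=first_stable
    )


# ---------------------------------------------------------------------------
# Estrus summaries
# ---------------------------------------------------------------------------

def estrus_proportions(records: Iterable[EstrusRecord]) -> pd.DataFrame:
    """Per-individual proportion of determined days spent in each state.

    Undetermined smears are excluded from the denominator and reported in a
    separate ``n_undetermined`` column; proportions over the four
    determined states sum to 1 per individual.  An individual whose smears
    are all undetermined gets NaN proportions.
    """
    records = list(records)
    if not records:
        raise ValueError("no estrus records")
    rows = []
    by_ind: dict[tuple[str, str], list[EstrusRecord]] = {}
    for r in records:
        by_ind.setdefault((r.cohort, r.individual), []).append(r)
    for (cohort, ind), recs in sorted(by_ind.items()):
        seen_days = [r.day for r in recs]
        if len(set(seen_days)) != len(seen_days):
            raise ValueError(
                f"duplicate estrus record for {ind!r} (cohort {cohort!r})"
            )
        determined = [r for r in recs if r.state != UNDETERMINED]
        n_det = len(determined)
        row = {
            "cohort": cohort,
            "individual": ind,
            "n_determined": n_det,
            "n_undetermined": len(recs) - n_det,
        }
        for state in ESTRUS_STATES:
            row[state] = (
                sum(r.state == state for r in determined) / n_det
                if n_det
                else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def estrus_rank_crosstab(
    records: Iterable[EstrusRecord],
    ranking: Sequence[str],
) -> pd.DataFrame:
    """Rank x state table of individual-day counts (determined smears only).

    ``ranking`` lists ids from most (rank 1) to least dominant; margins sum
    to the total number of determined records.
    """
    ranking = [str(i) for i in ranking]
    rank_of = {ind: k + 1 for k, ind in enumerate(ranking)}
    table = pd.DataFrame(
        0,
        index=pd.Index(range(1, len(ranking) + 1), name="rank"),
        columns=list(ESTRUS_STATES),
    )
    for r in records:
        if r.state == UNDETERMINED:
            continue
        if r.individual not in rank_of:
            raise ValueError(f"individual {r.individual!r} not in ranking")
        table.loc[rank_of[r.individual], r.state] += 1
    return table


def rates_by_estrus_state(
    events: Iterable[AgonisticEvent],
    records: Iterable[EstrusRecord],
    schedule: ObservationSchedule,
    direction: str = "given",
) -> tuple[pd.DataFrame, int]:
    """Hourly agonistic rate per individual-day, summarized by estrus state.

    Each individual-day's rate (events in which the individual was the
    winner for ``direction="given"``, the loser for ``"received"``, divided
    by that day's observed hours) is assigned to the day's estrus state.
    Returns a summary DataFrame of median and quartiles per (state,
    behavior) — zero-rate days included in the denominators — plus the count
    of events excluded because their (individual, day) had no determined
    estrus record.
    """
    if direction not in ("given", "received"):
        raise ValueError("direction must be 'given' or 'received'")
    records = list(records)
    state_of: dict[tuple[str, str, int], str] = {}
    for r in records:
        state_of[(r.cohort, r.individual, r.day)] = r.state

    # rate table: one row per (individual, day, behavior), then attach state
    individuals = sorted({(r.cohort, r.individual) for r in records})
    counts: dict[tuple[str, str, int, str], int] = {}
    excluded = 0
    for e in events:
        who = e.actor if direction == "given" else e.recipient
        key = (e.cohort, who, e.day)
        state = state_of.get(key)
        if state is None or state == UNDETERMINED:
            excluded += 1
            continue
        counts[(e.cohort, who, e.day, e.behavior.value)] = (
            counts.get((e.cohort, who, e.day, e.behavior.value), 0) + 1
        )

    rows = []
    for cohort, ind in individuals:
        for day in schedule.days():
            state = state_of.get((cohort, ind, day))
            if state is None or state == UNDETERMINED:
                continue
            hours = schedule.hours_for(day)
            for b in Behavior:
                c = counts.get((cohort, ind, day, b.value), 0)
                rows.append(
                    {
                        "cohort": cohort,
                        "individual": ind,
                        "day": day,
                        "state": state,
                        "behavior": b.value,
                        "rate": c / hours,
                    }
                )
    per_day = pd.DataFrame(rows)
    if per_day.empty:
        raise ValueError("no individual-days with determined estrus records")
    summary = (
        per_day.groupby(["state", "behavior"])["rate"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n_days="count",
        )
        .reset_index()
    )
    return summary, excluded
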