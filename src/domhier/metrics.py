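"""Sociomatrix-level dominance statistics.

Given a winner-by-loser frequency sociomatrix this module computes the
standard descriptive measures of hierarchy structure:

* David's scores (a win-proportion measure adjusted for opponent strength)
  and the hierarchy **steepness** derived from them;
* **Landau's modified h'**, the linearity of the implied dominance order,
  with tied/unknown dyads handled by repeated random resolution;
* **triangle transitivity** (ttri), the scaled proportion of transitive
  triads among fully decided triads;
* **directional consistency** (DC), the fraction of interactions flowing in
  each dyad's majority direction;
* **despotism**, the alpha's share of all wins;
* the **Gini coefficient** of win (or loss) counts;
* the **I&SI rank order**, which minimizes the number and strength of
  dyadic inconsistencies.

All statistics are invariant under simultaneous row/column permutation of
the matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import WinLossMatrix

__all__ = [
    "DavidsScoreSet",
    "MetricsReport",
    "relation_signs",
    "davids_scores",
    "steepness",
    "landaus_h",
    "landaus_h_prime",
    "triangle_transitivity",
    "directional_consistency",
    "despotism",
    "gini",
    "rank_isi",
    "isi_costs",
    "full_report",
]


def relation_signs(W: WinLossMatrix) -> np.ndarray:
    """Ordered-dyad relations: +1 win, -1 loss, 0 tie, NaN unknown.

    ``signs[i, j] = +1`` iff i beat j more often than the reverse
    (s_ij > s_ji); 0 marks a tie with at least one interaction; NaN marks a
    never-interacting dyad.  The diagonal is NaN.
    """
    s = W.counts.astype(float)
    signs = np.sign(s - s.T)
    signs[s + s.T == 0] = np.nan
    np.fill_diagonal(signs, np.nan)
    return signs


# ---------------------------------------------------------------------------
# David's scores and steepness
# ---------------------------------------------------------------------------

@dataclass
class DavidsScoreSet:
    """Per-individual David's score components.

    ``w`` is the sum of dyadic win proportions, ``w2`` the opponent-weighted
    version, ``l``/``l2`` the loss-side analogues, ``ds = w + w2 - l - l2``
    and ``norm_ds = (ds + N(N-1)/2) / N`` which lies in [0, N-1].
    ``ds_rank[i]`` is individual i's 1-based position in descending
    ``norm_ds`` (ties broken by total wins then label, for determinism).
    """

    ids: list[str]
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    ds: np.ndarray
    norm_ds: np.ndarray
    ds_rank: np.ndarray = field(default=None)  # type: ignore[assignment]

    def order(self) -> list[str]:
        """Ids from most to least dominant."""
        pos = np.argsort(self.ds_rank)
        return [self.ids[i] for i in pos]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "w": self.w,
                "w2": self.w2,
                "l": self.l,
                "l2": self.l2,
                "ds": self.ds,
                "norm_ds": self.norm_ds,
                "ds_rank": self.ds_rank,
            }
        )


def _win_proportions(W: WinLossMatrix, dyadic_correction: bool) -> np.ndarray:
    s = W.counts.astype(float)
    n = s + s.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, s / np.where(n > 0, n, 1), 0.0)
    if dyadic_correction:
        # D_ij shrinks P_ij toward 0.5 by 1/(n_ij + 1), de-weighting sparse dyads
        d = np.where(n > 0, p - (p - 0.5) / (n + 1), 0.0)
        p = d
    np.fill_diagonal(p, 0.0)
    return p


def davids_scores(
    W: WinLossMatrix, dyadic_correction: bool = False
) -> DavidsScoreSet:
    """David's scores from a frequency sociomatrix.

    With ``dyadic_correction`` the raw win proportion P_ij is replaced by
    D_ij = P_ij - (P_ij - 0.5)/(n_ij + 1), which discounts dyads observed
    only a few times.  Unobserved dyads contribute 0 either way.
    """
    if W.n < 2:
        raise ValueError("David's scores need at least 2 individuals")
    p = _win_proportions(W, dyadic_correction)
    w = p.sum(axis=1)
    l = p.sum(axis=0)
    w2 = p @ w
    l2 = p.T @ l
    ds = w + w2 - l - l2
    n = W.n
    norm_ds = (ds + n * (n - 1) / 2) / n
    wins = W.wins()
    order = sorted(
        range(n), key=lambda i: (-norm_ds[i], -wins[i], W.ids[i])
    )
    ds_rank = np.empty(n, dtype=np.int64)
    for rank, i in enumerate(order, start=1):
        ds_rank[i] = rank
    return DavidsScoreSet(
        ids=list(W.ids), w=w, w2=w2, l=l, l2=l2, ds=ds,
        norm_ds=norm_ds, ds_rank=ds_rank,
    )


def steepness(W: WinLossMatrix, dyadic_correction: bool = False) -> float:
    """Absolute OLS slope of descending normalized David's scores on rank.

    A steepness of 1 means dominance declines by a full unit of normalized
    David's score per rank step (a maximally uneven hierarchy); 0 means all
    individuals hold equal power.
    """
    ds = davids_scores(W, dyadic_correction=dyadic_correction)
    y = np.sort(ds.norm_ds)[::-1]
    x = np.arange(1, W.n + 1, dtype=float)
    if np.allclose(y, y[0]):
        return 0.0
    slope = np.polyfit(x, y, 1)[0]
    return float(abs(slope))


# ---------------------------------------------------------------------------
# Linearity: Landau's h and modified h'
# ---------------------------------------------------------------------------

def landaus_h(W: WinLossMatrix) -> float:
    """Landau's h for a complete tournament (every dyad strictly decided).

    h = 12/(N^3 - N) * sum_a (V_a - (N-1)/2)^2 where V_a is the number of
    individuals a dominates.  1 = perfectly linear order, 0 = maximally
    cyclic.  Raises if any dyad is tied or unobserved; use
    :func:`landaus_h_prime` for such matrices.
    """
    signs = relation_signs(W)
    off = ~np.eye(W.n, dtype=bool)
    if np.isnan(signs[off]).any() or (signs[off] == 0).any():
        raise ValueError(
            "matrix has tied or unobserved dyads; use landaus_h_prime"
        )
    return _h_from_dominated_counts((signs == 1).sum(axis=1), W.n)


def _h_from_dominated_counts(v: np.ndarray, n: int) -> float:
    dev = v - (n - 1) / 2
    return float(12.0 / (n**3 - n) * np.sum(dev**2))


def landaus_h_prime(
    W: WinLossMatrix,
    n_resolutions: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Landau's modified h': linearity with random resolution of undecided dyads.

    Every tied or unobserved dyad is independently assigned a direction with
    probability 1/2 each way; Landau's h is computed on the completed
    tournament; the mean over ``n_resolutions`` replicates is returned.
    With no undecided dyads this equals :func:`landaus_h` exactly.
    """
    if n_resolutions < 1:
        raise ValueError("n_resolutions must be >= 1")
    if W.n < 3:
        raise ValueError("linearity needs at least 3 individuals")
    signs = relation_signs(W)
    iu, ju = np.triu_indices(W.n, k=1)
    upper = signs[iu, ju]
    undecided = np.isnan(upper) | (upper == 0)
    v_base = np.nansum(np.where(signs == 1, 1, 0), axis=1).astype(float)
    if not undecided.any():
        return _h_from_dominated_counts(v_base, W.n)

    rng = np.random.default_rng(seed)
    ui, uj = iu[undecided], ju[undecided]
    r, u, n = n_resolutions, ui.size, W.n
    flips = rng.random((r, u)) < 0.5
    winners = np.where(flips, ui[None, :], uj[None, :])
    v = np.tile(v_base, (r, 1))
    np.add.at(v, (np.repeat(np.arange(r), u), winners.ravel()), 1)
    dev = v - (n - 1) / 2
    return float(np.mean(12.0 / (n**3 - n) * np.sum(dev**2, axis=1)))


# ---------------------------------------------------------------------------
# Triangle transitivity
# ---------------------------------------------------------------------------

def triangle_transitivity(W: WinLossMatrix) -> tuple[float, float]:
    """(Pt, ttri): proportion of transitive complete triads and its scaling.

    A triad is *complete* when all three of its dyads are strictly decided
    (a clear winner, no tie, at least one interaction); it is transitive
    when its three relations admit a linear order rather than a cycle.
    ``ttri = 4 * (Pt - 0.75)`` rescales so that 0 is the random-tournament
    expectation and 1 means every complete triad is transitive.  Returns
    ``(nan, nan)`` when no complete triad exists.
    """
    signs = relation_signs(W)
    decided = signs == 1  # i beats j strictly
    n = W.n
    transitive = 0
    complete = 0
    for a, b, c in itertools.combinations(range(n), 3):
        pairs = ((a, b), (a, c), (b, c))
        if any(not (decided[i, j] or decided[j, i]) for i, j in pairs):
            continue
        complete += 1
        # a complete triad is cyclic iff every vertex beats exactly one other
        out = (
            decided[a, b] + decided[a, c],
            decided[b, a] + decided[b, c],
            decided[c, a] + decided[c, b],
        )
        if sorted(out) != [1, 1, 1]:
            transitive += 1
    if complete == 0:
        return (math.nan, math.nan)
    pt = transitive / complete
    return (pt, 4.0 * (pt - 0.75))


# ---------------------------------------------------------------------------
# Directional consistency, despotism, Gini
# ---------------------------------------------------------------------------

def directional_consistency(W: WinLossMatrix) -> float:
    """DC = sum over dyads of |s_ij - s_ji| / sum over dyads of (s_ij + s_ji).

    1 means every dyad's interactions ran in a single direction; 0 means
    every dyad was perfectly balanced.  Tied dyads contribute their events
    to the denominator only.
    """
    s = W.counts
    if s.sum() == 0:
        raise ValueError("directional consistency undefined on an empty matrix")
    iu, ju = np.triu_indices(W.n, k=1)
    num = np.abs(s[iu, ju] - s[ju, iu]).sum()
    den = (s[iu, ju] + s[ju, iu]).sum()
    return float(num / den)


def despotism(W: WinLossMatrix, ranking: Sequence[str] | None = None) -> float:
    """Share of all wins performed by the top-ranked individual.

    ``ranking`` lists ids from most to least dominant; by default the
    David's-score order is used.  Only the first element matters.
    """
    if W.n_events == 0:
        raise ValueError("despotism undefined on an empty matrix")
    if ranking is None:
        ranking = davids_scores(W).order()
    alpha = str(ranking[0])
    if alpha not in W.ids:
        raise ValueError(f"top-ranked id {alpha!r} not in the matrix")
    return float(W.wins()[W.ids.index(alpha)] / W.n_events)


def gini(x: Sequence[float] | np.ndarray) -> float:
    """Gini coefficient of a non-negative vector.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)); 0 = perfect equality, and the
    maximum for length n is (n-1)/n < 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("gini needs at least 2 values")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini undefined for an all-zero vector")
    # O(n log n) via the sorted-rank identity, equivalent to the pairwise sum
    xs = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2 * np.sum(ranks * xs) / (n * total)) - (n + 1) / n)


# ---------------------------------------------------------------------------
# I&SI ranking
# ---------------------------------------------------------------------------

def isi_costs(W: WinLossMatrix, order: Sequence[str]) -> tuple[int, int]:
    """(I, SI) for a candidate rank order.

    I counts dyads where the lower-ranked individual dominates the
    higher-ranked one; SI sums the rank distances of those inconsistent
    dyads.
    """
    signs = relation_signs(W)
    pos = {v: k for k, v in enumerate(W.ids)}
    idx = [pos[str(i)] for i in order]
    inc = 0
    strength = 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            # a outranks b in the candidate order
            if signs[idx[b], idx[a]] == 1:
                inc += 1
                strength += b - a
    return inc, strength


def rank_isi(
    W: WinLossMatrix,
    n_tries: int = 100,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """I&SI rank order by pairwise-swap hill climbing.

    Starts from the David's-score order and greedily applies the pairwise
    swap that best lexicographically reduces (I, SI), restarting from
    shuffled perturbations ``n_tries`` times.  Deterministic under ``seed``.
    The result is never worse than the David's-score starting order.
    """
    if W.n < 2:
        raise ValueError("ranking needs at least 2 individuals")
    rng = np.random.default_rng(seed)
    start = davids_scores(W).order()

    def climb(order: list[str]) -> tuple[tuple[int, int], list[str]]:
        order = list(order)
        cost = isi_costs(W, order)
        improved = True
        while improved and cost != (0, 0):
            improved = False
            best_cost, best_swap = cost, None
            for a in range(len(order)):
                for b in range(a + 1, len(order)):
                    order[a], order[b] = order[b], order[a]
                    c = isi_costs(W, order)
                    order[a], order[b] = order[b], order[a]
                    if c < best_cost:
                        best_cost, best_swap = c, (a, b)
            if best_swap is not None:
                a, b = best_swap
                order[a], order[b] = order[b], order[a]
                cost = best_cost
                improved = True
        return cost, order

    best_cost, best_order = climb(start)
    for _ in range(max(0, n_tries - 1)):
        if best_cost == (0, 0):
            break
        perturbed = list(start)
        rng.shuffle(perturbed)
        cost, order = climb(perturbed)
        if cost < best_cost:
            best_cost, best_order = cost, order
    return best_order


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """All hierarchy measures for one cohort, with randomization p-values."""

    h_prime: float
    p_h_prime: float
    ttri: float
    p_ttri: float
    steepness: float
    p_steepness: float
    dc: float
    p_dc: float
    despotism: float
    gini_wins: float
    gini_losses: float
    n_events: int
    n_individuals: int

    #: Table column order used for CSV export.
    COLUMNS = (
        "h_prime", "ttri", "steepness", "dc", "despotism",
        "gini_wins", "gini_losses",
    )

    def to_dict(self) -> dict:
        return {
            "h_prime": self.h_prime,
            "p_h_prime": self.p_h_prime,
            "ttri": self.ttri,
            "p_ttri": self.p_ttri,
            "steepness": self.steepness,
            "p_steepness": self.p_steepness,
            "dc": self.dc,
            "p_dc": self.p_dc,
            "despotism": self.despotism,
            "gini_wins": self.gini_wins,
            "gini_losses": self.gini_losses,
            "n_events": self.n_events,
            "n_individuals": self.n_individuals,
        }


def full_report(
    W: WinLossMatrix,
    n_randomizations: int = 1000,
    n_resolutions: int = 1000,
    seed: int | None = None,
    dyadic_correction: bool = False,
) -> MetricsReport:
    """Assemble every hierarchy measure plus randomization p-values.

    Despotism uses the David's-score ranking.  p-values come from the
    significance module's default null schemes (dyad-level Bernoulli
    redistribution for DC and steepness; uniform tournaments for h' and
    ttri), each with ``n_randomizations`` draws.
    """
    from .significance import NullScheme, randomization_p

    rng = np.random.default_rng(seed)

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    h = landaus_h_prime(W, n_resolutions=n_resolutions, seed=sub_seed())
    _, tt = triangle_transitivity(W)
    stp = steepness(W, dyadic_correction=dyadic_correction)
    dc = directional_consistency(W)
    desp = despotism(W)
    g_w = gini(W.wins())
    g_l = gini(W.losses())

    def pval(stat: str) -> float:
        return randomization_p(
            W, stat, NullScheme(m=n_randomizations, seed=sub_seed())
        )

    return MetricsReport(
        h_prime=h, p_h_prime=pval("h_prime"),
        ttri=tt, p_ttri=pval("ttri"),
        steepness=stp, p_steepness=pval("steepness"),
        dc=dc, p_dc=pval("dc"),
        despotism=desp,
        gini_wins=g_w, gini_losses=g_l,
        n_events=W.n_events, n_individuals=W.n,
    )
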