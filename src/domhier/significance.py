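"""Randomization inference for sociomatrix statistics.

p-values are the proportion of randomized data sets whose statistic is
greater than or equal to the observed one, with an add-one correction so a
permutation p-value is never exactly zero:

    p = (1 + #{randomized >= observed}) / (M + 1)

Two null schemes are provided.  ``dyad_bernoulli`` keeps every dyad's total
interaction count n_ij and redistributes its outcomes as Binomial(n_ij, 1/2)
— the natural null for statistics driven by within-dyad asymmetry (DC,
steepness).  ``tournament_uniform`` keeps which dyads interacted and flips a
fair coin for each one's direction, producing binary random tournaments —
the natural null for order statistics (h', ttri).

QAP (quadratic assignment procedure) tests association between two
sociomatrices by permuting vertex labels — rows and columns jointly — of
one matrix, which preserves its dyadic structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .events import WinLossMatrix
from . import metrics as _m

__all__ = [
    "NullScheme",
    "QapResult",
    "DEFAULT_SCHEMES",
    "randomize_matrix",
    "randomization_p",
    "qap_correlation",
]


@dataclass(frozen=True)
class NullScheme:
    """A named randomization null with draw count and seed.

    ``name`` is ``"dyad_bernoulli"`` or ``"tournament_uniform"``; ``None``
    picks the statistic's default.  ``m`` is the number of randomizations.
    """

    name: str | None = None
    m: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("number of randomizations m must be >= 1")
        if self.name is not None and self.name not in (
            "dyad_bernoulli", "tournament_uniform"
        ):
            raise ValueError(f"unknown null scheme {self.name!r}")


#: Default null per named statistic.
DEFAULT_SCHEMES = {
    "dc": "dyad_bernoulli",
    "steepness": "dyad_bernoulli",
    "h_prime": "tournament_uniform",
    "ttri": "tournament_uniform",
}


def randomize_matrix(
    W: WinLossMatrix, scheme_name: str, rng: np.random.Generator
) -> WinLossMatrix:
    """One null draw of a sociomatrix under the given scheme."""
    s = W.counts
    n = W.n
    iu, ju = np.triu_indices(n, k=1)
    totals = s[iu, ju] + s[ju, iu]
    new = np.zeros_like(s)
    if scheme_name == "dyad_bernoulli":
        up = rng.binomial(totals, 0.5)
        new[iu, ju] = up
        new[ju, iu] = totals - up
    elif scheme_name == "tournament_uniform":
        active = totals > 0
        direction = rng.random(iu.size) < 0.5
        new[iu, ju] = (active & direction).astype(np.int64)
        new[ju, iu] = (active & ~direction).astype(np.int64)
    else:
        raise ValueError(f"unknown null scheme {scheme_name!r}")
    return WinLossMatrix(ids=list(W.ids), counts=new)


def _named_statistic(
    name: str, n_resolutions: int
) -> Callable[[WinLossMatrix, np.random.Generator], float]:
    if name == "dc":
        return lambda W, rng: _m.directional_consistency(W)
    if name == "steepness":
        return lambda W, rng: _m.steepness(W)
    if name == "h_prime":
        return lambda W, rng: _m.landaus_h_prime(
            W, n_resolutions=n_resolutions, seed=rng
        )
    if name == "ttri":
        return lambda W, rng: _m.triangle_transitivity(W)[1]
    raise ValueError(
        f"unknown statistic {name!r}; expected one of {sorted(DEFAULT_SCHEMES)}"
    )


def randomization_p(
    W: WinLossMatrix,
    statistic: str | Callable[[WinLossMatrix, np.random.Generator], float],
    scheme: NullScheme = NullScheme(),
    n_resolutions: int = 100,
) -> float:
    """One-sided randomization p-value for a sociomatrix statistic.

    ``statistic`` is a registered name ("dc", "steepness", "h_prime",
    "ttri") or a callable ``f(matrix, rng) -> float``.  For a named
    statistic with ``scheme.name`` unset the statistic's default null is
    used.  ``n_resolutions`` controls the inner tie-resolution replicates
    when h' is evaluated on null draws.

    Raises if the statistic is undefined (NaN) on the observed matrix.
    """
    if isinstance(statistic, str):
        scheme_name = scheme.name or DEFAULT_SCHEMES[statistic]
        stat = _named_statistic(statistic, n_resolutions)
    else:
        if scheme.name is None:
            raise ValueError("a callable statistic needs an explicit scheme name")
        scheme_name = scheme.name
        stat = statistic
    rng = np.random.default_rng(scheme.seed)
    observed = stat(W, rng)
    if math.isnan(observed):
        raise ValueError("statistic is undefined on the observed matrix")
    hits = 0
    for _ in range(scheme.m):
        draw = randomize_matrix(W, scheme_name, rng)
        value = stat(draw, rng)
        if not math.isnan(value) and value >= observed:
            hits += 1
    return (1 + hits) / (scheme.m + 1)


@dataclass(frozen=True)
class QapResult:
    """QAP matrix-correlation result with both permutation tails."""

    r: float
    p_greater: float
    p_lower: float
    n_perm: int


def qap_correlation(
    A: WinLossMatrix,
    B: WinLossMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> QapResult:
    """QAP correlation between two sociomatrices over the same individuals.

    The observed statistic is the Pearson correlation of the off-diagonal
    cells.  The null distribution applies the same random vertex-label
    permutation to the rows and columns of ``B`` and recomputes r,
    ``n_perm`` times.  Both one-sided tails are returned, add-one corrected.
    """
    if A.ids != B.ids:
        raise ValueError("matrices must share ids and ordering")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    off = ~np.eye(A.n, dtype=bool)
    a = A.counts[off].astype(float)
    b_mat = B.counts.astype(float)
    b = b_mat[off]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("off-diagonal cells have zero variance")
    observed = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    greater = 0
    lower = 0
    for _ in range(n_perm):
        perm = rng.permutation(A.n)
        bp = b_mat[np.ix_(perm, perm)][off]
        r = float(np.corrcoef(a, bp)[0, 1])
        if r >= observed:
            greater += 1
        if r <= observed:
            lower += 1
    return QapResult(
        r=observed,
        p_greater=(1 + greater) / (n_perm + 1),
        p_lower=(1 + lower) / (n_perm + 1),
        n_perm=n_perm,
    )
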