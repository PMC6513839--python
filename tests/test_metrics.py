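"""Dominance statistics against brute-force oracles and analytic values."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domhier import (
    WinLossMatrix,
    davids_scores,
    despotism,
    directional_consistency,
    full_report,
    gini,
    landaus_h,
    landaus_h_prime,
    rank_isi,
    steepness,
    triangle_transitivity,
)
from domhier.metrics import isi_costs

from conftest import perfect_linear_matrix, random_count_matrix, tournament_from_bits


# ---------------------------------------------------------------------------
# David's scores and steepness
# ---------------------------------------------------------------------------

class TestDavidsScores:
    def test_perfect_three_individual_hierarchy(self):
        # A>B, A>C, B>C once each: hand evaluation gives DS (3, 0, -3)
        W = perfect_linear_matrix(3)
        ds = davids_scores(W)
        assert ds.ds == pytest.approx([3.0, 0.0, -3.0])
        assert ds.norm_ds == pytest.approx([2.0, 1.0, 0.0])
        assert list(ds.ds_rank) == [1, 2, 3]

    def test_even_matrix_all_zero(self):
        counts = np.full((4, 4), 2)
        np.fill_diagonal(counts, 0)
        W = WinLossMatrix(ids=list("abcd"), counts=counts)
        assert davids_scores(W).ds == pytest.approx([0.0] * 4)

    def test_scores_sum_to_zero(self, rng):
        for _ in range(10):
            W = random_count_matrix(6, rng)
            assert davids_scores(W).ds.sum() == pytest.approx(0.0, abs=1e-9)
            assert davids_scores(W, dyadic_correction=True).ds.sum() == pytest.approx(
                0.0, abs=1e-9
            )

    def test_norm_ds_in_range(self, rng):
        W = random_count_matrix(8, rng)
        nds = davids_scores(W).norm_ds
        assert (nds >= -1e-9).all() and (nds <= 7 + 1e-9).all()

    def test_dyadic_correction_shrinks_sparse_dyads(self):
        # one observation per dyad: corrected proportions move toward 0.5
        W = perfect_linear_matrix(3)
        raw = davids_scores(W)
        corr = davids_scores(W, dyadic_correction=True)
        assert abs(corr.ds[0]) < abs(raw.ds[0])

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            davids_scores(WinLossMatrix(ids=["a"], counts=np.zeros((1, 1))))


class TestSteepness:
    def test_perfect_three_individual_matrix(self):
        assert steepness(perfect_linear_matrix(3)) == pytest.approx(1.0)

    def test_even_matrix_is_flat(self):
        counts = np.full((4, 4), 3)
        np.fill_diagonal(counts, 0)
        assert steepness(WinLossMatrix(ids=list("abcd"), counts=counts)) == 0.0

    def test_relabeling_invariance(self, rng):
        W = random_count_matrix(7, rng)
        perm = rng.permutation(7)
        assert steepness(W.permuted(perm)) == pytest.approx(steepness(W))

    def test_perfectly_linear_matrix_is_maximally_steep(self):
        assert steepness(perfect_linear_matrix(12)) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Landau's h and h'
# ---------------------------------------------------------------------------

def brute_force_h(W: WinLossMatrix) -> float:
    """Literal definition: dispersion of the dominated-counts V_a."""
    n = W.n
    v = []
    for a in range(n):
        v.append(sum(1 for b in range(n) if W.counts[a, b] > W.counts[b, a]))
    return 12.0 / (n**3 - n) * sum((va - (n - 1) / 2) ** 2 for va in v)


class TestLandausH:
    def test_transitive_triad_is_one(self):
        assert landaus_h(perfect_linear_matrix(3)) == pytest.approx(1.0)

    def test_cyclic_triad_is_zero(self):
        counts = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        W = WinLossMatrix(ids=list("abc"), counts=counts)
        assert landaus_h(W) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_brute_force_on_all_tournaments(self, n):
        """Exhaustive oracle: every complete tournament of size n."""
        n_dyads = n * (n - 1) // 2
        for bits in range(2**n_dyads):
            W = tournament_from_bits(n, bits)
            assert landaus_h(W) == pytest.approx(brute_force_h(W))

    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_perfect_linear_order_is_one(self, n):
        assert landaus_h(perfect_linear_matrix(n)) == pytest.approx(1.0)

    def test_undecided_dyad_rejected(self):
        W = WinLossMatrix(ids=list("abc"), counts=np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError, match="landaus_h_prime"):
            landaus_h(W)


class TestLandausHPrime:
    def test_no_undecided_dyads_equals_h_for_any_seed(self):
        W = perfect_linear_matrix(12)
        assert landaus_h_prime(W, n_resolutions=1, seed=0) == landaus_h(W)
        assert landaus_h_prime(W, n_resolutions=1, seed=99) == landaus_h(W)

    def test_all_unknown_three_individuals_approaches_enumerated_mean(self):
        # all 8 tournaments on 3 individuals: 6 transitive (h=1), 2 cyclic
        # (h=0), so E[h] = 0.75
        enumerated = [landaus_h(tournament_from_bits(3, b)) for b in range(8)]
        assert np.mean(enumerated) == pytest.approx(0.75)
        W = WinLossMatrix(ids=list("abc"), counts=np.zeros((3, 3), dtype=int))
        assert landaus_h_prime(W, n_resolutions=20000, seed=7) == pytest.approx(
            0.75, abs=0.02
        )

    def test_deterministic_under_seed(self, rng):
        W = random_count_matrix(6, rng, max_count=1)
        a = landaus_h_prime(W, n_resolutions=200, seed=42)
        b = landaus_h_prime(W, n_resolutions=200, seed=42)
        assert a == b

    def test_rejects_bad_resolution_count(self):
        with pytest.raises(ValueError):
            landaus_h_prime(perfect_linear_matrix(4), n_resolutions=0)


# ---------------------------------------------------------------------------
# Triangle transitivity
# ---------------------------------------------------------------------------

def brute_force_ttri(W: WinLossMatrix) -> tuple[float, float]:
    """Explicit enumeration of every triad by its three relations."""
    n = W.n
    wins = {
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and W.counts[i, j] > W.counts[j, i]
    }
    complete = transitive = 0
    for a, b, c in itertools.combinations(range(n), 3):
        decided = all(
            (i, j) in wins or (j, i) in wins
            for i, j in ((a, b), (a, c), (b, c))
        )
        if not decided:
            continue
        complete += 1
        cyclic = ({(a, b), (b, c), (c, a)} <= wins) or (
            {(b, a), (c, b), (a, c)} <= wins
        )
        if not cyclic:
            transitive += 1
    if complete == 0:
        return (float("nan"), float("nan"))
    pt = transitive / complete
    return pt, 4 * (pt - 0.75)


class TestTriangleTransitivity:
    def test_single_transitive_triad(self):
        pt, tt = triangle_transitivity(perfect_linear_matrix(3))
        assert (pt, tt) == (1.0, 1.0)

    def test_single_cyclic_triad(self):
        counts = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        pt, tt = triangle_transitivity(WinLossMatrix(ids=list("abc"), counts=counts))
        assert (pt, tt) == (0.0, -3.0)

    def test_matches_triad_enumeration_oracle(self, rng):
        for n in (4, 5, 6):
            for _ in range(25):
                W = random_count_matrix(n, rng, max_count=2)
                got = triangle_transitivity(W)
                want = brute_force_ttri(W)
                if np.isnan(want[0]):
                    assert np.isnan(got[0])
                else:
                    assert got == pytest.approx(want)

    def test_random_tournaments_center_near_zero(self, rng):
        # the 4(Pt - 0.75) scaling makes uniform tournaments average ~0
        vals = []
        for _ in range(300):
            bits = int(rng.integers(0, 2 ** 15))
            _, tt = triangle_transitivity(tournament_from_bits(6, bits))
            vals.append(tt)
        assert abs(np.mean(vals)) < 0.1

    def test_no_complete_triad_returns_nan(self):
        W = WinLossMatrix(ids=list("abc"), counts=np.zeros((3, 3), dtype=int))
        assert np.isnan(triangle_transitivity(W)[0])


# ---------------------------------------------------------------------------
# DC, despotism, Gini
# ---------------------------------------------------------------------------

class TestDirectionalConsistency:
    def test_one_directional_matrix(self):
        assert directional_consistency(perfect_linear_matrix(5, 3)) == 1.0

    def test_three_vs_one_dyad(self):
        counts = np.array([[0, 3], [1, 0]])
        assert directional_consistency(
            WinLossMatrix(ids=list("ab"), counts=counts)
        ) == pytest.approx(0.5)

    def test_mixed_dyads(self):
        # dyads 5-0 and 2-2: (5 + 0) / (5 + 4) = 5/9
        counts = np.array([[0, 5, 2], [0, 0, 0], [2, 0, 0]])
        assert directional_consistency(
            WinLossMatrix(ids=list("abc"), counts=counts)
        ) == pytest.approx(5 / 9)

    def test_empty_matrix_rejected(self):
        W = WinLossMatrix(ids=list("ab"), counts=np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            directional_consistency(W)


class TestDespotism:
    def test_alpha_performs_every_win(self):
        counts = np.zeros((12, 12), dtype=int)
        counts[0, 1:] = 4
        W = WinLossMatrix(ids=[f"i{k}" for k in range(12)], counts=counts)
        assert despotism(W) == 1.0

    def test_equal_win_counts(self):
        # every individual wins the same number of events
        n = 12
        counts = np.zeros((n, n), dtype=int)
        for i in range(n):
            counts[i, (i + 1) % n] = 3
        W = WinLossMatrix(ids=[f"i{k}" for k in range(n)], counts=counts)
        assert despotism(W, ranking=W.ids) == pytest.approx(1 / 12)

    def test_depends_only_on_top_of_ranking(self, rng):
        W = random_count_matrix(6, rng)
        r1 = ["3", "0", "1", "2", "4", "5"]
        r2 = ["3", "5", "4", "2", "1", "0"]
        assert despotism(W, ranking=r1) == despotism(W, ranking=r2)


def brute_force_gini(x) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    return float(
        sum(abs(a - b) for a in x for b in x) / (2 * n * n * x.mean())
    )


class TestGini:
    def test_perfect_equality(self):
        assert gini([1, 1, 1, 1]) == pytest.approx(0.0)

    def test_single_winner(self):
        # (4,0,0,0): mean |diff| sum 24 over 2*16*1 -> 0.75 = (n-1)/n
        assert gini([4, 0, 0, 0]) == pytest.approx(0.75)

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(20):
            x = rng.integers(0, 30, size=int(rng.integers(2, 21)))
            if x.sum() == 0:
                x[0] = 1
            assert gini(x) == pytest.approx(brute_force_gini(x))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=15).filter(
            lambda v: sum(v) > 0
        ),
        st.floats(0.1, 100, allow_nan=False),
    )
    def test_scale_invariance(self, x, c):
        assert gini(np.asarray(x) * c) == pytest.approx(gini(x), abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini([0, 0, 0])


# ---------------------------------------------------------------------------
# I&SI ranking
# ---------------------------------------------------------------------------

class TestRankIsi:
    def test_perfectly_linear_matrix_recovers_order(self):
        W = perfect_linear_matrix(6)
        order = rank_isi(W, n_tries=5, seed=0)
        assert order == W.ids
        assert isi_costs(W, order) == (0, 0)

    def test_never_worse_than_davids_score_start(self, rng):
        for _ in range(5):
            W = random_count_matrix(6, rng, max_count=3)
            start = davids_scores(W).order()
            best = rank_isi(W, n_tries=10, seed=1)
            assert isi_costs(W, best) <= isi_costs(W, start)

    def test_matches_exhaustive_search_on_small_matrices(self, rng):
        """Brute-force oracle over all orderings, N <= 5."""
        for n in (4, 5):
            for _ in range(8):
                W = random_count_matrix(n, rng, max_count=2)
                best = min(
                    isi_costs(W, list(perm))
                    for perm in itertools.permutations(W.ids)
                )
                got = rank_isi(W, n_tries=30, seed=3)
                assert isi_costs(W, got) == best

    def test_single_reversal_found(self):
        # linear order with one reversed dyad: optimum has I=1
        W = perfect_linear_matrix(4, wins_per_dyad=2)
        counts = W.counts.copy()
        counts[2, 1] = 5  # rank-3 beats rank-2 overall
        counts[1, 2] = 0
        W = WinLossMatrix(ids=W.ids, counts=counts)
        best = min(
            isi_costs(W, list(p)) for p in itertools.permutations(W.ids)
        )
        assert isi_costs(W, rank_isi(W, n_tries=20, seed=0)) == best


# ---------------------------------------------------------------------------
# Full report and shared invariants
# ---------------------------------------------------------------------------

class TestFullReport:
    def test_perfect_matrix_fixed_points(self):
        rep = full_report(
            perfect_linear_matrix(12), n_randomizations=50, n_resolutions=20,
            seed=0,
        )
        assert rep.h_prime == 1.0
        assert rep.ttri == 1.0
        assert rep.dc == 1.0
        assert rep.p_h_prime == pytest.approx(1 / 51)
        assert rep.n_events == 66

    def test_label_invariance(self, rng):
        W = random_count_matrix(8, rng, max_count=4)
        perm = rng.permutation(8)
        a = full_report(W, n_randomizations=30, n_resolutions=50, seed=5)
        b = full_report(W.permuted(perm), n_randomizations=30, n_resolutions=50, seed=5)
        for field in ("ttri", "steepness", "dc", "despotism", "gini_wins"):
            assert getattr(a, field) == pytest.approx(getattr(b, field))

    def test_pvalues_within_permutation_bounds(self, rng):
        W = random_count_matrix(6, rng, max_count=4)
        rep = full_report(W, n_randomizations=40, n_resolutions=50, seed=2)
        for p in (rep.p_h_prime, rep.p_ttri, rep.p_steepness, rep.p_dc):
            assert 1 / 41 <= p <= 1.0


class TestPermutationInvariance:
    @pytest.mark.parametrize(
        "stat",
        [
            lambda W: directional_consistency(W),
            lambda W: triangle_transitivity(W)[1],
            lambda W: steepness(W),
            lambda W: gini(W.wins()),
        ],
    )
    def test_metrics_invariant_under_relabeling(self, stat, rng):
        W = random_count_matrix(7, rng, max_count=4)
        perm = rng.permutation(7)
        a, b = stat(W), stat(W.permuted(perm))
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(b)
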