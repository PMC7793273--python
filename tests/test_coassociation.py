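import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulome.coassociation import (
    P_FLOOR,
    CoassocMatrix,
    anchored_overlap,
    cluster_matrix,
    count_overlap,
    poisson_score,
    significance_call,
)
from regulome.model import AnalysisConfig, ValidationError

from conftest import peakset_from_summits


def brute_force_k(sa, sb, window=150):
    """O(n^2) all-pairs reference count (summits on one chromosome)."""
    sa, sb = np.asarray(sa), np.asarray(sb)
    if len(sa) == 0 or len(sb) == 0:
        return 0
    return int((np.abs(sa[:, None] - sb[None, :]) <= window).any(axis=1).sum())


def poisson_upper_tail(k, lam, terms=200_000):
    """Direct summation oracle: sum_{j>=k} e^-lam lam^j / j!."""
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total, j = 0.0, k
    while term > 0 and j < k + terms:
        total += term
        j += 1
        term *= lam / j
        if term < total * 1e-18:
            total += term / (1 - lam / (j + 1)) if lam < j + 1 else term
            break
    return total


class TestCountOverlap:
    def test_three_vs_two_summits(self):
        a = peakset_from_summits([100, 400, 1000], "A")
        b = peakset_from_summits([120, 700], "B")
        oc = count_overlap(a, b)
        assert oc.k == 1  # only 100<->120; |400-700| = 300 > 150

    def test_self_overlap_is_total(self):
        a = peakset_from_summits(np.arange(0, 100_000, 400), "NFYB")
        oc = count_overlap(a, a)
        assert oc.k == len(a) and oc.share_a == 1.0

    def test_disjoint_chromosomes_give_zero(self):
        a = peakset_from_summits([100, 200], "A", chrom="chr1")
        b = peakset_from_summits([100, 200], "B", chrom="chr2")
        assert count_overlap(a, b).k == 0

    def test_each_summit_counted_once_near_two_partners(self):
        a = peakset_from_summits([500], "A")
        b = peakset_from_summits([400, 600], "B")
        oc = count_overlap(a, b)
        assert oc.k == 1 and oc.k_b == 2

    def test_window_boundary_inclusive(self):
        a = peakset_from_summits([0], "A")
        assert count_overlap(a, peakset_from_summits([150], "B")).k == 1
        assert count_overlap(a, peakset_from_summits([151], "B")).k == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        sa = rng.integers(0, 200_000, size=rng.integers(1, 500))
        sb = rng.integers(0, 200_000, size=rng.integers(1, 500))
        oc = count_overlap(peakset_from_summits(sorted(sa), "A"),
                           peakset_from_summits(sorted(sb), "B"))
        assert oc.k == brute_force_k(sa, sb)
        assert oc.k_b == brute_force_k(sb, sa)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        sa=st.lists(st.integers(0, 10_000), min_size=1, max_size=60),
        sb=st.lists(st.integers(0, 10_000), min_size=1, max_size=60),
    )
    def test_brute_force_equivalence_property(self, sa, sb):
        """Merge-based counting equals all-pairs counting on any input,
        including duplicates and dense clumps of summits."""
        oc = count_overlap(peakset_from_summits(sorted(sa), "A"),
                           peakset_from_summits(sorted(sb), "B"))
        assert oc.k == brute_force_k(sa, sb)
        assert oc.k_b == brute_force_k(sb, sa)


class TestPoissonScore:
    def test_small_instance_against_direct_summation(self):
        from regulome.coassociation import OverlapCount

        counts = OverlapCount("A", "B", 100, 100, 10, 10)
        res = poisson_score(counts, n_tests=1)
        assert res.lambda_exp == pytest.approx(0.04)
        oracle = poisson_upper_tail(10, 0.04)
        assert res.p_raw == pytest.approx(oracle, rel=1e-9)
        assert -math.log10(oracle) == pytest.approx(20.6, abs=0.5)

    def test_observed_equal_expected_scores_near_zero(self):
        from regulome.coassociation import OverlapCount

        lam = 10_000 * 10_000 / 250_000  # 400
        counts = OverlapCount("A", "B", 10_000, 10_000, round(lam), round(lam))
        res = poisson_score(counts, n_tests=1)
        assert abs(res.score) < 1.0

    def test_identical_20000_sets_hit_score_ceiling_323(self):
        a = peakset_from_summits(np.arange(20_000) * 500, "A")
        res = poisson_score(count_overlap(a, a), n_tests=1)
        assert res.p_bonf == 0.0  # underflow before the clamp
        assert res.int_score == 323

    def test_depletion_flips_sign(self):
        from regulome.coassociation import OverlapCount

        counts = OverlapCount("A", "B", 10_000, 10_000, 100, 100)  # lam = 400
        res = poisson_score(counts, n_tests=1)
        assert res.score < 0

    def test_monotone_in_k_above_lambda(self):
        from regulome.coassociation import OverlapCount

        scores = [poisson_score(OverlapCount("A", "B", 500, 500, k, k),
                                n_tests=1).score for k in range(1, 300, 10)]
        assert all(s2 >= s1 for s1, s2 in zip(scores, scores[1:]))

    def test_bonferroni_scales_p(self):
        from regulome.coassociation import OverlapCount

        counts = OverlapCount("A", "B", 100, 100, 10, 10)
        p1 = poisson_score(counts, n_tests=1).p_bonf
        p100 = poisson_score(counts, n_tests=100).p_bonf
        assert p100 == pytest.approx(min(1.0, p1 * 100))

    def test_invalid_n_accessible_rejected(self):
        from regulome.coassociation import OverlapCount

        with pytest.raises(ValidationError):
            poisson_score(OverlapCount("A", "B", 10, 10, 1, 1), n_accessible=0)


class TestSignificance:
    @pytest.mark.parametrize("score,share,expected", [
        (323.0, 0.23, True),   # the TAF1-style entry
        (150.0, 0.08, False),  # below the 10% share threshold
        (99.0, 0.50, False),   # strict score threshold
        (100.0, 0.50, False),  # boundary is strict
    ])
    def test_rules(self, score, share, expected):
        from regulome.coassociation import CoassocResult, OverlapCount

        res = CoassocResult(OverlapCount("A", "B", 1, 1, 1, 1), 0.1, 0.1, 0.1,
                            score, False)
        assert significance_call(res, share) is expected


class TestAnchoredOverlap:
    def test_identical_sets_inside_anchor(self):
        anchor = peakset_from_summits(np.arange(2000) * 10_000, "NFYB")
        a = peakset_from_summits(np.arange(150) * 10_000 + 30, "A")
        res = anchored_overlap(a, a, anchor)
        assert res.counts.share_a == 1.0  # identical sets share everything
        assert res.score > 100  # k = 150 vs lambda = 150*150/2000 = 11.25

    def test_disjoint_from_anchor_is_degenerate(self):
        anchor = peakset_from_summits([1000], "NFYB")
        a = peakset_from_summits([1010], "A")
        b = peakset_from_summits([900_000], "B")
        res = anchored_overlap(a, b, anchor)
        assert res.degenerate and res.counts.k == 0 and res.score == 0.0

    def test_empty_anchor_rejected(self):
        a = peakset_from_summits([10], "A")
        with pytest.raises(ValidationError):
            anchored_overlap(a, a, peakset_from_summits([], "N"))

    def test_planted_half_overlap_recovered(self):
        # anchor occupies 100 sites; a at all of them, b at half of them
        anchor_summits = np.arange(100) * 10_000
        anchor = peakset_from_summits(anchor_summits, "NFYB")
        a = peakset_from_summits(anchor_summits + 20, "A")
        b = peakset_from_summits(anchor_summits[:50] + 40, "B")
        res = anchored_overlap(a, b, anchor)
        assert res.counts.share_a == pytest.approx(0.5)


class TestClusterMatrix:
    def test_identical_rows_merge_first_at_zero(self):
        rows = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4, 1, 0, 2]])
        z, order, newick = cluster_matrix(CoassocMatrix(["a", "b", "c"], rows))
        assert z[0, 2] == pytest.approx(0.0)
        assert set(order) == {"a", "b", "c"}

    def test_two_block_structure_separates_at_top(self):
        rng = np.random.default_rng(1)
        base1, base2 = rng.normal(size=8), rng.normal(size=8)
        rows = np.vstack([base1 + 0.05 * rng.normal(size=8) for _ in range(3)]
                         + [base2 + 0.05 * rng.normal(size=8) for _ in range(3)])
        names = [f"m1_{i}" for i in range(3)] + [f"m2_{i}" for i in range(3)]
        z, order, _ = cluster_matrix(CoassocMatrix(names, rows))
        groups = {n[:2] for n in order[:3]}, {n[:2] for n in order[3:]}
        assert groups == ({"m1"}, {"m2"}) or groups == ({"m2"}, {"m1"})

    def test_anticorrelated_pair_merges_last_at_two(self):
        x = np.array([1.0, 2, 3, 4])
        rows = np.vstack([x, x * 1.5, -x])
        z, _, _ = cluster_matrix(CoassocMatrix(["a", "b", "c"], rows))
        assert z[-1, 2] == pytest.approx(2.0, abs=0.2)

    def test_constant_matrix_rejected(self):
        rows = np.ones((3, 4))
        with pytest.raises(ValidationError), pytest.warns(UserWarning):
            cluster_matrix(CoassocMatrix(["a", "b", "c"], rows))

    def test_newick_has_all_leaves(self):
        rows = np.array([[1.0, 2, 3], [3, 1, 0], [0, 5, 1]])
        _, _, newick = cluster_matrix(CoassocMatrix(["fa", "fb", "fc"], rows))
        assert all(n in newick for n in ("fa", "fb", "fc")) and newick.endswith(";")
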