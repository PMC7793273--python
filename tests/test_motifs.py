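import numpy as np
import pytest

from regulome.io import encode_sequence
from regulome.model import AnalysisConfig, ValidationError
from regulome.motifs import (
    BackgroundModel,
    MotifEnrichment,
    classify_ccaat,
    global_enrichment,
    local_enrichment,
    middle_a_offset,
    rank_enrichments,
    scan_windows,
)
from regulome.synthetic import ccaat_box_pwm, consensus_pwm, reverse_complement

from conftest import peakset_from_summits


def brute_force_best(window_codes, pwm, pseudo_frac=0.01):
    """Per-window exhaustive scan reference (both strands, normalized)."""
    lom = pwm.log_odds(pseudo_frac=pseudo_frac)
    lom_rc = pwm.reverse_complement().log_odds(pseudo_frac=pseudo_frac)
    lo, hi = lom.min(axis=1).sum(), lom.max(axis=1).sum()
    L = pwm.length
    best = -np.inf
    for mat in (lom, lom_rc):
        for p in range(len(window_codes) - L + 1):
            s = sum(mat[j, window_codes[p + j]] for j in range(L))
            best = max(best, s)
    return (best - lo) / (hi - lo)


class TestScan:
    def test_consensus_scores_exactly_one(self):
        pwm = consensus_pwm("TGACTCAG", "M1", "TF")
        win = encode_sequence("A" * 40 + "TGACTCAG" + "A" * 40)
        score, pos, strand = scan_windows(win[None, :], pwm)
        assert score[0] == pytest.approx(1.0)
        assert pos[0] == 40 and strand[0] == 0

    def test_anticonsensus_scores_zero_on_its_window(self):
        # a window made only of each position's worst base scores exactly 0
        pwm = consensus_pwm("TGACTCAG", "M1", "TF")
        lom = pwm.log_odds()
        worst = "".join("ACGT"[i] for i in np.argmin(lom, axis=1))
        win = encode_sequence(worst)
        score, _, _ = scan_windows(win[None, :], pwm)
        # reverse strand may score higher; forward anti-consensus bound holds
        fwd_lom_score = sum(lom[j, win[j]] for j in range(pwm.length))
        lo = lom.min(axis=1).sum()
        assert fwd_lom_score == pytest.approx(lo)

    def test_reverse_complement_hit_found_on_minus_strand(self):
        pwm = consensus_pwm("TGACTCAG", "M1", "TF")
        rc = reverse_complement("TGACTCAG")
        win = encode_sequence("A" * 30 + rc + "A" * 30)
        score, pos, strand = scan_windows(win[None, :], pwm)
        assert score[0] == pytest.approx(1.0)
        assert strand[0] == 1 and pos[0] == 30

    def test_strand_symmetry_of_best_score(self):
        rng = np.random.default_rng(0)
        pwm = consensus_pwm("GATAAGAC", "M2", "TF2")
        wins = rng.integers(0, 4, size=(20, 80), dtype=np.uint8)
        fwd_scores, _, _ = scan_windows(wins, pwm)
        rc_wins = (3 - wins)[:, ::-1]  # reverse complement of each window
        rc_scores, _, _ = scan_windows(rc_wins, pwm)
        np.testing.assert_allclose(fwd_scores, rc_scores, atol=1e-12)

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(3)
        pwm = ccaat_box_pwm()
        wins = rng.integers(0, 4, size=(50, 150), dtype=np.uint8)
        scores, _, _ = scan_windows(wins, pwm)
        oracle = [brute_force_best(w, pwm) for w in wins]
        np.testing.assert_allclose(scores, oracle, atol=1e-12)


class TestEnrichment:
    def _scores(self, values):
        from regulome.model import GenomicInterval
        from regulome.motifs import RegionScore

        return [RegionScore(GenomicInterval("chr1", i * 200, i * 200 + 150),
                            float(v), 0, "+") for i, v in enumerate(values)]

    def test_planted_signal_is_overwhelming(self):
        rng = np.random.default_rng(1)
        bg = BackgroundModel(mean=0.6, var=0.002, n=2000)
        peaks = self._scores(np.clip(rng.normal(0.95, 0.02, size=500), 0, 1))
        assert global_enrichment(peaks, bg) < 1e-10

    def test_background_draws_are_not_significant(self):
        rng = np.random.default_rng(2)
        sample = rng.normal(0.6, 0.05, size=2000)
        bg = BackgroundModel(mean=float(sample.mean()),
                             var=float(sample.var(ddof=1)), n=2000,
                             sample=sample)
        ps = []
        for _ in range(50):
            ps.append(global_enrichment(
                self._scores(rng.choice(sample, size=100)), bg))
        assert 0.2 < np.mean(np.asarray(ps) < 0.5) < 0.8  # roughly uniform

    def test_permutation_method_agrees_in_order_of_magnitude(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(0.6, 0.05, size=2000)
        bg = BackgroundModel(float(sample.mean()), float(sample.var(ddof=1)),
                             2000, sample)
        peaks = self._scores(rng.normal(0.62, 0.05, size=200))
        pz = global_enrichment(peaks, bg, method="z")
        pp = global_enrichment(peaks, bg, method="permutation",
                               rng=np.random.default_rng(0))
        assert (pz < 0.05) == (pp < 0.05)

    def test_zero_background_variance_rejected(self):
        with pytest.raises(ValidationError):
            global_enrichment(self._scores([0.5]), BackgroundModel(0.5, 0.0, 10))

    def test_local_planted_center_only(self):
        rng = np.random.default_rng(4)
        center = self._scores(np.clip(rng.normal(0.95, 0.02, 300), 0, 1))
        f5 = self._scores(rng.normal(0.6, 0.05, 300))
        f3 = self._scores(rng.normal(0.6, 0.05, 300))
        assert local_enrichment(center, (f5, f3)) < 1e-10

    def test_local_equal_plants_not_significant(self):
        rng = np.random.default_rng(5)
        center = self._scores(rng.normal(0.9, 0.03, 300))
        f5 = self._scores(rng.normal(0.9, 0.03, 300))
        f3 = self._scores(rng.normal(0.9, 0.03, 300))
        assert local_enrichment(center, (f5, f3)) > 1e-3

    def test_local_mismatched_counts_rejected(self):
        with pytest.raises(ValidationError):
            local_enrichment(self._scores([0.5, 0.6]),
                             (self._scores([0.5]), self._scores([0.5])))


class TestClassifyCcaat:
    def _results(self, ccaat_gp, ccaat_lp, other_gp=1.0):
        res = [MotifEnrichment("MA0060.1", ccaat_gp, ccaat_lp),
               MotifEnrichment("MA0001.1", other_gp, 1.0)]
        rank_enrichments(res)
        return res

    def test_primary_when_top_ranked(self):
        assert classify_ccaat(self._results(1e-50, 1e-60)) == "global_primary"

    def test_secondary_when_outranked_by_own_motif(self):
        assert classify_ccaat(self._results(1e-30, 1e-40, other_gp=1e-80)) \
            == "global_secondary"

    def test_local_only(self):
        assert classify_ccaat(self._results(1e-4, 1e-15)) == "local_only"

    def test_none(self):
        assert classify_ccaat(self._results(1e-4, 1e-6)) == "none"

    def test_missing_ccaat_matrix_rejected(self):
        res = [MotifEnrichment("MA0001.1", 1e-50, 1e-50)]
        with pytest.raises(ValidationError):
            classify_ccaat(res)


class TestPositionalBias:
    def test_middle_a_offset_of_synthetic_ccaat(self):
        pwm = ccaat_box_pwm()
        idx = pwm.consensus.find("CCAAT")
        assert middle_a_offset(pwm) == idx + 2
        assert pwm.consensus[middle_a_offset(pwm)] == "A"

    def test_matrix_without_ccaat_rejected(self):
        with pytest.raises(ValidationError):
            middle_a_offset(consensus_pwm("GGGGTTTT", "MX", "X"))

    # offsets with |d| < 10 would physically overwrite the 16 bp CCAAT
    # matrix with the 8 bp partner consensus, so plants use disjoint spacing
    @pytest.mark.parametrize("offset", [-20, -12, -11, -10, 10, 14, 20])
    def test_planted_offsets_recovered_exactly(self, offset):
        from regulome.motifs import positional_bias
        from regulome.synthetic import MotifPlant, make_genome, plant_sequences

        g = make_genome(1, 600_000, 150, seed=8)
        ccaat = ccaat_box_pwm()
        tf = consensus_pwm("TGACTCAG", "M1", "TF")
        plant_sequences(g, ccaat, [MotifPlant(tf, offset=offset, fraction=1.0)],
                        seed=9)
        centers = [(iv.start + iv.end) // 2 for iv in g.accessible_regions]
        co = peakset_from_summits(centers, "TF", chrom="chr1")
        pb = positional_bias(co, g.sequence, tf, ccaat)
        assert pb.mode_offset == offset

    def test_bimodal_plant_at_minus_10_and_minus_12(self):
        from regulome.motifs import positional_bias
        from regulome.synthetic import MotifPlant, make_genome, plant_sequences

        g = make_genome(1, 800_000, 200, seed=8)
        ccaat = ccaat_box_pwm()
        tf = consensus_pwm("CACGTGAC", "M3", "USF")
        half = np.arange(100)
        other = np.arange(100, 200)
        plant_sequences(g, ccaat,
                        [MotifPlant(tf, offset=-10, fraction=1.0, region_indices=half),
                         MotifPlant(tf, offset=-12, fraction=1.0, region_indices=other)],
                        seed=9)
        centers = [(iv.start + iv.end) // 2 for iv in g.accessible_regions]
        pb = positional_bias(peakset_from_summits(centers, "USF", chrom="chr1"),
                             g.sequence, tf, ccaat)
        vals, counts = np.unique(pb.offsets, return_counts=True)
        top2 = set(vals[np.argsort(counts)[-2:]])
        assert top2 == {-10, -12}

    def test_uniform_placement_is_rarely_called_biased(self):
        from regulome.motifs import positional_bias
        from regulome.synthetic import MotifPlant, make_genome, plant_sequences

        ok = 0
        for seed in range(10):
            g = make_genome(1, 500_000, 120, seed=seed)
            ccaat = ccaat_box_pwm()
            tf = consensus_pwm("TGACTCAG", "M1", "TF")
            plant_sequences(g, ccaat, [MotifPlant(None, fraction=1.0)], seed=seed)
            centers = [(iv.start + iv.end) // 2 for iv in g.accessible_regions]
            pb = positional_bias(peakset_from_summits(centers, "TF", chrom="chr1"),
                                 g.sequence, tf, ccaat)
            if pb.bias_p > 0.01:
                ok += 1
        assert ok >= 8

    def test_low_scoring_ccaat_regions_are_excluded(self):
        from regulome.motifs import positional_bias
        from regulome.synthetic import MotifPlant, make_genome, plant_sequences

        g = make_genome(1, 500_000, 100, seed=1)
        ccaat = ccaat_box_pwm()
        tf = consensus_pwm("TGACTCAG", "M1", "TF")
        # plant CCAAT in only half the regions: the rest should be excluded
        plant_sequences(g, ccaat,
                        [MotifPlant(tf, offset=-11, fraction=0.5)], seed=2)
        centers = [(iv.start + iv.end) // 2 for iv in g.accessible_regions]
        pb = positional_bias(peakset_from_summits(centers, "TF", chrom="chr1"),
                             g.sequence, tf, ccaat)
        assert pb.n_excluded > 0
        assert pb.mode_offset == -11
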