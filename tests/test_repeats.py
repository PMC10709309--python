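"""PWM scanning, motif density profiles, repeat enrichment with shuffle
nulls, and the 4-way motif/B1 peak taxonomy."""

import numpy as np
import pytest

from stagekit.genome import GenomeLayout, GenomicInterval, Peak
from stagekit.repeats import (
    MOTIF_IN_B1,
    MOTIF_NEXT_TO_B1,
    MOTIF_OUTSIDE_B1,
    NO_MOTIF,
    EnrichmentResult,
    MotifModel,
    RepeatAnnotation,
    accessible_repeat_enrichment,
    classify_peak_motif_repeat,
    consensus_motif_map,
    motif_density_profile,
    read_motifs,
    repeat_enrichment,
    scan_pwm,
    write_motifs,
)


def poly_a_motif(threshold=5.0, length=3):
    """+2 for A, -2 otherwise, per position."""
    lo = np.full((length, 4), -2.0)
    lo[:, 0] = 2.0
    return MotifModel("polyA", lo, threshold)


class TestScanPwm:
    def test_forward_hit(self):
        (hit,) = scan_pwm("AAA", poly_a_motif())
        assert (hit.strand, hit.score) == ("+", 6.0)
        assert (hit.interval.start, hit.interval.end) == (0, 3)

    def test_reverse_complement_hit(self):
        (hit,) = scan_pwm("TTT", poly_a_motif())
        assert (hit.strand, hit.score) == ("-", 6.0)

    def test_n_disqualifies_window(self):
        assert scan_pwm("ANA", poly_a_motif()) == []

    def test_threshold_above_max_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            poly_a_motif(threshold=7.0)

    def test_agrees_with_per_position_rescoring(self):
        """Exact score agreement with a brute-force rescoring oracle on a
        random 1-kb sequence, both strands."""
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        lo = rng.normal(0, 1.5, (6, 4))
        motif = MotifModel("rand", lo, float(np.sort(lo.max(axis=1))[:4].sum()))
        hits = {(h.interval.start, h.strand): h.score for h in scan_pwm(seq, motif)}
        comp = str.maketrans("ACGT", "TGCA")
        expected = {}
        for i in range(len(seq) - 6 + 1):
            window = seq[i:i + 6]
            fwd = sum(lo[j, "ACGT".index(b)] for j, b in enumerate(window))
            rc = window.translate(comp)[::-1]
            rev = sum(lo[j, "ACGT".index(b)] for j, b in enumerate(rc))
            if fwd >= motif.score_threshold:
                expected[(i, "+")] = fwd
            if rev >= motif.score_threshold:
                expected[(i, "-")] = rev
        assert set(hits) == set(expected)
        for k in hits:
            assert hits[k] == pytest.approx(expected[k])


def hit(chrom, start, length=3):
    from stagekit.repeats import MotifHit

    return MotifHit("m", GenomicInterval(chrom, start, start + length), "+", 6.0)


class TestMotifDensityProfile:
    def test_central_hit_every_peak(self):
        peaks = [Peak(GenomicInterval("chr1", c - 300, c + 300))
                 for c in (5_000, 9_000)]
        hits = [hit("chr1", c - 1) for c in (5_000, 9_000)]  # center = c
        profile = motif_density_profile(peaks, hits)
        assert profile[50] == 1.0  # central bin [0, 10)
        assert profile.sum() == 1.0

    def test_no_hits_all_zero(self):
        peaks = [Peak(GenomicInterval("chr1", 100, 700))]
        assert motif_density_profile(peaks, []).sum() == 0.0

    def test_binning_convention_plus_seven(self):
        peaks = [Peak(GenomicInterval("chr1", 4_700, 5_300))]  # center 5000
        profile = motif_density_profile(peaks, [hit("chr1", 5_006)])  # center +7
        assert profile[50] == 1.0  # offset +7 falls in bin [0, 10)

    def test_flank_edges(self):
        peaks = [Peak(GenomicInterval("chr1", 4_700, 5_300))]
        inside = motif_density_profile(peaks, [hit("chr1", 4_500 - 1)])  # -500
        outside = motif_density_profile(peaks, [hit("chr1", 5_500 - 1)])  # +500
        assert inside[0] == 1.0
        assert outside.sum() == 0.0


class TestRepeatEnrichment:
    def test_log2_pseudocount_formula(self):
        r = EnrichmentResult("B1", 10, 0.0, np.log2(11.0 / 1.0))
        assert r.log2_ratio == pytest.approx(3.4594, abs=1e-4)

    def test_observed_equal_expected_is_zero(self):
        genome = GenomeLayout({"chr1": 100_000})
        rng = np.random.default_rng(1)
        elements = [
            (GenomicInterval("chr1", int(s), int(s) + 150), "B1", "SINE")
            for s in rng.choice(np.arange(0, 99_000, 400), 80, replace=False)
        ]
        repeats = RepeatAnnotation(sorted(elements, key=lambda e: e[0].start))
        # peaks drawn by the same shuffle process as the null -> ratio ~ 0
        from stagekit.genome import shuffle_matched

        template = [Peak(GenomicInterval("chr1", 0, 200))] * 400
        placed = shuffle_matched(template, genome, 99)
        peaks = [Peak(iv) for iv in placed]
        (res,) = repeat_enrichment(peaks, repeats, genome, n_shuffles=400, seed=2)
        assert abs(res.log2_ratio) < 0.2

    def test_expected_converges_to_enumeration(self):
        """10-kb genome, one 1-kb repeat, 200-bp peaks: per-peak overlap
        probability is exactly 1199/9801 by start-position enumeration; the
        shuffle estimate at 500 shuffles must agree within 3 binomial sigma."""
        genome = GenomeLayout({"chr1": 10_000})
        repeats = RepeatAnnotation(
            [(GenomicInterval("chr1", 4_000, 5_000), "B1", "SINE")]
        )
        n_peaks, n_shuffles = 100, 500
        peaks = [Peak(GenomicInterval("chr1", 0, 200))] * n_peaks
        (res,) = repeat_enrichment(peaks, repeats, genome,
                                   n_shuffles=n_shuffles, seed=3)
        p = 1_199 / 9_801
        expected_count = n_peaks * p
        sigma = np.sqrt(n_peaks * p * (1 - p) / n_shuffles)
        assert abs(res.expected - expected_count) < 3 * sigma

    def test_unknown_family_warns(self):
        genome = GenomeLayout({"chr1": 10_000})
        repeats = RepeatAnnotation([(GenomicInterval("chr1", 0, 100), "B1", "SINE")])
        peaks = [Peak(GenomicInterval("chr1", 50, 250))]
        with pytest.warns(UserWarning, match="L1"):
            res = repeat_enrichment(peaks, repeats, genome, n_shuffles=2, seed=0,
                                    families=["L1"])
        assert res == []


class TestAccessibleRepeatEnrichment:
    def _repeats(self):
        return RepeatAnnotation(
            [(GenomicInterval("chr1", i * 1_000, i * 1_000 + 100), "B1", "SINE")
             for i in range(10)]
        )

    def test_whole_genome_accessible_ratio_one(self):
        genome = GenomeLayout({"chr1": 10_000})
        res = accessible_repeat_enrichment(
            [GenomicInterval("chr1", 0, 10_000)], self._repeats(), "B1", genome
        )
        assert res.observed == 10 and res.expected == pytest.approx(10.0)

    def test_accessible_exactly_on_elements(self):
        genome = GenomeLayout({"chr1": 10_000})
        accessible = [GenomicInterval("chr1", i * 1_000, i * 1_000 + 100)
                      for i in range(10)]  # 10% of the genome
        res = accessible_repeat_enrichment(accessible, self._repeats(), "B1", genome)
        assert res.observed / res.expected == pytest.approx(10.0)

    def test_no_overlap_uses_pseudocount(self):
        genome = GenomeLayout({"chr1": 10_000})
        res = accessible_repeat_enrichment(
            [GenomicInterval("chr1", 500, 600)], self._repeats(), "B1", genome
        )
        assert res.observed == 0
        assert res.log2_ratio == pytest.approx(np.log2(1 / (res.expected + 1)))


class TestPeakMotifTaxonomy:
    b1 = [GenomicInterval("chr1", 1_000, 1_135)]

    def _peak(self, start, end, name="p"):
        return Peak(GenomicInterval("chr1", start, end), 0.0, name)

    def test_hit_inside_b1_inside_peak(self):
        labels = classify_peak_motif_repeat(
            [self._peak(900, 1_300)], [hit("chr1", 1_050)], self.b1
        )
        assert labels["p"] == MOTIF_IN_B1

    def test_hit_outside_overlapping_b1(self):
        labels = classify_peak_motif_repeat(
            [self._peak(900, 1_300)], [hit("chr1", 920)], self.b1
        )
        assert labels["p"] == MOTIF_NEXT_TO_B1

    def test_hit_without_b1(self):
        labels = classify_peak_motif_repeat(
            [self._peak(5_000, 5_400)], [hit("chr1", 5_100)], self.b1
        )
        assert labels["p"] == MOTIF_OUTSIDE_B1

    def test_no_motif(self):
        labels = classify_peak_motif_repeat([self._peak(900, 1_300)], [], self.b1)
        assert labels["p"] == NO_MOTIF

    def test_labels_partition_peaks(self):
        rng = np.random.default_rng(4)
        peaks = [self._peak(int(s), int(s) + 300, f"p{i}")
                 for i, s in enumerate(rng.integers(0, 50_000, 100))]
        hits = [hit("chr1", int(s)) for s in rng.integers(0, 50_000, 200)]
        b1 = [GenomicInterval("chr1", int(s), int(s) + 135)
              for s in rng.integers(0, 50_000, 50)]
        labels = classify_peak_motif_repeat(peaks, hits, b1)
        assert len(labels) == 100


class TestConsensusMap:
    def test_embedded_instance_found(self):
        motif = poly_a_motif()
        res = consensus_motif_map("CCCAAACCC", [motif])
        assert res["polyA"]["positions"] == [3]
        assert res["polyA"]["frequency"] == 1.0

    def test_absent_motif_empty(self):
        res = consensus_motif_map("CCCCCCCC", [poly_a_motif()])
        assert res["polyA"]["positions"] == []

    def test_overlapping_motifs_reported_independently(self):
        m1, m2 = poly_a_motif(), poly_a_motif()
        m2.motif_id = "polyA2"
        res = consensus_motif_map("CCAAACC", [m1, m2])
        assert res["polyA"]["positions"] == res["polyA2"]["positions"] == [2]


def test_motif_file_roundtrip(tmp_path):
    probs = np.array([[0.85, 0.05, 0.05, 0.05],
                      [0.05, 0.85, 0.05, 0.05],
                      [0.05, 0.05, 0.05, 0.85]])
    motif = MotifModel.from_probabilities("toy", probs, 3.0)
    path = tmp_path / "motifs.txt"
    write_motifs([motif], path)
    (back,) = read_motifs(path)
    assert back.motif_id == "toy" and back.score_threshold == 3.0
    np.testing.assert_allclose(back.log_odds, motif.log_odds, atol=1e-5)
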