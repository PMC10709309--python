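"""Stage-specific peak rules, the MA-style differential stand-in, and the
footprint-change permutation statistic."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stagekit.dynamics import (
    accessibility_change,
    differential_peaks_ma,
    footprint_change,
    make_pairwise_calls,
    stage_specific_peaks,
)
from stagekit.genome import GenomeLayout, GenomicInterval, Peak
from stagekit.tracks import BinnedTrack

STAGES = ["s1", "s2", "s3", "s4", "s5"]


def z_frame(rows):
    return pd.DataFrame(rows, columns=STAGES,
                        index=[f"p{i}" for i in range(len(rows))])


def calls_favoring(stage, index):
    """All pairwise comparisons involving `stage` favor it; others ns."""
    out = {}
    for a, b in combinations(STAGES, 2):
        winner = stage if stage in (a, b) else "ns"
        out[(a, b)] = [winner] * len(index)
    return out


class TestStageSpecificPeaks:
    @pytest.mark.parametrize(
        "z,expected",
        [
            ([1.5, 0.2, -0.3, 0.5, -1.0], "s1"),          # two extra positives
            ([1.5, 0.2, 0.3, 0.5, 0.1], "shared/none"),   # four extra positives
            ([0.9, -1, -1, -1, -1], "shared/none"),       # focal z <= 1
        ],
    )
    def test_quoted_rule(self, z, expected):
        frame = z_frame([z])
        assignment = stage_specific_peaks(frame, calls_favoring("s1", frame.index))
        assert assignment["p0"] == expected

    def test_assigns_at_most_one_stage(self):
        rng = np.random.default_rng(0)
        frame = z_frame(rng.normal(0, 1.5, size=(100, 5)))
        # every comparison ns except s2 always favored
        assignment = stage_specific_peaks(frame, calls_favoring("s2", frame.index))
        assert set(assignment.unique()) <= {"s2", "shared/none"}

    def test_disfavored_stage_never_assigned(self):
        frame = z_frame([[2.0, -1, -1, -1, -1]])
        calls = calls_favoring("s1", frame.index)
        calls[("s1", "s2")] = ["s2"]  # s1 loses one comparison
        assert stage_specific_peaks(frame, calls)["p0"] == "shared/none"

    def test_missing_pair_raises(self):
        frame = z_frame([[2.0, -1, -1, -1, -1]])
        calls = calls_favoring("s1", frame.index)
        del calls[("s3", "s4")]
        with pytest.raises(KeyError, match="s3"):
            stage_specific_peaks(frame, calls)


class TestDifferentialPeaksMa:
    def test_identical_conditions_no_calls(self):
        rng = np.random.default_rng(1)
        sig = pd.DataFrame(rng.uniform(1, 50, (30, 2)),
                           index=[f"p{i}" for i in range(30)])
        res = differential_peaks_ma(sig, sig.copy())
        assert (res["call"] == "ns").all()

    def test_global_scaling_absorbed(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(rng.uniform(1, 50, (40, 2)),
                         index=[f"p{i}" for i in range(40)])
        res = differential_peaks_ma(a, 2.0 * a)
        assert (res["call"] == "ns").all()
        assert res["m"].abs().max() < 0.1

    def test_single_outlier_peak_called(self):
        # flat background, one peak jumping 1 -> 16: after median-M scaling
        # (median ~ 0 on the background) its normalized M is ~ 4
        idx = [f"p{i}" for i in range(20)]
        a = pd.DataFrame({"r1": [10.0] * 19 + [1.0]}, index=idx)
        b = pd.DataFrame({"r1": [10.0] * 19 + [16.0]}, index=idx)
        res = differential_peaks_ma(a, b)
        assert res.loc["p19", "call"] == "b"
        assert res.loc["p19", "m"] == pytest.approx(
            np.log2(16.01 / 1.01), abs=1e-9
        )

    def test_too_few_common_peaks_raises(self):
        a = pd.DataFrame({"r1": [1.0] * 5})
        with pytest.raises(ValueError, match="common peaks"):
            differential_peaks_ma(a, a)

    def test_make_pairwise_calls_shapes(self):
        rng = np.random.default_rng(3)
        idx = [f"p{i}" for i in range(15)]
        sigs = {s: pd.DataFrame(rng.uniform(1, 20, (15, 2)), index=idx)
                for s in ("2C", "8C")}
        calls = make_pairwise_calls(sigs)
        assert set(calls) == {("2C", "8C")}
        assert set(calls[("2C", "8C")]) <= {"2C", "8C", "ns"}


def _ztrack(genome, values_by_chrom):
    track = BinnedTrack(genome, 100,
                        {c: np.zeros_like(v, dtype=float)
                         for c, v in values_by_chrom.items()})
    track.zscore = {c: np.asarray(v, dtype=float)
                    for c, v in values_by_chrom.items()}
    return track


class TestAccessibilityChange:
    def test_delta_and_reduced_flag(self):
        genome = GenomeLayout({"chr1": 1_000})
        nc = _ztrack(genome, {"chr1": np.full(10, 2.0)})
        kd = _ztrack(genome, {"chr1": np.full(10, 0.5)})
        peaks = [Peak(GenomicInterval("chr1", 100, 300))]
        changes, frac = accessibility_change(peaks, nc, kd)
        assert changes[0].delta == pytest.approx(-1.5)
        assert changes[0].reduced and frac == 1.0

    def test_fraction_counts(self):
        genome = GenomeLayout({"chr1": 1_000})
        nc = _ztrack(genome, {"chr1": np.array([2, 2, 2, 2, 0, 0, 0, 0, 0, 0.0])})
        kd = _ztrack(genome, {"chr1": np.array([0, 0, 0, 2, 0, 0, 0, 0, 0, 0.0])})
        peaks = [Peak(GenomicInterval("chr1", i * 100, i * 100 + 100))
                 for i in range(4)]
        _, frac = accessibility_change(peaks, nc, kd)
        assert frac == pytest.approx(0.75)

    def test_tolerance_band(self):
        genome = GenomeLayout({"chr1": 200})
        nc = _ztrack(genome, {"chr1": np.array([1.0, 1.0])})
        kd = _ztrack(genome, {"chr1": np.array([0.95, 0.95])})
        changes, _ = accessibility_change(
            [Peak(GenomicInterval("chr1", 0, 200))], nc, kd, delta_threshold=0.1
        )
        assert not changes[0].reduced  # delta -0.05 inside the band


class TestFootprintChange:
    def _tracks(self, delta_bins, n_bins=20):
        genome = GenomeLayout({"chr1": n_bins * 100})
        nc = _ztrack(genome, {"chr1": np.zeros(n_bins)})
        kd = _ztrack(genome, {"chr1": np.asarray(delta_bins, dtype=float)})
        return genome, nc, kd

    def hits_at(self, centers, length=10):
        return [GenomicInterval("chr1", c - length // 2, c - length // 2 + length)
                for c in centers]

    def test_extreme_shift_hits_minimum_p(self):
        # occurrences sit on delta = -1 bins while the rest of the region is 0
        delta = np.zeros(20)
        delta[5] = -1.0
        _, nc, kd = self._tracks(delta)
        regions = [GenomicInterval("chr1", 400, 1_400)]
        hits = self.hits_at([550, 552, 554, 556, 558])
        (score,) = footprint_change(
            {"m": hits}, regions, nc, kd, window=40, n_perm=199, seed=0
        )
        assert score.p_value == pytest.approx(1 / 200)
        assert score.mean_delta == pytest.approx(-1.0)

    def test_zero_delta_everywhere(self):
        _, nc, kd = self._tracks(np.zeros(20))
        regions = [GenomicInterval("chr1", 0, 2_000)]
        (score,) = footprint_change(
            {"m": self.hits_at([100, 300, 500, 700, 900])}, regions, nc, kd,
            n_perm=99, seed=1,
        )
        assert score.mean_delta == 0.0
        assert score.p_value == 1.0

    def test_exact_mode_matches_independent_enumeration(self):
        """5 occurrences on a 20-position region: the exact-mode p equals a
        from-scratch enumeration over all C(20,5) position subsets."""
        rng = np.random.default_rng(7)
        delta = rng.normal(0, 1, 20)
        genome, nc, kd = self._tracks(delta)
        region = GenomicInterval("chr1", 1_000, 1_020)  # 20 bp, within bin 10
        centers = [1_001, 1_005, 1_009, 1_013, 1_017]
        (score,) = footprint_change(
            {"m": self.hits_at(centers, length=2)}, [region], nc, kd,
            window=100, seed=2, exact=True,
        )
        # independent oracle: per-position window means, brute force
        def window_mean(pos):
            lo, hi = max(0, (pos - 100) // 100), min(20, -(-(pos + 100) // 100))
            return delta[lo:hi].mean()

        pool = [window_mean(p) for p in range(1_000, 1_020)]
        obs = np.mean([window_mean(c) for c in centers])
        subsets = list(combinations(pool, 5))
        count = sum(abs(np.mean(s)) >= abs(obs) - 1e-12 for s in subsets)
        assert score.p_value == pytest.approx(count / len(subsets))

    def test_sparse_motif_skipped_with_warning(self):
        _, nc, kd = self._tracks(np.zeros(20))
        regions = [GenomicInterval("chr1", 0, 2_000)]
        with pytest.warns(UserWarning, match="skipped"):
            scores = footprint_change(
                {"rare": self.hits_at([100, 200])}, regions, nc, kd,
                n_perm=19, seed=3,
            )
        assert scores == []
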