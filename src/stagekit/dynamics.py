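"""Stage-specific peak identification and accessibility-change statistics.

Three analyses live here:

* **Stage-specific peaks.** Distal peaks pooled across stages are assigned to
  one stage when (i) the pairwise differential comparisons involving that
  stage favor it, (ii) its Z-scored signal there exceeds 1, and (iii) the
  signal is positive at no more than two additional stages.

* **MA-style differential comparison.** A deliberately simple normalized
  comparison between two conditions: per-peak M = log2 ratio, recentered so
  the median M over common peaks is zero (absorbing global scale), called
  differential at |M| >= 1 with a consistent sign across every replicate
  pair. This is a documented stand-in for a full hierarchical differential
  model; externally computed calls can be supplied instead wherever a
  pairwise-call mapping is accepted.

* **Footprint-change surrogate.** For each motif, the mean accessibility
  change (delta Z, knockdown minus control) in a window around its
  occurrences inside differentially accessible regions, against a null of
  equally sized position sets drawn uniformly from the same regions. This is
  a windowed aggregate statistic, not a base-pair footprint depth model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, Peak
from .tracks import BinnedTrack, region_signal

__all__ = [
    "AccessibilityChange",
    "FootprintChangeScore",
    "stage_signal_matrix",
    "stage_specific_peaks",
    "differential_peaks_ma",
    "make_pairwise_calls",
    "accessibility_change",
    "footprint_change",
]

Z_HIGH = 1.0       # focal-stage enrichment threshold (normalized RPKM > 1)
Z_POSITIVE = 0.0   # positivity threshold at non-focal stages
MAX_OTHER_POSITIVE = 2
MA_EPS = 0.01
MA_THRESHOLD = 1.0
DELTA_DEFAULT = 0.1


@dataclass(frozen=True)
class AccessibilityChange:
    peak: Peak
    delta: float  # z_KD - z_NC
    reduced: bool


@dataclass(frozen=True)
class FootprintChangeScore:
    motif_id: str
    mean_delta: float
    p_value: float
    n_occurrences: int


def stage_signal_matrix(
    peaks: Sequence[Peak], tracks_by_stage: Mapping[str, BinnedTrack]
) -> pd.DataFrame:
    """Peaks x stages matrix of mean Z-scored signal over each peak."""
    intervals = [p.interval for p in peaks]
    data = {
        stage: region_signal(track, intervals, use="zscore")
        for stage, track in tracks_by_stage.items()
    }
    index = [p.name or f"peak_{i}" for i, p in enumerate(peaks)]
    return pd.DataFrame(data, index=index)


def stage_specific_peaks(
    z_by_stage: pd.DataFrame,
    pairwise_calls: Mapping[tuple[str, str], Sequence[str]],
    z_high: float = Z_HIGH,
    z_positive: float = Z_POSITIVE,
    max_other_positive: int = MAX_OTHER_POSITIVE,
) -> pd.Series:
    """Assign each pooled distal peak to at most one stage.

    ``z_by_stage`` is peaks x stages (mean Z-scored signal over the peak);
    ``pairwise_calls[(a, b)]`` gives, per peak, which condition the
    differential comparison favors (``a``, ``b`` or ``"ns"``). A peak is
    specific to stage ``s`` when it is favored over at least one other stage,
    never disfavored in a comparison involving ``s``, z(s) > 1, and z > 0 at
    no more than two other stages. A peak qualifying at several stages (via
    ``ns`` calls) goes to the stage with the highest z. Non-qualifying peaks
    get the sentinel ``"shared/none"``.
    """
    stages = list(z_by_stage.columns)
    calls: dict[frozenset, pd.DataFrame] = {}
    for (a, b), winner in pairwise_calls.items():
        if a not in stages or b not in stages:
            raise KeyError(f"pairwise call for unknown stage pair {(a, b)}")
        calls[frozenset((a, b))] = pd.Series(list(winner), index=z_by_stage.index)
    for a, b in combinations(stages, 2):
        if frozenset((a, b)) not in calls:
            raise KeyError(f"missing differential calls for stage pair {(a, b)}")

    assignment = pd.Series("shared/none", index=z_by_stage.index, dtype=object)
    z = z_by_stage.to_numpy()
    for pi, peak in enumerate(z_by_stage.index):
        best: tuple[float, str] | None = None
        for si, s in enumerate(stages):
            if z[pi, si] <= z_high:
                continue
            others = [z[pi, ti] for ti, t in enumerate(stages) if t != s]
            if sum(v > z_positive for v in others) > max_other_positive:
                continue
            favored, disfavored = 0, 0
            for t in stages:
                if t == s:
                    continue
                w = calls[frozenset((s, t))][peak]
                if w == s:
                    favored += 1
                elif w == t:
                    disfavored += 1
            if disfavored or not favored:
                continue
            key = (z[pi, si], s)
            if best is None or key > best:
                best = key
        if best is not None:
            assignment[peak] = best[1]
    return assignment


def differential_peaks_ma(
    signal_a_reps: pd.DataFrame,
    signal_b_reps: pd.DataFrame,
    eps: float = MA_EPS,
    m_threshold: float = MA_THRESHOLD,
    min_common_peaks: int = 10,
) -> pd.DataFrame:
    """Median-M normalized differential comparison over common peaks.

    Inputs are peaks x replicates signal tables on the same (common) peak
    index. Returns a frame with columns ``m`` (normalized log2 B/A) and
    ``call`` in {``a``, ``b``, ``ns``}: differential iff |m| >= m_threshold
    and every replicate pair agrees in sign after normalization.
    """
    if not signal_a_reps.index.equals(signal_b_reps.index):
        raise ValueError("conditions must share one common-peak index")
    if signal_a_reps.shape[1] < 1 or signal_b_reps.shape[1] < 1:
        raise ValueError("need >= 1 replicate per condition")
    if len(signal_a_reps) < min_common_peaks:
        raise ValueError(
            f"need >= {min_common_peaks} common peaks for median-M scaling, "
            f"got {len(signal_a_reps)}"
        )
    la = np.log2(signal_a_reps.mean(axis=1) + eps)
    lb = np.log2(signal_b_reps.mean(axis=1) + eps)
    m = lb - la
    offset = float(np.median(m))
    m_norm = m - offset

    # Per replicate-pair normalized M, for the sign-consistency rule.
    pair_ms = []
    for ca in signal_a_reps.columns:
        for cb in signal_b_reps.columns:
            pair_ms.append(
                np.log2(signal_b_reps[cb] + eps)
                - np.log2(signal_a_reps[ca] + eps)
                - offset
            )
    pair_mat = np.column_stack(pair_ms)

    call = np.full(len(m_norm), "ns", dtype=object)
    up = (m_norm >= m_threshold).to_numpy() & (pair_mat > 0).all(axis=1)
    down = (m_norm <= -m_threshold).to_numpy() & (pair_mat < 0).all(axis=1)
    call[up] = "b"
    call[down] = "a"
    return pd.DataFrame({"m": m_norm, "call": call}, index=signal_a_reps.index)


def make_pairwise_calls(
    rep_signals_by_stage: Mapping[str, pd.DataFrame],
    eps: float = MA_EPS,
    m_threshold: float = MA_THRESHOLD,
) -> dict[tuple[str, str], list[str]]:
    """All-pairs differential calls in the form ``stage_specific_peaks`` wants.

    Each entry maps a stage pair to per-peak winners (the favored stage name
    or ``"ns"``) from :func:`differential_peaks_ma`.
    """
    stages = list(rep_signals_by_stage)
    out = {}
    for a, b in combinations(stages, 2):
        res = differential_peaks_ma(
            rep_signals_by_stage[a], rep_signals_by_stage[b],
            eps=eps, m_threshold=m_threshold,
        )
        out[(a, b)] = [a if c == "a" else b if c == "b" else "ns" for c in res["call"]]
    return out


def accessibility_change(
    peaks: Sequence[Peak],
    track_nc: BinnedTrack,
    track_kd: BinnedTrack,
    delta_threshold: float = DELTA_DEFAULT,
) -> tuple[list[AccessibilityChange], float]:
    """Per-peak accessibility change (Z_KD - Z_NC) and the reduced fraction.

    A peak counts as reduced when its delta falls below ``-delta_threshold``
    (default 0.1 Z-units, a tolerance band against normalization jitter).
    """
    intervals = [p.interval for p in peaks]
    z_nc = region_signal(track_nc, intervals, use="zscore")
    z_kd = region_signal(track_kd, intervals, use="zscore")
    changes = [
        AccessibilityChange(p, float(d), bool(d < -delta_threshold))
        for p, d in zip(peaks, z_kd - z_nc)
    ]
    frac = sum(c.reduced for c in changes) / len(changes) if changes else float("nan")
    return changes, frac


# ---------------------------------------------------------------------------
# Footprint-change surrogate
# ---------------------------------------------------------------------------


def _delta_prefix(track_nc: BinnedTrack, track_kd: BinnedTrack):
    """Per-chromosome prefix sums of (Z_KD - Z_NC) for O(1) window means."""
    if track_nc.bin_width != track_kd.bin_width:
        raise ValueError("tracks have different bin widths")
    prefix = {}
    for chrom in track_nc.genome.chrom_names:
        d = track_kd.values(chrom, "zscore") - track_nc.values(chrom, "zscore")
        prefix[chrom] = np.concatenate([[0.0], np.cumsum(d)])
    return prefix


def _window_means(
    positions: np.ndarray, chrom: str, prefix, bin_width: int, n_bins: int, window: int
) -> np.ndarray:
    lo = np.clip((positions - window) // bin_width, 0, n_bins)
    hi = np.clip(-(-(positions + window) // bin_width), 0, n_bins)
    cs = prefix[chrom]
    width = np.maximum(hi - lo, 1)
    return (cs[hi] - cs[lo]) / width


def footprint_change(
    motif_hits_by_motif: Mapping[str, Sequence[GenomicInterval]],
    differential_regions: Sequence[GenomicInterval],
    track_nc: BinnedTrack,
    track_kd: BinnedTrack,
    window: int = 100,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    min_occurrences: int = 5,
    exact: bool = False,
    exact_limit: int = 200_000,
) -> list[FootprintChangeScore]:
    """Permutation test for motif-aggregate accessibility change.

    For each motif, the statistic is the mean delta-Z (KD minus NC) over
    +/-``window`` bp around every occurrence whose center lies inside a
    differentially accessible region. The null re-draws position sets of the
    same size uniformly (without replacement) from all positions within those
    regions; two-sided p = (1 + #{|null| >= |observed|}) / (n_perm + 1).
    With ``exact=True`` and a feasibly small pool, all position subsets are
    enumerated instead and p is the exact subset fraction. Motifs with fewer
    than ``min_occurrences`` qualifying occurrences are skipped with a
    warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prefix = _delta_prefix(track_nc, track_kd)
    bw = track_nc.bin_width
    genome = track_nc.genome

    # Pool of candidate positions: every bp inside the differential regions.
    pool_pos: dict[str, np.ndarray] = {}
    for region in differential_regions:
        pos = np.arange(region.start, region.end)
        pool_pos.setdefault(region.chrom, [])
        pool_pos[region.chrom].append(pos)
    chroms, pool_vals = [], []
    for chrom, parts in pool_pos.items():
        pos = np.unique(np.concatenate(parts))
        vals = _window_means(pos, chrom, prefix, bw, -(-genome.length_of(chrom) // bw), window)
        chroms.append(chrom)
        pool_vals.append(vals)
    pool = np.concatenate(pool_vals) if pool_vals else np.array([])

    def inside(iv: GenomicInterval) -> bool:
        c = iv.center
        return any(
            r.chrom == iv.chrom and r.start <= c < r.end for r in differential_regions
        )

    scores = []
    for motif_id, hits in motif_hits_by_motif.items():
        occ = [h for h in hits if inside(h)]
        if len(occ) < min_occurrences:
            warnings.warn(
                f"motif {motif_id!r}: only {len(occ)} occurrences inside "
                "differential regions; skipped", stacklevel=2,
            )
            continue
        obs_vals = np.concatenate([
            _window_means(
                np.array([h.center for h in occ if h.chrom == chrom]),
                chrom, prefix, bw, -(-genome.length_of(chrom) // bw), window,
            )
            for chrom in {h.chrom for h in occ}
        ])
        obs = float(obs_vals.mean())
        n = len(occ)
        if len(pool) < n:
            raise ValueError("differential regions smaller than occurrence set")

        n_subsets = math.comb(len(pool), n)
        if exact and n_subsets <= exact_limit:
            count = sum(
                abs(np.mean(pool[list(idx)])) >= abs(obs) - 1e-12
                for idx in combinations(range(len(pool)), n)
            )
            p = count / n_subsets
        else:
            null = np.empty(n_perm)
            for k in range(n_perm):
                null[k] = pool[rng.choice(len(pool), size=n, replace=False)].mean()
            p = (1 + int((np.abs(null) >= abs(obs) - 1e-12).sum())) / (n_perm + 1)
        scores.append(FootprintChangeScore(motif_id, obs, float(p), n))
    return scores
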