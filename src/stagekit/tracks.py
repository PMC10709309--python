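"""Fragment-to-bin signal quantification and genome-wide normalization.

Deduplicated fragment intervals are reduced to RPKM over fixed-width bins
(default 100 bp), then Z-score normalized jointly across all genome bins so
that tracks from libraries of different depth and signal-to-noise are
comparable. Each fragment is counted once, in the bin containing its
midpoint, so total counts are conserved:

    sum_bins rpkm * (bin_width / 1000) * (library_size / 1e6) = n_fragments

The Z-score uses the population standard deviation; a constant track
normalizes to all zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import GenomeLayout, GenomicInterval

__all__ = [
    "FragmentSet",
    "BinnedTrack",
    "bin_signal",
    "zscore_normalize",
    "region_signal",
    "profile_matrix",
    "write_bedgraph",
]

DEFAULT_BIN_WIDTH = 100


@dataclass
class FragmentSet:
    """Deduplicated aligned fragments; library size = fragment count."""

    fragments: list[GenomicInterval]

    @property
    def library_size(self) -> int:
        return len(self.fragments)


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin vectors of RPKM and Z-scored signal."""

    genome: GenomeLayout
    bin_width: int
    rpkm: dict[str, np.ndarray]
    zscore: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def normalized(self) -> bool:
        return bool(self.zscore)

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome.length_of(chrom) // self.bin_width)  # ceil div

    def values(self, chrom: str, use: str = "auto") -> np.ndarray:
        """Bin vector for one chromosome; ``auto`` prefers Z-scores."""
        if use == "auto":
            use = "zscore" if self.normalized else "rpkm"
        if use == "zscore":
            if not self.normalized:
                raise ValueError("track not Z-score normalized yet")
            return self.zscore[chrom]
        return self.rpkm[chrom]


def bin_signal(
    fragments: FragmentSet,
    genome: GenomeLayout,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> BinnedTrack:
    """RPKM per fixed-width genome bin from fragment midpoints.

    RPKM = count / (bin_width / 1000) / (library_size / 1e6). The last,
    possibly partial, bin keeps the full bin_width in the denominator.
    """
    if fragments.library_size == 0:
        raise ValueError("empty fragment set (library_size = 0)")
    mids_by_chrom: dict[str, list[int]] = {c: [] for c in genome.chrom_names}
    for frag in fragments.fragments:
        if frag.chrom not in mids_by_chrom:
            raise KeyError(f"unknown chromosome {frag.chrom!r}")
        mids_by_chrom[frag.chrom].append(frag.start + frag.end)
    counts = {}
    for chrom, length in genome.chrom_lengths.items():
        n_bins = -(-length // bin_width)
        mids = np.asarray(mids_by_chrom[chrom], dtype=np.int64) // 2
        if mids.size and (mids.min() < 0 or mids.max() >= length):
            raise ValueError(f"fragment midpoint outside chromosome {chrom!r}")
        counts[chrom] = np.bincount(mids // bin_width, minlength=n_bins).astype(np.int64)
    scale = (bin_width / 1000.0) * (fragments.library_size / 1e6)
    rpkm = {chrom: c / scale for chrom, c in counts.items()}
    return BinnedTrack(genome, bin_width, rpkm)


def zscore_normalize(track: BinnedTrack) -> BinnedTrack:
    """Z-score the RPKM vectors jointly over all genome bins (population sd).

    Idempotent on its Z output; a zero-variance track maps to all zeros.
    """
    flat = np.concatenate([track.rpkm[c] for c in track.genome.chrom_names])
    mu = float(flat.mean())
    sd = float(flat.std())
    # guard against rounding: a constant track can yield sd ~ eps * |mu|
    if sd <= 1e-12 * max(1.0, abs(mu)):
        z = {c: np.zeros_like(v) for c, v in track.rpkm.items()}
    else:
        z = {c: (v - mu) / sd for c, v in track.rpkm.items()}
    return BinnedTrack(track.genome, track.bin_width, dict(track.rpkm), z)


def _region_bins(track: BinnedTrack, region: GenomicInterval) -> tuple[int, int]:
    """Index range of bins overlapping the region, clipped to the chromosome."""
    n = track.n_bins(region.chrom)
    lo = max(0, region.start // track.bin_width)
    hi = min(n, -(-region.end // track.bin_width))
    return lo, hi


def region_signal(
    track: BinnedTrack,
    regions: Sequence[GenomicInterval],
    use: str = "auto",
    statistic=np.mean,
) -> np.ndarray:
    """Per-region summary (default mean) over the bins each region overlaps.

    Every overlapped bin is weighted equally. Regions running off the
    chromosome end are clipped with a warning.
    """
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        if region.chrom not in track.genome:
            raise KeyError(f"unknown chromosome {region.chrom!r}")
        if region.end > track.genome.length_of(region.chrom):
            warnings.warn(
                f"region {region.chrom}:{region.start}-{region.end} clipped to "
                f"chromosome end", stacklevel=2,
            )
        lo, hi = _region_bins(track, region)
        vals = track.values(region.chrom, use)[lo:hi]
        out[i] = statistic(vals) if len(vals) else np.nan
    return out


def profile_matrix(
    track: BinnedTrack,
    anchors: Sequence[tuple[str, int]],
    flank: int,
    bin_width: int | None = None,
    use: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor-aligned signal matrix plus column means.

    Row i, column j holds the track value at position
    ``anchor_i - flank + j * w + w // 2``; positions off the genome are NaN
    and are excluded from the column means (``nanmean`` over rows).
    Returns ``(matrix, column_means)`` with ``2 * flank // w`` columns.
    """
    w = bin_width or track.bin_width
    n_cols = (2 * flank) // w
    mat = np.full((len(anchors), n_cols), np.nan)
    for i, (chrom, center) in enumerate(anchors):
        length = track.genome.length_of(chrom)
        vals = track.values(chrom, use)
        for j in range(n_cols):
            pos = center - flank + j * w + w // 2
            if 0 <= pos < length:
                mat[i, j] = vals[pos // track.bin_width]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_means = np.nanmean(mat, axis=0)
    return mat, col_means


def write_bedgraph(track: BinnedTrack, path, use: str = "auto") -> None:
    """Export the track as fixed-step bedGraph (one line per non-empty bin
    for RPKM, every bin for Z-scores)."""
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            vals = track.values(chrom, use)
            length = track.genome.length_of(chrom)
            for i, v in enumerate(vals):
                start = i * track.bin_width
                end = min(start + track.bin_width, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")
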