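"""Genome coordinate model and core interval algebra.

Coordinates are 0-based half-open throughout (BED convention). The atoms
defined here — :class:`GenomeLayout`, :class:`GenomicInterval`, :class:`Peak`
and :class:`GeneModel` — are consumed by every downstream analysis module.

Peak location classes follow the standard promoter/distal dichotomy used in
embryo CUT&RUN work: a peak overlapping a +/-2.5 kb window around any TSS is a
promoter peak; a peak at least 2.5 kb from every TSS is a distal peak and is
treated downstream as a putative enhancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "classify_peak_location",
    "nearest_tss_distance",
    "shuffle_matched",
    "DEFAULT_PROMOTER_HALFWIDTH",
]

DEFAULT_PROMOTER_HALFWIDTH = 2500


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths for one genome assembly."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        lengths = dict(self.chrom_lengths)
        if len(lengths) == 0:
            raise ValueError("genome has no chromosomes")
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chrom_lengths", lengths)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Edge-to-point distance; 0 when ``pos`` lies inside the interval.

        Edges sit at ``start`` and ``end - 1`` (the last covered base), so a
        point just past the right end is at distance 1.
        """
        if self.start <= pos < self.end:
            return 0
        if pos < self.start:
            return self.start - pos
        return pos - (self.end - 1)

    def validate(self, genome: GenomeLayout) -> None:
        if self.chrom not in genome:
            raise KeyError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome.length_of(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome.length_of(self.chrom)}"
            )


@dataclass
class Peak:
    """A called peak: an interval plus score, name, and a location class
    (``promoter`` / ``distal`` / ``unassigned``) set by classification."""

    interval: GenomicInterval
    score: float = 0.0
    name: str = ""
    location_class: str = "unassigned"
    nearest_gene: str | None = None
    nearest_gene_distance: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"peak {self.name!r} has non-finite score")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """Gene with a single TSS derived from its transcript span.

    TSS is ``txStart`` on the plus strand and ``txEnd - 1`` on the minus
    strand (refFlat semantics in 0-based coordinates).
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    span: GenomicInterval
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        tss = self.span.start if self.strand == "+" else self.span.end - 1
        object.__setattr__(self, "tss", tss)
        if not self.span.start <= tss < self.span.end:
            raise ValueError(f"gene {self.gene_id}: TSS outside span")


def _tss_index(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, list[GeneModel]]]:
    """Per-chromosome (sorted TSS array, genes in that order).

    Sorting is by (tss, gene_id) so that downstream tie-breaking — smaller
    distance first, then lexicographic gene_id — is deterministic.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gs], dtype=np.int64), gs)
    return index


def _nearest_in_index(
    interval: GenomicInterval,
    index: Mapping[str, tuple[np.ndarray, list[GeneModel]]],
) -> tuple[float, GeneModel | None]:
    entry = index.get(interval.chrom)
    if entry is None:
        return float("inf"), None
    tss_arr, gs = entry
    # Candidates: TSS just left/right of the interval, plus any TSS inside it.
    lo = int(np.searchsorted(tss_arr, interval.start, side="left"))
    hi = int(np.searchsorted(tss_arr, interval.end, side="left"))
    candidates = set(range(max(0, lo - 1), min(len(gs), hi + 1)))
    best: tuple[int, str] | None = None
    best_gene: GeneModel | None = None
    for i in sorted(candidates):
        d = interval.distance_to_point(int(tss_arr[i]))
        key = (d, gs[i].gene_id)
        if best is None or key < best:
            best = key
            best_gene = gs[i]
    assert best is not None and best_gene is not None
    return float(best[0]), best_gene


def nearest_tss_distance(
    anchor: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[float, str | None]:
    """Distance from an interval to the nearest gene TSS on its chromosome.

    Returns ``(distance, gene_id)``; distance is 0 when a TSS falls inside the
    anchor, and ``inf`` (with ``None``) when the chromosome carries no gene.
    Ties break on smaller distance then lexicographic gene_id.
    """
    dist, gene = _nearest_in_index(anchor, _tss_index(genes))
    return dist, (gene.gene_id if gene is not None else None)


def classify_peak_location(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    genome: GenomeLayout | None = None,
) -> list[Peak]:
    """Partition peaks into promoter vs distal relative to gene TSSs.

    A peak overlapping any window ``[tss - h, tss + h)`` is a promoter peak
    and is annotated with its nearest gene; otherwise it is distal (its
    minimum edge-to-TSS distance is then >= h by construction). With no genes
    supplied, all peaks stay ``unassigned`` and a warning is emitted.
    """
    if genome is not None:
        for p in peaks:
            p.interval.validate(genome)
        for g in genes:
            g.span.validate(genome)
    if not genes:
        warnings.warn("no genes supplied; peaks left unassigned", stacklevel=2)
        return [replace_location(p, "unassigned", None, None) for p in peaks]

    index = _tss_index(genes)
    out = []
    for p in peaks:
        dist, gene = _nearest_in_index(p.interval, index)
        if gene is None:
            out.append(replace_location(p, "distal", None, float("inf")))
            continue
        h = promoter_halfwidth
        window_lo, window_hi = gene.tss - h, gene.tss + h
        overlaps = p.interval.start < window_hi and window_lo < p.interval.end
        if overlaps:
            out.append(replace_location(p, "promoter", gene.gene_id, dist))
        else:
            out.append(replace_location(p, "distal", gene.gene_id, dist))
    return out


def replace_location(
    peak: Peak, location: str, gene_id: str | None, distance: float | None
) -> Peak:
    new = Peak(peak.interval, peak.score, peak.name)
    new.location_class = location
    new.nearest_gene = gene_id
    new.nearest_gene_distance = distance
    return new


# ---------------------------------------------------------------------------
# Length-matched shuffle null
# ---------------------------------------------------------------------------


def _allowed_segments(
    chrom_len: int, length: int, excluded: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Half-open ranges of valid start positions for an interval of ``length``
    on a chromosome, avoiding placements that overlap any excluded span."""
    max_start = chrom_len - length
    if max_start < 0:
        return []
    # A start s is forbidden iff [s, s+length) overlaps some excluded [a, b),
    # i.e. s in [a - length + 1, b).
    forbidden = sorted(
        (max(0, a - length + 1), min(max_start + 1, b)) for a, b in excluded
    )
    segments = []
    cursor = 0
    for a, b in forbidden:
        if b <= cursor:
            continue
        if a > cursor:
            segments.append((cursor, min(a, max_start + 1)))
        cursor = max(cursor, b)
        if cursor > max_start:
            break
    if cursor <= max_start:
        segments.append((cursor, max_start + 1))
    return [(a, b) for a, b in segments if b > a]


def valid_start_count(
    genome: GenomeLayout,
    length: int,
    excluded: Sequence[GenomicInterval] = (),
) -> dict[str, int]:
    """Number of valid start positions per chromosome for a given length."""
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in excluded:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: sum(
            b - a
            for a, b in _allowed_segments(clen, length, excl_by_chrom.get(chrom, []))
        )
        for chrom, clen in genome.chrom_lengths.items()
    }


def shuffle_matched(
    peaks: Sequence[Peak | GenomicInterval],
    genome: GenomeLayout,
    seed: int | np.random.Generator,
    excluded: Sequence[GenomicInterval] = (),
) -> list[GenomicInterval]:
    """Length-matched random control intervals, one per input peak.

    Each control keeps its source peak's length and is placed uniformly over
    all valid start positions genome-wide (chromosome chosen with probability
    proportional to its number of valid starts), never overlapping ``excluded``.
    Deterministic for a given seed. Raises if a peak has no valid placement.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in excluded:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    seg_cache: dict[int, list[tuple[str, list[tuple[int, int]]]]] = {}

    def segments_for(length: int):
        if length not in seg_cache:
            seg_cache[length] = [
                (chrom, _allowed_segments(clen, length, excl_by_chrom.get(chrom, [])))
                for chrom, clen in genome.chrom_lengths.items()
            ]
        return seg_cache[length]

    out = []
    for i, p in enumerate(peaks):
        iv = p.interval if isinstance(p, Peak) else p
        length = len(iv)
        per_chrom = segments_for(length)
        counts = np.array(
            [sum(b - a for a, b in segs) for _, segs in per_chrom], dtype=np.int64
        )
        total = int(counts.sum())
        if total == 0:
            name = p.name if isinstance(p, Peak) and p.name else f"#{i}"
            raise ValueError(f"no valid placement for peak {name} (length {length})")
        # Map one uniform draw over [0, total) to a (chromosome, start) pair.
        r = int(rng.integers(total))
        ci = int(np.searchsorted(np.cumsum(counts), r, side="right"))
        chrom, segs = per_chrom[ci]
        r -= int(counts[:ci].sum())
        for a, b in segs:
            if r < b - a:
                out.append(GenomicInterval(chrom, a + r, a + r + length))
                break
            r -= b - a
    return out


def overlaps_any(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> bool:
    """True iff ``query`` overlaps (>= 1 bp) at least one target interval."""
    for t in targets:
        if query.overlaps(t):
            return True
    return False


def count_overlapping(
    queries: Iterable[GenomicInterval], targets: Sequence[GenomicInterval]
) -> int:
    """Number of query intervals overlapping >= 1 target (sorted-sweep)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts_ends[chrom] = (
            np.array([a for a, _ in ivs], dtype=np.int64),
            np.maximum.accumulate(np.array([b for _, b in ivs], dtype=np.int64)),
        )
    n = 0
    for q in queries:
        entry = starts_ends.get(q.chrom)
        if entry is None:
            continue
        starts, cum_ends = entry
        k = int(np.searchsorted(starts, q.end, side="left"))
        if k > 0 and cum_ends[k - 1] > q.start:
            n += 1
    return n
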