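"""PWM motif scanning and repeat-family enrichment analytics.

Murine SINE B1 elements (~135 bp retrotransposon copies) can carry embedded
transcription-factor binding motifs, making them a reservoir of regulatory
sequence in early embryos. This module scans genomic sequence with log-odds
position weight matrices, profiles motif density around peak centers, tests
repeat-family enrichment in peak sets against length-matched shuffle nulls
(log2 observed/expected with a pseudocount), and classifies peaks into the
four-way taxonomy: motif in B1 / motif next to B1 / motif non-overlapping
with B1 / no motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    GenomeLayout,
    GenomicInterval,
    Peak,
    count_overlapping,
    shuffle_matched,
)

__all__ = [
    "MotifModel",
    "MotifHit",
    "RepeatAnnotation",
    "EnrichmentResult",
    "scan_pwm",
    "scan_genome",
    "motif_density_profile",
    "repeat_enrichment",
    "accessible_repeat_enrichment",
    "classify_peak_motif_repeat",
    "consensus_motif_map",
    "read_motifs",
    "write_motifs",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G
UNIFORM_BG = np.array([0.25, 0.25, 0.25, 0.25])
PROB_FLOOR = 1e-3  # clip PWM probabilities before taking log-odds


@dataclass
class MotifModel:
    """Log-odds PWM (positions x ACGT) with a score threshold."""

    motif_id: str
    log_odds: np.ndarray
    score_threshold: float
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("log-odds matrix must be positions x 4 (ACGT)")
        if not np.isfinite(self.log_odds).all():
            raise ValueError("log-odds matrix must be finite")
        if self.score_threshold > self.max_score + 1e-9:
            raise ValueError("threshold exceeds the maximum achievable score")

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_probabilities(
        cls,
        motif_id: str,
        probs: np.ndarray,
        score_threshold: float,
        background: np.ndarray | None = None,
    ) -> "MotifModel":
        """Build from per-position base probabilities; log-odds = log2(p/bg)
        with probabilities floored at 1e-3."""
        bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
        p = np.clip(np.asarray(probs, dtype=float), PROB_FLOOR, 1.0)
        return cls(motif_id, np.log2(p / bg), score_threshold, bg)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: GenomicInterval  # forward-strand coordinates, length = motif length
    strand: str
    score: float


@dataclass
class RepeatAnnotation:
    """Repeat elements labeled by family (B1, B2, MERVL, ...) and class."""

    elements: list[tuple[GenomicInterval, str, str]]  # (interval, family, class)

    def __post_init__(self) -> None:
        for iv, family, _cls in self.elements:
            if not family:
                raise ValueError(f"repeat at {iv.chrom}:{iv.start} has empty family")

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, family, _ in self.elements:
            seen.setdefault(family)
        return list(seen)

    def by_family(self, family: str) -> list[GenomicInterval]:
        return [iv for iv, fam, _ in self.elements if fam == family]

    @classmethod
    def from_bed_records(cls, peaks: Sequence[Peak]) -> "RepeatAnnotation":
        """Interpret BED column 4 as family, accepting 'class/family' syntax."""
        elements = []
        for p in peaks:
            name = p.name
            if "/" in name:
                cls_name, family = name.split("/", 1)
            else:
                cls_name, family = "", name
            elements.append((p.interval, family, cls_name))
        return cls(elements)


def _encode(sequence: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_pwm(
    sequence: str,
    motif: MotifModel,
    chrom: str = "seq",
    offset: int = 0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All positions where the motif's log-odds score meets its threshold.

    Windows containing N are disqualified. Minus-strand hits score the
    reverse complement but are reported on forward-strand coordinates.
    ``offset`` shifts reported coordinates (for scanning sub-sequences).
    """
    L = len(motif)
    codes = _encode(sequence)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return []
    # windows x motif-positions index matrix
    idx = codes[np.arange(n_win)[:, None] + np.arange(L)[None, :]]
    valid = (idx != 4).all(axis=1)
    safe = np.where(idx == 4, 0, idx)

    pos_idx = np.arange(L)
    fwd = motif.log_odds[pos_idx[None, :], safe].sum(axis=1)
    hits = []
    thr = motif.score_threshold - 1e-9
    for i in np.flatnonzero(valid & (fwd >= thr)):
        hits.append(
            MotifHit(
                motif.motif_id,
                GenomicInterval(chrom, offset + int(i), offset + int(i) + L),
                "+",
                float(fwd[i]),
            )
        )
    if both_strands:
        # Reverse complement of window = complement codes reversed; score it
        # with the forward matrix.
        rc = _COMPLEMENT_INDEX[safe][:, ::-1]
        rev = motif.log_odds[pos_idx[None, :], rc].sum(axis=1)
        for i in np.flatnonzero(valid & (rev >= thr)):
            hits.append(
                MotifHit(
                    motif.motif_id,
                    GenomicInterval(chrom, offset + int(i), offset + int(i) + L),
                    "-",
                    float(rev[i]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_genome(
    sequences: Mapping[str, str], motif: MotifModel, both_strands: bool = True
) -> list[MotifHit]:
    """Scan every chromosome sequence with one motif."""
    hits = []
    for chrom, seq in sequences.items():
        hits.extend(scan_pwm(seq, motif, chrom=chrom, both_strands=both_strands))
    return hits


def motif_density_profile(
    peaks: Sequence[Peak],
    hits: Sequence[MotifHit],
    flank: int = 500,
    resolution: int = 10,
) -> np.ndarray:
    """Average motif density around peak centers.

    Counts hit centers per ``resolution``-bp bin over [-flank, +flank)
    relative to each peak center, averaged over peaks: 100 bins for the
    default 10-bp resolution within 500 bp.
    """
    n_bins = (2 * flank) // resolution
    profile = np.zeros(n_bins)
    if not peaks:
        return profile
    hit_centers: dict[str, np.ndarray] = {}
    for h in hits:
        hit_centers.setdefault(h.interval.chrom, []).append(h.interval.center)
    hit_centers = {c: np.asarray(v) for c, v in hit_centers.items()}
    for p in peaks:
        centers = hit_centers.get(p.chrom)
        if centers is None:
            continue
        off = centers - p.interval.center
        sel = off[(off >= -flank) & (off < flank)]
        bins = (sel + flank) // resolution
        np.add.at(profile, bins.astype(int), 1)
    return profile / len(peaks)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed: float
    expected: float
    log2_ratio: float
    pseudocount: float = 1.0


def _log2_ratio(observed: float, expected: float, c: float) -> float:
    return float(np.log2((observed + c) / (expected + c)))


def repeat_enrichment(
    peaks: Sequence[Peak],
    repeats: RepeatAnnotation,
    genome: GenomeLayout,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
    pseudocount: float = 1.0,
    families: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Peak-level repeat-family enrichment against length-matched shuffles.

    observed = number of peaks overlapping (>= 1 bp) at least one element of
    the family; expected = the same count averaged over ``n_shuffles``
    length-matched random peak sets; enrichment = log2((obs + c)/(exp + c)).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wanted = list(families) if families is not None else repeats.families()
    available = set(repeats.families())
    intervals = [p.interval for p in peaks]
    shuffles = [shuffle_matched(intervals, genome, rng) for _ in range(n_shuffles)]

    results = []
    for family in wanted:
        if family not in available:
            warnings.warn(f"repeat family {family!r} absent from annotation; skipped",
                          stacklevel=2)
            continue
        elements = repeats.by_family(family)
        observed = count_overlapping(intervals, elements)
        expected = float(
            np.mean([count_overlapping(s, elements) for s in shuffles])
        )
        results.append(
            EnrichmentResult(
                family, observed, expected,
                _log2_ratio(observed, expected, pseudocount), pseudocount,
            )
        )
    return results


def accessible_repeat_enrichment(
    accessible_regions: Sequence[GenomicInterval],
    repeats: RepeatAnnotation,
    family: str,
    genome: GenomeLayout,
    pseudocount: float = 1.0,
) -> EnrichmentResult:
    """Enrichment of a repeat family within accessible chromatin, against a
    genome-fraction background.

    observed = family elements overlapping accessible regions; expected =
    total family elements x (accessible bp / genome bp). The plain ratio is
    observed/expected (0 maps through the pseudocounted log2).
    """
    elements = repeats.by_family(family)
    if not elements:
        raise ValueError(f"repeat family {family!r} absent from annotation")
    # Accessible bp: union length, merged per chromosome.
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in accessible_regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    accessible_bp = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_a, cur_b = spans[0]
        for a, b in spans[1:]:
            if a > cur_b:
                accessible_bp += cur_b - cur_a
                cur_a, cur_b = a, b
            else:
                cur_b = max(cur_b, b)
        accessible_bp += cur_b - cur_a
    observed = count_overlapping(elements, list(accessible_regions))
    expected = len(elements) * accessible_bp / genome.total_length
    return EnrichmentResult(
        family, observed, expected,
        _log2_ratio(observed, expected, pseudocount), pseudocount,
    )


MOTIF_IN_B1 = "motif_in_B1"
MOTIF_NEXT_TO_B1 = "motif_next_to_B1"
MOTIF_OUTSIDE_B1 = "motif_non_overlapping_B1"
NO_MOTIF = "no_motif"
PEAK_MOTIF_CLASSES = (MOTIF_IN_B1, MOTIF_NEXT_TO_B1, MOTIF_OUTSIDE_B1, NO_MOTIF)


def classify_peak_motif_repeat(
    peaks: Sequence[Peak],
    hits: Sequence[MotifHit],
    b1_elements: Sequence[GenomicInterval],
) -> dict[str, str]:
    """Four-way peak taxonomy by motif presence and B1 context.

    Per peak: ``motif_in_B1`` when >= 1 hit lies fully inside a B1 element
    that overlaps the peak; else ``motif_next_to_B1`` when the peak has a
    hit and overlaps B1; else ``motif_non_overlapping_B1`` when it has a hit
    but no B1 overlap; else ``no_motif``. Labels form a partition of peaks.
    """
    labels = {}
    for i, p in enumerate(peaks):
        name = p.name or f"peak_{i}"
        peak_hits = [h for h in hits if h.interval.overlaps(p.interval)]
        peak_b1 = [b for b in b1_elements if b.overlaps(p.interval)]
        if any(
            b.start <= h.interval.start and h.interval.end <= b.end
            for h in peak_hits for b in peak_b1
        ):
            labels[name] = MOTIF_IN_B1
        elif peak_hits and peak_b1:
            labels[name] = MOTIF_NEXT_TO_B1
        elif peak_hits:
            labels[name] = MOTIF_OUTSIDE_B1
        else:
            labels[name] = NO_MOTIF
    return labels


def consensus_motif_map(
    consensus_sequence: str, motifs: Sequence[MotifModel]
) -> dict[str, dict]:
    """Motif occurrence positions and frequency along a consensus sequence.

    Positions are 0-based offsets from the consensus start; frequency is
    hits per consensus copy (= hit count on the single consensus).
    """
    out = {}
    for motif in motifs:
        hits = scan_pwm(consensus_sequence, motif, chrom="consensus")
        out[motif.motif_id] = {
            "positions": [h.interval.start for h in hits],
            "strands": [h.strand for h in hits],
            "frequency": float(len(hits)),
        }
    return out


# ---------------------------------------------------------------------------
# Minimal HOMER-style motif text format
# ---------------------------------------------------------------------------


def read_motifs(path) -> list[MotifModel]:
    """Read motifs from a minimal HOMER-style text file.

    Each record: ``>motif_id<TAB>threshold`` then one row of four base
    probabilities (A C G T) per motif position. Probabilities are converted
    to log-odds against a uniform background.
    """
    motifs = []
    name, thr, rows = None, None, []

    def flush():
        if name is not None:
            if not rows:
                raise ValueError(f"motif {name!r} has no probability rows")
            motifs.append(MotifModel.from_probabilities(name, np.array(rows), thr))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected '>id<TAB>threshold'")
                name, thr, rows = fields[0], float(fields[1]), []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 probabilities")
                rows.append(vals)
    flush()
    return motifs


def write_motifs(motifs: Sequence[MotifModel], path) -> None:
    """Write motifs back in the minimal HOMER-style format (probabilities
    recovered from log-odds against each motif's background)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id}\t{m.score_threshold:g}\n")
            probs = (2.0 ** m.log_odds) * m.background
            for row in probs:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")
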