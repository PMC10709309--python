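"""Enhancer-gene linking and association statistics.

Distal peaks are treated as putative enhancers and assigned gene-centrically:
each gene links to its nearest distal peak within 50 kb of its TSS. Gene-set
overlaps (e.g. knockdown-downregulated genes vs promoter-bound genes) are
tested with a two-sided Fisher exact test on the 2x2 membership table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DifferentialResult
from .genome import GeneModel, Peak

__all__ = [
    "PeakGeneLink",
    "ContingencyResult",
    "assign_enhancer_targets",
    "cumulative_distance_curve",
    "contingency_association",
    "report_fraction",
    "group_fold_changes",
    "DEFAULT_LINK_DISTANCE",
]

DEFAULT_LINK_DISTANCE = 50_000


@dataclass(frozen=True)
class PeakGeneLink:
    gene_id: str
    peak: Peak
    distance: int  # TSS to nearest peak edge, bp
    tied: bool = False  # equidistant alternative existed (leftmost chosen)


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    direction: str  # "positive" (OR > 1), "negative" (OR < 1), "none"


def _nearest_peak(
    gene: GeneModel, peaks_by_chrom: Mapping[str, list[Peak]]
) -> tuple[Peak | None, int, bool]:
    """Nearest peak to a gene's TSS; ties resolved to the leftmost peak."""
    candidates = peaks_by_chrom.get(gene.chrom, [])
    best: tuple[int, int, int] | None = None  # (distance, start, index)
    for i, p in enumerate(candidates):
        d = p.interval.distance_to_point(gene.tss)
        key = (d, p.interval.start, i)
        if best is None or key < best:
            best = key
    if best is None:
        return None, -1, False
    tied = sum(
        1 for p in candidates if p.interval.distance_to_point(gene.tss) == best[0]
    ) > 1
    winner = candidates[best[2]]
    return winner, best[0], tied


def assign_enhancer_targets(
    genes: Sequence[GeneModel],
    distal_peaks: Sequence[Peak],
    max_distance: int = DEFAULT_LINK_DISTANCE,
) -> list[PeakGeneLink]:
    """Link each gene to its nearest distal peak within ``max_distance`` bp.

    Gene-centric: one link per gene (a peak may serve several genes). Genes
    with no peak in range are omitted. Equidistant candidates resolve to the
    leftmost peak, recorded via the ``tied`` flag.
    """
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in distal_peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    links = []
    for gene in genes:
        peak, distance, tied = _nearest_peak(gene, peaks_by_chrom)
        if peak is not None and distance <= max_distance:
            links.append(PeakGeneLink(gene.gene_id, peak, distance, tied))
    return links


def cumulative_distance_curve(
    gene_sets: Mapping[str, Sequence[str]],
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
    distance_grid: Sequence[int],
) -> pd.DataFrame:
    """Cumulative fraction of each gene set within each TSS-to-peak distance.

    F_set(d) = fraction of the set's genes whose nearest-peak distance is
    <= d (genes on peak-free chromosomes never accumulate). Rows = grid
    distances, columns = set names; each column is monotone in [0, 1].
    """
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    dist_by_gene = {}
    for gene in genes:
        _, d, _ = _nearest_peak(gene, peaks_by_chrom)
        dist_by_gene[gene.gene_id] = d if d >= 0 else np.inf
    grid = np.asarray(list(distance_grid))
    data = {}
    for name, ids in gene_sets.items():
        dists = np.array([dist_by_gene.get(g, np.inf) for g in ids])
        data[name] = (
            (dists[None, :] <= grid[:, None]).mean(axis=1)
            if len(ids)
            else np.zeros(len(grid))
        )
    return pd.DataFrame(data, index=grid)


def contingency_association(
    in_set_a: Sequence[bool], in_set_b: Sequence[bool]
) -> ContingencyResult:
    """Two-sided Fisher exact test on the 2x2 membership cross-table.

    The p-value sums hypergeometric probabilities of tables (at fixed
    margins) no more likely than the observed one. The odds ratio is the
    unconditional ad/bc, with a Haldane half-count correction applied when
    any cell is zero.
    """
    a_vec = np.asarray(in_set_a, dtype=bool)
    b_vec = np.asarray(in_set_b, dtype=bool)
    if a_vec.shape != b_vec.shape or a_vec.size == 0:
        raise ValueError("membership vectors must be equal-length and non-empty")
    a = int(np.sum(a_vec & b_vec))
    b = int(np.sum(a_vec & ~b_vec))
    c = int(np.sum(~a_vec & b_vec))
    d = int(np.sum(~a_vec & ~b_vec))
    return contingency_from_table(((a, b), (c, d)))


def contingency_from_table(
    table: tuple[tuple[int, int], tuple[int, int]]
) -> ContingencyResult:
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    direction = "positive" if odds > 1 else "negative" if odds < 1 else "none"
    return ContingencyResult(((a, b), (c, d)), float(odds), float(p), direction)


def report_fraction(numerator: int, denominator: int, digits: int = 0) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up.

    Half-up rounding reproduces conventionally printed percentages (e.g.
    45/224 -> 20%, 929/9744 -> 9.5%) that banker's rounding can miss.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-digits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def group_fold_changes(
    diff_results: Sequence[DifferentialResult],
    grouping: Mapping[str, tuple[bool, str]],
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Fold-change summaries per (bound, motif-count-bin) gene group.

    ``grouping`` maps gene_id -> (TF-bound at promoter?, motif-count bin
    label such as '0', '1', '2', '>=3'). Returns one row per non-empty group
    with the five-number log2FC summary; groups below ``min_group_size`` are
    flagged ``small``.
    """
    fc = {r.gene_id: r.log2_fold_change for r in diff_results}
    groups: dict[tuple[bool, str], list[float]] = {}
    for gene, key in grouping.items():
        if gene in fc:
            groups.setdefault(tuple(key), []).append(fc[gene])
    rows = []
    for (bound, motif_bin), vals in sorted(groups.items()):
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        rows.append(
            {
                "bound": bound,
                "motif_bin": motif_bin,
                "n": len(vals),
                "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
                "small": len(vals) < min_group_size,
            }
        )
    return pd.DataFrame(rows)
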