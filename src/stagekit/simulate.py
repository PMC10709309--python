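"""Seeded synthetic-data generators with planted ground truth.

Every pipeline stage is testable offline against data whose answers are
known by construction: a small genome carrying B1-like ~135-bp repeat
elements (a configurable fraction of which embed an exact binding-motif
instance at a fixed consensus offset), stage-wise FPKM tables with planted
gene programs (minor/major ZGA, maternal, stage-specific, early/late ICM),
and stage-resolved binding/accessibility fragment sets in which a simulated
knockdown attenuates signal at 8C-specific bound sites only.

The generator emulates the *statistical structure* of embryo CUT&RUN /
ATAC-seq / RNA-seq data — planted classes with margins, lognormal replicate
noise, length-scale-realistic repeats — not read-level sequencing noise,
mappability, or real repeat phylogeny. Defaults are fixed study conditions:
`p_motif_in_b1 = 0.525` and `accessible_b1_motif_rate = 0.664` mirror the
genome-wide and accessible-B1 motif rates reported for the real mouse
genome, and sigma = 0.2 log-units is a typical replicate-level FPKM noise
scale. All randomness flows through one `numpy` Generator seeded from the
config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .genome import GeneModel, GenomeLayout, GenomicInterval, Peak
from .repeats import MotifModel, RepeatAnnotation
from .tracks import FragmentSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "planted_motif",
    "generate_genome",
    "generate_expression",
    "generate_binding_and_accessibility",
    "generate_kd_expression",
    "generate_gene_models",
    "random_motif_occurrences",
    "simulate_all",
    "B1_CONSENSUS",
    "MOTIF_CONSENSUS",
    "MOTIF_OFFSET",
]

# Nuclear-receptor-like 9-bp motif planted in B1 copies; RC = TGACCTTGA.
MOTIF_CONSENSUS = "TCAAGGTCA"
MOTIF_OFFSET = 30  # fixed offset of the motif inside the B1-like consensus

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _family_consensus(family_seed: int, length: int, avoid: str) -> str:
    """Deterministic per-family consensus sequence, free of ``avoid`` and its
    reverse complement."""
    rng = np.random.default_rng(family_seed)
    rc = avoid[::-1].translate(str.maketrans("ACGT", "TGCA"))
    while True:
        seq = _random_seq(rng, length)
        if avoid not in seq and rc not in seq:
            return seq


# B1-like consensus: fixed for all seeds so consensus-relative coordinates are
# stable; the planted motif slot at MOTIF_OFFSET is filled per element copy.
B1_CONSENSUS = (
    _family_consensus(101, MOTIF_OFFSET, MOTIF_CONSENSUS)
    + MOTIF_CONSENSUS
    + _family_consensus(102, 135 - MOTIF_OFFSET - len(MOTIF_CONSENSUS), MOTIF_CONSENSUS)
)

_FAMILY_SPECS = {
    # family: (length, consensus-seed)
    "B2": (190, 201),
    "B4": (250, 202),
    "MERVL": (300, 203),
}

STAGES = ("FGO", "MII", "1C", "E2C", "L2C", "4C", "8C", "ICM", "TE")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort (fixed defaults)."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_repeats: int = 900
    family_mix: dict = field(
        default_factory=lambda: {"B1": 0.6, "B2": 0.2, "B4": 0.1, "MERVL": 0.1}
    )
    p_motif_in_b1: float = 0.525
    accessible_b1_motif_rate: float = 0.664
    b1_mutation_rate: float = 0.08
    # expression
    n_genes: int = 500
    n_genomic_genes: int = 60
    noise_sigma: float = 0.2  # lognormal replicate noise, log-units
    n_replicates: int = 2
    class_fractions: dict = field(
        default_factory=lambda: {
            "minor_ZGA": 0.10,
            "major_ZGA": 0.15,
            "major_ZGA_oocyte_upregulated": 0.03,
            "maternal": 0.15,
            "stage_specific:4C": 0.05,
            "stage_specific:8C": 0.05,
            "early_ICM": 0.06,
            "late_ICM": 0.04,
        }
    )
    # binding / accessibility
    n_peaks_2c_specific: int = 150
    n_peaks_8c_specific: int = 150
    n_peaks_shared: int = 100
    peak_halfwidth: int = 150
    fragments_per_site: int = 60
    n_background_fragments: int = 30_000
    fragment_length: int = 150
    fragment_spread: float = 80.0
    kd_effect: float = 0.9  # fractional loss of enriched fragments at 8C sites
    # knockdown expression comparison
    n_de_replicates: int = 4
    de_noise_sigma: float = 0.1
    kd_log2fc: float = 2.5
    p_down_early_icm: float = 0.45
    p_down_other: float = 0.08
    p_promoter_bound_down: float = 0.6
    p_promoter_bound_other: float = 0.1

    def __post_init__(self) -> None:
        for name, p in (
            ("p_motif_in_b1", self.p_motif_in_b1),
            ("accessible_b1_motif_rate", self.accessible_b1_motif_rate),
            ("kd_effect", self.kd_effect),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.chrom_length <= 0 or self.n_genes <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class GroundTruth:
    """Planted answers sufficient to score every classifier and enrichment."""

    gene_programs: dict[str, str] = field(default_factory=dict)
    early_icm: set = field(default_factory=set)
    late_icm: set = field(default_factory=set)
    b1_carrier: list[bool] = field(default_factory=list)  # per B1 element
    bound_b1_2c: list[int] = field(default_factory=list)  # indices into B1 list
    bound_b1_8c: list[int] = field(default_factory=list)
    bound_b1_shared: list[int] = field(default_factory=list)
    kd_down_genes: set = field(default_factory=set)
    promoter_bound_genes: set = field(default_factory=set)
    peak_carrier_fraction: float = float("nan")


def planted_motif(threshold: float = 12.0) -> MotifModel:
    """The generator's binding-motif PWM (0.85 consensus base / 0.05 others).

    At the default threshold only exact consensus matches (either strand)
    score through: one mismatch costs ~4.1 bits from the ~15.9-bit maximum.
    """
    probs = np.full((len(MOTIF_CONSENSUS), 4), 0.05)
    for i, base in enumerate(MOTIF_CONSENSUS):
        probs[i, "ACGT".index(base)] = 0.85
    return MotifModel.from_probabilities("planted_motif", probs, threshold)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return arr.tobytes().decode()


_MOTIF_RC = MOTIF_CONSENSUS[::-1].translate(str.maketrans("ACGT", "TGCA"))


def _contains_motif(seq: str) -> bool:
    return MOTIF_CONSENSUS in seq or _MOTIF_RC in seq


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeLayout, dict[str, str], RepeatAnnotation, list[bool]]:
    """Random genome with non-overlapping repeat elements.

    Returns (layout, sequences, repeats, b1_carrier) where ``b1_carrier[i]``
    says whether the i-th B1 element (in annotation order) embeds an exact
    planted-motif instance at the consensus offset. Non-carrier elements are
    regenerated until motif-free, so `p_motif_in_b1 = 0` yields a genome
    whose B1 copies contain no hit at all.
    """
    rng = rng or np.random.default_rng(config.seed)
    layout = GenomeLayout(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    seqs = {c: bytearray(_random_seq(rng, config.chrom_length).encode())
            for c in layout.chrom_names}

    families = list(config.family_mix)
    probs = np.array([config.family_mix[f] for f in families], dtype=float)
    probs /= probs.sum()
    fam_draw = rng.choice(len(families), size=config.n_repeats, p=probs)

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    elements: list[tuple[GenomicInterval, str, str]] = []
    b1_carrier: list[bool] = []
    chrom_names = layout.chrom_names

    for k in range(config.n_repeats):
        family = families[int(fam_draw[k])]
        if family == "B1":
            length = len(B1_CONSENSUS)
        else:
            length = _FAMILY_SPECS[family][0]
        # rejection-place without overlap
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(config.n_chroms))]
            start = int(rng.integers(config.chrom_length - length + 1))
            if all(not (start < b and a < start + length) for a, b in occupied[chrom]):
                break
        else:
            raise RuntimeError("could not place repeat element without overlap")
        occupied[chrom].append((start, start + length))

        if family == "B1":
            carrier = bool(rng.random() < config.p_motif_in_b1)
            while True:
                body = _mutate(rng, B1_CONSENSUS, config.b1_mutation_rate)
                if carrier:
                    body = (
                        body[:MOTIF_OFFSET]
                        + MOTIF_CONSENSUS
                        + body[MOTIF_OFFSET + len(MOTIF_CONSENSUS):]
                    )
                    break
                if not _contains_motif(body):
                    break
            b1_carrier.append(carrier)
            cls = "SINE"
        else:
            consensus = _family_consensus(_FAMILY_SPECS[family][1], length,
                                          MOTIF_CONSENSUS)
            while True:
                body = _mutate(rng, consensus, config.b1_mutation_rate)
                if not _contains_motif(body):
                    break
            cls = "LTR" if family == "MERVL" else "SINE"
        seqs[chrom][start:start + length] = body.encode()
        elements.append((GenomicInterval(chrom, start, start + length), family, cls))

    sequences = {c: bytes(s).decode() for c, s in seqs.items()}
    return layout, sequences, RepeatAnnotation(elements), b1_carrier


_CLASS_PROFILES = {
    # stage -> (low, high) uniform FPKM range of the class mean trajectory.
    # Margins sit well clear of the 5 / 1 FPKM decision thresholds relative
    # to the default 0.2 log-unit replicate noise.
    "minor_ZGA": {"FGO": (0, 2), "MII": (0, 2), "1C": (0, 2), "E2C": (15, 50),
                  "L2C": (15, 50), "4C": (10, 40), "8C": (10, 40),
                  "ICM": (5, 20), "TE": (5, 20)},
    "major_ZGA": {"FGO": (0, 2), "MII": (0, 2), "1C": (0, 2), "E2C": (0, 1.5),
                  "L2C": (15, 50), "4C": (10, 40), "8C": (10, 40),
                  "ICM": (5, 20), "TE": (5, 20)},
    "major_ZGA_oocyte_upregulated": {
        "FGO": (6, 9), "MII": (6, 9), "1C": (6, 9), "E2C": (8, 15),
        "L2C": (60, 120), "4C": (40, 90), "8C": (40, 90),
        "ICM": (20, 50), "TE": (20, 50)},
    "maternal": {"FGO": (12, 40), "MII": (12, 40), "1C": (8, 30),
                 "E2C": (4, 10), "L2C": (0.2, 2.5), "4C": (0, 2), "8C": (0, 2),
                 "ICM": (0, 2), "TE": (0, 2)},
    "stage_specific:4C": {"FGO": (0, 0.4), "MII": (0, 0.4), "1C": (0, 0.4),
                          "E2C": (0, 0.4), "L2C": (0, 0.4), "4C": (15, 50),
                          "8C": (10, 40), "ICM": (5, 20), "TE": (5, 20)},
    "stage_specific:8C": {"FGO": (0, 0.4), "MII": (0, 0.4), "1C": (0, 0.4),
                          "E2C": (0, 0.4), "L2C": (0, 0.4), "4C": (0, 0.4),
                          "8C": (15, 50), "ICM": (5, 20), "TE": (5, 20)},
    "early_ICM": {"FGO": (0, 0.4), "MII": (0, 0.4), "1C": (0, 0.4),
                  "E2C": (0, 0.4), "L2C": (0, 0.4), "4C": (0.5, 2),
                  "8C": (3, 10), "ICM": (15, 50), "TE": (0, 0.4)},
    "late_ICM": {"FGO": (0, 0.4), "MII": (0, 0.4), "1C": (0, 0.4),
                 "E2C": (0, 0.4), "L2C": (0, 0.4), "4C": (0, 0.4),
                 "8C": (0, 0.4), "ICM": (15, 50), "TE": (0, 0.4)},
    "none": {s: (0, 2) for s in STAGES},
}


def generate_expression(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionTable, GroundTruth]:
    """Stage-wise FPKM table with planted gene-program labels.

    Class-mean trajectories are drawn uniformly inside per-class FPKM bands
    whose margins exceed twice the replicate noise scale; replicates add
    lognormal noise exp(sigma * N(0,1)).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    truth = GroundTruth()
    labels = []
    for cls, frac in config.class_fractions.items():
        labels.extend([cls] * int(round(frac * config.n_genes)))
    labels.extend(["none"] * (config.n_genes - len(labels)))
    rng.shuffle(labels)

    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    cols = [f"{s}:{r + 1}" for s in STAGES for r in range(config.n_replicates)]
    values = np.zeros((config.n_genes, len(cols)))
    for gi, (gene, cls) in enumerate(zip(gene_ids, labels)):
        truth.gene_programs[gene] = cls
        profile = _CLASS_PROFILES[cls]
        ci = 0
        for stage in STAGES:
            lo, hi = profile[stage]
            mean = rng.uniform(lo, hi)
            for _ in range(config.n_replicates):
                values[gi, ci] = mean * np.exp(config.noise_sigma * rng.standard_normal())
                ci += 1
        if cls == "early_ICM":
            truth.early_icm.add(gene)
        elif cls == "late_ICM":
            truth.late_icm.add(gene)
    table = ExpressionTable(pd.DataFrame(values, index=gene_ids, columns=cols))
    return table, truth


def generate_kd_expression(
    config: SyntheticConfig,
    truth: GroundTruth,
    table: ExpressionTable,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """8C control vs knockdown replicate tables with planted downregulation.

    Early ICM genes are downregulated at a higher rate than other genes,
    each by the configured log2 effect; ``truth.kd_down_genes`` and
    ``truth.promoter_bound_genes`` (binding enriched among down genes)
    record the planted associations.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    base = table.stage_means()["8C"].clip(lower=0.5)
    genes = table.gene_ids
    down = set()
    for g in genes:
        p = config.p_down_early_icm if g in truth.early_icm else config.p_down_other
        if rng.random() < p:
            down.add(g)
    truth.kd_down_genes = down
    for g in genes:
        p = (
            config.p_promoter_bound_down
            if g in down
            else config.p_promoter_bound_other
        )
        if rng.random() < p:
            truth.promoter_bound_genes.add(g)

    n = config.n_de_replicates
    sig = config.de_noise_sigma

    def draw(mean: pd.Series) -> pd.DataFrame:
        noise = np.exp(sig * rng.standard_normal((len(genes), n)))
        return pd.DataFrame(mean.to_numpy()[:, None] * noise, index=genes,
                            columns=[f"rep{r + 1}" for r in range(n)])

    kd_mean = base.copy()
    for g in down:
        kd_mean[g] = base[g] / 2 ** config.kd_log2fc
    return draw(base), draw(kd_mean)


@dataclass
class BindingAccessibility:
    """Per-stage peaks, fragment sets and the knockdown contrast."""

    peaks_2c_specific: list[Peak]
    peaks_8c_specific: list[Peak]
    peaks_shared: list[Peak]
    fragments: dict[str, FragmentSet]  # keys like "2C_NC", "8C_KD", "2C:rep1"

    @property
    def all_peaks(self) -> list[Peak]:
        return self.peaks_2c_specific + self.peaks_8c_specific + self.peaks_shared


def _site_fragments(
    rng: np.random.Generator,
    center: int,
    chrom: str,
    chrom_len: int,
    n: int,
    length: int,
    spread: float,
) -> list[GenomicInterval]:
    mids = np.clip(
        rng.normal(center, spread, size=n).astype(int),
        length // 2,
        chrom_len - length // 2 - 1,
    )
    return [GenomicInterval(chrom, int(m - length // 2), int(m - length // 2 + length))
            for m in mids]


def generate_binding_and_accessibility(
    config: SyntheticConfig,
    layout: GenomeLayout,
    repeats: RepeatAnnotation,
    b1_carrier: list[bool],
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> BindingAccessibility:
    """Stage-resolved binding peaks and accessibility fragments over B1 sites.

    Bound sites are B1 elements sampled uniformly (so the fraction of peaks
    whose element carries the motif tracks ``p_motif_in_b1``), split into
    2C-specific, 8C-specific, and shared sets. Fragment sets carry uniform
    background plus Gaussian pileups at the stage's bound sites; the
    knockdown ("KD") condition keeps only ``1 - kd_effect`` of the enriched
    fragments at 8C-specific sites while 2C-specific and shared sites are
    untouched. Two replicate fragment sets per stage support differential
    comparisons.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    b1 = [iv for iv, fam, _ in repeats.elements if fam == "B1"]
    n_sites = (
        config.n_peaks_2c_specific + config.n_peaks_8c_specific + config.n_peaks_shared
    )
    if n_sites > len(b1):
        raise ValueError(f"need {n_sites} B1 elements, genome has {len(b1)}")
    chosen = rng.choice(len(b1), size=n_sites, replace=False)
    i2c = chosen[: config.n_peaks_2c_specific]
    i8c = chosen[config.n_peaks_2c_specific:
                 config.n_peaks_2c_specific + config.n_peaks_8c_specific]
    ishared = chosen[config.n_peaks_2c_specific + config.n_peaks_8c_specific:]

    def peaks_for(indices, tag) -> list[Peak]:
        out = []
        for j, idx in enumerate(indices):
            el = b1[int(idx)]
            c = el.center
            start = max(0, c - config.peak_halfwidth)
            end = min(layout.length_of(el.chrom), c + config.peak_halfwidth)
            out.append(Peak(GenomicInterval(el.chrom, start, end), 0.0, f"{tag}_{j:03d}"))
        return out

    ba = BindingAccessibility(
        peaks_for(i2c, "peak2C"), peaks_for(i8c, "peak8C"), peaks_for(ishared, "peakSh"),
        {},
    )
    if truth is not None:
        truth.bound_b1_2c = [int(i) for i in i2c]
        truth.bound_b1_8c = [int(i) for i in i8c]
        truth.bound_b1_shared = [int(i) for i in ishared]
        truth.peak_carrier_fraction = float(
            np.mean([b1_carrier[int(i)] for i in chosen])
        )

    chrom_names = layout.chrom_names
    flen, spread = config.fragment_length, config.fragment_spread

    def track(site_indices, per_site: int) -> FragmentSet:
        frags = []
        for ci in rng.integers(config.n_chroms, size=config.n_background_fragments):
            chrom = chrom_names[int(ci)]
            start = int(rng.integers(layout.length_of(chrom) - flen))
            frags.append(GenomicInterval(chrom, start, start + flen))
        for idx in site_indices:
            el = b1[int(idx)]
            frags.extend(
                _site_fragments(rng, el.center, el.chrom,
                                layout.length_of(el.chrom), per_site, flen, spread)
            )
        return FragmentSet(frags)

    per_site = config.fragments_per_site
    kd_per_site = max(0, int(round(per_site * (1.0 - config.kd_effect))))
    sites_2c = list(i2c) + list(ishared)
    sites_8c = list(i8c) + list(ishared)

    for rep in (1, 2):
        ba.fragments[f"2C:rep{rep}"] = track(sites_2c, per_site)
        ba.fragments[f"8C:rep{rep}"] = track(sites_8c, per_site)
    ba.fragments["2C_NC"] = track(sites_2c, per_site)
    ba.fragments["2C_KD"] = track(sites_2c, per_site)
    ba.fragments["8C_NC"] = track(sites_8c, per_site)
    # KD: 8C-specific pileups attenuated; shared sites untouched.
    kd = track(list(ishared), per_site)
    if kd_per_site > 0:
        for idx in i8c:
            el = b1[int(idx)]
            kd.fragments.extend(
                _site_fragments(rng, el.center, el.chrom,
                                layout.length_of(el.chrom), kd_per_site, flen, spread)
            )
    ba.fragments["8C_KD"] = kd
    return ba


def random_motif_occurrences(
    regions,
    n_motifs: int,
    occurrences_per_motif: int,
    rng: np.random.Generator,
    motif_length: int = len(MOTIF_CONSENSUS),
) -> dict[str, list[GenomicInterval]]:
    """Dummy motif-occurrence sets placed uniformly inside regions.

    Used for null calibration of the footprint statistic: each pseudo-motif
    gets ``occurrences_per_motif`` centers drawn from the regions' bp pool.
    """
    pool = [(r.chrom, p) for r in regions
            for p in range(r.start + motif_length, r.end - motif_length)]
    out = {}
    for m in range(n_motifs):
        picks = rng.choice(len(pool), size=occurrences_per_motif, replace=False)
        hits = []
        for i in picks:
            chrom, center = pool[int(i)]
            half = motif_length // 2
            hits.append(GenomicInterval(chrom, center - half, center - half + motif_length))
        out[f"null_motif_{m:03d}"] = hits
    return out


def generate_gene_models(
    config: SyntheticConfig,
    layout: GenomeLayout,
    gene_ids,
    rng: np.random.Generator,
) -> list[GeneModel]:
    """Place a subset of genes on the genome with evenly spaced, jittered TSSs.

    Only ``n_genomic_genes`` of the expression table's genes get coordinates
    (the genome is far smaller than a real one); spacing keeps promoter
    windows from tiling the whole sequence so distal space exists.
    """
    chosen = [gene_ids[i] for i in
              np.linspace(0, len(gene_ids) - 1, config.n_genomic_genes).astype(int)]
    per_chrom = -(-len(chosen) // config.n_chroms)
    spacing = config.chrom_length // (per_chrom + 1)
    models = []
    for k, gene in enumerate(chosen):
        chrom = layout.chrom_names[k // per_chrom]
        base = (k % per_chrom + 1) * spacing
        tss = int(np.clip(base + rng.integers(-spacing // 4, spacing // 4 + 1),
                          1000, config.chrom_length - 1001))
        strand = "+" if rng.random() < 0.5 else "-"
        span = (
            GenomicInterval(chrom, tss, tss + 1000, strand)
            if strand == "+"
            else GenomicInterval(chrom, tss - 999, tss + 1, strand)
        )
        models.append(GeneModel(gene, gene, chrom, strand, span))
    return models


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    layout: GenomeLayout
    sequences: dict[str, str]
    repeats: RepeatAnnotation
    expression: ExpressionTable
    truth: GroundTruth
    binding: BindingAccessibility
    gene_models: list[GeneModel]
    control_8c: pd.DataFrame
    kd_8c: pd.DataFrame


def simulate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generator under one seed and bundle the outputs."""
    rng = np.random.default_rng(config.seed)
    layout, sequences, repeats, b1_carrier = generate_genome(config, rng)
    expression, truth = generate_expression(config, rng)
    truth.b1_carrier = b1_carrier
    binding = generate_binding_and_accessibility(
        config, layout, repeats, b1_carrier, rng, truth
    )
    gene_models = generate_gene_models(config, layout, expression.gene_ids, rng)
    control_8c, kd_8c = generate_kd_expression(config, truth, expression, rng)
    return SyntheticDataset(
        config, layout, sequences, repeats, expression, truth, binding,
        gene_models, control_8c, kd_8c,
    )
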