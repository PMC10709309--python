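"""End-to-end orchestration of the synthetic analysis.

``run_full_analysis`` wires the stages together on one simulated cohort:
gene-program classification scored against the planted truth, fragment
binning and Z-normalization, promoter/distal peak annotation, stage-specific
peak assignment, knockdown accessibility and footprint statistics, repeat and
motif enrichment, enhancer-gene linking, and the association/fraction
reports. Every number in the returned summary is reproducible by calling the
underlying operation directly with the same configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, linking, repeats as rm, tracks
from .expression import (
    call_differential,
    classify_maternal_genes,
    classify_stage_specific_genes,
    classify_zga_genes,
    stratify_icm_genes,
    activation_ratio,
)
from .genome import GenomicInterval, classify_peak_location
from .simulate import (
    B1_CONSENSUS,
    SyntheticConfig,
    SyntheticDataset,
    planted_motif,
    random_motif_occurrences,
    simulate_all,
)

__all__ = ["PipelineConfig", "run_full_analysis"]

_KNOWN_KEYS = {
    "seed", "promoter_halfwidth", "link_distance", "z_high", "z_positive",
    "max_other_positive", "delta_threshold", "n_shuffles", "n_perm",
    "footprint_window", "pseudocount", "synthetic",
}


@dataclass
class PipelineConfig:
    """Pipeline thresholds; defaults are the analysis' standard settings
    (promoter +/-2.5 kb, 50-kb links, normalized-RPKM cutoffs 1/0 with at
    most two extra positive stages, and unit-pseudocount log2 enrichment)."""

    seed: int = 0
    promoter_halfwidth: int = 2500
    link_distance: int = 50_000
    z_high: float = 1.0
    z_positive: float = 0.0
    max_other_positive: int = 2
    delta_threshold: float = 0.1
    n_shuffles: int = 100
    n_perm: int = 199
    footprint_window: int = 100
    pseudocount: float = 1.0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        syn = raw.pop("synthetic", {})
        syn_cfg = SyntheticConfig(**syn) if isinstance(syn, dict) else syn
        return cls(synthetic=syn_cfg, **raw)


def _recovery(calls, truth_programs, wanted_prefixes) -> float:
    """Fraction of planted labels (with a wanted prefix) recovered exactly."""
    planted = {
        g: p for g, p in truth_programs.items()
        if any(p.startswith(w) for w in wanted_prefixes)
    }
    if not planted:
        return float("nan")
    by_gene = {c.gene_id: c.program for c in calls}
    return sum(by_gene.get(g) == p for g, p in planted.items()) / len(planted)


def run_full_analysis(
    config: PipelineConfig, outdir: str | Path | None = None
) -> dict:
    """Simulate one cohort and run every analysis stage on it.

    Returns a nested summary dict (JSON-serializable); when ``outdir`` is
    given, also writes the summary plus per-stage TSV tables there.
    """
    cfg = config
    scfg = cfg.synthetic
    if scfg.seed != cfg.seed:
        scfg = SyntheticConfig(**{**asdict(scfg), "seed": cfg.seed})
    data = simulate_all(scfg)
    summary: dict = {"seed": cfg.seed}

    summary["gene_programs"] = _gene_program_stage(cfg, data)
    summary["differential_expression"] = _differential_stage(cfg, data)
    track_bundle = _binned_tracks(data)
    summary["peak_annotation"] = _annotation_stage(cfg, data)
    summary["stage_specific_peaks"] = _stage_peak_stage(cfg, data, track_bundle)
    summary["accessibility"] = _accessibility_stage(cfg, data, track_bundle)
    summary["footprints"] = _footprint_stage(cfg, data, track_bundle)
    summary["repeat_enrichment"] = _repeat_stage(cfg, data)
    summary["motif_b1"] = _motif_b1_stage(cfg, data)
    summary["linking"] = _linking_stage(cfg, data)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _gene_program_stage(cfg: PipelineConfig, data: SyntheticDataset) -> dict:
    table = data.expression
    zga = classify_zga_genes(table)
    maternal = classify_maternal_genes(table)
    stage = classify_stage_specific_genes(
        table, ["FGO", "MII", "1C", "E2C", "L2C", "4C", "8C"]
    )
    icm_ids = sorted(data.truth.early_icm | data.truth.late_icm)
    icm = stratify_icm_genes(icm_ids, table)
    truth = data.truth.gene_programs
    n_by_program: dict[str, int] = {}
    for calls in (zga, maternal, stage):
        for c in calls:
            if c.program != "none":
                n_by_program[c.program] = n_by_program.get(c.program, 0) + 1
    icm_correct = len(icm["early_ICM"] & data.truth.early_icm) + len(
        icm["late_ICM"] & data.truth.late_icm
    )
    _, ratio_summary = activation_ratio(
        table, "L2C", "1C",
        [g for g, p in truth.items() if p.endswith("ZGA")],
    )
    _, ratio_none = activation_ratio(
        table, "L2C", "1C", [g for g, p in truth.items() if p == "none"]
    )
    return {
        "counts": n_by_program,
        "recovery_zga": _recovery(zga, truth,
                                  ["minor_ZGA", "major_ZGA"]),
        "recovery_maternal": _recovery(maternal, truth, ["maternal"]),
        "recovery_stage_specific": _recovery(stage, truth, ["stage_specific"]),
        "recovery_icm": icm_correct / max(1, len(icm_ids)),
        "zga_l2c_over_1c_median": ratio_summary.get("median"),
        "none_l2c_over_1c_median": ratio_none.get("median"),
    }


def _differential_stage(cfg: PipelineConfig, data: SyntheticDataset) -> dict:
    results = call_differential(data.control_8c, data.kd_8c)
    down = {r.gene_id for r in results if r.call == "down"}
    up = {r.gene_id for r in results if r.call == "up"}
    truth = data.truth
    early = truth.early_icm
    genes = data.expression.gene_ids
    other_expressed = [g for g in genes if g not in early]
    n_down_early = len(down & early)
    n_down_other = len(down & set(other_expressed))
    assoc = linking.contingency_association(
        [g in down for g in genes],
        [g in truth.promoter_bound_genes for g in genes],
    )
    down_bound_pct = (
        linking.report_fraction(
            sum(g in truth.promoter_bound_genes for g in down), len(down), 0
        )
        if down else float("nan")
    )
    return {
        "n_down": len(down),
        "n_up": len(up),
        "recall_planted_down": len(down & truth.kd_down_genes)
        / max(1, len(truth.kd_down_genes)),
        "early_icm_down_pct": linking.report_fraction(
            n_down_early, max(1, len(early)), 0
        ),
        "other_down_pct": linking.report_fraction(
            n_down_other, len(other_expressed), 1
        ),
        "down_bound_pct": down_bound_pct,
        "down_vs_bound_odds_ratio": assoc.odds_ratio,
        "down_vs_bound_p": assoc.p_value,
    }


def _binned_tracks(data: SyntheticDataset) -> dict[str, tracks.BinnedTrack]:
    out = {}
    for key, frags in data.binding.fragments.items():
        out[key] = tracks.zscore_normalize(
            tracks.bin_signal(frags, data.layout)
        )
    return out


def _annotation_stage(cfg: PipelineConfig, data: SyntheticDataset) -> dict:
    annotated = classify_peak_location(
        data.binding.all_peaks, data.gene_models, cfg.promoter_halfwidth,
        genome=data.layout,
    )
    n_prom = sum(p.location_class == "promoter" for p in annotated)
    return {
        "n_peaks": len(annotated),
        "n_promoter": n_prom,
        "n_distal": len(annotated) - n_prom,
    }


def _stage_peak_stage(cfg, data: SyntheticDataset, track_bundle) -> dict:
    peaks = data.binding.all_peaks
    intervals = [p.interval for p in peaks]
    names = [p.name for p in peaks]
    # Focal-stage thresholds use Z-scored signal averaged over replicates;
    # the MA-style differential runs on non-negative RPKM.
    z = pd.DataFrame(
        {
            stage: np.mean(
                [
                    tracks.region_signal(track_bundle[f"{stage}:rep{r}"],
                                         intervals, use="zscore")
                    for r in (1, 2)
                ],
                axis=0,
            )
            for stage in ("2C", "8C")
        },
        index=names,
    )
    rep_signals = {
        stage: pd.DataFrame(
            {
                f"rep{r}": tracks.region_signal(
                    track_bundle[f"{stage}:rep{r}"],
                    intervals, use="rpkm",
                )
                for r in (1, 2)
            },
            index=names,
        )
        for stage in ("2C", "8C")
    }
    calls = dynamics.make_pairwise_calls(rep_signals)
    assignment = dynamics.stage_specific_peaks(
        z, calls, cfg.z_high, cfg.z_positive, cfg.max_other_positive
    )
    names = list(z.index)
    truth_label = {}
    for p in data.binding.peaks_2c_specific:
        truth_label[p.name] = "2C"
    for p in data.binding.peaks_8c_specific:
        truth_label[p.name] = "8C"
    for p in data.binding.peaks_shared:
        truth_label[p.name] = "shared/none"
    correct = sum(assignment[n] == truth_label[n] for n in names)
    return {
        "n_2c_specific": int((assignment == "2C").sum()),
        "n_8c_specific": int((assignment == "8C").sum()),
        "n_shared": int((assignment == "shared/none").sum()),
        "accuracy_vs_planted": correct / len(names),
    }


def _accessibility_stage(cfg, data: SyntheticDataset, track_bundle) -> dict:
    changes, frac = dynamics.accessibility_change(
        data.binding.peaks_8c_specific,
        track_bundle["8C_NC"], track_bundle["8C_KD"], cfg.delta_threshold,
    )
    _, frac_shared = dynamics.accessibility_change(
        data.binding.peaks_shared,
        track_bundle["8C_NC"], track_bundle["8C_KD"], cfg.delta_threshold,
    )
    return {
        "fraction_reduced_8c_specific": frac,
        "fraction_reduced_shared": frac_shared,
        "mean_delta_8c_specific": float(np.mean([c.delta for c in changes])),
    }


def _footprint_stage(cfg, data: SyntheticDataset, track_bundle) -> dict:
    regions = [
        GenomicInterval(p.chrom, max(0, p.start - 200),
                        min(data.layout.length_of(p.chrom), p.end + 200))
        for p in data.binding.peaks_8c_specific
    ]
    motif = planted_motif()
    hits = rm.scan_genome(data.sequences, motif)
    hits_by_motif = {
        motif.motif_id: [h.interval for h in hits]
    }
    rng = np.random.default_rng(cfg.seed + 17)
    hits_by_motif.update(
        random_motif_occurrences(regions, n_motifs=20, occurrences_per_motif=8,
                                 rng=rng)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = dynamics.footprint_change(
            hits_by_motif, regions, track_bundle["8C_NC"], track_bundle["8C_KD"],
            window=cfg.footprint_window, n_perm=cfg.n_perm, seed=cfg.seed + 18,
        )
    by_id = {s.motif_id: s for s in scores}
    planted = by_id.get(motif.motif_id)
    null_ps = [s.p_value for s in scores if s.motif_id != motif.motif_id]
    return {
        "planted_motif_mean_delta": planted.mean_delta if planted else None,
        "planted_motif_p": planted.p_value if planted else None,
        "planted_motif_occurrences": planted.n_occurrences if planted else 0,
        "null_motif_median_p": float(np.median(null_ps)) if null_ps else None,
    }


def _repeat_stage(cfg, data: SyntheticDataset) -> dict:
    results = rm.repeat_enrichment(
        data.binding.all_peaks, data.repeats, data.layout,
        n_shuffles=cfg.n_shuffles, seed=cfg.seed + 19,
        pseudocount=cfg.pseudocount,
    )
    by_family = {
        r.category: {"observed": r.observed, "expected": r.expected,
                     "log2_ratio": r.log2_ratio}
        for r in results
    }
    acc = rm.accessible_repeat_enrichment(
        [p.interval for p in data.binding.all_peaks], data.repeats, "B1",
        data.layout, cfg.pseudocount,
    )
    by_family["accessible_B1"] = {
        "observed": acc.observed, "expected": acc.expected,
        "log2_ratio": acc.log2_ratio,
    }
    return by_family


def _motif_b1_stage(cfg, data: SyntheticDataset) -> dict:
    motif = planted_motif()
    hits = rm.scan_genome(data.sequences, motif)
    b1 = data.repeats.by_family("B1")
    labels = rm.classify_peak_motif_repeat(data.binding.all_peaks, hits, b1)
    n = len(labels)
    counts = {c: sum(v == c for v in labels.values()) for c in rm.PEAK_MOTIF_CLASSES}
    cons = rm.consensus_motif_map(B1_CONSENSUS, [motif])
    return {
        "counts": counts,
        "motif_in_b1_fraction": counts[rm.MOTIF_IN_B1] / n,
        "planted_motif_in_b1_fraction": data.truth.peak_carrier_fraction,
        "consensus_positions": cons[motif.motif_id]["positions"],
    }


def _linking_stage(cfg, data: SyntheticDataset) -> dict:
    annotated = classify_peak_location(
        data.binding.all_peaks, data.gene_models, cfg.promoter_halfwidth,
        genome=data.layout,
    )
    distal = [p for p in annotated if p.location_class == "distal"]
    links = linking.assign_enhancer_targets(
        data.gene_models, distal, cfg.link_distance
    )
    genomic_ids = [g.gene_id for g in data.gene_models]
    down = data.truth.kd_down_genes
    curve = linking.cumulative_distance_curve(
        {
            "down": [g for g in genomic_ids if g in down],
            "all": genomic_ids,
        },
        data.gene_models, distal, [5_000, 20_000, 50_000],
    )
    return {
        "n_distal_peaks": len(distal),
        "n_linked_genes": len(links),
        "linked_pct": linking.report_fraction(len(links), len(genomic_ids), 1),
        "cumulative_at_50kb_all": float(curve.loc[50_000, "all"]),
    }
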