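"""Gene-program classification from stage-wise FPKM tables.

Mouse preimplantation development proceeds FGO -> MII -> 1C -> early 2C ->
late 2C -> 4C -> 8C -> blastocyst (ICM/TE). Zygotic genome activation (ZGA)
genes switch on in the embryo (minor wave at early 2C, major wave at late 2C),
maternal genes are deposited in the oocyte and degraded by late 2C, and
stage-specific genes first fire at one defined stage after complete prior
silence. The classifiers here apply fixed FPKM thresholds to stage means:

* ZGA: oocyte FPKM < 5 in both FGO and MII, then FPKM > 5 with >= 3-fold rise
  at early 2C (minor) or late 2C (major). Oocyte-expressed genes (> 5) with a
  >= 5-fold late-2C rise form a special major-ZGA subclass.
* maternal: oocyte FPKM > 5 and a >= 3-fold drop by late 2C.
* stage-specific: first stage with FPKM > 5 while every preceding stage from
  FGO stays < 1.
* early vs late ICM: ICM-specific genes split on 8C FPKM >= 1.

The fold-change baseline aggregates oocyte stages by their max, floored at a
pseudocount of 0.1 FPKM so that fully silent genes still qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionTable",
    "GeneProgramCall",
    "DifferentialResult",
    "classify_zga_genes",
    "classify_maternal_genes",
    "classify_stage_specific_genes",
    "stratify_icm_genes",
    "call_differential",
    "activation_ratio",
    "FPKM_ON",
    "FPKM_SILENT",
    "BASELINE_EPS",
    "RATIO_EPS",
]

FPKM_ON = 5.0        # "expressed" threshold for ZGA/maternal/stage rules
FPKM_SILENT = 1.0    # "silenced" threshold for stage-specific rules
FOLD_UP = 3.0        # minimum activation fold for ZGA
FOLD_UP_SPECIAL = 5.0  # oocyte-upregulated major-ZGA subclass
FOLD_DOWN = 3.0      # minimum degradation fold for maternal genes
BASELINE_EPS = 0.1   # pseudocount floor on the oocyte baseline (FPKM)
RATIO_EPS = 0.01     # pseudocount for activation ratios and log2FC
DE_FDR = 0.01
DE_LOG2FC = 2.0


@dataclass
class ExpressionTable:
    """Genes x stage-replicates FPKM matrix with replicate structure.

    ``values`` columns are named ``stage:replicate`` (e.g. ``L2C:1``); the
    per-stage value used by every classifier is the mean over replicates.
    """

    values: pd.DataFrame
    replicate_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicate_map:
            rep_map: dict[str, list[str]] = {}
            for col in self.values.columns:
                stage = col.split(":")[0]
                rep_map.setdefault(stage, []).append(col)
            self.replicate_map = rep_map
        for stage, cols in self.replicate_map.items():
            if not cols:
                raise ValueError(f"stage {stage!r} has no replicate columns")
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_names(self) -> list[str]:
        return list(self.replicate_map)

    def stage_means(self) -> pd.DataFrame:
        """Genes x stages matrix of replicate means."""
        return pd.DataFrame(
            {s: self.values[cols].mean(axis=1) for s, cols in self.replicate_map.items()}
        )

    def require_stages(self, stages: Iterable[str]) -> None:
        missing = [s for s in stages if s not in self.replicate_map]
        if missing:
            raise KeyError(f"stages missing from expression table: {missing}")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


@dataclass(frozen=True)
class GeneProgramCall:
    gene_id: str
    program: str  # minor_ZGA | major_ZGA | major_ZGA_oocyte_upregulated |
    #               maternal | stage_specific:<stage> | early_ICM | late_ICM | none
    evidence: str = ""


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    log2_fold_change: float
    fdr: float
    call: str  # down | up | ns

    def __post_init__(self) -> None:
        if self.call == "down" and not (
            self.log2_fold_change <= -DE_LOG2FC and self.fdr < DE_FDR
        ):
            raise ValueError(f"inconsistent 'down' call for {self.gene_id}")
        if self.call == "up" and not (
            self.log2_fold_change >= DE_LOG2FC and self.fdr < DE_FDR
        ):
            raise ValueError(f"inconsistent 'up' call for {self.gene_id}")


def _oocyte_baseline(means: pd.DataFrame, oocyte_stages: Sequence[str]) -> pd.Series:
    return means[list(oocyte_stages)].max(axis=1)


def classify_zga_genes(
    table: ExpressionTable,
    oocyte_stages: Sequence[str] = ("FGO", "MII"),
    e2c_stage: str = "E2C",
    l2c_stage: str = "L2C",
) -> list[GeneProgramCall]:
    """Call minor/major ZGA genes from oocyte vs 2-cell FPKM dynamics.

    Minor ZGA: silent oocyte (< 5 FPKM in every oocyte stage), early-2C
    FPKM > 5 with a >= 3-fold rise over the oocyte baseline. Major ZGA: the
    same criteria first met at late 2C. Oocyte-expressed genes (> 5) with a
    >= 5-fold late-2C rise join major ZGA as a flagged subclass.
    """
    table.require_stages([*oocyte_stages, e2c_stage, l2c_stage])
    means = table.stage_means()
    baseline = _oocyte_baseline(means, oocyte_stages)
    floor = np.maximum(baseline, BASELINE_EPS)
    oocyte_silent = (means[list(oocyte_stages)] < FPKM_ON).all(axis=1)
    oocyte_expressed = baseline > FPKM_ON

    e2c_on = (means[e2c_stage] > FPKM_ON) & (means[e2c_stage] >= FOLD_UP * floor)
    l2c_on = (means[l2c_stage] > FPKM_ON) & (means[l2c_stage] >= FOLD_UP * floor)
    special = oocyte_expressed & (means[l2c_stage] >= FOLD_UP_SPECIAL * floor)

    calls = []
    for gene in table.gene_ids:
        if oocyte_silent[gene] and e2c_on[gene]:
            program = "minor_ZGA"
            ev = f"{e2c_stage}={means.loc[gene, e2c_stage]:.3g}>{FPKM_ON:g}"
        elif oocyte_silent[gene] and l2c_on[gene]:
            program = "major_ZGA"
            ev = f"{l2c_stage}={means.loc[gene, l2c_stage]:.3g}>{FPKM_ON:g}"
        elif special[gene]:
            program = "major_ZGA_oocyte_upregulated"
            ev = f"oocyte={baseline[gene]:.3g},{l2c_stage}={means.loc[gene, l2c_stage]:.3g}"
        else:
            program, ev = "none", ""
        calls.append(GeneProgramCall(gene, program, ev))
    return calls


def classify_maternal_genes(
    table: ExpressionTable,
    oocyte_stages: Sequence[str] = ("FGO", "MII"),
    l2c_stage: str = "L2C",
) -> list[GeneProgramCall]:
    """Call maternal genes: oocyte-expressed (> 5 FPKM) with a >= 3-fold drop
    by the late 2-cell stage."""
    table.require_stages([*oocyte_stages, l2c_stage])
    means = table.stage_means()
    baseline = _oocyte_baseline(means, oocyte_stages)
    is_maternal = (baseline > FPKM_ON) & (means[l2c_stage] <= baseline / FOLD_DOWN)
    return [
        GeneProgramCall(
            g,
            "maternal" if is_maternal[g] else "none",
            f"oocyte={baseline[g]:.3g},{l2c_stage}={means.loc[g, l2c_stage]:.3g}"
            if is_maternal[g]
            else "",
        )
        for g in table.gene_ids
    ]


def classify_stage_specific_genes(
    table: ExpressionTable, ordered_stages: Sequence[str]
) -> list[GeneProgramCall]:
    """Assign genes to the earliest stage where they fire (FPKM > 5) after
    complete silence (FPKM < 1) at every preceding stage from FGO.

    A gene whose first FPKM > 5 stage is preceded by any stage in [1, 5] is
    not stage-specific; a gene never exceeding 5 gets ``none``.
    """
    table.require_stages(ordered_stages)
    means = table.stage_means()[list(ordered_stages)]
    calls = []
    for gene in table.gene_ids:
        row = means.loc[gene].to_numpy()
        program, ev = "none", ""
        on = np.flatnonzero(row > FPKM_ON)
        if on.size:
            first = int(on[0])
            if first > 0 and bool((row[:first] < FPKM_SILENT).all()):
                stage = ordered_stages[first]
                program = f"stage_specific:{stage}"
                ev = f"{stage}={row[first]:.3g}, preceding max={row[:first].max():.3g}"
        calls.append(GeneProgramCall(gene, program, ev))
    return calls


def stratify_icm_genes(
    icm_specific_ids: Sequence[str],
    table: ExpressionTable,
    eight_cell_stage: str = "8C",
    threshold: float = 1.0,
) -> dict[str, set[str]]:
    """Split ICM-specific genes into early (8C FPKM >= 1) vs late (< 1).

    Early ICM genes are already on at the 8-cell stage; late ICM genes switch
    on only in the blastocyst. Genes at exactly the threshold are early and
    are reported in the ``boundary`` set for inspection.
    """
    table.require_stages([eight_cell_stage])
    missing = set(icm_specific_ids) - set(table.gene_ids)
    if missing:
        raise KeyError(f"ICM gene ids absent from table: {sorted(missing)[:5]}")
    means = table.stage_means()[eight_cell_stage]
    early = {g for g in icm_specific_ids if means[g] >= threshold}
    late = set(icm_specific_ids) - early
    boundary = {g for g in early if means[g] == threshold}
    return {"early_ICM": early, "late_ICM": late, "boundary": boundary}


def call_differential(
    control_reps: pd.DataFrame,
    kd_reps: pd.DataFrame,
    pvalues: Mapping[str, float] | pd.Series | None = None,
    eps: float = RATIO_EPS,
    fdr_threshold: float = DE_FDR,
    log2fc_threshold: float = DE_LOG2FC,
) -> list[DifferentialResult]:
    """Differential-expression calls between knockdown and control replicates.

    log2FC = log2((mean KD + eps) / (mean control + eps)); genes with BH-FDR
    < 0.01 and |log2FC| >= 2 are called ``up``/``down`` by sign. When no
    per-gene p-values are injected, a Welch t-test on log2(FPKM + eps) across
    replicates serves as the built-in test; with a single replicate per side
    every p-value is 1 (no inference possible).
    """
    if len(control_reps) == 0:
        raise ValueError("no genes to test")
    if not control_reps.index.equals(kd_reps.index):
        raise ValueError("control and KD tables must share the same gene index")
    mean_c = control_reps.mean(axis=1)
    mean_k = kd_reps.mean(axis=1)
    log2fc = np.log2((mean_k + eps) / (mean_c + eps))

    if pvalues is not None:
        pvals = pd.Series(pvalues).reindex(control_reps.index)
        if pvals.isna().any():
            raise ValueError("supplied p-values do not cover all genes")
    elif control_reps.shape[1] < 2 or kd_reps.shape[1] < 2:
        pvals = pd.Series(1.0, index=control_reps.index)
    else:
        lc = np.log2(control_reps + eps)
        lk = np.log2(kd_reps + eps)
        t = stats.ttest_ind(lk, lc, axis=1, equal_var=False)
        pvals = pd.Series(np.nan_to_num(t.pvalue, nan=1.0), index=control_reps.index)

    fdr = pd.Series(
        multipletests(pvals.to_numpy(), method="fdr_bh")[1], index=control_reps.index
    )
    out = []
    for gene in control_reps.index:
        fc, q = float(log2fc[gene]), float(fdr[gene])
        if q < fdr_threshold and fc >= log2fc_threshold:
            call = "up"
        elif q < fdr_threshold and fc <= -log2fc_threshold:
            call = "down"
        else:
            call = "ns"
        out.append(DifferentialResult(gene, fc, q, call))
    return out


def activation_ratio(
    table: ExpressionTable,
    numerator_stage: str,
    denominator_stage: str,
    gene_set: Sequence[str] | None = None,
    eps: float = RATIO_EPS,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-gene stage-to-stage activation ratios with a boxplot summary.

    ratio = (FPKM_num + eps) / (FPKM_den + eps); the summary is the
    five-number set (min, q1, median, q3, max). Empty gene sets yield an
    empty series and an empty summary.
    """
    table.require_stages([numerator_stage, denominator_stage])
    means = table.stage_means()
    genes = list(gene_set) if gene_set is not None else table.gene_ids
    if not genes:
        return pd.Series(dtype=float), {}
    num = means.loc[genes, numerator_stage]
    den = means.loc[genes, denominator_stage]
    ratios = (num + eps) / (den + eps)
    q = np.percentile(ratios, [0, 25, 50, 75, 100])
    summary = dict(zip(["min", "q1", "median", "q3", "max"], map(float, q)))
    return ratios, summary


def program_calls_to_frame(calls: Sequence[GeneProgramCall]) -> pd.DataFrame:
    """Tabulate program calls for TSV export."""
    return pd.DataFrame(
        [(c.gene_id, c.program, c.evidence) for c in calls],
        columns=["gene_id", "program", "evidence"],
    ).set_index("gene_id")
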