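# stagekit

Stage-resolved regulatory-genomics analyses for mouse preimplantation
embryos, packaged as a tested Python library with an end-to-end synthetic
demonstration.

## The problem

During the first cleavages of the mouse embryo, the zygotic genome switches
on in two waves (minor ZGA at the 1-cell/early 2-cell stage, major ZGA at
the late 2-cell stage) while maternal transcripts are degraded. Orphan
nuclear receptors such as NR5A2 bind chromatin stage-specifically — often
inside SINE B1 retrotransposon copies that carry an embedded binding motif —
and open putative enhancers whose target genes fire at defined stages.
Connecting TF occupancy maps (CUT&RUN), chromatin accessibility (ATAC-seq),
and stage-wise expression (RNA-seq FPKM tables) requires a chain of small,
exacting analyses:

* **Gene programs** from FPKM dynamics: a gene is *minor/major ZGA* if it is
  oocyte-silent (FPKM < 5 in FGO and MII) and rises above 5 FPKM with a
  ≥ 3-fold gain at the early/late 2-cell stage; oocyte-expressed genes with a
  ≥ 5-fold late-2C gain form a flagged major-ZGA subclass; *maternal* genes
  are oocyte-expressed (> 5) and drop ≥ 3-fold by late 2C; *stage-specific*
  genes first exceed 5 FPKM at one stage with every earlier stage below 1;
  ICM-specific genes split into *early* vs *late* on 8-cell FPKM ≥ 1.
* **Signal tracks**: deduplicated fragments → RPKM over 100-bp genome bins →
  genome-wide Z-score normalization, so tracks from different libraries are
  comparable.
* **Stage-specific peaks**: a pooled distal peak belongs to stage *s* when
  its normalized signal exceeds 1 there, is positive at no more than two
  other stages, and the pairwise differential comparisons favor *s*.
* **Repeat/motif enrichment**: observed peak–repeat overlaps against
  length-matched shuffled peak sets, reported as log₂(obs + 1)/(exp + 1);
  log-odds PWM scanning; motif density at 10-bp resolution around peak
  centers; and a four-way peak taxonomy (motif in B1 / motif next to B1 /
  motif outside B1 / no motif).
* **Knockdown statistics**: differential expression at FDR < 0.01 and
  |log₂FC| ≥ 2; per-peak accessibility change ΔZ = Z_KD − Z_NC; a
  permutation footprint statistic (mean ΔZ in ±100 bp around a motif's
  occurrences inside differentially accessible regions, against random
  position sets); Fisher exact association between gene sets; enhancer–gene
  linking to the nearest distal peak within 50 kb of the TSS.

Real embryo datasets are genome-scale; this package ships a seeded
synthetic-data generator that plants all of the above structure in a small
genome so that every operation is testable offline, with known answers.

## Worked example

`analysis/` contains numbered drivers that re-run the full story on the
synthetic cohort (seed 1). For example:

```bash
$ python analysis/02_classify_gene_programs.py
zga: 140 genes called, recovered 140/140 planted labels (100.0%)
maternal: 75 genes called, recovered 75/75 planted labels (100.0%)
stage_specific: 64 genes called, recovered 50/50 planted labels (100.0%)
ICM stratification: 30 early / 20 late (8C FPKM >= 1 rule)

$ python analysis/05_repeats_and_motifs.py
    B1: observed 400 vs expected  104.0 -> log2 O/E +1.93
    B4: observed  10 vs expected   25.1 -> log2 O/E -1.25
 MERVL: observed  10 vs expected   28.6 -> log2 O/E -1.43
    B2: observed  11 vs expected   46.8 -> log2 O/E -1.99
motif-in-B1 peaks: 54.5% (planted carrier rate 53.8%)
motif density peaks at offset -40 bp from peak centers
consensus map: motif at positions [30] of the B1-like consensus

$ python analysis/04_knockdown_effects.py
51 downregulated genes; 41% promoter-bound (OR=7.8, Fisher p=5.9e-09)
accessibility reduced at 100.0% of 8C-specific peaks (shared peaks: 2.0%)
planted motif footprint: mean dZ=-2.18, p=0.005 over 95 occurrences
```

Reading these together: all 400 binding peaks sit on B1 elements (log₂ O/E
+1.9 against the shuffle null, other families depleted), the fraction of
peaks whose B1 carries the embedded motif matches the planted rate, and the
simulated knockdown removes accessibility at essentially all 8C-specific
sites — the planted motif's footprint statistic is strongly negative at the
smallest attainable permutation p (1/200) — while shared sites are
untouched. Gene-program classifiers recover their planted labels, and
downregulated genes are strongly associated with promoter binding.

The same stages are available as a CLI (`stagekit simulate`,
`classify-genes`, `annotate-peaks`, `bin-signal`, `stage-peaks`,
`diff-access`, `footprints`, `repeat-enrich`, `link-genes`, `assoc`,
`report`, `run-all`); `stagekit run-all --seed 1 --outdir out/` writes a
machine-readable `summary.json` for the whole pipeline.

## Layout

```
src/stagekit/        library: genome, io, expression, tracks, dynamics,
                     repeats, linking, simulate, pipeline, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
docs/methods.md      models, parameters, design choices, limitations
```
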