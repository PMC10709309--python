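# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinate model and interval algebra

All coordinates are 0-based half-open (plain BED dialect, 3–6 columns).
A gene's TSS is `txStart` on the plus strand and `txEnd − 1` on the minus
strand (refFlat semantics). Edge-to-point distances treat the interval's
edges as `start` and `end − 1`, so a TSS inside an interval is at distance 0
and a peak starting exactly `h` bp right of a TSS is at distance `h`.

**Promoter vs distal.** A peak overlapping any window `[tss − h, tss + h)`
(default h = 2500 bp, symmetric about the TSS regardless of strand) is a
promoter peak; otherwise it is distal, and its minimum edge-to-TSS distance
is then ≥ h by construction, making the partition exclusive. Overlap wins at
the boundary; a peak at exactly 2.5 kb without window overlap is distal.
Nearest-gene ties break on smaller distance, then lexicographic gene id —
arbitrary but deterministic.

**Length-matched shuffles.** The null for repeat enrichment places, for each
observed peak, one random interval of identical length uniformly over all
valid start positions genome-wide; chromosomes are weighted by their number
of valid starts, and an optional exclusion set is honored exactly: valid
start segments are computed by subtracting the exclusion intervals, then one
uniform integer indexes into the remaining positions. This makes degenerate
cases (a single allowed gap) deterministic and lets tests verify the
placement distribution by exhaustive enumeration. A peak with no valid
placement raises an error naming it.

## Gene-program classifiers

Per-stage values are replicate means of FPKM. Thresholds (FPKM 5 for "on",
FPKM 1 for "silent", 3-fold activation/decay, 5-fold for the
oocyte-expressed major-ZGA subclass, 8C FPKM ≥ 1 for early ICM) are the
field's stage-classification conventions and are module constants. Two
choices were open:

* **Fold-change baseline.** The oocyte baseline is the max over oocyte
  stages (FGO, MII), floored at a pseudocount of 0.1 FPKM so that a fully
  silent oocyte still yields a finite fold change. The max is the
  conservative aggregation: a gene must rise relative to its highest oocyte
  level.
* **Boundary genes.** Early-vs-late ICM stratification uses `≥ 1` (a gene at
  exactly 1.0 is early) and reports boundary genes separately so a stricter
  `> 1` reading can be audited.

Minor vs major ZGA is decided by the earliest qualifying stage (early 2C ⇒
minor), matching the two-wave framing. The three programs
(minor/major ZGA, maternal) are mutually exclusive by their threshold
windows; a property test asserts this on random tables.

**Differential expression.** log₂FC = log₂((mean KD + ε)/(mean control + ε))
with ε = 0.01; calls require BH-adjusted FDR < 0.01 and |log₂FC| ≥ 2, with
the sign giving direction. The built-in test is a per-gene Welch t-test on
log₂(FPKM + ε) across replicates — a deliberately simple surrogate for a
count-model test — and externally computed p-values can be injected to
bypass it entirely; with a single replicate per side all p-values are 1.

## Signal tracks

Fragments are counted once each, in the 100-bp bin containing their
midpoint, so bin counts conserve the library exactly:
Σ rpkm · (bin_kb) · (library/10⁶) = fragment count. RPKM uses the full bin
width in the denominator even for the last partial bin (affects ≤ 1 bin per
chromosome). Z-score normalization is computed jointly over all genome bins
with the population (n) standard deviation; a track whose sd is ≤ 1e−12
relative to its mean (i.e., constant up to rounding) maps to all zeros, and
renormalizing a Z track is a no-op to 1e−9. Per-replicate tracks are
normalized before any averaging. Region summaries weight every overlapped
bin equally; profile matrices sample the track at bin-center offsets and
mark off-genome columns missing (excluded from column means).

## Peak dynamics

**Stage-specific peaks.** A pooled distal peak is assigned to stage *s* iff
(i) its mean Z over the peak exceeds 1 at *s*, (ii) Z > 0 at no more than
two other stages, and (iii) the pairwise differential comparisons involving
*s* favor it — interpreted as: *s* wins at least one comparison and loses
none (ties/ns allowed). If several stages qualify through non-significant
comparisons, the stage with the highest Z wins, guaranteeing at most one
assignment. The "no more than two additional stages" rule is applied
verbatim even for short stage lists, where it cannot bind.

**MA-style differential comparison.** Between two conditions over common
peaks: M = log₂(mean B + ε) − log₂(mean A + ε), recentred by its median over
peaks (≥ 10 peaks required), so a global multiplicative shift in one
condition produces zero calls. A peak is differential at |M| ≥ 1 with the
same sign in every replicate pair. This is a stand-in for hierarchical-model
normalization, chosen for transparency; external pairwise calls can be
supplied to the stage-assignment step instead.

**Accessibility change.** Per-peak ΔZ = Z_KD − Z_NC from region means on
Z-tracks; "reduced" means ΔZ < −δ with δ = 0.1 Z-units, a tolerance band
against normalization jitter (no numeric threshold is conventional here; δ
is config-exposed).

**Footprint statistic.** Per motif: the mean ΔZ in ±window (default 100 bp)
around every occurrence whose center lies inside the differentially
accessible regions; the null redraws equally sized position sets uniformly,
without replacement, from all bp positions inside those regions, and the
two-sided p is (1 + #{|null| ≥ |obs|})/(n_perm + 1), bounded below by
1/(n_perm + 1). When the subset count is small an exact mode enumerates all
position subsets instead. Motifs with fewer than 5 qualifying occurrences
are skipped. This windowed aggregate deliberately ignores Tn5 insertion
bias and base-pair footprint shape: it answers "which motifs lose
accessibility", not "what does the footprint look like".

## Repeats and motifs

PWMs are log-odds matrices (log₂ p/background, probabilities floored at
1e−3, uniform background unless supplied). Scanning scores every window on
both strands, reports minus-strand hits on forward coordinates, and
disqualifies windows containing N. Motif density is counted by hit centers
in 10-bp bins over ±500 bp around peak centers, averaged over peaks.

Repeat enrichment is peak-level: observed = peaks overlapping ≥ 1 bp of the
family, expected = the same count averaged over length-matched shuffles,
enrichment = log₂((obs + 1)/(exp + 1)) with the symmetric unit pseudocount
(the ratio is undefined at zero otherwise). A bp-level variant was
considered and rejected as the quoted rule counts peaks. The
accessible-repeat variant uses a genome-fraction background: expected =
n_family × accessible_bp/genome_bp on the merged accessible union.

The four-way taxonomy is evaluated per peak in priority order: *motif in
B1* requires a hit fully contained in a B1 element that overlaps the peak
(containment is the unambiguous reading of "falls into"); then *motif next
to B1* (hit + B1 overlap), *motif non-overlapping B1* (hit, no B1), *no
motif*. The labels partition the peak set.

## Linking statistics

Gene-centric enhancer assignment: each gene links to its nearest distal
peak within 50 kb of its TSS (one link per gene; a peak may serve several
genes; equidistant ties go to the leftmost peak and are flagged).
Set-vs-set association uses the two-sided Fisher exact test (p sums
hypergeometric probabilities ≤ the observed table's), with a Haldane
half-count odds-ratio correction when a cell is zero. Printed percentages
round half-up, which reproduces conventionally printed values that banker's
rounding can miss. Fold-change group summaries are five-number sets with
groups under 3 genes flagged.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions used by every recovery and calibration test.

* **Genome**: 2 chromosomes × 400 kb of uniform random sequence, 900
  non-overlapping repeat elements (60% B1-like at 135 bp, plus B2/B4/MERVL
  stand-ins at 190/250/300 bp), each family derived from a fixed consensus
  with 8% per-base mutation. A fraction `p_motif_in_b1 = 0.525` of B1 copies
  carries an exact 9-bp nuclear-receptor-like motif (TCAAGGTCA) at consensus
  offset 30; non-carriers are regenerated until motif-free, so a zero rate
  means zero hits in B1. The 0.525 default (and the 0.664
  `accessible_b1_motif_rate` preset) name the genome-wide and accessible-B1
  motif rates reported for the real mouse genome, letting tests target a
  realistic regime without claiming to reproduce real-data numbers. The
  planted PWM (0.85/0.05 probabilities, threshold 12 bits) admits only exact
  consensus matches; spurious background hits are rare (~2 expected per
  800 kb) and land outside B1.
* **Expression**: 500 genes, class-mean FPKM trajectories drawn uniformly
  inside per-class bands whose distances to the 5/1-FPKM decision
  thresholds exceed twice the replicate noise scale, then 2 replicates with
  lognormal noise (σ = 0.2 log-units — a typical replicate-level FPKM
  spread). Class fractions: 10% minor ZGA, 15% major ZGA, 3%
  oocyte-upregulated major ZGA, 15% maternal, 5% + 5% stage-specific
  (4C/8C), 6% + 4% early/late ICM, rest background.
* **Binding/accessibility**: 150 + 150 + 100 bound B1 elements
  (2C-specific / 8C-specific / shared), sampled uniformly over B1 so the
  peak-level motif-carrier fraction tracks `p_motif_in_b1`; 300-bp peaks
  centered on elements; fragment sets = 30,000 uniform background fragments
  plus Gaussian pileups (60 fragments, σ = 80 bp) at each bound site; two
  replicates per stage. The knockdown keeps only `1 − kd_effect` (default
  10%) of the enriched fragments at 8C-specific sites, leaving 2C-specific
  and shared sites untouched.
* **Knockdown expression**: 4 replicates per condition at σ = 0.1; early
  ICM genes are downregulated (−2.5 log₂) at rate 0.45 vs 0.08 for others,
  and promoter binding is planted at rate 0.6 among downregulated vs 0.1
  among other genes, creating the association the Fisher test recovers.

**What the generator does not emulate**: read-level sequencing error,
mappability and GC bias, repeat phylogeny/divergence structure, Tn5
insertion preference, diploidy, or count-distribution details (FPKM noise
is lognormal, not negative-binomial). Passing recovery tests therefore
demonstrates that the operations implement their rules correctly and are
calibrated under exchangeable nulls — not that real-data preprocessing
(alignment, deduplication, peak calling) is handled, which is out of scope.

All randomness flows through one seeded `numpy` Generator; identical seeds
give byte-identical outputs in every emitted format.

## Problem sizes and determinism

The default cohort (800 kb genome, 900 repeats, 400 peaks, 500 genes × 2
replicates, ~40k fragments per track) was chosen so a full pipeline run
completes in a few seconds and the whole suite in well under a minute,
while keeping statistical checks meaningful: 400 peaks put the binomial
standard error of the motif-in-B1 fraction at ~2.5 points (recovery pools
three cohorts, ~1.4 points, against the ±5-point acceptance band), and 200
pseudo-motifs at n_perm = 199 make the null-calibration KS test sensitive
to miscalibration of a few percent. Fisher p-values are verified against
exhaustive hypergeometric enumeration for all table totals ≤ 40; the
shuffle null is verified against exact start-position enumeration on a
10-kb genome.

## Known limitations

* The MA-style differential call and the Welch-test DE are transparent
  surrogates, not reimplementations of hierarchical count models; both have
  injection points for externally computed results.
* The footprint statistic's null assumes positions within differential
  regions are exchangeable; structured within-region signal (e.g., strong
  position effects unrelated to the motif) would inflate it.
* `stage_specific_peaks` trusts the supplied pairwise calls; with
  conflicting calls a peak simply goes unassigned rather than being
  arbitrated.
* Peak–repeat overlap is binary at ≥ 1 bp; a bp-resolved variant would be
  needed for fine-grained repeat-age analyses, which are out of scope.
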