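# Methods

## Problem and approach

Hexaploid wheat tolerates whole-chromosome and whole-arm dosage changes,
which is why panels of nullisomic-tetrasomic, ditelosomic, terminal-deletion
and addition stocks exist for every chromosome. Such a panel turns gene
localization into interval logic: a locus required for a qualitative
phenotype (here, the formation of viable hybrid seed in crosses with rye,
controlled by the *Dee-D1* locus on chromosome arm 1DL) must lie in the
region absent from every line that lacks the phenotype and present in every
line that shows it. `delmap` implements this deletion-bin mapping pipeline
end to end: binned read-count simulation or ingestion, coverage-based
karyotyping, interval mapping with homoeologous dosage compensation, and
the accompanying spike-fertility statistics.

## Coordinate model

Chromosomes are linear with a single centromere; coordinates are 0-based
half-open bp, bins are fixed-width (default 1 Mb, last bin possibly short,
never dropped), and the short arm sits on the low-coordinate side by default
(configurable per chromosome). Breakpoints are expressed as fraction length
(FL): distance from the centromere divided by arm length, so a deletion
stock with breakpoint FL 0.41 retains the proximal 41% of the arm.
`position_of` rounds half away from the centromere; `fl_of ∘ position_of`
is the identity within 1 bp of arm resolution (property-tested).

Real assemblies do not come with round-number centromeres, and the
centromere position is deliberately a mandatory user input: FL values alone
cannot be converted to bp without it. The bundled demo layout is therefore
**synthetic**: group-1 chromosomes of 500 Mb with centromeres at 200/150/100
Mb (1A/1B/1D), chosen so that every bundled FL breakpoint falls exactly on a
1 Mb bin boundary. FL-scale results on this layout are exact; bp
coordinates are illustrative only.

## Synthetic data generator

The generator emulates the statistical structure of genotyping-by-sequencing
(GBS) coverage over an aneuploid panel:

- **Karyotype events** (nullisomy, tetrasomy, telosomic, terminal deletion
  with an FL breakpoint, arm addition) expand deterministically to per-bin
  copy numbers; stocks are homozygous, so doses move in steps of two
  (0/2/4). A bin belongs to an arm, and to the deleted region, by its
  midpoint. Contradictory event combinations raise an error naming the bin.
- **Counts**: `E[c_ib] = s_i · d · w_b · cn_ib / 2`, with library factors
  `s_i` (default 1), panel mean depth `d` (default 50 reads/bin at two
  copies), and per-bin capture weights `w_b` drawn once per panel from a
  log-normal with mean 1 and σ = 0.5 and shared across lines — GBS bin
  coverage is heavy-tailed and reproducible between libraries because it is
  driven by restriction-site density. Count noise is Poisson by default;
  negative-binomial (dispersion k) and a degenerate "none" law (counts equal
  the expectation exactly, for oracle tests) are available.
- **Viability** is a pure function of truth copy numbers: viable iff the
  locus bin carries ≥ 1 dose, or the homoeolocus on the compensating
  chromosome carries ≥ 4 doses (the nullisomic-1D/tetrasomic-1B karyotype is
  viable through this rule). Compensation is deterministic for viability;
  for quantitative traits compensated lines sit a configurable fraction
  (default 0.5) of the full effect away from baseline — that fraction is a
  free parameter of the generator, not an empirically established value.
- **Traits**: Gaussian replicates (default n = 5) around line means
  `baseline + effect · x`, with x ∈ {0, 0.5, 1} as above. The bundled model
  uses euploid baselines (spike length 8.2 cm, 21.4 spikelets, 63.8 grains,
  TGW 35.3 g, seed set 87.3%) and locus-absence effects (+2.8 cm, +0.4,
  −43.6, −13.0 g, −41.8%) matching the published contrasts in sign and
  rough magnitude. sd = 0 is allowed as the deterministic limit (replicates
  equal the means exactly); negative sd is an error.

The default simulation layout is a synthetic 21-chromosome complement
(7 groups × A/B/D, 500 Mb each). This matters: step 1 of the normalization
divides by the line's total read count, so a missing arm inflates the
log2 ratio of every other bin by `log2(total_ref / total_line)`. On a
realistic 21-chromosome genome the shift from one missing arm is ≤ ~0.06
and harmless; on a 3-chromosome toy it reaches 0.45 and corrupts state
calls. Ratio-to-total normalization is only valid while the aneuploid
fraction of the genome is small — a genuine limitation of the method, not
of the implementation.

What the generator does **not** emulate: read-level artifacts (mapping
bias, PCR duplicates), GC-dependent bias beyond the static capture weights,
segregating heterogeneity within a stock, mosaicism, partial-arm
translocations, and trait covariance between traits or with the
environment. Passing tests therefore demonstrate correctness of the
computational pipeline under a faithful count model, not robustness to
every artifact of real GBS libraries.

## Coverage karyotyping

1. **Two-step normalization**: per-line proportions of pseudocounted bin
   counts (pseudocount 0.5; avoids log of zero in deleted regions while
   keeping them strongly negative — the choice only matters for zero bins),
   then per-bin log2 ratio against the euploid reference line. The
   reference track is exactly zero; rescaling any line's counts is a no-op
   (exact only at pseudocount 0; property-tested at 1e-12).
2. **Smoothing**: running median, default window 3 bins, truncated at the
   edges, never crossing chromosome boundaries; robust to single-bin
   artifacts.
3. **State calling**: thresholds at log2 midpoints between the expected
   ratios of copy numbers 0..4 relative to 2 (−2.0, −0.5, 0.5, 0.8);
   configurable. The published analogue of this step was visual inspection
   of plotted tracks, so the numeric rule is a reconstruction and is
   deliberately exposed as parameters.
4. **Segmentation**: maximal constant runs; runs shorter than `min_run`
   (default 3) are absorbed into the neighbour with the closer mean
   smoothed ratio. Ties go to the lower-index neighbour — a fixed,
   order-independent rule (ties are measure-zero on real tracks).
5. **Classification**: per-arm template matching. Arm dosage is assessed at
   the *segment* level: each run is relabelled by the precision-weighted
   mean of its **raw** log2 ratios, with weights equal to the per-bin
   effective depth `1/(1/c_line + 1/c_ref)` (the inverse sampling variance
   of the ratio up to a constant). Weighting by depth and using raw rather
   than smoothed values makes the label insensitive to clusters of
   low-coverage bins, whose ratios are the noisiest; in homozygous mode the
   candidate doses are {0, 2, 4} with boundaries at −2 and 0.5 (a flag
   re-enables odd doses). Runs shorter than `min_event` bins (default 5 —
   below any credible cytogenetic event at 1 Mb resolution) are treated as
   depth artifacts and absorbed. Templates: whole chromosome 0 →
   nullisomy; 4 → tetrasomy; one arm 2 / other 0 → telosomic; proximal 2
   then distal 0 on one arm → terminal deletion with the breakpoint at the
   boundary of the first deleted bin (reported as a one-bin-wide interval,
   the calling resolution); one arm 4 / rest 2 → arm addition. Everything
   else is reported as an unclassified pattern with its raw segments
   attached, never silently dropped.

At 50 reads/bin with a single reference library, sampling noise of the
*reference* itself is shared by every line's track, and occasional ≥5-bin
artifact clusters survive; these surface as unclassified patterns (about
0.1–0.2 per line per 10,500 bins in the bundled conditions). Measured
performance under the bundled conditions (seeded, recomputed by the test
suite): breakpoint bin within ±1 of truth in ≥ 95% of 200 simulated
deletion stocks; all five event kinds classified exactly in the noise-free
limit.

## Locus mapping

`map_locus` computes, over constraining lines (phenotype known, not
compensated): candidate bins = {absent in every non-viable line} minus
{absent in any viable line}, where "absent" means called copy number 0 (the
stocks are homozygous; single-dose states do not constrain). Maximal runs
of candidate bins become candidate intervals with FL bounds; multiple
disjoint intervals are all reported; an empty result returns diagnostics
rather than raising. Adding a constraining line can only shrink the
candidate set (property-tested), and the output is checked bin-for-bin
against an independent exhaustive oracle on 500 random panels.

**Compensation** is applied before mapping: a line is flagged compensated
when its dosage is ≥ `required_copies` (default 4) over *every* bin of the
compensating chromosome. The homoeolocus position cannot be known before
the locus is mapped, so whole-chromosome dosage is the operational
criterion; it exactly captures the tetrasomic-compensation karyotype.
Compensated lines are excluded from both constraint sets — their viability
is explained without the target locus. `detect_conflicts` reports, under a
no-compensation model, every line whose phenotype contradicts a candidate
(the compensated nullisomic-tetrasomic line is the canonical conflict).

The command-line `map-locus` stage consumes called karyotype *events*
(breakpoints and whole-arm/chromosome doses) rather than raw per-bin
states: events are the unit of evidence a deletion panel provides, and
event-level dosage is immune to residual per-bin state noise (a tetrasomic
chromosome whose track straddles the 3/4 threshold still yields a clean
tetrasomy event).

`genes_in_interval` intersects a GFF3 annotation with a candidate interval
under the any-overlap rule (GFF3 1-based inclusive coordinates converted
internally), with an optional attribute filter for high-confidence genes;
malformed records are warned about and skipped, with a final count.

## Spike-fertility statistics

- Seed set (%) = 100 · grains in florets 1–2 / (2 · developed spikelets),
  capped at 100; reduced spikelets enter through the denominator choice.
- Potential spikelet productivity (%) = 100 · grains at harvest maturity /
  floret primordia at the terminal-spikelet stage, per spikelet position
  (basal / central / apical).
- Multi-line comparison: one-way ANOVA per trait with protected Fisher's
  LSD flags against a control line: pairwise tests are made only when the
  omnibus F rejects at the same level, and a line is flagged at the
  smallest α ∈ {0.05 → "*", 0.01 → "**"} at which its |mean difference|
  exceeds `t(1−α/2, df_e) · sqrt(MSE · (1/n_i + 1/n_c))`. Lines with fewer
  than two replicates are excluded with a warning. No further
  multiple-testing correction is applied by default (a Bonferroni option
  exists), matching the usual reporting style of protected LSD.

With exactly two groups the procedure collapses to the pooled two-sample
t-test (omnibus p equal to 1e−10; tested), so its per-comparison type-I
error is exactly nominal — the calibration check runs in that two-group
setting. With more groups, protected LSD is *conservative* per comparison
under the complete null (the omnibus gate bounds the family-wise rate by
α), which is why the null-panel check asserts "no flags in ≥ 94% of
trait-families" rather than a two-sided band around α.

## Numerical and design choices

- Pseudocount 0.5 before step-1 normalization (default); zero-count
  reference bins with pseudocount 0 raise an instructive error.
- Rounding in `position_of`: half away from the centromere, making the
  FL→bp→FL round trip exact at integer positions.
- Bin membership of breakpoints: midpoint rule, symmetric and
  order-independent.
- All randomness flows from a single seed per simulation; stage-local
  generators are derived from it, and identical config + seed gives
  byte-identical outputs (tested through the CLI).
- Problem sizes in the bundled analyses: 16 lines × 10,500 bins for the
  panel demonstration; 200 replicate two-line panels on a 6 × 500 Mb layout
  for breakpoint recovery; 500 random 2 × 60 Mb panels for mapper
  soundness; 1000 two-group draws for the LSD calibration. These sizes give
  Monte-Carlo error comfortably below the asserted margins.

## Reproducing the real-data quantities

The physical candidate interval on the reference assembly
(259,000,000–494,000,000 bp on 1DL) and its gene content (5,655 genes,
2,650 high-confidence) depend on the real GBS libraries (ENA accession
PRJEB37818) and the IWGSC RefSeq v1.1 annotation, neither of which is
bundled. The pipeline from raw reads would be:

```sh
# per accession: trim, map to the Chinese Spring assembly, keep unique hits
cutadapt -a AGATCGGAAGAGC -o trimmed.fq.gz raw.fq.gz
minimap2 -ax sr CS_refseq_v1.0.fa trimmed.fq.gz | samtools sort -o line.bam
samtools view -q 20 -b line.bam > line.uniq.bam
# 1 Mb bin counts -> long-format TSV (line, chrom, start, end, count)
bedtools makewindows -g CS_refseq_v1.0.genome -w 1000000 > bins.bed
bedtools coverage -a bins.bed -b line.uniq.bam -counts \
  | awk -v L=LINE '{print L"\t"$1"\t"$2"\t"$3"\t"$4}' >> counts.tsv

delmap karyotype --counts counts.tsv --layout cs_layout.yaml --reference CS --out karyo/
delmap map-locus --events karyo/events.json --phenotypes pheno.tsv \
  --layout cs_layout.yaml --compensation 1B:4 \
  --gff iwgsc_v1.1_genes.gff3 --hc-attr primary_confidence_class --hc-value HC \
  --out mapping/
```

`cs_layout.yaml` must supply the assembly's chromosome lengths and
centromere positions (required user input; see above). None of these
downloads run in the bundled analyses or tests.

## Known limitations

- No sub-bin breakpoint refinement; breakpoints are one-bin intervals.
- No heterozygous or mosaic dosage states in the default homozygous mode.
- No GC or mappability correction beyond what the shared capture weights
  absorb; a real panel with batch effects between libraries would need an
  additional normalization step.
- The mapper is purely qualitative presence/absence logic — no statistical
  fine-mapping, LOD scores, or recombination-based refinement, which is the
  correct scope for a deletion-stock panel but cannot rank positions within
  the candidate interval.
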