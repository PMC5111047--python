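# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the limitations of the package. Everything stated
here is computed by the test suite or `scripts/acceptance.py`; nothing is
quoted from elsewhere.

## Methylation calling

Bisulfite sequencing reports a CpG as methylated when its cytosine failed
to convert. Conversion itself fails at a small rate e, so the calling
problem is a one-sided binomial test per site and library:

    m ~ Binomial(m + u, e)   under the null of zero methylation,
    p = P(X >= m)

with e estimated as unconverted/total read-cytosines on the unmethylated
lambda spike-in, floored at 1e-6 so a perfectly converted control still
yields a proper null. When an independent estimate from non-genic
non-CpG cytosines is supplied, a greater than two-fold discrepancy
between the two raises a warning — a cheap concordance check on the
spike-in calibration.

Choices worth stating:

* **Dyad combination.** The two strands of a CpG dyad are summed into one
  site keyed by the 0-based plus-strand C position (symmetric-methylation
  assumption). All internal coordinates are 0-based half-open; 1-based
  conventions exist only at the GFF3/BED/report file boundaries.
* **Coverage filter.** "More than three reads" is read strictly: a site
  is testable at coverage >= 4.
* **Multiple testing.** BH runs within each library over its testable
  sites, matching per-library calling; the pooled dataset (counts summed
  across libraries before testing, never fractions averaged) gets its own
  BH family.
* **Gene status.** A gene is methylated when >= 1 exonic CpG is called
  methylated in the pooled data; an exon+intron variant is also emitted,
  since feature-level summaries differ between the two conventions.
  Feature-level methylation is the coverage-weighted pooled fraction
  sum(m)/sum(m+u); the unweighted mean of site fractions is emitted
  alongside for comparison.
* 5mC and 5hmC are indistinguishable to this protocol; no correction is
  attempted.

Calibration: on a simulated fully unmethylated genome (1e5 CpGs, e =
0.5%, coverage ~ Poisson(10)) the fraction of testable sites called
methylated at FDR 0.01 is measured by the acceptance script and bounded
by the BH guarantee (<= 1%).

## Differential methylation

Windows of 200 bp tile each scaffold from 0 (terminal remainders kept); a
CpG belongs to the window containing its dyad position. For a comparison
the 8 libraries split 4 vs 4 (caste: both sexes pooled per caste; sex:
both castes pooled per sex). A window is testable when at least 3 of 4
libraries per side have summed window coverage >= 5 and at least one
member CpG is called methylated in at least half of all libraries. The
"half of the samples" rule is interpreted per-CpG within the window
(>= 1 member CpG methylated in >= 4 of 8 libraries) and is configurable.

The test models replicate counts beta-binomially in the mean/precision
parameterization alpha = pi\*theta, beta = (1-pi)\*theta. Group means are
fitted by bounded one-dimensional likelihood maximisation (xatol 1e-8,
bounds [1e-9, 1-1e-9]); the LRT 2(l_alt - l_null) is referred to
chi-square with 1 df. BH runs separately per comparison (caste and sex
are distinct hypothesis families). Significance additionally requires an
absolute fitted difference > 0.15 (regions) or > 0.20 with q < 0.01
(confident DMCs).

**Dispersion.** The precision theta is estimated by method of moments
from the window plus its +-200-bp flanking windows. Each window-by-group
combination contributes the residuals of its replicate fractions around
its own pooled mean, so a genuine group difference does not inflate the
estimate; using the estimated mean loses one degree of freedom per cell,
absorbed by a (1 - 1/k) factor. The estimate is clipped to [1, 1e6];
replicates with no excess variance hit the ceiling (binomial limit).
Summing counts across flanking windows before estimating — rather than
treating them as separate cells — would average away replicate variance
and under-estimate dispersion several-fold; the cell-wise form recovers a
generating theta = 15 within [10, 22] (median over simulations) and
theta = 20 to within a few percent at 8 libraries.

**Calibration.** With the precision at its generating value the LRT
p-values are uniform on replicated null windows (KS p > 0.01 at 5000
windows; the acceptance script recomputes this). With the precision
estimated from only 8 libraries the test is mildly anti-conservative
(empirical type-I around 6% at nominal 5%), which is the expected price
of moment estimation at this replication level; the planted-recovery and
permutation analyses below run the full estimated-dispersion path and
absorb that noise.

A note on the reference implementation this design mirrors: tiling-window
beta-binomial testing with locally pooled dispersion follows the
methylKit/methylSig family of DMR callers, but the degrees-of-freedom
approximation those tools use is unpublished, so the chi-square(1) LRT is
used here and validated by simulation calibration rather than numeric
identity.

**Merging and assignment.** Bookended significant windows with the same
hypermethylation direction merge into DMRs (idempotent, order
independent). Each DMR is assigned the feature type with maximal bp
overlap, ties broken exon > promoter > intron > downstream-2kb >
intergenic; genes containing >= 1 DMR form the DMG table with direction
counts. The conservative list intersects the two constituent pairwise
comparisons (e.g. AF vs WF and AM vs WM) and keeps genes significant in
both with a consistent direction.

**Recovery under the study conditions.** Planted caste DMRs with
pi_alate = 0.75 vs pi_worker = 0.45 (delta = 0.30), coverage 20 per CpG
per library, 2 replicates x 4 libraries per side, are recovered with
power >= 80% at q < 0.05 and |diff| > 15%, with <= 5% of null windows
significant (acceptance script; observed power is 100% with zero false
windows at the simulated sizes, 20 planted among ~300 testable windows).

## Permutation false discovery

With 8 libraries split 4 vs 4 there are C(8,4)/2 = 35 unordered balanced
relabelings, 34 excluding the true one. The beta-binomial path can be
re-run on any subset of them; the t-test variant (Welch t on replicate
window fractions, BH, same effect-size filter) follows the published
100-iteration procedure by resampling schemes with replacement, since
the distinct scheme space is smaller than 100. Untransformed fractions
are the default; an arcsine-square-root variant sits behind a flag.
Observed and shuffled runs share one code path, so every filter applied
to the real labeling is applied to every shuffle. The summary reports
empirical p = (1 + #{null >= observed})/(1 + n) and observed over the
null mean (mean floored at 1).

On null synthetic data the observed count falls within the central 95%
of the shuffle distribution; with planted caste effects it exceeds the
null maximum (empirical p = 1/101 at 100 shuffles).

## Expression and its integration

FPKM = count x 1e9 / (length_bp x library_total). Per gene: within-morph
replicate CV (sd/mean, averaged over morphs), between-morph absolute
difference on log2(FPKM+1), and specificity. The specificity formula was
an open choice; the tau index (0 uniform, 1 exclusive) is used and is
swappable. Expression level is reported as the mean of morph means —
also an open choice, flagged in the code.

**Antisense.** Genes overlapping > 50% of another gene are excluded.
Per library, a gene's antisense count is tested against Binomial(total,
library-wide antisense proportion over included loci), BH within library;
a gene is flagged when > 1/3 of libraries are significant. The continuous
metric is the mean antisense read proportion across replicates of each
sample type. Planted loci at 30% antisense against a 5% baseline at
100x coverage are recovered in >= 95% of simulations with <= 5% null
flagging (acceptance script; observed 100% and 0%).

**Methylation-expression models.** Spearman correlations per predictor
plus a joint OLS of the rank-transformed response on standardized
rank-transformed predictors, giving comparable coefficients;
zero-variance or collinear predictors are dropped with a warning.
Gene-family metrics (proportion of species with a member, mean copy
number, focal-species copy ratio) stratify the model by recent
duplication. DMG contrasts use rank-sum tests (CV, |delta|), Fisher
exact tests (DMG x spliced 2x2) and nearest differentially-spliced-exon
distances; differential expression and exon-usage calls are consumed as
input tables from external tools, not re-fitted.

## Landscape descriptions

Metagene profiles use 40 proportional gene-body bins plus 20 fixed-bp
flank bins by default (granularity was unstated in the source design;
these defaults are configurable), strand-flipped so every gene reads
5'->3'; an absolute mode profiles the first/last 4 kb in 100-bp bins.
Neighbouring genes are not excised from flanks; with the dense gene
spacing of methylated clusters this blends adjacent gene-body signal
into the flank bins, which is flagged here rather than silently
corrected. Junction profiles use internal exon-intron junctions only,
truncated (never padded) at short features, with a methylated-exon-only
variant (exon contains >= 1 pooled-methylated CpG). CpG o/e =
N_CG x L / (N_C x N_G) — the L (not L-1) variant, stated because both
exist. Deciles are equal-size by rank with stable gene-id tie-breaking.
Repeat analysis classes repeats (>= 3 covered CpGs) as exonic, intronic
or non-genic; the non-genic "surrounding region" is a +-2-kb flank
excluding any repeat or gene bp (width was an open choice). Ortholog
methylation classes label 1-to-1 ortholog sets by which species are
methylated; incomplete rows are dropped and counted.

## Motif analysis

Test sequences are 150-bp windows centred on confident DMCs (75 bp left,
74 bp right of the anchor; "surrounding" could also mean +-150 bp, so the
width is a parameter). Controls are windows centred on methylated
(> 30%) non-differential cytosines within 1.5 kb of a tested DMC and not
overlapping any test window, which controls for the CpG-composition bias
of methylated regions; the achieved control:test ratio is reported.

PWM scans score every position on both strands with log2 likelihood
ratios against a background estimated from the pooled control set
(uniform available via flag). Per-position p-values come from the exact
null score distribution, built by dynamic programming over motif columns;
partial sums accumulate left-to-right exactly as sequence scoring does,
so the distribution's support coincides bit-for-bit with scanned scores
and p-values equal full k-mer enumeration (verified to 1e-12 for motifs
up to 8 bp). If the state space of a long dense matrix explodes past 2e6
states, partial sums are rounded to 9 decimals; point-mass miRNA
matrices never trigger this. Hits are BH q < 0.1 within a sequence set
(per motif per set; the alternative poolings are flagged as open).

Mature miRNAs become point-mass PWMs (U->T, pseudocount 0.01 per
off-letter); both the mature sequence and its reverse complement are
matched, and the 5' and 3' arms of one hairpin are separate motifs.
Per-motif enrichment combines a one-sided Fisher exact test on
sequences-with-a-hit (a deliberate, simpler surrogate for rank-based
enrichment statistics) with the size-normalised fold
(pos_hits/n_pos)/(max(neg_hits,1)/n_neg); the max(neg,1) convention is
what reproduces the published table's zero-negative rows exactly.
Phenotype specificity re-runs the Fisher test using the other
phenotype's test set as control, labelling motifs caste/sex/ns.

## The synthetic-data generator

The generator emulates, at desk scale, exactly the structure the
analyses assume: bimodal gene-body methylation (default 70% of genes
methylated at level 0.8, the rest at 0.01, promoters unmethylated),
spatial clustering of methylated genes (clustered genes are also more
closely spaced, so spacing analyses see the signal), 4 phenotypes x 2
methylome replicates and x 3 transcriptome replicates, planted caste- or
sex-biased regions of 200 bp inside designated genes, conversion error
0.5% applied as failed conversion at unmethylated cytosines (optional
over-conversion of methylated cytosines, default 0), a fully
unmethylated lambda control with the same error, negative-binomial
expression with morph effects and a binomial antisense fraction, and
motif consensus sequences written adjacent to planted DMRs. Coverage is
Poisson per dyad per library; methylated reads are
Binomial(cov, pi(1-over) + (1-pi)e) — the simplest model consistent with
the caller's assumptions. One RNG stream per output file, keyed by
(master seed, file name), so adding samples never reshuffles existing
ones and a fixed seed reproduces every byte.

What it does **not** emulate: read-level data (no FASTQ, no alignment
artefacts), sequence-composition biases, covariation between coverage
and methylation, linked-site correlation beyond the planted block
structure, age/colony/tissue heterogeneity. Passing tests therefore
demonstrate statistical correctness of the pipeline under its stated
assumptions, not robustness to real-data artefacts upstream of the
count tables.

**Problem sizes.** The validation studies use 40 genes across 4
scaffolds (~300 testable windows, 20 planted DMRs), 5000 null windows
for calibration, 100 simulation replicates for the antisense and
dispersion checks, and 100 resampled relabelings for the permutation
analysis — sizes at which every measured rate is stable across seeds
while a full run of tests plus acceptance script stays around a minute
each.

**Strong DMCs for the motif stage.** Single-CpG tests at coverage 20 and
delta = 0.30 sit near the confident-DMC boundary (q ~ 0.01) by design —
confident DMCs are the extreme tail of a real dataset. The motif-stage
simulations therefore plant strong regions (e.g. 0.9 vs 0.1) so a
non-degenerate DMC set exists; the window-level recovery criterion keeps
the harder delta = 0.30 conditions.

## Known limitations

* The chi-square(1) reference for the LRT is asymptotic; at very low
  coverage (a few reads per window) p-values become discrete and
  conservative.
* Moment-based dispersion at 2 replicates per phenotype is noisy; the
  local pooling mitigates but does not remove this (see calibration
  above).
* The Fisher sequences-with-hit test ignores hit multiplicity within a
  sequence; the fold-enrichment statistic reports it instead.
* No covariate adjustment (age, colony, tissue composition) — the design
  has none to offer; whole-body samples confound allometry with
  methylation differences, and nothing in the statistics can separate
  them.
* Methylation "block" detection (the large highly methylated regions
  visible in browser views) is intentionally out of scope: no defined
  algorithm exists for it, and the landscape profiles capture the same
  structure descriptively.
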