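# Methods

## Probe-to-repeat assignment

All coordinates are handled internally as 0-based half-open intervals.
RepeatMasker `.out` files (1-based inclusive) and GTF are converted on read;
BED passes through unchanged. The repeat `class/family` column is split on the
first `/`; a bare class (e.g. `Satellite`) doubles as its own family. The
taxonomy constrains families to exactly one class (LINE ⊇ {L1, L2}, SINE ⊇
{Alu, MIR}, LTR ⊇ {ERV1, ERVL, ERVL-MaLR, ERVK}); satellite DNA is carried as
a non-RTE control class and anything else is binned as `Other`.

Probe context is decided against a gene model: one bp of exon overlap makes a
probe exonic (excluded from RTE quantification, since its signal is dominated
by the host transcript); a probe inside a gene body but clear of exons is
intronic; everything else — including probes on chromosomes absent from the
model — is intergenic. Probes without coordinates carry an `unknown` context
and are always excluded. Only intergenic and intronic probes are assigned.

Assignment is single-best: each probe maps to the repeat it overlaps most
(≥ 1 bp qualifies; no minimum-overlap fraction is imposed because probes are
short relative to repeats). Ties break to the leftmost repeat start, then to
the lexicographically smallest repeat name, so results are deterministic and
independent of input order. Single-best assignment rather than
multi-assignment means a probe spanning two nested repeats is never counted
twice in a class score. Strand is stored but ignored for overlap: expression
probes interrogate transcripts from either strand and methylation is
strand-symmetric at CpGs.

## RTE scores

The score of a class or family in a sample is the unweighted mean of its
assigned probe values (log2 intensity, beta value, or RPM). A class pools
probes directly rather than averaging family means, so families contributing
more probes weigh more — a deliberate choice that mirrors how per-probe
evidence accumulates, and is tested explicitly. Duplicate feature rows in an
input matrix are collapsed to their per-sample mean before any scoring.

For sequencing data, each read is counted once against its best-overlap
repeat (same tie-break as probes) and counts are RPM-normalised:
value = 1e6 · count / total, so each sample column sums to 1e6 when the
column total is the denominator.

## Signature scoring

Single-sample signature scores are rank-based: genes are ranked 1..n
ascending within each sample (average ranks on ties), and a signature's score
is its mean rank linearly rescaled so that 0/1 correspond to the signature
occupying the bottom/top m ranks. Scoring is unidirectional (up-sets only):
the six BAR signatures are plain gene lists without down-components. Scores
therefore depend only on within-sample ranks and are invariant to any
monotone transform of a sample's values — the property that lets microarray
intensities and RPM values be scored identically. Genes absent from the
matrix are intersected away silently but always reported per signature.
Symbols are matched case-insensitively after whitespace stripping; no alias
resolution is attempted.

## Stratification and statistics

Quartile groups are low (≤ Q1), medium, high (> Q3), with
linear-interpolation quantiles; boundary ties go to the extreme groups so the
partition is deterministic. Median splits put the median element in the low
group. Pearson correlations use pairwise deletion of missing values and
two-sided p-values from the t distribution with n−2 df. Group contrasts use
the unpaired two-sided Wilcoxon rank-sum test with normal approximation,
continuity and tie correction (all contrasts in this workflow compare
independent sample groups, so the signed-rank variant is never needed; exact
enumeration is not used because cohort group sizes make the approximation
accurate). Star annotations use raw p at {0.05, 0.01, 0.001, 0.0001}; a
Benjamini–Hochberg helper is provided but off by default, matching the
convention of annotating raw p-values in this literature.

## Gene-set variation scoring

The per-sample enrichment score is computed in three steps: (1) per gene, a
Gaussian-kernel CDF estimate across samples with bandwidth sd/4 (sample sd,
ddof = 1; zero-spread genes get 0.5 everywhere) — the continuous-data kernel;
a count-kernel mode is out of scope; (2) per sample, genes are ranked by
descending CDF value (ties broken by input gene order for determinism) and
weighted symmetrically by |G/2 − rank|, emphasising both expression extremes;
(3) a running sum over the descending ranking adds w/Σw at member genes and
subtracts 1/(G−m) at non-members, and the ES is the maximum positive plus the
minimum negative deviation (difference of extremes). Note that because step 1
is a within-gene CDF, shifting an entire gene row does not change its scores:
the statistic measures relative expression across samples. The
difference-of-extremes ES of a set and its complement have opposite signs
when the set is concentrated at one end of the ranking, but not for arbitrary
data — the test suite checks the concentrated case.

Differential enrichment between high and low strata is a Welch t-test on the
per-sample ES with calls up/down at |mean difference| > 0.1 and p < 0.05.
The low logFC threshold is intentional: ES values live on a compressed scale.
Welch's t was chosen over a moderated t because variance moderation across
gene sets is not reimplemented here. Gene-set name hygiene mirrors common
MSigDB practice: sets ending `_UP`/`_DN` and three known-redundant
inflammation sets are dropped; keyword selection (e.g. 'inflammatory',
'dna_repair') happens upstream.

## Single-cell pseudo-bulk

Per-cell counts (genes plus RTE class/family rows, as produced by scTE-style
quantifiers) are summed exactly into (cell type, sample) pseudo-bulk
profiles; unannotated cells are dropped with a logged count. RPM
normalisation of a pseudo-bulk column uses the combined denominator of gene
counts plus RTE *class* counts; family rows are normalised with the same
denominator but excluded from it to avoid double-counting their class.
Sample-level signature scores sum the gene rows over **all** cells of a
sample (not per cell type) before RPM and rank scoring — the two readings of
"all cells of the same type" are one flag apart (`sample_level_counts`), and
aggregation over all cells is the default because the signature score is
meant to characterise the donor, not a compartment. Samples are median-split
on a chosen signature (SASP by default) and each (cell type, RTE feature) is
contrasted high vs low by rank-sum; cell types with fewer than two samples
per group are skipped with a warning.

## Synthetic cohorts

The generators plant the minimal structure that reproduces the dissociation
the analysis is designed to detect: a standard-normal latent biological-age
factor B per sample, independent of chronological age. Defaults (all
overridable in `SyntheticConfig`):

- **Cohort**: n = 600 samples, ages uniform over 15–101 years — spanning the
  range of large published blood cohorts (hundreds to ~1200 samples).
- **Expression** (log2-intensity scale): baseline N(8, 1) per feature, noise
  sd 1.0. Signature genes (6 sets × 15) load 1.0 on B. RTE probes (4 per
  family, 8–16 per class) load per class: PBMC mode LINE +0.9, LTR +0.9,
  SINE −0.7, Satellite 0; monocyte mode flips SINE to +0.7. Age has zero
  expression effect by default, so age–RTE correlations are null by
  construction. Expected correlations are analytic: a class score with
  loading b and residual sd s has r = b/√(b² + s²) against B.
- **Methylation**: beta = clip(b0 + slope·(age − midpoint) + ε, 0, 1) with
  b0 ≈ 0.6 (probe-level jitter sd 0.05), slope −0.002 per year for every
  class, noise sd 0.04. With these values clipping touches essentially no
  data point (clip, not logit, for transparency). Matched expression is
  anti-coupled to methylation for LINE/LTR probes and independent for SINE
  and satellite probes.
- **Annotation**: a deterministic non-overlapping genome layout on one
  chromosome; each modelled family gets probes_per_family assignable probes
  alternating intronic/intergenic placement, one exonic decoy over a repeat,
  and one intergenic probe over no repeat — every truth label is unambiguous,
  so the annotation module must recover contexts at 100%.
- **Single cell**: 5 PBMC cell types (Plasma, NK, BC, TC, M14), 16 samples,
  25 cells per (sample, type), 300 genes at ~7 counts/gene/cell (negative
  binomial, size 10) and RTE classes at 30 counts/cell, so RTE reads are a
  small fraction of each library as in real data. Half the samples are
  high-B: their signature genes scale by 1.6 with the cell's expected total
  gene output held fixed (otherwise library-composition shifts would make
  every RTE RPM group-dependent), and the planted (Plasma, LINE) rate is
  multiplied by 3 in those samples only. The binary high/low latent state is
  a modelling simplification that makes the signature-based median split
  recover the truth cleanly.

Every generator is a pure function of (config, seed) — fixed seed gives
byte-identical output files — and writes a ground-truth JSON (ages, latent
factor, couplings, probe truth map, planted folds) next to its outputs, so
recovery tests read truth from file rather than re-deriving it.

What the generators do **not** emulate: batch and dye effects, probe
cross-hybridisation, twin/longitudinal dependence, cell-type abundance
shifts, doublets, or realistic repeat nesting. Passing recovery tests
therefore demonstrates that the pipeline detects the planted statistical
structure at realistic sizes and noise levels — not that it would be robust
to every artefact of real array or droplet data.

## Problem sizes and numerical choices

Calibration checks use 2000 null replicates (Pearson at n = 200, Welch at
30/30), giving a binomial sd of ~0.5% around the nominal 5% level. Gene-set
recovery uses 50 replicates of a 400-gene, 40-sample matrix with a 10-gene
set shifted +1.5 sd in half the samples; the 400-gene background keeps the
compositional effect of the shift on decoy sets small, as in genome-scale
matrices. Single-cell recovery uses 25 replicates of the default
configuration. Quantile estimation uses NumPy's linear interpolation;
rank ties use average ranks; GSVA rank ties break by gene order. All
stochastic tests are seeded.

## Known limitations

- Real HT-12 manifests and RepeatMasker releases are required to reproduce
  published probe counts (e.g. how many noncoding probes cover RTEs); the
  package reports whatever its inputs yield and makes no claim about
  manifest-specific counts.
- The microarray path assumes normalised input matrices; no background
  correction, batch correction, or probe QC beyond duplicate collapsing.
- Longitudinal/twin cohorts are treated cross-sectionally.
- GSVA here implements one variant (Gaussian kernel, difference of
  extremes); other scoring modes (ssGSEA, PLAGE, z-score) are out of scope.
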