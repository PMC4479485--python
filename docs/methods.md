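# Methods

## Study design being modelled

The pipeline targets a pooled-library design: one wild-type (WT) pool and
two independent overexpressor (OE) lines, each sequenced once. There are
no biological replicates within genotype; the two OE lines act as
replicas of the perturbation, and robustness comes from requiring every
differential call to replicate, with the same sign, across both
OE-vs-WT comparisons. All statistics downstream of the count table are
implemented here; read trimming, assembly, mapping and annotation
generation are upstream concerns and out of scope.

## Differential expression without replicates

Kal's Z-test treats a gene's reads as a binomial draw from its library
and compares the two proportions with the pooled two-sample z statistic.
It is exact in its assumptions only under pure counting (Poisson) noise;
with biological overdispersion it is anti-conservative, which is an
inherent property of replicate-free designs, not of this implementation.
The pipeline therefore (a) runs the test on raw counts and library-total
denominators, where the statistic is defined, and (b) takes fold changes
from quantile-normalized RPKM, where between-library distributional
differences have been removed. The two-fold / p ≤ 0.001 double cutoff
and the two-line same-direction intersection are the decision rule;
p-values at this stage are deliberately not multiplicity-adjusted (the
rule is a fixed raw-p screen; FDR control lives in the enrichment stage).
Cutoffs are boundary-inclusive (|log2 FC| ≥ 1, p ≤ 0.001).

Genes with zero counts in both compared libraries are untestable and
excluded (statistic and p reported as NaN, call `none`). For fold
changes, a pseudo-count of 1 expression unit is added to both sides only
when one side is zero, keeping log2 ratios finite without perturbing
measured genes. Library totals default to the column sums of the count
table; an external override is accepted because a mapper's total mapped
reads may legitimately exceed the per-gene sum.

## Quantile normalization

Columns are forced onto the mean empirical distribution: each column's
sorted values are replaced by the across-sample mean of sorted values,
ranks preserved. Ties receive the mean of their rank positions
(linear interpolation at fractional ranks), so heavily tied columns —
e.g. the zero-count block — map to the average of the corresponding rank
means rather than an arbitrary ordering.

## GO enrichment

Exact hypergeometric upper tail per term, BH step-up adjustment across
all tested terms, enriched at adjusted p < 0.05. Enrichment is computed
on literal annotation sets: no GO-graph propagation (a gene annotated to
a child term does not implicitly carry its ancestors), and no
minimum-annotation filter; both choices keep the test a pure function of
the annotation table handed in. The descriptive category summary
truncates percentages toward zero at two decimals using integer
arithmetic (`(10000·count // total)/100`), which is the convention that
consistently reproduces published category tables of this style; it is
applied uniformly rather than per-case rounding.

## Pathway Z-score

Per-EC fold change is the unweighted mean of its coding genes' log2
fold changes (same pseudo-count policy as the DEG stage). A pathway is
retained when at least five of its ECs carry a fold change — "mapped"
means fold-change-bearing, so an EC whose coding genes are all absent
from the expression table does not count toward retention. The
resampling pool is the set of **distinct** ECs over all retained
pathways: an enzyme shared by several pathways enters the null once, so
the null is not weighted by pathway multiplicity. Sets are drawn without
replacement within a set and independently across sets; the default 100
sets matches the conventional choice, and an exhaustive mode enumerates
all C(pool, k) subsets for small pools (used by the oracle tests). The
reported p is normal-theory from Z — 100 draws cannot resolve empirical
p below ~0.02 — with the empirical rank p emitted alongside. A
numerically degenerate null (all subset means equal within ~1e-12
relative) returns Z = 0, p = 1 when the observed mean coincides with the
null mean, and is an error otherwise.

## Metabolite chain

Median normalization divides each sample row by its median intensity
(the row-normalization convention of web metabolomics portals);
subtraction was rejected because it can produce non-positive values that
the subsequent log10 step cannot accept. Pareto scaling divides centred
columns by the square root of the standard deviation, so scaled columns
have mean 0 and variance equal to the pre-scaling sd; constant columns
(sd = 0 to ~100 eps relative) are zeroed with a warning. The volcano
fold-change threshold is not dictated by the modelled workflow and
defaults to 2 (configurable); the t-test is unpaired, equal-variance,
two-sided, computed on the scaled values, while fold changes come from
raw group means so they remain interpretable as intensity ratios.

## qPCR

Relative expression is 2^−ΔΔCt with amplification efficiency fixed at 2
(ideal doubling; no efficiency estimates are modelled). Concordance
correlates log2 RNA-seq fold change against log2 relative expression —
both are log-scale effect measures, making Pearson's r scale-appropriate.

## Synthetic data

The generator emulates the modelled study at desk scale, and its
defaults are the pinned test conditions:

- **Counts** (`gen_counts`): 2,000 genes, 5×10^5 reads per library,
  log-normal baseline abundances (σ = 1.5, long-tailed so both deep and
  shallow genes occur), negative-binomial counts with dispersion 0.05
  (modest biological variability; 0 gives Poisson for calibration runs).
  5% of genes get their mean multiplied by 2^±3 in both OE libraries,
  same sign in both — the two-line "replica" design. Gene lengths are
  uniform on 200–5,386 bp, the contig-length range of the assembly style
  being modelled. Library sizes of 10^5–10^6 keep per-gene counts in the
  regime where the proportion test has power at 8-fold shifts.
- **Annotations** (`gen_annotations`): 20 GO terms assigned at ~2 per
  gene background; one term additionally attached to true DE genes with
  probability 0.9 (the planted enrichment). Six pathways × 6 ECs, each
  EC carried by one gene; the first pathway's ECs map onto up-regulated
  truth genes, giving it a coordinated positive shift, while the other
  pathways draw from null genes.
- **Metabolites** (`gen_metabolites`): 125 metabolites, 6 samples per
  group, log-normal intensities (log10 noise sd 0.15); two metabolites
  shifted by ±0.6 log10 units between groups (one up, one down in OE).
- **qPCR** (`gen_qpcr`): 17-gene panel (truth genes first, padded with
  nulls), constant-Ct reference gene, OE Ct = WT Ct − true log2 FC, so
  zero-noise ΔΔCt recovers the planted fold change exactly.

What the generator does **not** emulate: mapping ambiguity and
multi-mapping read loss, GC/length biases beyond the RPKM length term,
correlated gene expression, annotation incompleteness or bias, batch
effects, metabolite missingness and censoring at the detection limit,
and qPCR efficiency differences. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under its own
assumptions, not that those assumptions hold for any particular real
dataset.

## Problem sizes and numerical choices

Test and acceptance runs use 2,000-gene × 3-library simulations, 20
seeds for null-rate estimates (≈80,000 gene-level null tests), 2,000
null pathways over a 40-EC pool, and 20 × 125 null metabolites; these
sizes put Monte-Carlo error comfortably inside the asserted bands while
keeping a full run in seconds. Oracle checks are exact: the
hypergeometric tail is compared with pmf enumeration for every valid
configuration with M ≤ 25, and the pathway Z with the exhaustive
C(8,5) = 56-subset null. Ties, zero counts, zero variance and degenerate
resampling pools are all handled by the explicit rules above rather than
by silent NaN propagation.

## Known limitations

- The proportion test inherits the replicate-free design's
  anti-conservativeness under overdispersion; calibration holds under
  Poisson noise and degrades as dispersion grows. This is a property of
  the method being implemented, surfaced (not hidden) by the generator's
  negative-binomial default.
- GO enrichment without graph propagation understates enrichment of
  ancestor terms when annotations are leaf-heavy.
- The pathway null treats enzymes as exchangeable; co-regulation within
  pathways makes the null narrower than biology would produce.
- Published headline numbers from the motivating study design (total DEG
  counts, specific pathway Z-scores, platform correlations) depend on
  the original raw data, assembler and database snapshots and are not
  targets of this package; the pipeline reproduces the *procedures* and
  validates them on synthetic truth.
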