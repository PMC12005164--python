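# Methods

## The measurement problem

Maize endosperm is triploid: two genome copies come from the maternal
parent and one from the paternal parent. When reads from reciprocal
crosses (A×B and B×A) are aligned to the concatenated parental genome
assemblies, each gene model yields two *gene-allele* rows — one per
parental genome — and each allele is observed once as maternally and once
as paternally inherited. A gene whose alleles are expressed in proportion
to genome dosage therefore contributes 2/3 of its transcripts from the
maternal side; genomic imprinting shows up as a departure from that 2:1
expectation, not from 1:1.

`imprintseq` quantifies this with the **reciprocal expression ratio**

    RER = maternal RPM / (maternal RPM + paternal RPM),

computed per gene allele and time point from replicate-mean RPM in each
cross direction. RER is 2/3 under dosage-proportional biparental
expression, 1 for exclusively maternal expression, and 0 for exclusively
paternal expression.

### RER conventions

* RER is computed from replicate-**mean** RPM per direction, not averaged
  per-replicate ratios. Means are the natural group-level summary of the
  normalized count table and are stable when a single replicate has few
  reads.
* RER is undefined (NaN) when both direction means are zero; such alleles
  are gated to `not_expressed` by the expression floor before the ratio is
  consulted.
* The per-time-point expression summary used for all filters is the mean
  of the two direction means, `(maternal RPM + paternal RPM) / 2`, so it
  is invariant under exchanging the parents.

## Significance: the fold-change-threshold NB test

Calling a gene imprinted requires *significantly more than* a 2-fold
maternal/paternal difference, so that the 2:1 dosage itself is inside the
null. Per gene allele and time point, the maternal group (samples in which
the allele's genome is the mother) is tested against the paternal group
(the reciprocal direction) under a negative-binomial model:

* counts are scaled by total-count size factors (library total / 10^6,
  the same convention as RPM);
* per-gene dispersion is estimated by the method of moments,
  `alpha = (var - mean) / mean^2` pooled across the two groups, then
  shrunk toward a fitted `a0/mu + a1` mean–dispersion trend with a prior
  weight of 6 degrees of freedom (raw estimates at 3+3 replicates are far
  too noisy to use alone), floored at 1e-8;
* the composite null H0: |log2FC| <= 1 is tested by two one-sided Wald
  tests at +1 and −1, with p = min(1, 2·min(p+, p−)); significance
  requires both the BH-adjusted p below alpha and a point estimate
  exceeding the threshold;
* a group whose mean is exactly zero is given a half-read pseudo-level so
  the estimate and its standard error stay finite (all-zero genes are
  flagged untestable, get p = 1, and are excluded from the BH
  denominator);
* BH adjustment is performed separately per time point, across all
  testable gene alleles of both genomes.

This is a re-implementation of the *contract* of the DESeq2
`lfcThreshold = 1, altHypothesis = "greaterAbs"` call — NB Wald test with
a fold-change-threshold composite null and BH FDR — not of DESeq2's
internals (no empirical-Bayes dispersion posterior, no apeglm shrinkage,
no Cook's outlier handling, no independent filtering). The test suite
checks calibration properties directly (type-I error at and inside the
null boundary, power monotonicity, label-swap antisymmetry) and checks
qualitative agreement with pyDESeq2 on clear effects.

## Status ladder and thresholds

Per gene allele and time point (defaults in `ImprintThresholds`):

| status | rule |
|---|---|
| `not_expressed` | mean RPM < 1 |
| `MEG` | RER >= 0.9 and padj < 0.05 |
| `PEG` | RER <= 0.3 and padj < 0.05 |
| `maternal_bias` | RER > 0.8 (no significance gate) |
| `paternal_bias` | RER < 0.4 |
| `biparental` | otherwise |

Imprinting cutoffs are closed (>= / <=), bias cutoffs strict (> / <);
boundary values are rare and the convention is fixed here. The
significance-free bias statuses deliberately capture parent-of-origin
preference that the stringent imprinting call misses at modest depth.

## Temporal-consistency groups

Gene alleles imprinted at >= 1 time point are classified after a global
filter requiring mean RPM >= 1 across time points
(`filtered_low_expression` otherwise). Rules apply hierarchically — first
match wins — which makes the groups disjoint:

1. **Group 1**: expressed (>= 1 RPM) and imprinted in the same direction
   at every time point.
2. **Group 2**: imprinted in the same direction at every time point at
   which it is expressed (vacuously including hypothetical profiles with
   no expressed time point; in practice the status ladder makes an
   imprinted call imply expression).
3. **Group 3**: parentally biased in the imprint's direction at *every*
   non-imprinted time point. The strict-every reading was adopted (rather
   than "most"); it is what makes Group 3 a statement about consistent
   bias, and it is exposed through the rule functions should a laxer
   variant be needed.
4. **Group 4**: >= 5 RPM at every time point and at least one time point
   that is neither imprinted nor same-direction biased — genes gaining or
   losing imprinting while clearly expressed.
5. `unassigned` otherwise.

A profile imprinted in both directions at different time points ("mixed";
never produced by the generator and not expected in data) skips Groups
1–3 and is evaluated for Group 4 with bias-in-either-direction as the
bias notion. Both classifiers (`call_status`, `assign_group`) are verified
against independently coded brute-force rule tables over the full
enumeration of status vectors and RPM regimes.

The bias-consistency summary cross-tabulates, for MEGs and PEGs
separately, single- versus multi-time-point imprinting against the number
of time points at which the RER meets the lenient bias threshold.

## Cross-genotype conservation

A panel of reciprocal crosses between the reference line (B73) and several
alternate genotypes, profiled at one time point (14 DAP), is reduced to a
per-(gene, genotype) table: imprinting is called on the alternate-genome
allele rows and joined to reference gene ids through **single-copy
syntelogs** (pan-gene groups with exactly one member in both genomes);
alleles without an informative syntelog are excluded. A syntelog counts as
expressed when its combined (maternal + paternal) direction-mean RPM is at
least 1 — the grouping filter's floor reused for coherence, since no
separate value is dictated by the problem.

**Percent same imprint** for a gene with reference direction MEG (PEG) is
the number of genotypes whose RER exceeds 0.8 (falls below 0.4) divided by
the number of genotypes with an expressed syntelog. Conservation is
deliberately assessed on the lenient *bias* thresholds rather than
significance-gated calls, so the panel's shallower sequencing does not
masquerade as lost imprinting. The reference direction for each gene comes
from the reference time-series call, not from a panel consensus.
Group-level summaries drop genes expressed in fewer than 4 genotypes. The
paternal-bias threshold is configurable (0.4 by default; a 0.3 variant
used in some per-genotype tallies is reachable through
`ImprintThresholds`).

## Developmental clustering

Per-direction, per-time-point replicate-mean RPM trajectories are
max-normalized (each gene divided by its own maximum; all-zero genes
dropped; ties at the maximum all receive 1.0 with the earliest peak
reported) and clustered with k-means, k = 9 by default. The backend is
scikit-learn's Lloyd algorithm with k-means++ initialization and 25
restarts at a fixed seed: determinism and restart-minimum selection are
what matter here, not parity with any particular k-means variant. Labels
are canonicalized by centroid peak time and then by decreasing peak
sharpness, so they are stable under gene-order permutation. Cluster
assignments fitted on one direction are transferred by gene identity to
the reciprocal direction, supporting the consistency check that
reciprocal per-cluster mean trajectories track the fitted centroids.
No RPM floor is applied before clustering beyond dropping all-zero genes.

## Tissue preference

From a 10-tissue expression atlas, a gene is endosperm preferred when
strictly more than 65% of its summed RPM across tissue replicates comes
from the endosperm columns (RPM-summed, not raw-read-summed, matching the
atlas's normalization), multitissue otherwise, and not-expressed with an
all-zero row. The mutant-vs-wild-type DE comparison is an *input* list
(DE gene ids plus a detection universe); the package cross-tabulates it
against groups and tissue classes but does not recompute the published
comparison. Genes outside the universe form the "not detected" bin.

## The synthetic-data generator

The generator emulates the study design — 2 reciprocal directions × 4
time points (11/14/17/21 DAP) × 3 replicates, ~5 million reads per
library — with negative-binomial gene totals split binomially between the
two allele rows at the gene's maternal transcript fraction. Defaults
(3,000 genes):

| class | n | maternal fraction | expression |
|---|---|---|---|
| MEG_constitutive | 400 | 0.97 at all time points | lognormal, median 50 RPM |
| PEG_constitutive | 100 | 0.03 at all time points | median 50 RPM |
| MEG/PEG_transient | 100 + 100 | 0.97/0.03 at a random proper subset of time points, 2/3 elsewhere | median 100 RPM (clearly expressed, so the variable-imprinting group is recoverable) |
| maternal_bias | 200 | 0.97 at one time point, 0.86 at the rest | median 50 RPM |
| paternal_bias | 200 | 0.03 at one time point, 0.30 at the rest | median 50 RPM |
| biparental | 1,850 | 2/3 | median 250 RPM, sigma 1.0; a 7% low-expression submix straddles the 1–5 RPM filters |
| zein_like | 10 | 2/3 | 10,000–50,000 RPM peaking at 17 DAP |
| silent | 40 | — | 0 |

Design notes:

* The bias-class fractions (0.86, 0.30) sit mid-window between the
  imprinting and bias cutoffs: a design-time power calculation at
  dispersion 0.05 and 3 replicates shows the RER standard error
  (~0.02–0.04) would push a fraction nearer the window edges across a
  threshold at an appreciable per-time-point rate.
* The NB dispersion default is 0.05, a typical bulk-RNA-seq value for
  controlled biological replicates; no empirical dispersions are
  available to match.
* Library sizes are lognormal with CV 0.15 around 5 million reads.
  Because only ~3,000 genes stand in for a full transcriptome, per-gene
  RPM levels are set high enough that nominal RPM sums to roughly one
  million; realized RPM is still mildly inflated at early time points
  when the zein-like ramp has not yet claimed its share of the library —
  the same compositional effect the storage-protein genes exert on real
  endosperm libraries.
* Presence/absence variation: each gene is present in a non-reference
  genotype with probability 0.9; reads from an absent allele are
  discarded. Per-class conservation rates (0.85 constitutive, 0.6 bias,
  0.3 transient) decide whether an alternate genotype retains the class's
  parental bias or reverts to 2/3 — this plants the stepwise
  group-conservation gradient. The reference pair always carries the
  class behavior.
* The tissue atlas gives endosperm-preferred genes a 0.70–0.95 endosperm
  share and multitissue genes 0.05–0.55, so at zero noise the classifier
  is exact by construction; multiplicative lognormal noise is available.
* All randomness flows from a single mandatory seed through
  `numpy.random.default_rng`; identical seeds reproduce identical count
  matrices.

What the generator does **not** emulate: read-level artifacts (mapping
and reference bias between parental assemblies, positional coverage),
genes silent at a subset of time points (so the default experiment
populates Group 2 only through noise; the Group 2 rule is exercised by
constructed profiles and the exhaustive rule-table enumeration),
cis-regulatory correlation structure between genes, and batch effects.
Passing recovery tests on this generator therefore demonstrates that the
statistical machinery and the classification rules behave as specified
under the declared noise model — not that real libraries meet that model.

## Problem sizes and determinism

The default synthetic experiment is ~3,000 genes (6,000 gene-allele
rows) × 24 libraries; the full pipeline including an 8-genotype panel
completes in well under a minute on one CPU, and the calibration checks
use 4,000–5,000 simulated genes. These sizes were chosen so that recovery
rates have small Monte-Carlo error while the whole analysis remains
desk-scale. Every stochastic step (simulation, k-means restarts) is
seeded; a pipeline re-run with the same seed writes a byte-identical
report.

## Known limitations

* Dispersion shrinkage is a fixed-prior method-of-moments scheme, not
  DESeq2's empirical-Bayes posterior; at 3+3 replicates the test leans on
  the trend fit, which assumes dispersions are exchangeable across genes
  of similar expression.
* The Wald normal approximation is optimistic for alleles with very few
  reads; such alleles rarely pass the RER and expression gates, but their
  p-values should not be over-interpreted.
* Group assignment consumes hard status calls; a gene hovering at a
  threshold can change group between seeds. The rationale string records
  which rule fired.
* `percent_same_imprint` treats genotypes symmetrically and ignores
  panel sequencing depth differences beyond the expression gate.
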