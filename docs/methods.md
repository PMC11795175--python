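# Methods

## Overview

`sigoverlap` asks, for a collection of disease-model differential-expression
(DEG) signatures, how strongly each resembles three reference expression
signatures — hippocampal maturation, brain pH, and neural hyperexcitation —
and whether those resemblances co-vary across models. The analysis has five
stages: DEG calling, rank-based overlap testing, signed index construction,
cross-dataset correlation, and pathway enrichment meta-analysis. A synthetic
generator supplies all inputs with known ground truth.

## Signatures and symbol space

A signature is a set of genes with signed, nonzero, finite scores, ranked by
absolute score descending; ties in |score| are ordered lexicographically by
symbol, and the scan below only evaluates cutoffs at tie-group boundaries,
so the lexicographic order can never change a p-value. Duplicate symbols are
merged deterministically by keeping the largest |score| (first occurrence on
an exact tie), which favors the strongest signal and makes parsing stable
under row duplication.

Symbols are compared case-insensitively, and upper-casing is the default
cross-species bridge (mouse `Fos` vs human `FOS` vs rat symbols). This
symbol-identity proxy is deliberate: the comparisons mix mouse DEG lists
with a human-derived pH gene list and a rat-derived seizure list, and for
well-annotated genes symbol identity recovers most one-to-one orthologs. An
explicit two-column ortholog table can be supplied where that proxy is not
acceptable; unmapped genes are dropped with logged counts.

The hypergeometric background ("universe") is an explicit, logged choice:
the intersection (default) or union of the assayed gene lists. The
intersection is conservative — every gene in the denominator was measurable
in every dataset — and is what the pipeline uses; references are restricted
to the universe before testing.

## DEG calling

A gene is differentially expressed when |fold change| > 1.2 and two-sided
t-test p < 0.05, both strict, uncorrected. The t-test is Welch's
(unequal-variance, Welch–Satterthwaite df): a robust default given that
platform conventions for such lists vary between plain, pooled and moderated
t statistics. When both groups have zero variance no evidence is computable
and p is set to 1 with a warning. Fold changes are case over control;
linear-scale matrices use the ratio of group means, log2-scale matrices the
difference. No normalization, batch correction, or moderated statistics are
applied — inputs are assumed preprocessed.

At the generator's default design (3 vs 3 samples, planted |log2FC| = 1.0,
residual sd = 0.25) the realized per-gene power of this criterion is ~0.88:
the noncentral-t power at 4 df would be ~0.95, but Welch's estimated df
drops below 4 whenever the sample variances diverge by chance. The recovery
property tests assert at this realized level (≥ 85% recovered, ≤ 7%
unplanted genes called).

## The running Fisher overlap test

For query signature Q (ranked) and reference set R in universe size N, the
scan computes at every tie-group boundary k the hypergeometric upper tail
P(X ≥ x_k) with X ~ HG(N, |R|, k) and x_k the observed overlap in the top
k; p_raw = min_k p_k, corrected by the number of evaluated cutoffs
(Bonferroni), with k_best the smallest attaining cutoff. Degenerate inputs
(empty query or reference) return p = 1. This concrete formulation —
minimum over an exhaustive rank scan with cutoff-count correction — was
chosen as the simplest reproducible and oracle-checkable reading of
rank-based overlap testing; commercial implementations of the idea are
proprietary and differ in unknown details (see Limitations).

A full comparison runs five scans: the four directional pairs (query-up vs
reference-up, down/down, up/down, down/up; the query side is scanned, the
reference side is a fixed set) and one unsigned scan of the full query
ranking against the full reference set, which supplies the overall overlap
p-value. The overall p is deliberately *not* a combination of the four
directional p-values: no standard combination reproduces how published
overall overlap p-values relate to their directional components, so the
unsigned scan is used and documented as this package's definition.

Concordant evidence is −log10 p(up-up) − log10 p(down-down); discordant
likewise for the opposite pairs; the dominant direction is positive
(concordant) on ties, with a logged warning. The four directional overlap
gene sets are pairwise disjoint and partition the query∩reference
intersection exactly, because every signature entry has nonzero direction.

### Numerics

All tails are computed in log space from a cached gammaln table. Above the
distribution mode the upper tail is summed directly with log-sum-exp,
preserving relative accuracy for arbitrarily small p (a self-comparison of
an 800-gene signature in a 5000-gene universe has log10 p < −700, far below
linear float range); at or below the mode, where p is bounded away from 0,
the complement of the lower tail is used. Linear-scale p fields are floored
at the smallest subnormal float after underflow; the log10 fields are
authoritative and are what the index transform consumes.

## Similarity indices and correlations

The similarity index is −log10(overall p), signed by the dominant direction
(+ concordant, − discordant); p = 1 maps to exactly 0. The sign convention
makes "immature", "acidified", and "hyperexcited" datasets plot on opposite
sides of zero from mature/alkaline/quiescent ones. Negating every reference
score flips the index exactly (the directional scans swap pairwise) and
leaves the overall p unchanged.

Before any index is computed the three reference signatures are made
pairwise disjoint: every gene present in two or more of them is removed
from all, so cross-index correlations cannot be driven by shared member
genes. The operation is idempotent and errors out rather than empty a
signature.

Indices are assembled into one row per dataset; rows with a failed
comparison are flagged incomplete and excluded listwise from each pairwise
correlation. Correlations are Pearson r with the two-sided p from the
t transform on n−2 df plus the OLS line (for plotting); Spearman is
available as an option. At least 3 complete rows are required and zero
variance in either index is an error.

## Pathway enrichment meta-analysis

Per dataset and reference, the direction-agnostic intersection of the DEG
signature with the reference is tested against a GMT collection with the
same hypergeometric upper tail, as a fixed-set test — once intersected, the
overlap genes carry no meaningful internal ranking, so a rank scan would be
spurious. Terms are intersected with the universe first (term_size is
post-intersection); no multiple-testing correction is applied because the
output is a ranking. Per term, evidence is combined across datasets as
meta_score = Σ −log10 p (rank-equivalent to Fisher's combined statistic,
transparent and exactly additive over any partition of the datasets); the
table is sorted by meta_score with lexicographic tie-breaks and truncated
to the top 15 by default.

## Synthetic data

The generator emulates the study conditions end to end:

- **Universe**: 5000 genes (`G00001`…) by default.
- **References**: maturity 800 genes and hyperexcitation 1200 genes with
  log-normal |log2FC| magnitudes (median ≈ 0.6) and random signs; pH with
  exactly 39 up- and 268 down-regulated genes, signed S-value-like scores.
  The hyperexcitation default is a scaled-down stand-in for a ~7000-gene
  seizure signature and is configurable up to that scale; 1200 keeps the
  full suite fast at one CPU. With `disjoint_references` (default) the
  three gene sets are disjoint by construction.
- **Datasets**: per-gene control means ~ Normal(7, 1.5) on the log2 scale;
  for each reference, ⌊rho_concordant·size⌋ genes are shifted in the
  direction of their reference score and ⌊rho_discordant·size⌋ opposite,
  by effect_log2fc (default 1.0) jittered uniformly ±10% per gene;
  off-reference background DEGs at fraction 0.02 with random directions;
  per-sample Gaussian log2 noise (sd 0.25) over 3 control + 3 case samples.
  Floors make planted counts exactly assertable. Every planted gene and its
  intended direction is recorded in a truth record.
- **Cohorts**: 20 datasets over a severity grid s ∈ [0.1, 0.95]; the
  default trend sets maturity- and pH-discordance and hyperexcitation-
  concordance all to 0.05 + 0.45·s (with a small 0.03 opposite-direction
  baseline), so the three indices co-vary by construction — this trend is
  the mechanism that reproduces the expected sign pattern (maturity~pH
  r > 0, both hyperexcitation pairs r < 0) and is a modeling choice, not an
  empirical claim. Planting uses one fixed permutation per reference, so
  planted sets are nested across datasets; the GMT's planted term is drawn
  from the genes every dataset plants against maturity, and its top rank in
  the meta-analysis is therefore a recovery check, not an accident. A
  `null` trend plants nothing and yields calibrated, non-significant
  correlations.

Everything is reproducible byte-for-byte from the single config seed.

What the generator does *not* emulate: platform/probe structure, missing
values, heteroskedastic or count-based noise, correlated genes, batch
effects, or per-study sample sizes. Passing tests therefore demonstrate the
statistics behave correctly under a clean expression model, not that real
heterogeneous microarray/RNA-seq collections would yield identical numbers.

With noise_sd = 0 replicates are identical and a t-test is uninformative by
design; the deterministic limit is exercised through `truth_signature`,
which applies only the fold-change filter and recovers the planted genes
exactly.

## Pipeline and reproducibility

`run_all` executes simulate/load → DEG call → harmonize → disjointify →
universe → overlaps → index table → correlations → meta-enrichment, writing
TSV/JSON outputs plus a manifest (config echo, package version, seed) and a
log under the chosen output directory. Outputs are written to the directory
the caller names (no timestamps) precisely so that reruns with the same
config and seed are byte-identical; the manifest suffices to reproduce a
run. Per-dataset failures flag the affected row and are listed in the
manifest rather than aborting the run.

## Test problem sizes

The suite validates the hypergeometric tail against exact integer
enumeration on full (K, n, x) grids at N ∈ {7, 18, 33, 47, 60}, the full
comparison against a literal all-cutoff brute-force scan on 200 random
instances with universes up to 60 genes, null calibration on 200 replicates
at universe 2000, and recovery/sign-pattern checks at the generator's
default scale (universe 5000, 20-dataset cohort). These sizes were chosen
to keep the whole suite around a minute or two on one CPU while leaving the
statistics' behavior fully exercised.

## Known limitations

- The exact scoring of proprietary rank-based overlap platforms (their scan
  correction, overall-p aggregation, and meta-analysis weighting) is not
  public; this package defines each choice explicitly (cutoff-count
  Bonferroni, unsigned overall scan, Σ −log10 p meta-score) and should not
  be expected to reproduce such platforms' numbers on real data.
- Symbol-identity harmonization mishandles genes whose orthology is not
  one-to-one; supply an ortholog map for rigorous cross-species work.
- The DEG criterion uses raw p-values by design; DEG lists are inputs to a
  rank statistic, not inferential endpoints.
- Moderated/limma-style tests are not implemented; datasets derived with
  them will differ from this package's Welch-based calls.
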