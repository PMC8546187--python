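# Methods

## Scope and data model

The package integrates three evidence layers around a phenotype contrast
(the bundled example: high vs. low milk-protein percentage in Holstein
cows, sampled in lactation, HP/LP, and in the dry period, HD/LD):

1. per-contrast differential-expression (DE) tables for miRNAs, as emitted
   by an upstream count-model tool (the negative-binomial fit itself is out
   of scope — its output table is the interface);
2. sample-matched miRNA and gene expression matrices plus a predicted
   miRNA→target table (score / hybridization energy);
3. single-trait GWAS summary statistics (per-SNP effect estimates β) and
   genomic annotations of miRNA precursors and genes.

All interval coordinates are handled internally as **1-based inclusive**
(GFF3-native); BED input/output is converted at the file boundary. Strand
is read and carried but ignored by window arithmetic — every flank used by
the pipeline is symmetric, so strand-aware windows would change nothing.

## DE sets

A record is DE iff |log₂FC| > 0.8 **and** p < 0.05, both strict — the
thresholds are printed as strict inequalities wherever this decision rule
is used, and the bundled published network table contains rows whose
adjusted p-value is missing or above 0.05, which confirms that the decision
is made on the raw p-value and fold change only. `padj` is therefore
carried as payload, never consulted. Direction is the sign of log₂FC; the
reference group of the contrast is the caller's bookkeeping, and the
package never flips published signs.

Set comparison between two contrasts is plain set algebra with the
inclusion–exclusion identity asserted in tests. On the bundled example
lists it reproduces 28 DE miRNAs (11 up / 17 down), 52 (22 up / 30 down),
14 common and a union of 66.

### Pattern clustering

DE miRNA expression patterns (rows = miRNAs, columns = group means) are
mean-normalized per row and clustered by k-means (Lloyd, Euclidean,
25 random restarts, fixed seed). The number of clusters is chosen by the
gap statistic against a uniform reference over the data's bounding box
(50 reference draws) with the one-standard-error rule: the smallest k with
gap(k) ≥ gap(k+1) − s(k+1). Restart count and reference count are
package choices; they trade runtime for stability and are exposed as
arguments. A degenerate input (all rows carrying the same pattern) returns
k = 1 without invoking the reference machinery.

## Target filtering and the network

Predictions are kept at score ≥ 50 and energy ≤ −20 kcal/mol — inclusive,
matching the conventions of the predictor's own documentation. Multiple
predicted sites on one (miRNA, gene) pair are collapsed to the best-score
site before correlation, since pairs are counted at the (miRNA, gene)
level.

Correlation uses all matched samples (n = 12 in the bundled design: two
groups × two stages × three animals). Pearson r is computed by the
product-moment formula and the two-sided p-value from
t = r·√((n−2)/(1−r²)) on n−2 df. A constant expression vector has no
defined correlation; the pair is excluded with a logged warning rather
than crashing. A pair survives iff r < 0 and p < 0.05 — raw p-values by
default, matching the stated screening rule; a Benjamini–Hochberg mode
exists behind `adjust="bh"` but is off by default. Network edges keep the
pairs whose miRNA and gene are both DE.

At n = 12 the two-sided 5% critical value is |r| ≈ 0.576, so planted pairs
with population r = −0.9 are recovered with ≈ 93% sensitivity (measured,
20 seeds × 50 pairs), and independent pairs pass at ≈ 2.5% (the negative
half of a 5% two-sided test).

## GWAS-signal enrichment

Candidate windows are the features extended by a symmetric flank
(defaults: ±50 kb for precursors — precursors are short, so proximal
regulatory SNPs are captured by the flank — and ±5 kb for target genes),
clipped at position 1, and **merged** within a feature set so no SNP is
counted twice in one statistic. The background index ranks the SNPs inside
the merged background windows 1…M in genomic order. Candidate SNPs must be
a subset of the background (checked; violations raise). An exclusion
region with margin (default ±1 Mb, sized for a major-effect gene like
*DGAT1*) is removed from the SNP table before indexing.

The statistic is T_sum = Σβ² over candidate SNPs. The permutation null
circularly shifts candidate ranks by uniform R ∈ 1…M; the empirical
p-value is (N_over + 1)/(n_perm + 1) with N_over counted under a strict
`>` (a `≥` tie mode exists and is more conservative). Numerical choices:

* The printed constant 10,001 in the source formula is the
  n_perm = 10,000 case of the general n_perm + 1 denominator.
* R = M (the identity shift) is allowed by the shift formula and kept by
  default — the +1 in the p-value keeps it valid; a no-identity option
  samples R ∈ 1…M−1.
* An exhaustive mode enumerates all M shifts, giving the exact permutation
  distribution; it matches an independent loop-based oracle exactly in
  tests (ties at the identity shift are resolved with correctly rounded
  sums on the oracle side).
* A candidate set with no SNPs yields an explicit "no testable SNPs" row
  (m = 0, NaN statistics) rather than T_sum = 0, and is excluded from the
  FDR family.
* Scaling every candidate |β| with the rest of the background fixed can
  only lower the p-value (asserted in tests).

The random stream is keyed on (seed, feature-set id), so results are
invariant to evaluation order. FDR is Benjamini–Hochberg across whatever
family one `run_enrichment` call produces — per trait by default, matching
the column structure of multi-trait result tables; other families are a
matter of how calls are batched. A second null, `random_set`, draws
same-size SNP sets from the background without preserving spacing; it
mirrors the random-gene-set procedure used for target windows and agrees
with the circular shift on exchangeable synthetic data.

## Synthetic data

The generator's defaults are the study conditions the pipeline is
validated under, not tuning knobs:

* **Annotation** — precursors 60–120 bp, genes 1–100 kb, placed without
  overlap by distributing the free space of each chromosome as random gaps;
  infeasible placements raise.
* **GWAS effects** — β ~ N(0, σ₀²) with σ₀ = 0.01, inflated to
  N(0, λσ₀²) inside the flanked windows of designated features
  (membership uses exactly the enrichment module's window rule). A
  zero-mean normal is the conventional shape for polygenic marker-effect
  estimates; no distribution is dictated by the method itself, which only
  squares and sums.
* **Expression** — miRNA columns are log-normal (TPM-like skew); planted
  pairs are built as gene = a − miRNA + noise, *linear in the delivered
  values*, with the noise variance set from the analytic log-normal
  variance so the population correlation equals `pair_r` exactly (and
  sample r = −1 exactly when pair_r = −1). Planted gene columns
  consequently live on a normalized scale that may go negative, like
  variance-stabilized RNA-seq expression. 12 samples by default.
* **DE tables** — exact planted counts of up/down/null records; null
  records fail the fold-change criterion, the p criterion, or both, in
  rotation; `padj` is a plausible inflation of p with ~10% missing values.

One seed drives everything through fixed per-operation sub-streams
(`SeedSequence([seed, op])`), so identical configs give byte-identical
files and adding an operation never perturbs another's output.

What the generator deliberately does **not** emulate: linkage
disequilibrium between SNPs (effects are independent marginal estimates,
so the circular-shift null is *exactly* exchangeable — cleaner than real
GWAS data, where LD makes the shift's spacing preservation matter);
count-level sequencing noise; library-size or GC artifacts; correlated
co-expression modules beyond the planted pairs. Passing tests therefore
demonstrate correctness of the machinery and calibration under
exchangeability, not robustness to LD or normalization artifacts.

## Validation experiments and problem sizes

`mirgwas.experiments` holds the standing experiments; the test suite and
`scripts/acceptance.py` both run them at these sizes:

* **Null calibration** — 500 single-precursor candidate sets over five
  50-Mb chromosomes, ~60 SNPs per ±50 kb window, 200 permutations each.
  The rejection rate at α = 0.05 must sit in the binomial 95% band
  [0.032, 0.070] around the attainable level 10/201 ≈ 0.0498, and the
  p-value CDF must be super-uniform up to three binomial standard errors.
* **Planted recovery** — per seed, 100 precursors on one 50-Mb chromosome,
  5 with λ = 3; a planted feature counts as recovered when its min-rank
  p-value is in the top decile. Pooled over 20 seeds the recovered
  fraction must be ≥ 0.8 (measured: 1.0 — with ~60 SNPs, a 3× variance
  excess is far outside the null spread √(2m)·σ₀²).
* **Correlation screen** — 20 seeds × 50 planted r = −0.9 pairs at n = 12;
  sensitivity ≥ 0.9, and zero pass-throughs once the gene axis is flipped
  to make every planted correlation positive.

## Design choices where the design was open

* DE direction is stored by sign of log₂FC only; the package never
  re-labels published tables against a reference group.
* Correlation is computed over all matched samples; stage-specific
  correlation (n = 6) is possible by subsetting the matrices, not by a
  special mode.
* The FDR family is whatever one call tests; batching by trait is the
  default usage.
* The bundled published network table lists 25 distinct target-gene names
  while the accompanying prose counts 24 differentially expressed genes;
  the package reports counts from its own edge lists and documents the
  discrepancy rather than forcing agreement. Similarly, published
  known/novel miRNA inventories are inputs here, and discrepancies between
  summary counts in different parts of a source document are not
  adjudicated.

## Known limitations

* No LD-aware null: on real summary statistics the circular shift
  preserves local ordering but not LD blocks, so p-values can be
  anti-conservative when candidate windows have atypical LD.
* The gap statistic with a bounding-box uniform reference can over-split
  elongated clusters; 25 restarts keep k-means stable but do not guarantee
  a global optimum.
* The expression simulator plants only pairwise structure; realistic
  co-expression networks would inflate the apparent false-positive rate of
  the correlation screen on real data.
* The pipeline assumes SNP positions and feature annotations share one
  genome build; nothing lifts coordinates over.
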