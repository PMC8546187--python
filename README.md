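# mirgwas

Tools for asking whether the miRNAs that respond to a phenotype also sit on
the trait's genetic signal. The package integrates three layers of evidence
the way miRNA studies in livestock and other outbred populations do:

1. **DE miRNA sets** — apply the joint differential-expression threshold
   (|log₂ fold change| > 0.8 and p < 0.05) to per-contrast DE tables,
   partition two contrasts into common / unique miRNAs, and cluster
   expression patterns by k-means with gap-statistic model selection.
2. **Inverse-correlation target filtering** — keep predicted miRNA targets
   (score ≥ 50, hybridization energy ≤ −20 kcal/mol) whose expression is
   negatively Pearson-correlated with the miRNA (r < 0, two-sided p < 0.05)
   across sample-matched expression matrices, then select network edges
   where miRNA *and* target are both DE.
3. **GWAS-signal enrichment** — test whether single-trait GWAS effect
   estimates β are inflated inside candidate feature windows (e.g. the
   ±50 kb flanks of DE miRNA precursors, or the ±5 kb flanks of their
   correlated targets) relative to a background feature set.

A synthetic-data generator plants known structure at every stage —
variance-inflated GWAS windows, inversely correlated miRNA–gene pairs over
12 matched samples, DE tables with exact up/down counts — so the whole
pipeline is testable without any external download.

## The enrichment statistic

For the *m* SNPs inside a candidate feature's windows,

```
T_sum = Σᵢ₌₁..m βᵢ²
```

where β is the marker-effect estimate from the GWAS summary statistics.
The null distribution comes from a **circular-shift permutation**: the
background SNPs are ranked 1…M in genomic order, the candidate SNPs occupy
ranks N₁…Nₙ, and for a uniform offset R ∈ 1…M each rank moves to

```
Pᵢ = Nᵢ + R        if Nᵢ + R ≤ M
Pᵢ = Nᵢ + R − M    otherwise,
```

preserving the candidate set's size and internal spacing while sliding it
around the background. With N_over the number of permutations whose
statistic strictly exceeds the observed one,

```
p = (N_over + 1) / (n_perm + 1),
```

and Benjamini–Hochberg FDR is applied across the tested family. An
exclusion region (e.g. ±1 Mb around a major-effect gene such as *DGAT1*)
can be removed from the SNP table before indexing, and a random same-size
SNP-set null is available as an alternative to the circular shift.

## Worked example

Simulate 60 precursor loci on two chromosomes, inflate the effect variance
3× inside the ±20 kb windows of five of them, and test an inflated and a
null candidate set against the full precursor background:

```python
from mirgwas import (SimulationConfig, simulate_annotation,
                     simulate_gwas_summary, run_enrichment)

config = SimulationConfig(
    n_chromosomes=2, chrom_length=5_000_000, n_snps=20_000,
    n_precursors=60, n_genes=0, sigma0=0.01,
    inflation_lambda=3.0,
    enriched_feature_ids=("mir_1", "mir_2", "mir_3", "mir_4", "mir_5"),
    seed=7,
)
precursors, _ = simulate_annotation(config)
snps = simulate_gwas_summary(config, precursors, flank=20_000)

result = run_enrichment(
    snps,
    candidate_sets={
        "inflated": precursors.subset(config.enriched_feature_ids),
        "null": precursors.subset([f"mir_{i}" for i in range(31, 36)]),
    },
    background=precursors,
    flank=20_000, nperm=10_000, seed=7,
)
print(result.to_string(index=False))
```

prints

```
feature_set   m     tsum  n_over   pvalue      fdr
   inflated 389 0.101533       2 0.000300 0.000600
       null 346 0.035401    3837 0.383762 0.383762
```

The inflated windows hold 389 SNPs whose squared effects sum to 0.102 —
only 2 of 10,000 circular shifts exceed that, so p = 3/10,001 ≈ 0.0003 —
while the five uninflated control precursors are indistinguishable from
the background (p ≈ 0.38).

The same thing from the shell, end to end:

```
mirgwas simulate --outdir demo --seed 7
mirgwas all --config demo/config.yaml
```

which writes a synthetic dataset, runs every stage, and reports per-stage
survivor counts (28 DE miRNAs in contrast A with 11 up / 17 down, 52 in
contrast B, the correlated-pair and network censuses, and the enrichment
table) plus a `report.json` with config hash and output checksums.
Re-running the same config reproduces byte-identical tables. `mirgwas de`,
`correlate`, `network` and `enrich` run single stages.

The package also bundles the published DE miRNA lists and milk-protein
regulatory network from a Holstein mammary study as
`mirgwas.datasets` — handy worked examples for the set algebra (28/52
DE miRNAs, 14 common, union 66) and the network census (22 distinct
miRNAs).

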