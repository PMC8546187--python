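"""Synthetic data with planted structure for every pipeline stage.

The generator emulates the data model of a miRNA / mRNA / GWAS integration
study on matched mammary samples:

* genome annotation — miRNA precursor loci (60-120 bp hairpins) and gene
  loci (1-100 kb) placed without overlap on a small set of chromosomes;
* GWAS summary statistics — per-SNP effect estimates beta drawn from a
  zero-mean normal, with the variance inflated by ``inflation_lambda``
  inside the (flanked) windows of designated "enriched" features;
* expression matrices — miRNA TPM values (log-normal marginals) and gene
  expression on a normalized linear scale, sample-matched across the same
  ordered sample list, with ``n_true_pairs`` planted inversely correlated
  miRNA-gene pairs;
* DE tables — per-miRNA log2 fold change and p-value with exact planted
  counts of up/down/null calls.

Effects are marginal estimates with no linkage disequilibrium between
SNPs, so the circular-shift permutation null downstream is exactly
exchangeable. All randomness flows from ``SimulationConfig.seed`` through
fixed per-operation sub-streams, so adding an operation never perturbs the
output of another and identical configs give bit-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import build_windows
from .intervals import FeatureSet, GenomicInterval
from . import io as mio

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_gwas_summary",
    "simulate_expression",
    "simulate_de_table",
    "write_dataset",
]

# fixed sub-stream tags: adding a new operation must append, never reorder
_STREAM_ANNOTATION = 1
_STREAM_GWAS = 2
_STREAM_EXPRESSION = 3
_STREAM_DE = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    ``sigma0`` is the background standard deviation of the marker effect
    estimates; ``inflation_lambda`` multiplies the effect *variance* inside
    the windows of ``enriched_feature_ids`` (1 = null). ``pair_r`` is the
    population Pearson correlation of planted miRNA-gene pairs and must be
    negative. ``n_samples`` defaults to 12, mirroring a two-group x
    two-stage x three-animal design.
    """

    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_snps: int = 5_000
    n_genes: int = 100
    n_precursors: int = 50
    sigma0: float = 0.01
    inflation_lambda: float = 1.0
    enriched_feature_ids: tuple[str, ...] = ()
    n_samples: int = 12
    n_true_pairs: int = 0
    pair_r: float = -0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be > 0")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.inflation_lambda < 1:
            raise ValueError("inflation_lambda must be >= 1")
        if not (-1 <= self.pair_r < 0):
            raise ValueError("pair_r must lie in [-1, 0)")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if min(self.n_genes, self.n_precursors, self.n_true_pairs, self.n_samples) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_true_pairs > min(self.n_precursors, self.n_genes):
            raise ValueError("n_true_pairs exceeds available miRNAs or genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _place_on_chrom(
    rng: np.random.Generator,
    chrom: str,
    chrom_length: int,
    lengths: np.ndarray,
    ids: list[str],
) -> list[GenomicInterval]:
    """Place non-overlapping intervals of given lengths at random positions."""
    total = int(lengths.sum())
    free = chrom_length - total
    if free < 0:
        raise ValueError(
            f"cannot place {len(lengths)} intervals totalling {total} bp "
            f"on {chrom} of length {chrom_length}"
        )
    offsets = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])]) + 1
    return [
        GenomicInterval(chrom=chrom, start=int(s), end=int(s + l - 1), feature_id=fid)
        for s, l, fid in zip(starts, lengths, ids)
    ]


def _simulate_feature_set(
    rng: np.random.Generator,
    config: SimulationConfig,
    n: int,
    min_len: int,
    max_len: int,
    prefix: str,
    name: str,
) -> FeatureSet:
    intervals: list[GenomicInterval] = []
    per_chrom: dict[int, list[int]] = {c: [] for c in range(config.n_chromosomes)}
    for i in range(n):
        per_chrom[i % config.n_chromosomes].append(i)
    for c in range(config.n_chromosomes):
        idx = per_chrom[c]
        if not idx:
            continue
        lengths = rng.integers(min_len, max_len + 1, size=len(idx))
        ids = [f"{prefix}_{i + 1}" for i in idx]
        intervals.extend(
            _place_on_chrom(rng, _chrom_name(c), config.chrom_length, lengths, ids)
        )
    return FeatureSet(intervals, name=name)


def simulate_annotation(config: SimulationConfig) -> tuple[FeatureSet, FeatureSet]:
    """Place miRNA precursor and gene intervals; returns (precursors, genes).

    Precursors are 60-120 bp, genes 1-100 kb, non-overlapping within each
    feature set, 1-based inclusive, within chromosome bounds. Raises if a
    chromosome cannot hold its share of intervals.
    """
    rng = config.rng(_STREAM_ANNOTATION)
    precursors = _simulate_feature_set(
        rng, config, config.n_precursors, 60, 120, "mir", "precursors"
    )
    genes = _simulate_feature_set(
        rng, config, config.n_genes, 1_000, 100_000, "gene", "genes"
    )
    return precursors, genes


def simulate_gwas_summary(
    config: SimulationConfig, features: FeatureSet, flank: int = 0
) -> pd.DataFrame:
    """Simulate per-SNP effect estimates over uniformly placed SNPs.

    beta ~ N(0, sigma0^2) outside enriched features and
    N(0, inflation_lambda * sigma0^2) inside the flanked windows of
    ``config.enriched_feature_ids`` — membership uses exactly the window
    rule of the enrichment stage (symmetric ``flank``, merged, inclusive
    endpoints). Positions are unique and sorted within each chromosome.
    """
    rng = config.rng(_STREAM_GWAS)
    counts = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    counts[: config.n_snps % config.n_chromosomes] += 1
    frames = []
    for c, n_c in enumerate(counts):
        if n_c == 0:
            continue
        pos = np.unique(rng.integers(1, config.chrom_length + 1, size=int(n_c)))
        while len(pos) < n_c:  # top up collisions; loop ends almost immediately
            extra = rng.integers(1, config.chrom_length + 1, size=int(n_c) - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chrom = _chrom_name(c)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": np.sort(pos)}))
    snps = pd.concat(frames, ignore_index=True)
    snps.insert(0, "snp_id", [f"snp_{i + 1}" for i in range(len(snps))])

    sd = np.full(len(snps), config.sigma0)
    if config.enriched_feature_ids and config.inflation_lambda > 1:
        enriched = features.subset(config.enriched_feature_ids)
        windows = build_windows(enriched, flank)
        inside = _in_windows(snps, windows)
        sd[inside] = config.sigma0 * np.sqrt(config.inflation_lambda)
    snps["beta"] = rng.standard_normal(len(snps)) * sd
    return snps


def _in_windows(snps: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Boolean mask of SNPs falling in any window (inclusive endpoints)."""
    mask = np.zeros(len(snps), dtype=bool)
    for chrom, win in windows.groupby("chrom"):
        sel = snps["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        pos = snps.loc[sel, "pos"].to_numpy()
        starts = win["start"].to_numpy()
        ends = win["end"].to_numpy()
        # windows are merged and sorted: searchsorted gives the window left of pos
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
        mask[np.flatnonzero(sel)[hit]] = True
    return mask


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample-matched miRNA and gene expression with planted inverse pairs.

    The first ``n_true_pairs`` (mir_i, gene_i) pairs are constructed as
    ``gene = a - mirna + noise`` with the noise variance set so the
    population Pearson correlation equals ``pair_r`` exactly (noise-free,
    hence sample r = -1, when pair_r = -1). miRNA columns have log-normal
    marginals mimicking TPM skew; unplanted gene columns are independent
    draws on a normalized scale. Returns (mirna matrix, gene matrix,
    true-pair table); both matrices share an identical ordered sample list.
    """
    if config.n_samples < 3:
        raise ValueError("need at least 3 samples for downstream correlation")
    rng = config.rng(_STREAM_EXPRESSION)
    n, n_mir, n_gene = config.n_samples, config.n_precursors, config.n_genes
    samples = _sample_names(n)

    log_mu = rng.uniform(0.0, 4.0, size=n_mir)
    log_sd = 0.8
    mirna = np.exp(log_mu[None, :] + log_sd * rng.standard_normal((n, n_mir)))

    gene = rng.normal(loc=8.0, scale=2.0, size=(n, n_gene))
    pairs = []
    for k in range(config.n_true_pairs):
        m = mirna[:, k]
        # population variance of the log-normal miRNA column
        v = (np.exp(log_sd**2) - 1.0) * np.exp(2 * log_mu[k] + log_sd**2)
        r = config.pair_r
        noise_sd = np.sqrt(v * (1.0 / r**2 - 1.0))
        gene[:, k] = np.exp(log_mu[k]) * 3.0 - m + noise_sd * rng.standard_normal(n)
        pairs.append((f"mir_{k + 1}", f"gene_{k + 1}", r))
    mirna_df = pd.DataFrame(
        mirna, index=samples, columns=[f"mir_{j + 1}" for j in range(n_mir)]
    )
    gene_df = pd.DataFrame(
        gene, index=samples, columns=[f"gene_{j + 1}" for j in range(n_gene)]
    )
    pair_df = pd.DataFrame(pairs, columns=["mirna_id", "gene_id", "target_r"])
    return mirna_df, gene_df, pair_df


def _sample_names(n: int) -> list[str]:
    """HP/LP/HD/LD group labels when n divides evenly, else plain S1..Sn."""
    if n % 4 == 0:
        per = n // 4
        return [f"{g}{j + 1}" for g in ("HP", "LP", "HD", "LD") for j in range(per)]
    return [f"S{i + 1}" for i in range(n)]


def simulate_de_table(
    n_up: int,
    n_down: int,
    n_null: int,
    seed: int = 0,
    mirna_ids: list[str] | None = None,
    lfc_threshold: float = 0.8,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """DE table with exact planted counts of up / down / non-DE records.

    Up records have log2fc > ``lfc_threshold`` and p < ``p_threshold``;
    down records mirror them with negative fold change; null records fail
    at least one criterion. ``padj`` is carried as a plausible adjusted
    value (sometimes missing), but is never part of the DE decision.
    """
    for name, v in [("n_up", n_up), ("n_down", n_down), ("n_null", n_null)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_DE]))
    total = n_up + n_down + n_null
    if mirna_ids is None:
        mirna_ids = [f"mir_{i + 1}" for i in range(total)]
    elif len(mirna_ids) != total:
        raise ValueError("mirna_ids length must equal n_up + n_down + n_null")

    lfc = np.empty(total)
    pval = np.empty(total)
    lfc[:n_up] = rng.uniform(lfc_threshold + 0.05, 3.5, size=n_up)
    pval[:n_up] = rng.uniform(1e-8, p_threshold * 0.9, size=n_up)
    lfc[n_up : n_up + n_down] = -rng.uniform(lfc_threshold + 0.05, 3.5, size=n_down)
    pval[n_up : n_up + n_down] = rng.uniform(1e-8, p_threshold * 0.9, size=n_down)
    for j in range(n_null):
        i = n_up + n_down + j
        kind = j % 3
        if kind == 0:  # fold change too small
            lfc[i] = rng.uniform(-lfc_threshold, lfc_threshold)
            pval[i] = rng.uniform(0.0, 1.0)
        elif kind == 1:  # not significant
            lfc[i] = rng.uniform(-3.5, 3.5)
            pval[i] = rng.uniform(p_threshold + 0.01, 1.0)
        else:  # fails both
            lfc[i] = rng.uniform(-lfc_threshold, lfc_threshold)
            pval[i] = rng.uniform(p_threshold + 0.01, 1.0)
    padj = np.minimum(pval * rng.uniform(1.0, 8.0, size=total), 1.0)
    padj[rng.random(total) < 0.1] = np.nan  # upstream tools emit NA rows
    table = pd.DataFrame(
        {"mirna_id": mirna_ids, "log2fc": lfc, "pvalue": pval, "padj": padj}
    )
    return table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def write_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    flank: int = 0,
    de_counts: tuple[int, int, int] = (11, 17, 100),
    de_counts_b: tuple[int, int, int] = (22, 30, 100),
) -> dict[str, str]:
    """Materialize a full synthetic dataset plus a manifest; returns file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    precursors, genes = simulate_annotation(config)
    snps = simulate_gwas_summary(config, precursors, flank=flank)
    mirna, gene, pairs = simulate_expression(config)
    n_mir = config.n_precursors
    de_a = simulate_de_table(
        *de_counts, seed=config.seed, mirna_ids=[f"mir_{i+1}" for i in range(sum(de_counts))]
    )
    de_b = simulate_de_table(
        *de_counts_b,
        seed=config.seed + 1,
        mirna_ids=[f"mir_{i+1}" for i in range(sum(de_counts_b))],
    )
    files = {
        "precursors_bed": str(outdir / "precursors.bed"),
        "genes_bed": str(outdir / "genes.bed"),
        "gwas_tsv": str(outdir / "gwas_summary.tsv"),
        "mirna_expression_tsv": str(outdir / "mirna_expression.tsv"),
        "gene_expression_tsv": str(outdir / "gene_expression.tsv"),
        "true_pairs_tsv": str(outdir / "true_pairs.tsv"),
        "de_table_a_tsv": str(outdir / "de_hp_vs_lp.tsv"),
        "de_table_b_tsv": str(outdir / "de_hd_vs_ld.tsv"),
        "manifest_json": str(outdir / "manifest.json"),
    }
    mio.write_intervals(precursors, files["precursors_bed"], format="bed")
    mio.write_intervals(genes, files["genes_bed"], format="bed")
    mio.write_gwas_summary(snps, files["gwas_tsv"])
    mio.write_expression(mirna, files["mirna_expression_tsv"])
    mio.write_expression(gene, files["gene_expression_tsv"])
    pairs.to_csv(files["true_pairs_tsv"], sep="\t", index=False)
    mio.write_de_table(de_a, files["de_table_a_tsv"])
    mio.write_de_table(de_b, files["de_table_b_tsv"])
    manifest = {
        "config": dataclasses.asdict(config),
        "flank": flank,
        "n_expressed_mirnas": n_mir,
        "files": {k: Path(v).name for k, v in files.items()},
    }
    manifest["config"]["enriched_feature_ids"] = list(config.enriched_feature_ids)
    with open(files["manifest_json"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return files
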