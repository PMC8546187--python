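"""Sum-based GWAS-signal enrichment with a circular-shift permutation null.

For a candidate feature set (e.g. the flanked precursor loci of a group of
differentially expressed miRNAs), the test statistic is the sum of squared
marker effects over the SNPs inside the candidate windows,

    T_sum = sum_i beta_i^2 .

The null distribution is obtained by circularly shifting the candidate
SNPs' ranks within the background: the SNPs falling in the background
windows are numbered 1..M in genomic order, the candidate SNPs occupy
ranks N_1..N_n, and for a uniform offset R in 1..M each rank moves to

    P_i = N_i + R        if N_i + R <= M
    P_i = N_i + R - M    otherwise,

so the candidate set's size and internal spacing are preserved while its
placement on the background is randomized. The empirical p-value is

    p = (N_over + 1) / (n_perm + 1)

with N_over the number of permutations whose statistic exceeds the
observed one (strictly, by default). Benjamini-Hochberg FDR is applied
across whatever family of results one call produces.

An alternative null draws same-size random SNP sets from the background
("random_set" mode), matching the procedure used for gene-target windows
when spacing preservation is not wanted.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import FeatureSet, GenomicInterval, merge_intervals

__all__ = [
    "BackgroundIndex",
    "build_windows",
    "exclude_region",
    "build_background_index",
    "assign_snps",
    "compute_tsum",
    "circular_shift",
    "empirical_pvalue",
    "permutation_tsums",
    "run_enrichment",
    "bh_fdr",
]


def build_windows(features: FeatureSet, flank: int) -> pd.DataFrame:
    """Extend every feature by ``flank`` bp on both sides and merge overlaps.

    Windows are clipped at position 1; the result is a chrom/start/end
    table of disjoint, sorted, 1-based inclusive intervals.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    frame = features.to_frame()
    if frame.empty:
        return merge_intervals(frame)
    frame = frame.assign(
        start=np.maximum(frame["start"] - flank, 1), end=frame["end"] + flank
    )
    return merge_intervals(frame[["chrom", "start", "end"]])


def exclude_region(
    snps: pd.DataFrame, region: GenomicInterval, margin: int = 0
) -> pd.DataFrame:
    """Drop SNPs within ``margin`` bp of ``region`` on its chromosome."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    lo = max(region.start - margin, 1)
    hi = region.end + margin
    drop = (
        (snps["chrom"] == region.chrom) & (snps["pos"] >= lo) & (snps["pos"] <= hi)
    )
    return snps.loc[~drop].reset_index(drop=True)


@dataclass
class BackgroundIndex:
    """Background SNPs ranked 1..M in genomic (chrom, pos) order."""

    snps: pd.DataFrame  # snp_id, chrom, pos, beta — sorted, rank i+1 at row i
    betas: np.ndarray  # squared later by callers as needed

    @property
    def M(self) -> int:
        return len(self.snps)


def build_background_index(
    snps: pd.DataFrame, background_windows: pd.DataFrame
) -> BackgroundIndex:
    """Restrict SNPs to background windows and rank them 1..M genomically."""
    inside = _window_mask(snps, background_windows)
    bg = (
        snps.loc[inside]
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    if bg.empty:
        raise ValueError("background windows contain no SNPs")
    return BackgroundIndex(snps=bg, betas=bg["beta"].to_numpy(dtype=float))


def _window_mask(snps: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Membership mask over merged, sorted windows (inclusive endpoints)."""
    mask = np.zeros(len(snps), dtype=bool)
    if windows.empty or snps.empty:
        return mask
    chroms = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    for chrom, win in windows.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = win["start"].to_numpy()
        ends = win["end"].to_numpy()
        p = pos[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        hit = (idx >= 0) & (p <= ends[np.clip(idx, 0, len(ends) - 1)])
        mask[np.flatnonzero(sel)[hit]] = True
    return mask


def assign_snps(
    index: BackgroundIndex, windows: pd.DataFrame, all_snps: pd.DataFrame | None = None
) -> np.ndarray:
    """Ranks (1-based, ascending) of background SNPs inside candidate windows.

    If ``all_snps`` is given, any SNP that falls in a candidate window but
    is absent from the background raises: candidates must be a subset of
    the background for the circular shift to be well defined.
    """
    if all_snps is not None:
        cand_all = int(_window_mask(all_snps, windows).sum())
        cand_bg = int(_window_mask(index.snps, windows).sum())
        if cand_all != cand_bg:
            raise ValueError(
                f"{cand_all - cand_bg} candidate SNP(s) lie outside the background; "
                "background windows must cover every candidate SNP"
            )
    mask = _window_mask(index.snps, windows)
    return np.flatnonzero(mask) + 1


def compute_tsum(betas: np.ndarray, candidate_ranks: np.ndarray) -> float:
    """Sum of squared effects over the candidate ranks (1-based)."""
    ranks = np.asarray(candidate_ranks, dtype=np.int64)
    if ranks.size == 0:
        raise ValueError("no testable SNPs: the candidate windows contain no SNPs")
    return float(np.sum(np.asarray(betas, dtype=float)[ranks - 1] ** 2))


def circular_shift(candidate_ranks: np.ndarray, M: int, R: int) -> np.ndarray:
    """Shift ranks by R with wrap-around past M; a bijection on 1..M."""
    if not 1 <= R <= M:
        raise ValueError(f"shift R must lie in 1..{M}, got {R}")
    ranks = np.asarray(candidate_ranks, dtype=np.int64)
    if ranks.size and (ranks.min() < 1 or ranks.max() > M):
        raise ValueError("candidate ranks must lie in 1..M")
    shifted = ranks + R
    return np.where(shifted > M, shifted - M, shifted)


def empirical_pvalue(
    tsum_obs: float, permuted: np.ndarray, tie: str = "strict"
) -> tuple[int, float]:
    """(N_over, p) with p = (N_over + 1) / (n_perm + 1).

    ``tie='strict'`` counts permuted statistics strictly greater than the
    observed one; ``tie='geq'`` counts ties as exceedances (conservative).
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size < 1:
        raise ValueError("need at least one permuted statistic")
    if tie == "strict":
        n_over = int(np.sum(permuted > tsum_obs))
    elif tie == "geq":
        n_over = int(np.sum(permuted >= tsum_obs))
    else:
        raise ValueError("tie must be 'strict' or 'geq'")
    return n_over, (n_over + 1) / (permuted.size + 1)


def permutation_tsums(
    index: BackgroundIndex,
    candidate_ranks: np.ndarray,
    nperm: int,
    rng: np.random.Generator,
    null_mode: str = "circular",
    exhaustive: bool = False,
    allow_identity: bool = True,
) -> np.ndarray:
    """Null T_sum values under circular-shift or random-set resampling.

    ``exhaustive=True`` (circular mode only) enumerates all M distinct
    shifts instead of sampling, giving the exact permutation distribution.
    """
    beta2 = index.betas**2
    ranks0 = np.asarray(candidate_ranks, dtype=np.int64) - 1  # 0-based
    M = index.M
    if null_mode == "circular":
        if exhaustive:
            R = np.arange(1, M + 1)
        else:
            high = M if allow_identity else M - 1
            if high < 1:
                raise ValueError("background too small for a no-identity shift")
            R = rng.integers(1, high + 1, size=nperm)
        shifted = (ranks0[None, :] + R[:, None]) % M  # 0-based wrap
        return beta2[shifted].sum(axis=1)
    if null_mode == "random_set":
        n = ranks0.size
        out = np.empty(nperm)
        for j in range(nperm):
            pick = rng.choice(M, size=n, replace=False)
            out[j] = beta2[pick].sum()
        return out
    raise ValueError("null_mode must be 'circular' or 'random_set'")


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(
    snps: pd.DataFrame,
    candidate_sets: Mapping[str, FeatureSet],
    background: FeatureSet,
    flank: int = 0,
    candidate_flank: int | None = None,
    nperm: int = 10_000,
    seed: int = 0,
    exclusion: GenomicInterval | None = None,
    exclusion_margin: int = 1_000_000,
    tie: str = "strict",
    null_mode: str = "circular",
    exhaustive: bool = False,
    allow_identity: bool = True,
    apply_fdr: bool = True,
) -> pd.DataFrame:
    """Run the enrichment test for each candidate feature set.

    The background index is built once from the SNPs inside the merged,
    ``flank``-extended background windows (after the optional exclusion
    region is removed). Each candidate set is extended by
    ``candidate_flank`` (defaults to ``flank``), assigned background ranks,
    and tested with ``nperm`` permutations. The random stream is keyed on
    (seed, feature-set id) so results do not depend on evaluation order.

    Returns one row per candidate set: feature_set, m, tsum, n_over,
    pvalue, fdr. A candidate set with no testable SNPs gets m=0 and NaN
    statistics rather than a zero, and is left out of the FDR family.
    """
    if nperm < 1 and not exhaustive:
        raise ValueError("nperm must be >= 1")
    if exclusion is not None:
        snps = exclude_region(snps, exclusion, exclusion_margin)
    bg_windows = build_windows(background, flank)
    index = build_background_index(snps, bg_windows)
    if candidate_flank is None:
        candidate_flank = flank

    rows = []
    for fs_id in candidate_sets:
        features = candidate_sets[fs_id]
        windows = build_windows(features, candidate_flank)
        ranks = assign_snps(index, windows, all_snps=snps)
        if ranks.size == 0:
            rows.append((fs_id, 0, np.nan, np.nan, np.nan))
            continue
        if ranks.size > index.M:
            raise ValueError("candidate set larger than background")
        tsum = compute_tsum(index.betas, ranks)
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(fs_id.encode())])
        )
        permuted = permutation_tsums(
            index,
            ranks,
            nperm,
            rng,
            null_mode=null_mode,
            exhaustive=exhaustive,
            allow_identity=allow_identity,
        )
        n_over, pvalue = empirical_pvalue(tsum, permuted, tie=tie)
        rows.append((fs_id, int(ranks.size), tsum, n_over, pvalue))

    result = pd.DataFrame(
        rows, columns=["feature_set", "m", "tsum", "n_over", "pvalue"]
    )
    result["fdr"] = np.nan
    if apply_fdr:
        tested = result["pvalue"].notna()
        if tested.any():
            result.loc[tested, "fdr"] = bh_fdr(result.loc[tested, "pvalue"].to_numpy())
    return result
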