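"""Differential-expression set operations and pattern clustering.

A miRNA is called differentially expressed (DE) when its raw p-value is
below 0.05 and |log2 fold change| exceeds 0.8 — both strictly. The adjusted
p-value, when present, is carried through but plays no part in the call:
upstream tools emit DE tables whose padj column may be missing or NA.

Cross-comparison set algebra (common / unique DE miRNAs between two
contrasts) and k-means clustering of expression patterns with gap-statistic
model selection live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["DeSetComparison", "filter_de", "compare_de_sets", "cluster_patterns"]

DEFAULT_LFC_THRESHOLD = 0.8
DEFAULT_P_THRESHOLD = 0.05


def filter_de(
    records: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Apply the joint DE threshold and label direction by the sign of log2fc.

    Keeps rows with |log2fc| > lfc_threshold and pvalue < p_threshold (both
    strict), adding a ``direction`` column ('up' for positive fold change,
    'down' for negative). The sign convention of the input table is kept
    as-is; which group is the reference is the caller's bookkeeping.
    """
    if records.empty:
        out = records.copy()
        out["direction"] = pd.Series(dtype=str)
        return out
    lfc = records["log2fc"].to_numpy(dtype=float)
    p = records["pvalue"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("pvalue outside [0, 1]")
    if not np.all(np.isfinite(lfc)):
        raise ValueError("non-finite log2fc")
    keep = (np.abs(lfc) > lfc_threshold) & (p < p_threshold)
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class DeSetComparison:
    """Partition of two DE identifier sets into common and unique parts."""

    set_a_ids: frozenset[str]
    set_b_ids: frozenset[str]
    common_ids: frozenset[str]
    a_only_ids: frozenset[str]
    b_only_ids: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.set_a_ids | self.set_b_ids)

    def to_dict(self) -> dict:
        return {
            "a": sorted(self.set_a_ids),
            "b": sorted(self.set_b_ids),
            "common": sorted(self.common_ids),
            "a_only": sorted(self.a_only_ids),
            "b_only": sorted(self.b_only_ids),
            "union_size": self.union_size,
        }


def compare_de_sets(set_a, set_b) -> DeSetComparison:
    """Venn partition of two DE miRNA identifier collections."""
    a = frozenset(set_a)
    b = frozenset(set_b)
    return DeSetComparison(
        set_a_ids=a,
        set_b_ids=b,
        common_ids=a & b,
        a_only_ids=a - b,
        b_only_ids=b - a,
    )


def mean_normalize(matrix: np.ndarray) -> np.ndarray:
    """Per-row mean normalization: subtract each row's mean."""
    matrix = np.asarray(matrix, dtype=float)
    return matrix - matrix.mean(axis=1, keepdims=True)


def _within_dispersion(X: np.ndarray, k: int, seed: int, n_restarts: int) -> tuple[np.ndarray, float]:
    """Cluster with k-means (Lloyd, best of ``n_restarts``) and return (labels, W_k)."""
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return labels, float(km.inertia_)


def cluster_patterns(
    matrix: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(1, 10),
    seed: int = 0,
    n_restarts: int = 25,
    n_refs: int = 50,
) -> tuple[np.ndarray, int]:
    """k-means clustering of expression patterns with gap-statistic selection.

    Rows (one per miRNA, columns = group means) are mean-normalized so that
    the clustering groups *patterns* rather than expression levels. The
    number of clusters is chosen by the gap statistic against a uniform
    reference distribution over the data's bounding box, with the standard
    one-standard-error rule: the smallest k with
    gap(k) >= gap(k+1) - s(k+1). Returns (labels for the chosen k, chosen k).
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain positive integers")
    if max(ks) > X.shape[0]:
        raise ValueError(f"k_range maximum {max(ks)} exceeds row count {X.shape[0]}")
    X = mean_normalize(X)

    # degenerate: all rows carry the same pattern -> a single cluster
    if np.allclose(X, X[0], atol=1e-12):
        return np.zeros(X.shape[0], dtype=int), 1

    rng = np.random.default_rng(seed)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    tiny = 1e-300  # guards log of an exactly-zero dispersion

    labels_by_k: dict[int, np.ndarray] = {}
    log_w = np.empty(len(ks))
    log_w_ref = np.empty((len(ks), n_refs))
    ref_data = [rng.uniform(lo, hi, size=X.shape) for _ in range(n_refs)]
    for i, k in enumerate(ks):
        labels_by_k[k], w = _within_dispersion(X, k, seed, n_restarts)
        log_w[i] = np.log(max(w, tiny))
        for j, ref in enumerate(ref_data):
            _, w_ref = _within_dispersion(ref, k, seed, n_restarts=1)
            log_w_ref[i, j] = np.log(max(w_ref, tiny))

    gap = log_w_ref.mean(axis=1) - log_w
    s = log_w_ref.std(axis=1, ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)

    chosen = ks[int(np.argmax(gap))]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            chosen = ks[i]
            break
    return labels_by_k[chosen], chosen
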