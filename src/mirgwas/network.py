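"""miRNA-target filtering and regulatory-network edge selection.

Predicted miRNA-gene pairs (score / hybridization-energy tables as emitted
by seed-match predictors) are first filtered on score >= 50 and energy
<= -20 kcal/mol (inclusive). Surviving pairs are then tested for inverse
expression correlation: Pearson r over sample-matched miRNA and gene
expression, keeping pairs with r < 0 and two-sided p < 0.05. Finally, the
network stage keeps only edges whose miRNA and gene are both differentially
expressed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_predictions",
    "pearson_pair",
    "correlate_targets",
    "select_de_de_edges",
    "network_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 50.0
DEFAULT_MAX_ENERGY = -20.0


def filter_predictions(
    pairs: pd.DataFrame,
    min_score: float = DEFAULT_MIN_SCORE,
    max_energy: float = DEFAULT_MAX_ENERGY,
) -> pd.DataFrame:
    """Keep predictions with score >= min_score and energy <= max_energy.

    Both thresholds are inclusive. Expects columns mirna_id, gene_id,
    score, energy.
    """
    keep = (pairs["score"] >= min_score) & (pairs["energy"] <= max_energy)
    return pairs.loc[keep].reset_index(drop=True)


def pearson_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p for two sample-matched expression vectors.

    The p-value comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom. A constant vector has no defined correlation: the pair is
    reported as (nan, nan) and logged, so callers exclude it rather than
    crash.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant expression vector: correlation undefined, pair excluded")
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def collapse_best_site(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple predicted sites per (miRNA, gene) to the best-score one."""
    order = pairs.sort_values("score", ascending=False, kind="mergesort")
    return order.drop_duplicates(["mirna_id", "gene_id"], keep="first").reset_index(
        drop=True
    )


def correlate_targets(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    predicted_pairs: pd.DataFrame,
    p_threshold: float = 0.05,
    inverse_only: bool = True,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Retain predicted pairs that are inversely correlated in expression.

    Both matrices are samples x features and must carry an identical ordered
    sample list (checked before any computation). Multiple sites per
    (miRNA, gene) are collapsed to one pair beforehand. A pair is kept when
    r < 0 (if ``inverse_only``) and p < ``p_threshold``; with
    ``adjust='bh'`` the cut is applied to Benjamini-Hochberg adjusted
    p-values instead of raw ones. Output columns: mirna_id, gene_id, r,
    pvalue, n, sorted by (mirna_id, pvalue).
    """
    if list(mirna_expr.index) != list(gene_expr.index):
        raise ValueError("miRNA and gene expression matrices have different sample lists")
    pairs = collapse_best_site(predicted_pairs)
    n = len(mirna_expr.index)
    rows = []
    for mirna_id, gene_id in pairs[["mirna_id", "gene_id"]].itertuples(index=False):
        if mirna_id not in mirna_expr.columns or gene_id not in gene_expr.columns:
            continue  # pair not measured in expression -> cannot be evaluated
        r, p = pearson_pair(
            mirna_expr[mirna_id].to_numpy(), gene_expr[gene_id].to_numpy()
        )
        if np.isnan(r):
            continue
        rows.append((mirna_id, gene_id, r, p, n))
    table = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "r", "pvalue", "n"])
    if table.empty:
        return table
    crit = table["pvalue"].to_numpy()
    if adjust == "bh":
        from .enrichment import bh_fdr

        crit = bh_fdr(crit)
    keep = crit < p_threshold
    if inverse_only:
        keep &= table["r"].to_numpy() < 0
    return (
        table.loc[keep]
        .sort_values(["mirna_id", "pvalue"], kind="mergesort")
        .reset_index(drop=True)
    )


def select_de_de_edges(
    correlated_pairs: pd.DataFrame, de_mirnas, de_genes
) -> pd.DataFrame:
    """Edges whose miRNA and target gene are both differentially expressed."""
    de_m = set(de_mirnas)
    de_g = set(de_genes)
    keep = correlated_pairs["mirna_id"].isin(de_m) & correlated_pairs["gene_id"].isin(
        de_g
    )
    return correlated_pairs.loc[keep].reset_index(drop=True)


def network_summary(edges: pd.DataFrame) -> dict[str, int]:
    """Distinct miRNA / gene / edge counts of an edge table."""
    dedup = edges.drop_duplicates(["mirna_id", "gene_id"])
    return {
        "n_mirnas": int(dedup["mirna_id"].nunique()),
        "n_genes": int(dedup["gene_id"].nunique()),
        "n_edges": int(len(dedup)),
    }


def write_edge_list(
    edges: pd.DataFrame, edge_path, node_path=None
) -> None:
    """Export edges (TSV) plus an optional node-attribute sidecar (type column)."""
    edges.to_csv(edge_path, sep="\t", index=False)
    if node_path is not None:
        nodes = pd.concat(
            [
                pd.DataFrame({"node": edges["mirna_id"].unique(), "type": "miRNA"}),
                pd.DataFrame({"node": edges["gene_id"].unique(), "type": "gene"}),
            ],
            ignore_index=True,
        )
        nodes.to_csv(node_path, sep="\t", index=False)
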