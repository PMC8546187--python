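"""Readers and writers for the tabular formats the pipeline touches.

Formats handled here:

* BED6 and GFF3 feature intervals (BED is 0-based half-open on disk and
  converted to the internal 1-based inclusive convention at this boundary;
  GFF3 is already 1-based inclusive).
* GWAS summary statistics: TSV with header columns
  ``snp_id  chrom  pos  beta`` (extra columns such as ``se`` or ``pvalue``
  are preserved as payload).
* Expression matrices: TSV with one row per sample and one column per
  feature; the first column holds the sample name.
* DE tables: TSV with ``mirna_id  log2fc  pvalue`` and optional ``padj``.

Also houses the small-RNA annotation priority rule and the TPM expression
filter.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import FeatureSet, GenomicInterval

__all__ = [
    "SmallRnaClass",
    "read_intervals",
    "write_intervals",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_expression",
    "write_expression",
    "read_de_table",
    "write_de_table",
    "resolve_small_rna_class",
    "filter_expressed",
]


class SmallRnaClass(enum.IntEnum):
    """Small-RNA annotation classes; the integer value is the priority rank.

    When a read maps to loci of several classes it is assigned to the class
    with the smallest rank: known miRNA outranks rRNA, rRNA outranks tRNA,
    and so on down to ta-siRNA.
    """

    KNOWN_MIRNA = 1
    RRNA = 2
    TRNA = 3
    SNRNA = 4
    SNORNA = 5
    REPEAT = 6
    NOVEL_MIRNA = 7
    TA_SIRNA = 8


def resolve_small_rna_class(matched: Iterable[SmallRnaClass]) -> SmallRnaClass:
    """Resolve a multi-class annotation to the single highest-priority class."""
    matched = list(matched)
    if not matched:
        raise ValueError("cannot resolve an empty set of small-RNA classes")
    return min(matched)


# --------------------------------------------------------------------------
# intervals


def read_intervals(path: str | Path, format: str = "bed") -> FeatureSet:
    """Read BED6 or GFF3 intervals into a :class:`FeatureSet`.

    BED coordinates (0-based, half-open) are converted to 1-based inclusive;
    GFF3 coordinates are used as-is. Duplicate feature ids raise.
    """
    fmt = format.lower()
    if fmt not in {"bed", "gff3"}:
        raise ValueError(f"unknown interval format {format!r}; use 'bed' or 'gff3'")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 4:
                        raise ValueError("BED needs at least 4 columns (name required)")
                    chrom, start0, end0, name = fields[:4]
                    strand = fields[5] if len(fields) >= 6 else "."
                    start = int(start0) + 1  # half-open zero-based -> inclusive
                    end = int(end0)
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    chrom = fields[0]
                    start = int(fields[3])
                    end = int(fields[4])
                    strand = fields[6]
                    name = _gff3_id(fields[8])
                intervals.append(
                    GenomicInterval(
                        chrom=chrom, start=start, end=end, feature_id=name, strand=strand
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed {fmt} line {lineno}: {exc}") from exc
    return FeatureSet(intervals, name=path.stem)


def _gff3_id(attributes: str) -> str:
    for part in attributes.split(";"):
        key, _, value = part.strip().partition("=")
        if key == "ID":
            return value
    raise ValueError(f"GFF3 attributes without an ID tag: {attributes!r}")


def write_intervals(features: FeatureSet, path: str | Path, format: str = "bed") -> None:
    """Write a FeatureSet as BED6 (converting back to 0-based half-open) or GFF3."""
    fmt = format.lower()
    path = Path(path)
    with open(path, "w") as fh:
        for iv in features:
            if fmt == "bed":
                fh.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.feature_id}\t0\t{iv.strand}\n"
                )
            elif fmt == "gff3":
                fh.write(
                    f"{iv.chrom}\tmirgwas\tregion\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t"
                    f"ID={iv.feature_id}\n"
                )
            else:
                raise ValueError(f"unknown interval format {format!r}")


# --------------------------------------------------------------------------
# GWAS summary statistics

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "beta"]


def read_gwas_summary(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV, validate, and sort by (chrom, pos).

    Required header columns: snp_id, chrom, pos, beta. pos must be a
    positive integer and beta a finite real; the offending row index is
    reported otherwise. Extra columns are kept.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str}, comment="#")
    if table.empty:
        raise ValueError(f"{path}: empty GWAS summary file")
    missing = [c for c in GWAS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("pos", "beta"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col!r} at row {int(bad[0])} "
                f"(value {table.loc[bad[0], col]!r})"
            )
        table[col] = coerced
    if not np.isfinite(table["beta"]).all():
        bad_row = int(table.index[~np.isfinite(table["beta"])][0])
        raise ValueError(f"{path}: non-finite beta at row {bad_row}")
    table["pos"] = table["pos"].astype(np.int64)
    table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return table


def write_gwas_summary(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# expression matrices and DE tables


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV (sample rows x feature columns, first col = sample)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample")


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    required = ["mirna_id", "log2fc", "pvalue"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    return table


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# expression filter


def filter_expressed(
    matrix: pd.DataFrame, tpm_threshold: float = 0.5, min_samples: int = 2
) -> list[str]:
    """Features expressed above ``tpm_threshold`` in at least ``min_samples`` samples.

    Both comparisons are strict: a feature at exactly the threshold in every
    sample is dropped. ``matrix`` is samples x features. Negative expression
    values are rejected.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    keep = (values > tpm_threshold).sum(axis=0) >= min_samples
    return [c for c, k in zip(matrix.columns, keep) if k]
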