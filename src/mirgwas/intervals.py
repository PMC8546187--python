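"""Genomic intervals and feature sets.

All coordinates are held internally as 1-based inclusive (GFF3-native).
BED input/output is converted at the file boundary (see :mod:`mirgwas.io`).
Strand is carried but never used in window arithmetic: every flanking
window in the pipeline is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["GenomicInterval", "FeatureSet"]


@dataclass(frozen=True)
class GenomicInterval:
    """One named interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    feature_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(
                f"interval {self.feature_id!r}: start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise ValueError(
                f"interval {self.feature_id!r}: end {self.end} < start {self.start}"
            )
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureSet:
    """An ordered collection of uniquely named genomic intervals."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [iv.feature_id for iv in self.intervals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids in FeatureSet: {dupes}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def ids(self) -> list[str]:
        return [iv.feature_id for iv in self.intervals]

    def subset(self, feature_ids: Iterable[str]) -> "FeatureSet":
        """Return the features whose ids are in ``feature_ids`` (order kept)."""
        wanted = set(feature_ids)
        missing = wanted - set(self.ids())
        if missing:
            raise KeyError(f"unknown feature ids: {sorted(missing)}")
        return FeatureSet(
            [iv for iv in self.intervals if iv.feature_id in wanted], name=self.name
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: chrom, start, end (1-based inclusive), strand, feature_id."""
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": np.array([iv.start for iv in self.intervals], dtype=np.int64),
                "end": np.array([iv.end for iv in self.intervals], dtype=np.int64),
                "strand": [iv.strand for iv in self.intervals],
                "feature_id": [iv.feature_id for iv in self.intervals],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str = "") -> "FeatureSet":
        ivs = [
            GenomicInterval(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                feature_id=str(row.feature_id),
                strand=str(getattr(row, "strand", ".")),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(ivs, name=name)


def merge_intervals(frame: pd.DataFrame) -> pd.DataFrame:
    """Union of 1-based inclusive intervals, merged per chromosome.

    Adjacent intervals (end + 1 == next start) are merged as well, since
    they cover a contiguous run of bases. Returns columns chrom/start/end
    sorted by (chrom, start).
    """
    if frame.empty:
        return pd.DataFrame({"chrom": [], "start": [], "end": []}).astype(
            {"start": np.int64, "end": np.int64}
        )
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    ordered = frame.sort_values(["chrom", "start", "end"], kind="mergesort")
    for chrom, grp in ordered.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + 1:  # overlap or direct adjacency
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.array(out_start, dtype=np.int64),
            "end": np.array(out_end, dtype=np.int64),
        }
    )
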