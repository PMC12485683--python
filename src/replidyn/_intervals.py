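"""Vectorised genomic-interval arithmetic shared across modules.

All intervals are 0-based, half-open, held in DataFrames with at least
``chrom``, ``start`` and ``end`` columns.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["merge_intervals", "union_length", "GenomeLayout", "CoverageIndex"]


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: sorted, per-chromosome merge of overlapping/adjacent records."""
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        # a new block starts where the interval begins past the running max end
        new_block = np.ones(len(sub), dtype=bool)
        new_block[1:] = starts[1:] > ends[:-1]
        block = np.cumsum(new_block) - 1
        merged_start = pd.Series(starts).groupby(block).min().to_numpy()
        merged_end = pd.Series(ends).groupby(block).max().to_numpy()
        out.append(pd.DataFrame({"chrom": chrom, "start": merged_start, "end": merged_end}))
    return pd.concat(out, ignore_index=True)


def union_length(df: pd.DataFrame) -> int:
    m = merge_intervals(df)
    if len(m) == 0:
        return 0
    return int((m["end"] - m["start"]).sum())


class GenomeLayout:
    """Maps (chrom, pos) to a single absolute coordinate axis.

    Concatenating chromosomes lets interval queries use one sorted array
    instead of per-chromosome dictionaries; chromosome boundaries are never
    crossed because callers only form intervals within one chromosome.
    """

    def __init__(self, genome: dict[str, int]):
        self.genome = dict(genome)
        self.names = list(genome)
        offs, total = {}, 0
        for name, length in genome.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has nonpositive length {length}")
            offs[name] = total
            total += int(length)
        self.offset = offs
        self.total = total

    def to_abs(self, chrom, pos) -> np.ndarray:
        if isinstance(chrom, str):
            off = self.offset[chrom]
            return np.asarray(pos, dtype=np.int64) + off
        off = np.array([self.offset[c] for c in chrom], dtype=np.int64)
        return np.asarray(pos, dtype=np.int64) + off

    def frame_to_abs(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        missing = set(df["chrom"]) - set(self.offset)
        if missing:
            raise KeyError(f"unknown chromosome(s): {sorted(missing)}")
        off = df["chrom"].map(self.offset).to_numpy(dtype=np.int64)
        return df["start"].to_numpy(np.int64) + off, df["end"].to_numpy(np.int64) + off


class CoverageIndex:
    """Prefix-sum index over a merged interval set for O(log n) overlap queries."""

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout):
        self.layout = layout
        m = merge_intervals(df)
        if len(m):
            s, e = layout.frame_to_abs(m)
            order = np.argsort(s)
            self.starts, self.ends = s[order], e[order]
        else:
            self.starts = np.empty(0, dtype=np.int64)
            self.ends = np.empty(0, dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(self.ends - self.starts)])

    @property
    def total_bp(self) -> int:
        return int(self.cum[-1])

    def covered_before(self, x: np.ndarray) -> np.ndarray:
        """Total covered bp strictly left of absolute coordinate(s) x."""
        x = np.atleast_1d(np.asarray(x, dtype=np.int64))
        idx = np.searchsorted(self.starts, x, side="right")
        res = self.cum[idx].astype(np.int64)
        prev = idx - 1
        mask = prev >= 0
        if mask.any():
            res[mask] -= np.maximum(0, self.ends[prev[mask]] - x[mask])
        return res

    def overlap_abs(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return self.covered_before(ends) - self.covered_before(starts)

    def overlap_frame(self, df: pd.DataFrame) -> np.ndarray:
        s, e = self.layout.frame_to_abs(df)
        return self.overlap_abs(s, e)

    def total_overlap(self, df: pd.DataFrame) -> int:
        # query intervals may themselves overlap each other; that is the
        # caller's choice (factor peaks are counted with multiplicity)
        return int(self.overlap_frame(df).sum())
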