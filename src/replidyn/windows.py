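"""Fixed-window binning: fork/event counts, RFD and chromosome coverage.

Replication fork directionality (RFD) in a window is
``(rightward - leftward) / (rightward + leftward)`` over fork counts, from
-1 (fully leftward) through 0 (balanced) to +1 (fully rightward).  Windows
with no forks carry a missing value, never 0 — zero would assert balance.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._intervals import merge_intervals

__all__ = [
    "make_windows",
    "bin_features",
    "window_stats",
    "rfd",
    "chromosome_coverage",
    "stats_matrix",
    "direction_bias_calls",
    "write_bedgraph",
]

DEFAULT_BIN = 100_000


def make_windows(genome: dict[str, int], bin_size: int = DEFAULT_BIN) -> pd.DataFrame:
    """Non-overlapping windows tiling each chromosome; the last may be short."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _window_index(df, genome, bin_size, assign):
    """Window keys (chrom, window start) for each feature; 'overlap' may repeat features."""
    for chrom in df["chrom"].unique():
        if chrom not in genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
    bad = df[(df["start"] < 0) | (df["start"] >= df["chrom"].map(genome))]
    if len(bad):
        b = bad.iloc[0]
        raise ValueError(f"feature at {b['chrom']}:{b['start']} beyond chromosome length")
    if assign == "start":
        keys = df.assign(win=(df["start"] // bin_size) * bin_size)[["chrom", "win"]]
        keys["_feature"] = df.index
        return keys
    if assign == "overlap":
        rows = []
        for idx, r in df.iterrows():
            first = (r["start"] // bin_size) * bin_size
            last = ((min(r["end"], genome[r["chrom"]]) - 1) // bin_size) * bin_size
            for w in range(first, last + 1, bin_size):
                rows.append((r["chrom"], w, idx))
        return pd.DataFrame(rows, columns=["chrom", "win", "_feature"])
    raise ValueError(f"unknown assign rule {assign!r}")


def bin_features(features: pd.DataFrame, genome: dict[str, int],
                 bin_size: int = DEFAULT_BIN, assign: str = "start") -> pd.DataFrame:
    """Count features per window.

    ``assign='start'`` (default) counts each feature once, in the window
    containing its start coordinate; ``'overlap'`` counts it in every window
    it overlaps.  Returns the full window tiling with a ``count`` column.
    """
    wins = make_windows(genome, bin_size)
    keys = _window_index(features, genome, bin_size, assign)
    counts = keys.groupby(["chrom", "win"]).size()
    wins["count"] = [counts.get((c, s), 0) for c, s in zip(wins["chrom"], wins["start"])]
    return wins


def window_stats(forks: pd.DataFrame | None, genome: dict[str, int],
                 bin_size: int = DEFAULT_BIN, assign: str = "start",
                 origins: pd.DataFrame | None = None,
                 terminations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-window fork-direction counts, RFD, coverage, and event counts.

    ``forks`` needs ``chrom``, ``start`` (fork call start) and ``direction``
    columns; pass the tabular view from :func:`replidyn.io_bed.fork_frame`
    after renaming ``fork_start`` or use :func:`fork_windows_input`.
    """
    wins = make_windows(genome, bin_size)
    for col in ("right_count", "left_count", "origin_count", "termination_count"):
        wins[col] = 0
    if forks is not None and len(forks):
        for direction, col in (("R", "right_count"), ("L", "left_count")):
            sub = forks[forks["direction"] == direction]
            if len(sub):
                wins[col] = bin_features(sub, genome, bin_size, assign)["count"]
    for events, col in ((origins, "origin_count"), (terminations, "termination_count")):
        if events is not None and len(events):
            wins[col] = bin_features(events, genome, bin_size, assign)["count"]
    wins["fork_coverage"] = wins["right_count"] + wins["left_count"]
    wins["rfd"] = rfd(wins["right_count"], wins["left_count"])
    return wins


def fork_windows_input(records) -> pd.DataFrame:
    """Adapt fork records to the window-binning input (start = fork call start)."""
    from .io_bed import fork_frame
    df = fork_frame(records)
    return df.rename(columns={"fork_start": "start", "fork_end": "end"})[
        ["chrom", "start", "end", "direction"]]


def rfd(right_counts, left_counts):
    """(R - L) / (R + L); NaN where a window holds no forks."""
    r = np.asarray(right_counts, dtype=float)
    l = np.asarray(left_counts, dtype=float)
    total = r + l
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (r - l) / np.where(total > 0, total, 1), np.nan)
    return out


def chromosome_coverage(intervals: pd.DataFrame, genome: dict[str, int]) -> pd.Series:
    """Fraction of each chromosome covered by the union of the intervals."""
    for chrom in intervals["chrom"].unique():
        if chrom not in genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
    clipped = intervals.copy()
    clipped["end"] = np.minimum(clipped["end"], clipped["chrom"].map(genome))
    clipped["start"] = np.maximum(clipped["start"], 0)
    merged = merge_intervals(clipped[clipped["start"] < clipped["end"]])
    cov = merged.assign(bp=merged["end"] - merged["start"]).groupby("chrom")["bp"].sum()
    return pd.Series({c: float(cov.get(c, 0)) / length for c, length in genome.items()},
                     name="coverage")


def stats_matrix(stats: pd.DataFrame, value: str = "rfd") -> pd.DataFrame:
    """Chromosome x bin matrix of a window statistic, NA-padded to the longest chromosome."""
    df = stats.copy()
    df["bin"] = df["start"] // (df["end"] - df["start"]).max()
    return df.pivot_table(index="chrom", columns="bin", values=value, dropna=False)


def direction_bias_calls(stats: pd.DataFrame, threshold: float = 0.8,
                         min_forks: int = 10) -> pd.DataFrame:
    """Windows with a strong directionality bias: |RFD| >= threshold at adequate depth."""
    ok = (stats["fork_coverage"] >= min_forks) & (stats["rfd"].abs() >= threshold)
    out = stats[ok].copy()
    out["bias"] = np.where(out["rfd"] > 0, "rightward", "leftward")
    return out.reset_index(drop=True)


def write_bedgraph(stats: pd.DataFrame, value: str, path) -> None:
    """Export one window statistic as bedgraph (missing values skipped)."""
    sub = stats.dropna(subset=[value])
    sub[["chrom", "start", "end", value]].to_csv(path, sep="\t", header=False, index=False)
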