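"""Fork-call quality filtering and track-length statistics.

Filtering keeps the high-confidence fork set: calls with negative stall
codes are removed (−1 termination, −2 segmentation error, −3 read end, −4
indel proximity), as are calls whose BrdU segment abuts a molecule end
(those lengths are censored by the read boundary).  Because labeling is
sequential EdU-then-BrdU, an initiation-linked call flagged only with code
−1 can optionally be retained: BrdU following EdU still marks reliable fork
progression from an origin.

Track metrics follow the standard conventions of analog pulse experiments:
the BrdU/EdU length ratio (ratios above 100 treated as outliers), the
BrdU/read-length normalization, N50 (length-weighted median) and the fork
progression rate N50 / pulse duration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_bed import ForkRecord, fork_frame

__all__ = [
    "FilterResult",
    "LengthSummary",
    "filter_forks",
    "track_metrics",
    "length_summary",
    "n50",
    "fork_rate",
    "percentile_trim",
    "qc_report",
]

REASONS = ("stall_-1", "stall_-2", "stall_-3", "stall_-4", "brdu_at_read_end", "zero_edu")


@dataclass
class FilterResult:
    retained: list
    rejected: list  # (ForkRecord, reason) pairs

    @property
    def reason_counts(self) -> dict:
        counts = {r: 0 for r in REASONS}
        for _rec, reason in self.rejected:
            counts[reason] += 1
        return counts


def _rejection_reason(rec: ForkRecord, origin_linked, retain_initiation, end_slack) -> str | None:
    if rec.stall_score < 0:
        code = int(rec.stall_score)
        if not (code == -1 and retain_initiation
                and origin_linked is not None and rec.read_id in origin_linked):
            return f"stall_{code}"
    if rec.brdu_length > 0 and (
            rec.brdu_start - rec.read_start <= end_slack
            or rec.read_end - rec.brdu_end <= end_slack):
        return "brdu_at_read_end"
    if rec.edu_length == 0:
        return "zero_edu"
    return None


def filter_forks(records, *, origin_linked=None, retain_initiation: bool = True,
                 end_slack: int = 0) -> FilterResult:
    """Partition fork calls into retained and rejected (with reason codes).

    ``origin_linked`` is an optional set of read ids known to derive from an
    initiation event; with ``retain_initiation`` those survive a −1 stall
    code.  ``end_slack`` widens the BrdU-at-read-end test (default exact
    abutment).  Every input record appears exactly once in the output.
    """
    retained, rejected = [], []
    for rec in records:
        reason = _rejection_reason(rec, origin_linked, retain_initiation, end_slack)
        if reason is None:
            retained.append(rec)
        else:
            rejected.append((rec, reason))
    return FilterResult(retained, rejected)


def track_metrics(records, ratio_outlier_threshold: float = 100.0) -> pd.DataFrame:
    """Per-record length metrics for filtered forks.

    Records with zero EdU length are dropped (the ratio is undefined);
    ratios above the outlier threshold stay in the table but are flagged so
    ratio summaries can exclude them.
    """
    df = fork_frame(records)
    df = df[df["edu_length"] > 0].copy()
    df["ratio"] = df["brdu_length"] / df["edu_length"]
    df["norm_brdu"] = df["brdu_length"] / df["read_length"]
    df["ratio_outlier"] = df["ratio"] > ratio_outlier_threshold
    cols = ["read_id", "chrom", "direction", "edu_length", "brdu_length",
            "read_length", "ratio", "norm_brdu", "ratio_outlier"]
    return df[cols].reset_index(drop=True)


@dataclass
class LengthSummary:
    n: int
    mean: float
    median: float
    n50: float


def n50(lengths) -> float:
    """Largest L such that segments of length >= L hold at least half the total."""
    arr = np.sort(np.asarray(lengths, dtype=float))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set is undefined")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return float(arr[min(idx, arr.size - 1)])


def length_summary(lengths) -> LengthSummary:
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("length summary of an empty set is undefined")
    return LengthSummary(n=int(arr.size), mean=float(arr.mean()),
                         median=float(np.median(arr)), n50=n50(arr))


def fork_rate(n50_bp: float, pulse_minutes: float) -> float:
    """Fork progression rate = N50 / pulse duration, to 0.1 bp/min."""
    if pulse_minutes <= 0:
        raise ValueError("pulse duration must be positive")
    if n50_bp == 0:
        warnings.warn("zero N50 yields a zero fork rate", stacklevel=2)
        return 0.0
    return round(n50_bp / pulse_minutes, 1)


def percentile_trim(values, lo: float = 1.0, hi: float = 99.0) -> np.ndarray:
    """Keep values within the [lo, hi] percentile range, inclusive.

    Percentiles use linear interpolation between order statistics.  Intended
    for distribution exports/plots, not for summary statistics.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return arr
    p_lo, p_hi = np.percentile(arr, [lo, hi])
    return arr[(arr >= p_lo) & (arr <= p_hi)]


def qc_report(result: FilterResult) -> pd.DataFrame:
    """Record-count accounting through the filter, one row per reason."""
    counts = result.reason_counts
    rows = [("input", len(result.retained) + len(result.rejected)),
            ("retained", len(result.retained))]
    rows += [(f"rejected_{reason}", counts[reason]) for reason in REASONS]
    return pd.DataFrame(rows, columns=["category", "count"])
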