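"""Chromatin-state and replication-timing integration for labeled tracks.

Chromatin states 0-9 map onto three broad categories: euchromatin (states
1-5, transcriptionally active/accessible), heterochromatin (states 0 and
6-8, repressive/compact; state 0 marks regions unmapped in the older
assembly and predominantly repetitive), and silent (state 9, no hallmark
modifications).  A track is assigned a state only when its BrdU interval is
fully contained in a single-state block (adjacent same-state intervals are
merged first); boundary-spanning tracks are excluded.

Replication-timing segments (~100 bp, scored, grouped 0-3 from earliest to
latest) are aggregated into fixed 30-kb windows by dominant cumulative
overlap, and tracks are mapped to the window they overlap most.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._intervals import CoverageIndex, GenomeLayout, merge_intervals
from .io_bed import AnnotationTrack
from .windows import make_windows

__all__ = [
    "STATE_CATEGORY",
    "state_category",
    "assign_state_containment",
    "compare_groups",
    "quintile_composition",
    "timing_windows",
    "assign_track_to_window",
    "timing_correlation",
    "timing_quartiles",
    "category_density",
    "brdu_intervals",
]

STATE_CATEGORY = {**{s: "euchromatin" for s in (1, 2, 3, 4, 5)},
                  **{s: "heterochromatin" for s in (0, 6, 7, 8)},
                  9: "silent"}


def state_category(state: int) -> str:
    return STATE_CATEGORY[int(state)]


def brdu_intervals(records) -> pd.DataFrame:
    """BrdU segment intervals of fork records, as a generic interval frame."""
    from .io_bed import fork_frame
    df = fork_frame(records)
    out = df.rename(columns={"brdu_start": "start", "brdu_end": "end"})[
        ["chrom", "start", "end", "read_id", "direction", "read_length"]]
    out["length"] = out["end"] - out["start"]
    return out


def _merged_state_blocks(state_track: AnnotationTrack) -> pd.DataFrame:
    """Merge adjacent same-state intervals into contiguous blocks."""
    blocks = []
    df = state_track.records
    for state, sub in df.groupby("state"):
        m = merge_intervals(sub)
        m["state"] = state
        blocks.append(m)
    return pd.concat(blocks, ignore_index=True).sort_values(
        ["chrom", "start"], kind="stable").reset_index(drop=True)


def assign_state_containment(tracks: pd.DataFrame,
                             state_track: AnnotationTrack) -> pd.DataFrame:
    """Strict single-state containment assignment.

    A track gets state ``s`` iff its interval lies entirely inside one
    contiguous state-``s`` block; otherwise (boundary-spanning or over a gap
    in the state map) it is unassigned (state NA) and excluded from
    state-stratified analyses.
    """
    blocks = _merged_state_blocks(state_track)
    out = tracks.copy().reset_index(drop=True)
    out["state"] = pd.array([pd.NA] * len(out), dtype="Int64")
    n_gap = 0
    for chrom, sub in out.groupby("chrom", sort=False):
        b = blocks[blocks["chrom"] == chrom].sort_values("start")
        if not len(b):
            n_gap += len(sub)
            continue
        bs = b["start"].to_numpy()
        be = b["end"].to_numpy()
        bstate = b["state"].to_numpy()
        idx = np.searchsorted(bs, sub["start"].to_numpy(), side="right") - 1
        valid = idx >= 0
        contained = np.zeros(len(sub), dtype=bool)
        contained[valid] = sub["end"].to_numpy()[valid] <= be[idx[valid]]
        rows = out.index.get_indexer(sub.index)
        assigned = rows[contained]
        out.loc[assigned, "state"] = bstate[idx[contained]].astype(int)
        n_gap += int((~valid).sum())
    if n_gap:
        warnings.warn(f"{n_gap} track(s) fall over gaps in the state map", stacklevel=2)
    out["category"] = out["state"].map(
        lambda s: STATE_CATEGORY[int(s)] if pd.notna(s) else pd.NA)
    return out


@dataclass
class GroupComparison:
    summary: pd.DataFrame      # per-group n/mean/median
    pairwise: pd.DataFrame     # two-sided rank-sum p per pair
    h_stat: float | None       # Kruskal-Wallis across >= 3 groups
    h_pvalue: float | None


def compare_groups(values_by_group: dict[str, np.ndarray]) -> GroupComparison:
    """Nonparametric location comparison across groups.

    Two-sided Mann-Whitney U for every pair; Kruskal-Wallis omnibus test when
    three or more groups are present.  Raises on an empty group, naming it.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    for name, vals in values_by_group.items():
        if len(np.asarray(vals)) == 0:
            raise ValueError(f"group {name!r} is empty")
    names = list(values_by_group)
    summary = pd.DataFrame({
        "group": names,
        "n": [len(values_by_group[g]) for g in names],
        "mean": [float(np.mean(values_by_group[g])) for g in names],
        "median": [float(np.median(values_by_group[g])) for g in names],
    })
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            u, p = sps.mannwhitneyu(values_by_group[a], values_by_group[b],
                                    alternative="two-sided")
            rows.append((a, b, float(u), float(p)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "u_stat", "p_value"])
    h = hp = None
    if len(names) >= 3:
        h, hp = (float(v) for v in sps.kruskal(*[values_by_group[g] for g in names]))
    return GroupComparison(summary, pairwise, h, hp)


def quintile_composition(tracks: pd.DataFrame, state_track: AnnotationTrack,
                         genome: dict[str, int], normalize: bool = False) -> pd.DataFrame:
    """Per-length-quintile chromatin-state composition.

    Tracks are ranked by length (stable ties on length, chrom, start) and cut
    into five equal-count groups Q1 (shortest) .. Q5 (longest).  Within each
    quintile, overlapping tracks are merged to non-redundant intervals and
    the per-state bp proportion is computed.  With ``normalize`` each
    proportion is divided by the state's genomic fraction (1.0 = no
    enrichment).
    """
    if len(tracks) < 5:
        raise ValueError("need at least five tracks for quintiles")
    layout = GenomeLayout(genome)
    df = tracks.copy()
    if "length" not in df:
        df["length"] = df["end"] - df["start"]
    df = df.sort_values(["length", "chrom", "start"], kind="stable").reset_index(drop=True)
    df["quintile"] = pd.cut(np.arange(len(df)), bins=5,
                            labels=["Q1", "Q2", "Q3", "Q4", "Q5"])
    states = sorted(state_track.records["state"].unique())
    state_index = {s: CoverageIndex(state_track.records[state_track.records["state"] == s],
                                    layout) for s in states}
    genome_bp = sum(genome.values())
    rows = []
    for q in ["Q1", "Q2", "Q3", "Q4", "Q5"]:
        merged = merge_intervals(df[df["quintile"] == q])
        total = float((merged["end"] - merged["start"]).sum())
        for s in states:
            bp = state_index[s].total_overlap(merged)
            prop = bp / total if total else 0.0
            if normalize:
                frac = state_index[s].total_bp / genome_bp
                prop = prop / frac if frac else np.nan
            rows.append((q, s, bp, prop))
    return pd.DataFrame(rows, columns=["quintile", "state", "bp", "proportion"])


def timing_windows(timing: AnnotationTrack, genome: dict[str, int],
                   window_bp: int = 30_000) -> pd.DataFrame:
    """Fixed windows labeled with the dominant replication-timing group.

    The dominant group is the one with the greatest cumulative segment
    overlap in the window (tie -> lowest group index, flagged).  Windows with
    no overlapping segments are excluded.  Also reports the mean segment
    score and segment count per window.
    """
    layout = GenomeLayout(genome)
    wins = make_windows(genome, window_bp)
    seg = timing.records
    group_index = {g: CoverageIndex(seg[seg["group"] == g], layout) for g in range(4)}
    overlaps = np.column_stack([
        group_index[g].overlap_frame(wins) if group_index[g].total_bp else
        np.zeros(len(wins), dtype=np.int64) for g in range(4)])
    total = overlaps.sum(axis=1)
    dominant = overlaps.argmax(axis=1)  # argmax takes the lowest index on ties
    tie = (overlaps == overlaps.max(axis=1, keepdims=True)).sum(axis=1) > 1

    # mean score and count of segments overlapping each window (by segment midpoint window)
    mid = (seg["start"] + seg["end"]) // 2
    key = pd.DataFrame({"chrom": seg["chrom"], "win": (mid // window_bp) * window_bp,
                        "score": seg["score"]})
    agg = key.groupby(["chrom", "win"])["score"].agg(["mean", "size"])
    idx = pd.MultiIndex.from_arrays([wins["chrom"], wins["start"]])
    wins["mean_score"] = agg["mean"].reindex(idx).to_numpy()
    wins["region_count"] = agg["size"].reindex(idx).fillna(0).astype(int).to_numpy()
    wins["dominant_group"] = dominant
    wins["tie"] = tie
    return wins[total > 0].reset_index(drop=True)


def assign_track_to_window(tracks: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Assign each track to the window it overlaps most (tie -> leftmost, flagged)."""
    out = tracks.copy().reset_index(drop=True)
    out["window_idx"] = -1
    out["window_tie"] = False
    for chrom, sub in out.groupby("chrom", sort=False):
        w = windows[windows["chrom"] == chrom]
        if not len(w):
            continue
        ws, we = w["start"].to_numpy(), w["end"].to_numpy()
        widx = w.index.to_numpy()
        for row, (s, e) in zip(out.index.get_indexer(sub.index),
                               zip(sub["start"], sub["end"])):
            ov = np.minimum(we, e) - np.maximum(ws, s)
            ov = np.maximum(ov, 0)
            if ov.max() <= 0:
                continue
            best = int(ov.argmax())
            out.loc[row, "window_idx"] = widx[best]
            out.loc[row, "window_tie"] = bool((ov == ov.max()).sum() > 1)
    return out


def timing_correlation(track_lengths, window_scores) -> tuple[float, float, int, int]:
    """Pearson correlation on log10(track length) vs log10(window mean timing score).

    Pairs with a nonpositive value on either axis cannot be log-transformed
    and are excluded; the count of exclusions is returned.
    """
    x = np.asarray(window_scores, dtype=float)
    y = np.asarray(track_lengths, dtype=float)
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("need at least three positive (length, score) pairs")
    r, p = sps.pearsonr(np.log10(x[ok]), np.log10(y[ok]))
    return float(r), float(p), int(ok.sum()), n_excluded


def timing_quartiles(timing: AnnotationTrack, bp_weighted: bool = False) -> AnnotationTrack:
    """Partition timing segments into score quartiles and merge adjacent same-quartile runs.

    Quartile boundaries come from the score quantiles of segment records (or
    bp-weighted quantiles with ``bp_weighted``); merging adjacent intervals in
    the same quartile gives the coverage needed for center-overlap assignment.
    """
    seg = timing.records.copy()
    if bp_weighted:
        order = seg.sort_values("score")
        w = (order["end"] - order["start"]).cumsum()
        qs = [float(order["score"].iloc[np.searchsorted(w, w.iloc[-1] * f)])
              for f in (0.25, 0.5, 0.75)]
    else:
        qs = [float(seg["score"].quantile(f)) for f in (0.25, 0.5, 0.75)]
    seg["group"] = np.searchsorted(qs, seg["score"].to_numpy(), side="right")
    merged = []
    for (chrom, grp), sub in seg.groupby(["chrom", "group"]):
        m = merge_intervals(sub)
        m["group"] = grp
        m["score"] = float(sub["score"].mean())
        merged.append(m)
    out = pd.concat(merged, ignore_index=True)
    return AnnotationTrack("timing", out)


def category_density(events: pd.DataFrame, partition: pd.DataFrame,
                     category_col: str, per_bp: int = 100_000) -> pd.DataFrame:
    """Event density per category of a genome partition (events per 100 kb).

    Events are assigned by the overlap of their center with a partition
    interval; centers in coverage gaps are discarded and tallied.  Density is
    count / category bp x ``per_bp``; zero-length categories are excluded
    with a warning.
    """
    rows = []
    assigned = pd.Series(pd.NA, index=events.index, dtype="object")
    for chrom, sub in events.groupby("chrom", sort=False):
        p = partition[partition["chrom"] == chrom].sort_values("start")
        if not len(p):
            continue
        ps, pe = p["start"].to_numpy(), p["end"].to_numpy()
        cats = p[category_col].to_numpy()
        centers = sub["center"].to_numpy()
        idx = np.searchsorted(ps, centers, side="right") - 1
        ok = (idx >= 0) & (centers < pe[np.maximum(idx, 0)])
        vals = np.where(ok, cats[np.maximum(idx, 0)], None)
        assigned.loc[sub.index] = vals
    n_discarded = int(assigned.isna().sum())
    sizes = partition.assign(bp=partition["end"] - partition["start"]) \
        .groupby(category_col)["bp"].sum()
    counts = assigned.dropna().value_counts()
    for cat, bp in sizes.items():
        if bp <= 0:
            warnings.warn(f"category {cat!r} has zero mapped length; excluded", stacklevel=2)
            continue
        count = int(counts.get(cat, 0))
        rows.append((cat, count, int(bp), count / bp * per_bp))
    out = pd.DataFrame(rows, columns=["category", "count", "bp", "density"])
    out.attrs["n_discarded"] = n_discarded
    return out
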