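"""Origin/termination event statistics.

Raw origin and termination calls are standardized to uniform 200-bp events
around the call midpoint.  On top of that set: inter-event spacings,
between-replicate overlap, origin clustering, nearest-ORC-peak distances
with a randomized-placement null, and the repeated-sampling simulation that
estimates how many shared origins pure chance would produce when drawing a
dataset-sized sample from the pool of mappable origin positions.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "standardize_events",
    "inter_event_distances",
    "replicate_overlap",
    "jaccard_overlap",
    "expected_origin_count",
    "expected_overlap_simulation",
    "expected_repeats_closed_form",
    "origin_clusters",
    "nearest_peak_distances",
    "OverlapSimResult",
    "NearestDistanceResult",
]

EVENT_HALF_WIDTH = 100


def standardize_events(calls: pd.DataFrame, kind: str,
                       half_width: int = EVENT_HALF_WIDTH) -> pd.DataFrame:
    """Uniform fixed-width events centered on call midpoints.

    The center is ``floor((start + end) / 2)``; the event spans
    ``[center - half_width, center + half_width)`` (200 bp by default),
    clipped at 0 near chromosome starts with a ``clipped`` flag.
    """
    if kind not in ("origin", "termination"):
        raise ValueError(f"unknown event kind {kind!r}")
    center = (calls["start"] + calls["end"]) // 2
    start = center - half_width
    clipped = start < 0
    out = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": np.maximum(start, 0),
        "end": center + half_width,
        "center": center,
        "kind": kind,
        "clipped": clipped,
    })
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def inter_event_distances(events: pd.DataFrame) -> pd.DataFrame:
    """Consecutive midpoint spacings per chromosome, in kb.

    Chromosomes with fewer than two events contribute nothing; ordering of
    the input does not matter (midpoints are sorted per chromosome).
    """
    rows = []
    for chrom, sub in events.groupby("chrom", sort=True):
        mids = np.sort(sub["center"].to_numpy())
        if len(mids) < 2:
            continue
        d = np.diff(mids) / 1000.0
        rows.append(pd.DataFrame({"chrom": chrom, "distance_kb": d}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "distance_kb"])
    return pd.concat(rows, ignore_index=True)


def _any_intersection(a: pd.DataFrame, b: pd.DataFrame, expand_bp: int) -> np.ndarray:
    """Boolean per a-row: does its (expanded) interval hit any b interval?"""
    hits = np.zeros(len(a), dtype=bool)
    for chrom, sub_a in a.groupby("chrom", sort=False):
        sub_b = b[b["chrom"] == chrom]
        if not len(sub_b):
            continue
        bs = np.sort(sub_b["start"].to_numpy())
        be = np.sort(sub_b["end"].to_numpy())
        qs = sub_a["start"].to_numpy() - expand_bp
        qe = sub_a["end"].to_numpy() + expand_bp
        # number of b starting before the query end minus number ending at/before query start
        n_before_end = np.searchsorted(bs, qe, side="left")
        n_closed = np.searchsorted(be, qs, side="right")
        hits[a.index.get_indexer(sub_a.index)] = n_before_end > n_closed
    return hits


def replicate_overlap(events_a: pd.DataFrame, events_b: pd.DataFrame,
                      expand_bp: int = 0) -> int:
    """Count of A events whose (optionally expanded) interval intersects any B event."""
    return int(_any_intersection(events_a.reset_index(drop=True), events_b, expand_bp).sum())


def jaccard_overlap(events_a: pd.DataFrame, events_b: pd.DataFrame,
                    expand_bp: int = 0) -> float:
    """Symmetric overlap: shared / (|A| + |B| - shared) counting hits on each side."""
    a_hits = replicate_overlap(events_a, events_b, expand_bp)
    b_hits = replicate_overlap(events_b, events_a, expand_bp)
    shared = (a_hits + b_hits) / 2.0
    denom = len(events_a) + len(events_b) - shared
    return float(shared / denom) if denom else 0.0


def expected_origin_count(mappable_bp: int, spacing_bp: int) -> int:
    """How many origins fit in the mappable genome at a given average spacing."""
    if mappable_bp <= 0 or spacing_bp <= 0:
        raise ValueError("mappable size and spacing must be positive")
    n = mappable_bp // spacing_bp
    if n == 0:
        warnings.warn("mappable genome shorter than one spacing; expecting 0 origins",
                      stacklevel=2)
    return int(n)


@dataclass
class OverlapSimResult:
    n_sites: int
    n_draws: int
    n_sims: int
    mean_repeats: float
    sd_repeats: float
    repeats: np.ndarray  # per-simulation repeated-draw counts


def expected_repeats_closed_form(n_sites: int, n_draws: int) -> float:
    """E[draws - distinct] for uniform sampling with replacement (birthday collisions)."""
    m, n = n_sites, n_draws
    return n - m * (1.0 - (1.0 - 1.0 / m) ** n)


def expected_overlap_simulation(n_sites: int, n_draws: int, n_sims: int,
                                seed: int | np.random.Generator = 0) -> OverlapSimResult:
    """Repeated-sampling null for shared events.

    Each simulation draws ``n_draws`` site indices uniformly with replacement
    from ``n_sites`` candidate sites; a *repeat* is a draw landing on an
    already-drawn site (draws minus distinct sites).  The mean repeat count
    over ``n_sims`` simulations is the expected number of shared events under
    purely random, independent origin usage.
    """
    if min(n_sites, n_draws, n_sims) < 1:
        raise ValueError("n_sites, n_draws and n_sims must all be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.integers(0, n_sites, size=(n_sims, n_draws))
    draws.sort(axis=1)
    distinct = 1 + (np.diff(draws, axis=1) > 0).sum(axis=1)
    repeats = n_draws - distinct
    return OverlapSimResult(n_sites=n_sites, n_draws=n_draws, n_sims=n_sims,
                            mean_repeats=float(repeats.mean()),
                            sd_repeats=float(repeats.std(ddof=1)) if n_sims > 1 else 0.0,
                            repeats=repeats)


def origin_clusters(events: pd.DataFrame, window_bp: int = 40_000,
                    min_count: int = 3) -> float:
    """Fraction of events lying in some window of ``window_bp`` holding >= min_count events."""
    if not len(events):
        return 0.0
    clustered = 0
    for _chrom, sub in events.groupby("chrom", sort=False):
        mids = np.sort(sub["center"].to_numpy())
        n = len(mids)
        in_cluster = np.zeros(n, dtype=bool)
        j = 0
        for i in range(n):
            while mids[i] - mids[j] > window_bp:
                j += 1
            if i - j + 1 >= min_count:
                in_cluster[j:i + 1] = True
        clustered += int(in_cluster.sum())
    return clustered / len(events)


@dataclass
class NearestDistanceResult:
    observed: np.ndarray           # per-event nearest-peak distance, bp
    null: np.ndarray               # (n_perms, n_events) distances under random placement
    observed_median: float
    null_median: float
    observed_mean: float
    null_mean: float
    t_stat: float
    p_value: float

    def log10_observed(self) -> np.ndarray:
        return np.log10(self.observed + 1.0)

    def log10_null(self) -> np.ndarray:
        return np.log10(self.null + 1.0)


def _nearest(event_centers: np.ndarray, peak_centers: np.ndarray) -> np.ndarray:
    peaks = np.sort(peak_centers)
    idx = np.searchsorted(peaks, event_centers)
    left = np.where(idx > 0, np.abs(event_centers - peaks[np.maximum(idx - 1, 0)]), np.inf)
    right = np.where(idx < len(peaks), np.abs(peaks[np.minimum(idx, len(peaks) - 1)]
                                              - event_centers), np.inf)
    return np.minimum(left, right)


def nearest_peak_distances(events: pd.DataFrame, peaks: pd.DataFrame,
                           genome: dict[str, int], n_perms: int = 1000,
                           seed: int | np.random.Generator = 0) -> NearestDistanceResult:
    """Distance from each event center to the nearest peak midpoint, with a null.

    The null re-places the same number of events per chromosome uniformly at
    random, ``n_perms`` times.  Means of observed vs pooled null distances
    are compared with a two-sided Student's t-test.  Events on chromosomes
    without any peak are excluded with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peak_mid = peaks.assign(center=(peaks["start"] + peaks["end"]) // 2)
    obs_parts, null_parts = [], []
    for chrom in sorted(events["chrom"].unique()):
        ev = events[events["chrom"] == chrom]
        pk = peak_mid[peak_mid["chrom"] == chrom]
        if not len(pk):
            warnings.warn(f"no peaks on {chrom}; {len(ev)} events excluded", stacklevel=2)
            continue
        centers = ev["center"].to_numpy()
        pcenters = np.sort(pk["center"].to_numpy())
        obs_parts.append(_nearest(centers, pcenters))
        rand = rng.integers(0, genome[chrom], size=(n_perms, len(centers)))
        nulls = np.abs(rand[..., None] - pcenters[None, None, :]).min(axis=2) \
            if len(pcenters) * len(centers) * n_perms <= 2_000_000 else None
        if nulls is None:  # large case: searchsorted per permutation
            nulls = np.vstack([_nearest(row, pcenters) for row in rand])
        null_parts.append(nulls)
    if not obs_parts:
        raise ValueError("no events share a chromosome with the peak set")
    observed = np.concatenate(obs_parts)
    null = np.hstack(null_parts)
    t_stat, p_value = sps.ttest_ind(observed, null.ravel(), equal_var=False)
    return NearestDistanceResult(
        observed=observed, null=null,
        observed_median=float(np.median(observed)), null_median=float(np.median(null)),
        observed_mean=float(observed.mean()), null_mean=float(null.mean()),
        t_stat=float(t_stat), p_value=float(p_value))
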