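"""Pulse-label replication-fork simulator with known ground truth.

Emulates the single-molecule readout of a sequential analog-labeling design:
cells incorporate EdU for a short pulse, then BrdU for a longer pulse, so
each replication fork deposits an ordered EdU→BrdU segment pair on the
nascent strand.  Rightward forks carry BrdU 3' of EdU in genome coordinates;
diverging fork pairs share an origin (EdU segments interior) and converging
forks define a termination where their fronts meet.

The model:

* Origins are a homogeneous Poisson process per replication-timing domain
  (intensity scaled per timing group), restricted to a margin away from
  chromosome ends so labeled segments stay interior.
* All origins fire at time zero; each fork moves at a constant speed drawn
  from the chromatin state at its origin times lognormal noise.
* Converging fronts stop where they meet (speed-weighted midpoint); a
  termination is called only if the meeting falls within the BrdU phase —
  earlier meetings leave no BrdU continuity and are not called.
* Each emitted fork becomes one sequenced molecule.  Quality defects are
  injected mutually exclusively per fork: a negative stall code (−1
  termination, −2 segmentation error, −3 read end, −4 indel proximity) or a
  BrdU-at-read-end truncation, at configured rates.
* Optional per-region rightward-fork bias: inside a bias region exactly one
  fork of each pair is emitted (rightward with probability p), planting a
  window directionality of 2p−1; elsewhere both forks are emitted.

Companion annotation tracks (chromatin states 0–9, replication-timing
segments with scores and groups 0–3, genes with strand and RPKM, ORC-like
peaks offset from true origins, blacklist) are generated from the same seed
so every downstream analysis is exercisable with known truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io_bed import AnnotationTrack, ForkRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Annotations",
    "SimResult",
    "simulate_replication",
    "emit_annotations",
    "simulate_dataset",
]

EU_STATES = frozenset({1, 2, 3, 4, 5})
HET_STATES = frozenset({0, 6, 7, 8})
SILENT_STATES = frozenset({9})


def _default_speeds() -> dict[int, float]:
    # heterochromatic states run ~1.25x faster than euchromatic ones, the
    # silent state in between; euchromatin anchored near the bulk fork rate
    speeds = {s: 970.0 for s in EU_STATES}
    speeds.update({s: 1212.5 for s in HET_STATES})
    speeds[9] = 1090.0
    return speeds


def _default_stall_rates() -> dict[int, float]:
    return {-1: 0.07, -2: 0.03, -3: 0.05, -4: 0.03}


def _default_timing_multipliers() -> dict[int, float]:
    # earliest-firing domains carry ~2x the origin intensity of the latest
    return {0: 1.33, 1: 1.11, 2: 0.89, 3: 0.67}


def _default_timing_scores() -> dict[int, float]:
    return {0: 3.0, 1: 2.0, 2: 1.2, 3: 0.5}


@dataclass
class SimulationConfig:
    """All tunables of the simulator; defaults give a minutes-scale toy genome."""

    genome: tuple = (("chrSimI", 5_000_000), ("chrSimII", 5_000_000))
    seed: int = 0
    # pulse schedule, minutes
    edu_minutes: float = 7.0
    brdu_minutes: float = 15.0
    chase_minutes: float = 0.0
    # fork kinematics, bp/min per chromatin state
    per_state_fork_speed: dict = field(default_factory=_default_speeds)
    speed_noise_sd: float = 0.05  # lognormal sigma on per-fork speed
    min_analog_bp: int = 200  # shorter analog segments are not callable
    # origin placement
    origin_rate_per_bp: float = 1.0 / 50_000
    origin_rate_timing_multiplier: dict = field(default_factory=_default_timing_multipliers)
    # optional (chrom, start, end, p_rightward) fork-direction bias regions
    rfd_bias: tuple = ()
    # read-length model (lognormal with a detection floor)
    read_length_median_bp: float = 50_000.0
    read_length_sigma: float = 0.6
    read_length_min_bp: int = 15_000
    # injected defects
    stall_code_rates: dict = field(default_factory=_default_stall_rates)
    truncation_rate: float = 0.35
    # annotation generation
    state_block_mean_bp: float = 50_000.0
    state_weights: dict = field(default_factory=lambda: {
        0: 0.08, 1: 0.09, 2: 0.09, 3: 0.09, 4: 0.09,
        5: 0.09, 6: 0.09, 7: 0.10, 8: 0.08, 9: 0.20})
    timing_domain_mean_bp: float = 250_000.0
    timing_segment_bp: int = 100
    timing_group_scores: dict = field(default_factory=_default_timing_scores)
    timing_score_sd: float = 0.15
    gene_gap_mean_bp: float = 3_000.0
    gene_length_median_bp: float = 2_000.0
    gene_length_sigma: float = 0.6
    zero_rpkm_fraction: float = 0.3
    orc_offset_median_bp: float = 6_309.0
    orc_link_fraction: float = 1.0
    orc_peak_width_bp: int = 500
    orc_background_rate_per_bp: float = 1.0 / 500_000
    blacklist_n_per_chrom: int = 2
    blacklist_length_bp: int = 20_000

    @property
    def total_minutes(self) -> float:
        return self.edu_minutes + self.chase_minutes + self.brdu_minutes

    def genome_dict(self) -> dict[str, int]:
        return {name: int(length) for name, length in self.genome}

    def max_speed(self) -> float:
        return max(self.per_state_fork_speed.values()) * math.exp(4 * self.speed_noise_sd)

    def margin_bp(self) -> int:
        return int(self.max_speed() * self.total_minutes * 1.2)

    def validate(self) -> None:
        if not self.genome:
            raise ValueError("genome must contain at least one chromosome")
        for name, length in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has nonpositive length")
        for v in (self.edu_minutes, self.brdu_minutes):
            if v <= 0:
                raise ValueError("pulse durations must be positive")
        if self.chase_minutes < 0:
            raise ValueError("chase duration must be nonnegative")
        if any(v <= 0 for v in self.per_state_fork_speed.values()):
            raise ValueError("fork speeds must be positive")
        probs = [self.truncation_rate, self.zero_rpkm_fraction, self.orc_link_fraction,
                 *self.stall_code_rates.values()]
        probs += [p for *_x, p in self.rfd_bias]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.stall_code_rates.values()) + self.truncation_rate > 1:
            raise ValueError("defect rates sum above 1")
        shortest = min(length for _n, length in self.genome)
        if 2 * self.margin_bp() >= shortest:
            raise ValueError(
                "degenerate genome: speeds x durations exceed chromosome length "
                f"(need > {2 * self.margin_bp()} bp, shortest chromosome {shortest} bp)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["rfd_bias"] = [list(r) for r in self.rfd_bias]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["genome"] = tuple(tuple(g) for g in d.get("genome", ()))
        d["rfd_bias"] = tuple(tuple(r) for r in d.get("rfd_bias", ()))
        for key in ("per_state_fork_speed", "state_weights", "origin_rate_timing_multiplier",
                    "timing_group_scores"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        if "stall_code_rates" in d:
            d["stall_code_rates"] = {int(k): float(v) for k, v in d["stall_code_rates"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """What the simulator actually planted, for recovery checks."""

    origins: pd.DataFrame          # chrom, pos, t_fire
    terminations: pd.DataFrame     # chrom, pos
    per_track_speed: dict          # read_id -> bp/min
    planted_rfd: pd.DataFrame      # chrom, start, end, p_right (bias regions only)
    origin_linked_read_ids: frozenset
    clipped_read_ids: frozenset    # forks stopped by a collision before pulse end
    injected_defects: dict         # reason -> count over emitted forks

    def write(self, directory) -> None:
        import os
        os.makedirs(directory, exist_ok=True)
        self.origins.to_csv(f"{directory}/truth_origins.tsv", sep="\t", index=False)
        self.terminations.to_csv(f"{directory}/truth_terminations.tsv", sep="\t", index=False)
        pd.DataFrame({"read_id": list(self.per_track_speed),
                      "speed_bp_per_min": list(self.per_track_speed.values())}
                     ).to_csv(f"{directory}/truth_speeds.tsv", sep="\t", index=False)
        pd.DataFrame({"reason": list(self.injected_defects),
                      "count": list(self.injected_defects.values())}
                     ).to_csv(f"{directory}/truth_defects.tsv", sep="\t", index=False)


@dataclass
class Annotations:
    states: AnnotationTrack
    timing: AnnotationTrack
    genes: AnnotationTrack
    orc_peaks: AnnotationTrack
    blacklist: AnnotationTrack
    timing_domains: pd.DataFrame  # chrom, start, end, group (pre-segmentation)


@dataclass
class SimResult:
    records: list
    origin_calls: pd.DataFrame
    termination_calls: pd.DataFrame
    truth: GroundTruth
    annotations: Annotations


# ---------------------------------------------------------------------------
# generation helpers


def _tile_blocks(rng, length, mean_bp, min_bp):
    """Consecutive block lengths (exponential, floored) tiling [0, length)."""
    lengths = []
    total = 0
    while total < length:
        block = max(min_bp, int(rng.exponential(mean_bp)))
        lengths.append(block)
        total += block
    starts = np.concatenate([[0], np.cumsum(lengths[:-1])]).astype(np.int64)
    ends = np.minimum(starts + np.array(lengths, dtype=np.int64), length)
    return starts, ends


def _gen_annotations(cfg: SimulationConfig, rng) -> Annotations:
    genome = cfg.genome_dict()
    state_ids = sorted(cfg.state_weights)
    weights = np.array([cfg.state_weights[s] for s in state_ids], dtype=float)
    weights = weights / weights.sum()

    state_rows, domain_rows, seg_rows, gene_rows, black_rows = [], [], [], [], []
    for chrom, length in genome.items():
        # chromatin states
        starts, ends = _tile_blocks(rng, length, cfg.state_block_mean_bp, 5_000)
        states = rng.choice(state_ids, size=len(starts), p=weights)
        state_rows.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "state": states}))
        # timing domains + ~100 bp scored segments
        dstarts, dends = _tile_blocks(rng, length, cfg.timing_domain_mean_bp, 30_000)
        groups = rng.integers(0, 4, size=len(dstarts))
        domain_rows.append(pd.DataFrame(
            {"chrom": chrom, "start": dstarts, "end": dends, "group": groups}))
        for ds, de, g in zip(dstarts, dends, groups):
            seg_starts = np.arange(ds, de, cfg.timing_segment_bp, dtype=np.int64)
            seg_ends = np.minimum(seg_starts + cfg.timing_segment_bp, de)
            scores = cfg.timing_group_scores[int(g)] + rng.normal(
                0.0, cfg.timing_score_sd, size=len(seg_starts))
            seg_rows.append(pd.DataFrame(
                {"chrom": chrom, "start": seg_starts, "end": seg_ends,
                 "score": np.maximum(scores, 1e-3), "group": int(g)}))
        # genes; the zero-RPKM fraction is constructed exactly (rounded count)
        pos, gid = 0, 0
        rows = []
        while True:
            gap = max(200, int(rng.exponential(cfg.gene_gap_mean_bp)))
            glen = max(200, int(rng.lognormal(math.log(cfg.gene_length_median_bp),
                                              cfg.gene_length_sigma)))
            if pos + gap + glen > length:
                break
            start = pos + gap
            strand = "+" if rng.random() < 0.5 else "-"
            rpkm = float(rng.lognormal(math.log(5.0), 1.2))
            rows.append((chrom, start, start + glen, f"{chrom}_g{gid:05d}", strand, rpkm))
            pos = start + glen
            gid += 1
        genes_df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "strand", "rpkm"])
        n_zero = int(round(cfg.zero_rpkm_fraction * len(genes_df)))
        if n_zero:
            zero_idx = rng.choice(len(genes_df), size=n_zero, replace=False)
            genes_df.loc[zero_idx, "rpkm"] = 0.0
        gene_rows.append(genes_df)
        # blacklist
        if cfg.blacklist_n_per_chrom > 0:
            bl_starts = rng.integers(0, max(1, length - cfg.blacklist_length_bp),
                                     size=cfg.blacklist_n_per_chrom)
            black_rows.append(pd.DataFrame(
                {"chrom": chrom, "start": np.sort(bl_starts),
                 "end": np.sort(bl_starts) + cfg.blacklist_length_bp}))

    states = AnnotationTrack("chromatin_state", pd.concat(state_rows, ignore_index=True))
    timing = AnnotationTrack("timing", pd.concat(seg_rows, ignore_index=True))
    genes = AnnotationTrack("genes", pd.concat(gene_rows, ignore_index=True))
    blacklist = AnnotationTrack("blacklist", pd.concat(black_rows, ignore_index=True)
                                if black_rows else pd.DataFrame(columns=["chrom", "start", "end"]))
    domains = pd.concat(domain_rows, ignore_index=True)
    # ORC peaks are origin-dependent; filled in by the core driver
    orc = AnnotationTrack("peaks", pd.DataFrame(columns=["chrom", "start", "end"]))
    return Annotations(states, timing, genes, orc, blacklist, domains)


def _place_origins(cfg: SimulationConfig, ann: Annotations, rng) -> dict[str, np.ndarray]:
    genome = cfg.genome_dict()
    margin = cfg.margin_bp()
    out = {}
    for chrom, length in genome.items():
        lo, hi = margin, length - margin
        doms = ann.timing_domains[ann.timing_domains["chrom"] == chrom]
        positions = []
        for _, d in doms.iterrows():
            s, e = max(int(d["start"]), lo), min(int(d["end"]), hi)
            if e <= s:
                continue
            lam = cfg.origin_rate_per_bp * cfg.origin_rate_timing_multiplier[int(d["group"])]
            n = rng.poisson(lam * (e - s))
            if n:
                positions.append(rng.integers(s, e, size=n))
        pos = np.sort(np.concatenate(positions)) if positions else np.empty(0, dtype=np.int64)
        # coincident origins would produce zero-length gaps; nudge duplicates
        pos = np.unique(pos)
        out[chrom] = pos.astype(np.int64)
    return out


def _state_lookup(states_df: pd.DataFrame, chrom: str):
    sub = states_df[states_df["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    vals = sub["state"].to_numpy()

    def lookup(x):
        return int(vals[np.searchsorted(starts, x, side="right") - 1])

    return lookup


def _bias_lookup(cfg: SimulationConfig, chrom: str):
    regions = [(s, e, p) for c, s, e, p in cfg.rfd_bias if c == chrom]

    def lookup(x):
        for s, e, p in regions:
            if s <= x < e:
                return p
        return None

    return lookup


def _gen_orc(cfg: SimulationConfig, origins: dict[str, np.ndarray], rng) -> AnnotationTrack:
    genome = cfg.genome_dict()
    half = cfg.orc_peak_width_bp // 2
    scale = cfg.orc_offset_median_bp / math.log(2)
    rows = []
    for chrom, length in genome.items():
        centers = []
        for x in origins[chrom]:
            if rng.random() < cfg.orc_link_fraction:
                off = rng.exponential(scale) * (1 if rng.random() < 0.5 else -1)
                centers.append(int(np.clip(x + off, half, length - half)))
        n_bg = rng.poisson(cfg.orc_background_rate_per_bp * length)
        if n_bg:
            centers.extend(int(c) for c in rng.integers(half, length - half, size=n_bg))
        for c in sorted(centers):
            rows.append((chrom, c - half, c + half))
    return AnnotationTrack("peaks", pd.DataFrame(rows, columns=["chrom", "start", "end"])
                           if rows else pd.DataFrame(columns=["chrom", "start", "end"]))


def _simulate_core(cfg: SimulationConfig) -> SimResult:
    cfg.validate()
    genome = cfg.genome_dict()
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    r_ann, r_orig, r_fork, r_read, r_defect, r_orc = map(np.random.default_rng, streams)

    ann = _gen_annotations(cfg, r_ann)
    origins = _place_origins(cfg, ann, r_orig)
    ann.orc_peaks = _gen_orc(cfg, origins, r_orc)

    t_e, t_c, t_b = cfg.edu_minutes, cfg.chase_minutes, cfg.brdu_minutes
    t_total = cfg.total_minutes
    defect_kinds = [f"stall_{c}" for c in sorted(cfg.stall_code_rates, reverse=True)]
    defect_probs = [cfg.stall_code_rates[c] for c in sorted(cfg.stall_code_rates, reverse=True)]
    defect_kinds.append("brdu_at_read_end")
    defect_probs.append(cfg.truncation_rate)
    cum_probs = np.cumsum(defect_probs)

    records: list[ForkRecord] = []
    origin_call_rows, term_call_rows, term_truth_rows = [], [], []
    truth_origin_rows = []
    per_track_speed: dict[str, float] = {}
    clipped: list[str] = []
    injected = {k: 0 for k in defect_kinds}
    injected["clean"] = 0

    for chrom, length in genome.items():
        xs = origins[chrom]
        truth_origin_rows.extend((chrom, int(x), 0.0) for x in xs)
        if len(xs) == 0:
            continue
        state_of = _state_lookup(ann.states.records, chrom)
        bias_of = _bias_lookup(cfg, chrom)
        base = np.array([cfg.per_state_fork_speed[state_of(x)] for x in xs])
        noise = np.exp(r_fork.normal(0.0, cfg.speed_noise_sd, size=(len(xs), 2)))
        v_l, v_r = base * noise[:, 0], base * noise[:, 1]

        # meeting times between the right fork of i and the left fork of i+1
        gaps = np.diff(xs).astype(float)
        t_meet = np.full(len(xs), np.inf)  # index i: meeting in gap (i, i+1)
        if len(xs) > 1:
            t_meet[:-1] = gaps / (v_r[:-1] + v_l[1:])

        for i, x in enumerate(xs):
            x = float(x)
            tau_r = min(t_total, t_meet[i])
            tau_l = min(t_total, t_meet[i - 1]) if i > 0 else t_total

            def segments(v, tau, sign):
                """EdU and BrdU genomic intervals for one fork (sign +1 right, -1 left)."""
                len_e = v * min(tau, t_e)
                len_b = v * max(0.0, min(tau, t_total) - t_e - t_c)
                if sign > 0:
                    edu = (x, x + len_e)
                    bs = x + v * (t_e + t_c)
                    brdu = (bs, bs + len_b) if len_b > 0 else (edu[1], edu[1])
                else:
                    edu = (x - len_e, x)
                    bs = x - v * (t_e + t_c)
                    brdu = (bs - len_b, bs) if len_b > 0 else (edu[0], edu[0])
                return (tuple(int(round(p)) for p in edu),
                        tuple(int(round(p)) for p in brdu))

            (edu_l, brdu_l) = segments(v_l[i], tau_l, -1)
            (edu_r, brdu_r) = segments(v_r[i], tau_r, +1)

            keep = {}
            for d, edu, brdu, v, tau in (("L", edu_l, brdu_l, v_l[i], tau_l),
                                         ("R", edu_r, brdu_r, v_r[i], tau_r)):
                ok = (edu[1] - edu[0] >= cfg.min_analog_bp
                      and brdu[1] - brdu[0] >= cfg.min_analog_bp)
                keep[d] = (ok, edu, brdu, v, tau)

            p_bias = bias_of(x)
            emit = ["L", "R"]
            if p_bias is not None:
                emit = ["R"] if r_fork.random() < p_bias else ["L"]

            emitted = []
            for d in emit:
                ok, edu, brdu, v, tau = keep[d]
                if not ok:
                    continue
                read_id = f"{chrom}_{i:05d}_{d}"
                rec = _emit_read(cfg, chrom, length, read_id, d, edu, brdu,
                                 cum_probs, defect_kinds, injected, r_read, r_defect)
                records.append(rec)
                per_track_speed[read_id] = float(v)
                if tau < t_total:
                    clipped.append(read_id)
                emitted.append(d)

            # an origin call needs both diverging forks on the molecule
            if emit == ["L", "R"] and len(emitted) == 2:
                w = int(r_fork.integers(100, 401))
                origin_call_rows.append((chrom, int(x) - w, int(x) + w))

            # termination between this origin and the next
            if i < len(xs) - 1 and t_e + t_c < t_meet[i] <= t_total:
                m = int(round(x + v_r[i] * t_meet[i]))
                term_truth_rows.append((chrom, m))
                w = int(r_fork.integers(100, 401))
                term_call_rows.append((chrom, max(0, m - w), min(length, m + w)))

    truth = GroundTruth(
        origins=pd.DataFrame(truth_origin_rows, columns=["chrom", "pos", "t_fire"]),
        terminations=pd.DataFrame(term_truth_rows, columns=["chrom", "pos"]),
        per_track_speed=per_track_speed,
        planted_rfd=pd.DataFrame(list(cfg.rfd_bias),
                                 columns=["chrom", "start", "end", "p_right"]),
        origin_linked_read_ids=frozenset(per_track_speed),
        clipped_read_ids=frozenset(clipped),
        injected_defects=injected,
    )
    origin_calls = pd.DataFrame(origin_call_rows, columns=["chrom", "start", "end"])
    termination_calls = pd.DataFrame(term_call_rows, columns=["chrom", "start", "end"])
    return SimResult(records, origin_calls, termination_calls, truth, ann)


def _emit_read(cfg, chrom, chrom_len, read_id, direction, edu, brdu,
               cum_probs, defect_kinds, injected, r_read, r_defect):
    span_start = min(edu[0], brdu[0])
    span_end = max(edu[1], brdu[1])
    span = span_end - span_start

    read_len = int(round(r_read.lognormal(math.log(cfg.read_length_median_bp),
                                          cfg.read_length_sigma)))
    read_len = max(read_len, cfg.read_length_min_bp, span + 2)
    read_len = min(read_len, chrom_len)
    slack = read_len - span
    left_pad = 1 + int(r_read.random() * (slack - 1))
    read_start = span_start - left_pad
    read_end = read_start + read_len
    if read_start < 0:
        read_end -= read_start
        read_start = 0
    if read_end > chrom_len:
        read_start -= read_end - chrom_len
        read_end = chrom_len
    strand = "+" if r_read.random() < 0.5 else "-"

    u = r_defect.random()
    u_score = r_defect.random()
    k = int(np.searchsorted(cum_probs, u, side="right"))
    stall_score = float(u_score)
    if k < len(defect_kinds):
        kind = defect_kinds[k]
        injected[kind] += 1
        if kind.startswith("stall_"):
            stall_score = float(int(kind.split("_")[1]))
        else:  # BrdU truncated at a molecule end
            if direction == "R":
                read_end = brdu[1]
            else:
                read_start = brdu[0]
    else:
        injected["clean"] += 1

    rec = ForkRecord(
        chrom=chrom, fork_start=span_start, fork_end=span_end, read_id=read_id,
        read_start=read_start, read_end=read_end, direction=direction, strand=strand,
        edu_start=edu[0], edu_end=edu[1], brdu_start=brdu[0], brdu_end=brdu[1],
        stall_score=stall_score)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# public operations


def simulate_dataset(config: SimulationConfig) -> SimResult:
    """Run the full generator: fork records, event calls, truth and annotations."""
    return _simulate_core(config)


def simulate_replication(config: SimulationConfig):
    """Simulate pulse-labeled molecules.

    Returns ``(fork_records, origin_calls, termination_calls, ground_truth)``;
    deterministic under a fixed ``config.seed``.
    """
    res = _simulate_core(config)
    return res.records, res.origin_calls, res.termination_calls, res.truth


def emit_annotations(config: SimulationConfig) -> Annotations:
    """Generate the companion annotation tracks for the same seed/config.

    Consistent with :func:`simulate_replication` for an identical config: the
    ORC peaks are offset from the same planted origins.
    """
    return _simulate_core(config).annotations
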