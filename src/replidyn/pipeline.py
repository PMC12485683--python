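"""End-to-end orchestration: simulate -> QC -> windows -> events -> integration -> enrichment.

One global seed is fanned out to stage-indexed substreams, so stages are
reproducible in isolation and the whole run is checksum-stable.  Every stage
writes plain-text outputs (BED/bedgraph/TSV/JSON) plus a manifest recording
parameters, per-stage record counts and file checksums.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotation, enrichment, events, qc, transcription, windows
from .io_bed import fork_frame, write_fork_bed, write_genome, write_track
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "qc", "windows", "events", "chromatin", "timing",
          "transcription", "enrichment")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    bin_size: int = 100_000
    timing_window_bp: int = 30_000
    retain_initiation: bool = True
    n_perms: int = 200
    n_factors: int = 8
    stages: tuple = STAGES

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("simulation", None)
        cfg = cls(**d)
        if sim is not None:
            sim["genome"] = tuple(tuple(g) for g in sim.get("genome", ()))
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    sim_cfg = config.simulation or SimulationConfig(seed=_stage_seed(config.seed, "simulate"))
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": {"bin_size": config.bin_size,
                                     "timing_window_bp": config.timing_window_bp,
                                     "n_perms": config.n_perms},
                      "stages": {}, "files": {}}

    def emit(name, path):
        manifest["files"][name] = _checksum(path)

    def stage_done(name, **counts):
        manifest["stages"][name] = {"status": "complete", **counts}

    try:
        # --- simulate -----------------------------------------------------
        res = simulate_dataset(sim_cfg)
        genome = sim_cfg.genome_dict()
        write_fork_bed(res.records, f"{out}/forks.bed")
        res.origin_calls.to_csv(f"{out}/origin_calls.bed", sep="\t", header=False, index=False)
        res.termination_calls.to_csv(f"{out}/termination_calls.bed", sep="\t",
                                     header=False, index=False)
        for name, track in (("states", res.annotations.states),
                            ("timing", res.annotations.timing),
                            ("genes", res.annotations.genes),
                            ("orc_peaks", res.annotations.orc_peaks),
                            ("blacklist", res.annotations.blacklist)):
            write_track(track, f"{out}/{name}.bed")
            emit(f"{name}.bed", f"{out}/{name}.bed")
        write_genome(genome, f"{out}/genome.tsv")
        res.truth.write(f"{out}/truth")
        sim_cfg.to_yaml(f"{out}/simulation.yaml")
        for f in ("forks.bed", "origin_calls.bed", "termination_calls.bed", "genome.tsv"):
            emit(f, f"{out}/{f}")
        stage_done("simulate", n_forks=len(res.records),
                   n_origin_calls=len(res.origin_calls),
                   n_termination_calls=len(res.termination_calls))
        if config.stages == ("simulate",):
            return _finish(manifest, out)

        # --- qc -----------------------------------------------------------
        filt = qc.filter_forks(res.records,
                               origin_linked=res.truth.origin_linked_read_ids,
                               retain_initiation=config.retain_initiation)
        write_fork_bed(filt.retained, f"{out}/forks_retained.bed")
        qc.qc_report(filt).to_csv(f"{out}/qc_report.tsv", sep="\t", index=False)
        metrics = qc.track_metrics(filt.retained)
        metrics.to_csv(f"{out}/track_metrics.tsv", sep="\t", index=False)
        emit("forks_retained.bed", f"{out}/forks_retained.bed")
        emit("qc_report.tsv", f"{out}/qc_report.tsv")
        stage_done("qc", n_in=len(res.records), n_retained=len(filt.retained),
                   n_rejected=len(filt.rejected))

        # --- windows --------------------------------------------------------
        forks_all = windows.fork_windows_input(res.records)  # unfiltered, per convention
        std_origins = events.standardize_events(res.origin_calls, "origin")
        std_terms = events.standardize_events(res.termination_calls, "termination")
        wstats = windows.window_stats(forks_all, genome, config.bin_size,
                                      origins=std_origins, terminations=std_terms)
        wstats.to_csv(f"{out}/window_stats.tsv", sep="\t", index=False)
        windows.write_bedgraph(wstats, "rfd", f"{out}/rfd.bedgraph")
        cov = windows.chromosome_coverage(forks_all, genome)
        cov.to_csv(f"{out}/chromosome_coverage.tsv", sep="\t", header=["coverage"])
        emit("window_stats.tsv", f"{out}/window_stats.tsv")
        emit("rfd.bedgraph", f"{out}/rfd.bedgraph")
        stage_done("windows", n_windows=len(wstats))

        # --- events ---------------------------------------------------------
        std_origins.to_csv(f"{out}/origins_200bp.bed", sep="\t", header=False, index=False)
        std_terms.to_csv(f"{out}/terminations_200bp.bed", sep="\t", header=False, index=False)
        dists_o = events.inter_event_distances(std_origins)
        dists_t = events.inter_event_distances(std_terms)
        dists_o.to_csv(f"{out}/inter_origin_kb.tsv", sep="\t", index=False)
        dists_t.to_csv(f"{out}/inter_termination_kb.tsv", sep="\t", index=False)
        clustered = events.origin_clusters(std_origins)
        near = events.nearest_peak_distances(
            std_origins, res.annotations.orc_peaks.records, genome,
            n_perms=min(config.n_perms, 200),
            seed=_stage_seed(config.seed, "events"))
        with open(f"{out}/events_summary.json", "w") as fh:
            json.dump({"n_origins": len(std_origins), "n_terminations": len(std_terms),
                       "median_inter_origin_kb": float(dists_o["distance_kb"].median())
                       if len(dists_o) else None,
                       "median_inter_termination_kb": float(dists_t["distance_kb"].median())
                       if len(dists_t) else None,
                       "clustered_origin_fraction": clustered,
                       "origin_orc_median_bp": near.observed_median,
                       "origin_orc_null_median_bp": near.null_median}, fh, indent=1)
        emit("events_summary.json", f"{out}/events_summary.json")
        stage_done("events", n_origins=len(std_origins), n_terminations=len(std_terms))

        # --- chromatin -----------------------------------------------------
        tracks = annotation.brdu_intervals(filt.retained)
        assigned = annotation.assign_state_containment(tracks, res.annotations.states)
        assigned.to_csv(f"{out}/brdu_state_assignment.tsv", sep="\t", index=False)
        by_cat = {c: sub["length"].to_numpy()
                  for c, sub in assigned.dropna(subset=["category"]).groupby("category")
                  if len(sub)}
        if len(by_cat) >= 2:
            comp = annotation.compare_groups(by_cat)
            comp.summary.to_csv(f"{out}/chromatin_group_summary.tsv", sep="\t", index=False)
            comp.pairwise.to_csv(f"{out}/chromatin_group_tests.tsv", sep="\t", index=False)
        quint = annotation.quintile_composition(tracks, res.annotations.states, genome)
        quint.to_csv(f"{out}/quintile_composition.tsv", sep="\t", index=False)
        state_partition = res.annotations.states.records.assign(
            category=res.annotations.states.records["state"].map(annotation.STATE_CATEGORY))
        dens = annotation.category_density(std_origins, state_partition, "category")
        dens.to_csv(f"{out}/origin_density_by_category.tsv", sep="\t", index=False)
        emit("brdu_state_assignment.tsv", f"{out}/brdu_state_assignment.tsv")
        stage_done("chromatin", n_assigned=int(assigned["state"].notna().sum()))

        # --- timing --------------------------------------------------------
        twin = annotation.timing_windows(res.annotations.timing, genome,
                                         config.timing_window_bp)
        twin.to_csv(f"{out}/timing_windows.tsv", sep="\t", index=False)
        mapped = annotation.assign_track_to_window(tracks, twin)
        ok = mapped["window_idx"] >= 0
        r, p, n, n_excl = annotation.timing_correlation(
            mapped.loc[ok, "length"],
            twin.loc[mapped.loc[ok, "window_idx"], "mean_score"].to_numpy())
        with open(f"{out}/timing_correlation.json", "w") as fh:
            json.dump({"pearson_r": r, "p_value": p, "n": n, "n_excluded": n_excl}, fh)
        quart = annotation.timing_quartiles(res.annotations.timing)
        tdens = annotation.category_density(std_origins, quart.records, "group")
        tdens.to_csv(f"{out}/origin_density_by_timing_quartile.tsv", sep="\t", index=False)
        emit("timing_windows.tsv", f"{out}/timing_windows.tsv")
        stage_done("timing", n_windows=len(twin), n_tracks_mapped=int(ok.sum()))

        # --- transcription -------------------------------------------------
        expr = transcription.assign_expression(tracks, res.annotations.genes.records)
        expr["category"] = assigned["category"]
        expr.to_csv(f"{out}/track_expression.tsv", sep="\t", index=False)
        corr = transcription.expression_correlations(expr)
        corr.to_csv(f"{out}/expression_correlations.tsv", sep="\t", index=False)
        emit("expression_correlations.tsv", f"{out}/expression_correlations.tsv")
        stage_done("transcription",
                   n_qualifying=int(expr["mean_rpkm"].notna().sum()))

        # --- enrichment ----------------------------------------------------
        rng = np.random.default_rng(_stage_seed(config.seed, "enrichment"))
        factors = _synthetic_factor_panel(genome, std_origins, config.n_factors, rng)
        panel = enrichment.enrichment_panel(
            factors, std_origins, genome, n_perms=config.n_perms,
            blacklist=res.annotations.blacklist.records,
            seed=_stage_seed(config.seed, "enrichment_perms"))
        panel.to_csv(f"{out}/enrichment_origins.tsv", sep="\t", index=False)
        emit("enrichment_origins.tsv", f"{out}/enrichment_origins.tsv")
        stage_done("enrichment", n_factors=len(panel))
    except Exception as exc:  # pragma: no cover - re-raised with stage context
        failed = [s for s in STAGES if s not in manifest["stages"]]
        raise RuntimeError(f"pipeline failed in stage {failed[0] if failed else '?'}: {exc}"
                           ) from exc
    return _finish(manifest, out)


def _finish(manifest, out):
    with open(f"{out}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _synthetic_factor_panel(genome, origin_events, n_factors, rng):
    """Demonstration factor panel: random peak sets plus one origin-tracking factor."""
    factors = {}
    for i in range(max(0, n_factors - 1)):
        rows = []
        for chrom, length in genome.items():
            n = 1 + rng.poisson(length / 500_000)
            starts = rng.integers(0, length - 1_000, size=n)
            rows.append(pd.DataFrame({"chrom": chrom, "start": np.sort(starts),
                                      "end": np.sort(starts) + 1_000}))
        factors[f"random_{i:02d}"] = pd.concat(rows, ignore_index=True)
    if n_factors >= 1 and len(origin_events):
        near = origin_events.copy()
        near["start"] = np.maximum(0, near["center"] - 500)
        near["end"] = near["center"] + 500
        factors["origin_proximal"] = near[["chrom", "start", "end"]]
    return factors
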