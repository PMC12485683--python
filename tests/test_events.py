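import numpy as np
import pandas as pd
import pytest

from replidyn.events import (expected_origin_count, expected_overlap_simulation,
                             expected_repeats_closed_form, inter_event_distances,
                             nearest_peak_distances, origin_clusters,
                             replicate_overlap, standardize_events)

from conftest import random_intervals


def overlap_oracle(a, b, expand):
    """All-pairs O(n^2) intersection count of A events against B."""
    count = 0
    for _, ra in a.iterrows():
        for _, rb in b.iterrows():
            if ra["chrom"] == rb["chrom"] and \
                    ra["start"] - expand < rb["end"] and rb["start"] < ra["end"] + expand:
                count += 1
                break
    return count


def clusters_oracle(events, window_bp, min_count):
    """Exhaustive pair scan marking all runs of >= min_count within window_bp."""
    clustered = 0
    total = 0
    for _chrom, sub in events.groupby("chrom"):
        mids = np.sort(sub["center"].to_numpy())
        total += len(mids)
        flags = np.zeros(len(mids), dtype=bool)
        for j in range(len(mids)):
            for k in range(j, len(mids)):
                if mids[k] - mids[j] <= window_bp and k - j + 1 >= min_count:
                    flags[j:k + 1] = True
        clustered += flags.sum()
    return clustered / total if total else 0.0


class TestStandardize:
    def test_midpoint_and_width(self):
        calls = pd.DataFrame({"chrom": ["chr2L"], "start": [1000], "end": [1500]})
        ev = standardize_events(calls, "origin")
        assert ev["center"].iloc[0] == 1250
        assert (ev["start"].iloc[0], ev["end"].iloc[0]) == (1150, 1350)
        assert not ev["clipped"].iloc[0]

    def test_clip_at_chromosome_start(self):
        calls = pd.DataFrame({"chrom": ["chr2L"], "start": [40], "end": [60]})
        ev = standardize_events(calls, "origin")
        assert (ev["start"].iloc[0], ev["end"].iloc[0]) == (0, 150)
        assert ev["clipped"].iloc[0]

    def test_count_preserved_and_width_uniform(self, default_sim):
        _cfg, res = default_sim
        ev = standardize_events(res.origin_calls, "origin")
        assert len(ev) == len(res.origin_calls)
        unclipped = ev[~ev["clipped"]]
        assert ((unclipped["end"] - unclipped["start"]) == 200).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            standardize_events(pd.DataFrame({"chrom": [], "start": [], "end": []}), "peak")


class TestInterEventDistances:
    def test_consecutive_midpoints(self):
        ev = pd.DataFrame({"chrom": ["c", "c"], "center": [1000, 51_000]})
        d = inter_event_distances(ev)
        assert d["distance_kb"].tolist() == [50.0]

    def test_single_event_contributes_nothing(self):
        ev = pd.DataFrame({"chrom": ["c"], "center": [1000]})
        assert len(inter_event_distances(ev)) == 0

    def test_order_independence(self, rng):
        centers = rng.integers(0, 10**6, size=200)
        ev = pd.DataFrame({"chrom": "c", "center": centers})
        shuffled = ev.sample(frac=1, random_state=1)
        a = inter_event_distances(ev)["distance_kb"].to_numpy()
        b = inter_event_distances(shuffled)["distance_kb"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_poisson_spacing_mean(self, rng):
        """Poisson origins at 1/50 kb -> mean spacing ~50 kb within 3 SE."""
        lam = 1 / 50_000
        n = rng.poisson(lam * 5 * 10**7)
        ev = pd.DataFrame({"chrom": "c",
                           "center": np.sort(rng.integers(0, 5 * 10**7, size=n))})
        d = inter_event_distances(ev)["distance_kb"]
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 50.0) < 3 * se


class TestReplicateOverlap:
    def test_identical_sets_fully_shared(self):
        ev = pd.DataFrame({"chrom": "c", "start": np.arange(5) * 1000,
                           "end": np.arange(5) * 1000 + 200})
        assert replicate_overlap(ev, ev) == 5

    def test_disjoint_chromosomes(self):
        a = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [200]})
        b = pd.DataFrame({"chrom": ["c2"], "start": [0], "end": [200]})
        assert replicate_overlap(a, b) == 0

    def test_expansion_widens_matches(self):
        a = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [200]})
        b = pd.DataFrame({"chrom": ["c"], "start": [700], "end": [900]})
        assert replicate_overlap(a, b) == 0
        assert replicate_overlap(a, b, expand_bp=1000) == 1

    @pytest.mark.parametrize("expand", [0, 1000])
    def test_matches_all_pairs_oracle(self, rng, toy_genome, expand):
        a = random_intervals(rng, toy_genome, 300, min_len=200, max_len=200)
        b = random_intervals(rng, toy_genome, 300, min_len=200, max_len=200)
        assert replicate_overlap(a, b, expand) == overlap_oracle(a, b, expand)


class TestExpectedCounts:
    def test_mappable_genome_worked_example(self):
        assert expected_origin_count(143_726_002, 40_000) == 3_593

    def test_small_arithmetic(self):
        assert expected_origin_count(80_000, 40_000) == 2

    def test_sub_spacing_genome_warns(self):
        with pytest.warns(UserWarning):
            assert expected_origin_count(39_999, 40_000) == 0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_origin_count(0, 40_000)


class TestOverlapSimulation:
    def test_single_site_always_repeats(self):
        res = expected_overlap_simulation(n_sites=1, n_draws=5, n_sims=20, seed=0)
        assert (res.repeats == 4).all()

    def test_converges_to_closed_form(self):
        res = expected_overlap_simulation(3_593, 1_513, 1_000, seed=7)
        expected = expected_repeats_closed_form(3_593, 1_513)
        se = res.sd_repeats / np.sqrt(res.n_sims)
        assert abs(res.mean_repeats - expected) < 3 * se

    def test_seed_reproducibility(self):
        a = expected_overlap_simulation(100, 50, 50, seed=3)
        b = expected_overlap_simulation(100, 50, 50, seed=3)
        np.testing.assert_array_equal(a.repeats, b.repeats)


class TestOriginClusters:
    def test_three_close_origins_fully_clustered(self):
        ev = pd.DataFrame({"chrom": "c", "center": [1000, 6000, 11_000]})
        assert origin_clusters(ev) == 1.0

    def test_widely_spaced_not_clustered(self):
        ev = pd.DataFrame({"chrom": "c", "center": np.arange(5) * 100_000})
        assert origin_clusters(ev) == 0.0

    def test_matches_exhaustive_oracle(self, rng):
        ev = pd.DataFrame({"chrom": rng.choice(["c1", "c2"], size=150),
                           "center": rng.integers(0, 2 * 10**6, size=150)})
        assert origin_clusters(ev) == pytest.approx(clusters_oracle(ev, 40_000, 3))


class TestNearestPeakDistances:
    def test_coincident_event_and_peak(self, toy_genome):
        ev = pd.DataFrame({"chrom": ["chrA"], "center": [5000],
                           "start": [4900], "end": [5100]})
        pk = pd.DataFrame({"chrom": ["chrA"], "start": [4900], "end": [5100]})
        res = nearest_peak_distances(ev, pk, toy_genome, n_perms=10, seed=0)
        assert res.observed[0] == 0
        assert res.log10_observed()[0] == 0.0

    def test_single_peak_distance(self, toy_genome):
        ev = pd.DataFrame({"chrom": ["chrA"], "center": [10_000],
                           "start": [9_900], "end": [10_100]})
        pk = pd.DataFrame({"chrom": ["chrA"], "start": [0], "end": [0 + 1]})
        res = nearest_peak_distances(ev, pk, toy_genome, n_perms=10, seed=0)
        assert res.observed[0] == 10_000

    def test_peakless_chromosome_warns_and_excludes(self, toy_genome):
        ev = pd.DataFrame({"chrom": ["chrA", "chrB"], "center": [5000, 5000],
                           "start": [4900, 4900], "end": [5100, 5100]})
        pk = pd.DataFrame({"chrom": ["chrA"], "start": [4000], "end": [4200]})
        with pytest.warns(UserWarning, match="chrB"):
            res = nearest_peak_distances(ev, pk, toy_genome, n_perms=10, seed=0)
        assert len(res.observed) == 1

    def test_planted_orc_offset_recovered_null_larger(self):
        from replidyn.events import standardize_events
        from replidyn.simulate import SimulationConfig, simulate_dataset
        cfg = SimulationConfig(seed=21, genome=(("chrL", 60_000_000),),
                               origin_rate_per_bp=1.0 / 200_000,
                               origin_rate_timing_multiplier={g: 1.0 for g in range(4)},
                               orc_background_rate_per_bp=0.0)
        res = simulate_dataset(cfg)
        truth = res.truth.origins
        ev = pd.DataFrame({"chrom": truth["chrom"], "start": truth["pos"] - 100,
                           "end": truth["pos"] + 100})
        ev = standardize_events(ev, "origin")
        out = nearest_peak_distances(ev, res.annotations.orc_peaks.records,
                                     cfg.genome_dict(), n_perms=100, seed=2)
        assert out.observed_median == pytest.approx(6_309, rel=0.15)
        assert out.null_median > out.observed_median
        assert out.p_value < 1e-3
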