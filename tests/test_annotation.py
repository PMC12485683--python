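import numpy as np
import pandas as pd
import pytest

from replidyn.annotation import (STATE_CATEGORY, assign_state_containment,
                                 assign_track_to_window, category_density,
                                 compare_groups, quintile_composition,
                                 timing_correlation, timing_quartiles,
                                 timing_windows)
from replidyn.io_bed import AnnotationTrack


def state_track(rows):
    return AnnotationTrack("chromatin_state",
                           pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


def containment_oracle(tracks, states, genome):
    """Per-bp check: assigned iff every bp of the track carries one state."""
    arrays = {}
    for chrom, length in genome.items():
        arr = np.full(length, -1, dtype=int)
        for _, s in states.records[states.records["chrom"] == chrom].iterrows():
            arr[s["start"]:s["end"]] = s["state"]
        arrays[chrom] = arr
    out = []
    for _, t in tracks.iterrows():
        seg = arrays[t["chrom"]][t["start"]:t["end"]]
        uniq = np.unique(seg)
        out.append(int(uniq[0]) if len(uniq) == 1 and uniq[0] >= 0 else None)
    return out


class TestCategoryMap:
    def test_states_partition_into_three_categories(self):
        cats = [STATE_CATEGORY[s] for s in range(10)]
        assert set(cats) == {"euchromatin", "heterochromatin", "silent"}
        assert [s for s in range(10) if STATE_CATEGORY[s] == "euchromatin"] == [1, 2, 3, 4, 5]
        assert [s for s in range(10) if STATE_CATEGORY[s] == "silent"] == [9]


class TestContainment:
    def test_track_inside_block_assigned(self):
        states = state_track([("c", 0, 500, 7)])
        tracks = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200]})
        out = assign_state_containment(tracks, states)
        assert out["state"].iloc[0] == 7
        assert out["category"].iloc[0] == "heterochromatin"

    def test_boundary_spanning_track_unassigned(self):
        states = state_track([("c", 0, 500, 2), ("c", 500, 1000, 7)])
        tracks = pd.DataFrame({"chrom": ["c"], "start": [400], "end": [600]})
        out = assign_state_containment(tracks, states)
        assert pd.isna(out["state"].iloc[0])

    def test_adjacent_same_state_blocks_merged_before_test(self):
        states = state_track([("c", 0, 500, 7), ("c", 500, 1000, 7)])
        tracks = pd.DataFrame({"chrom": ["c"], "start": [400], "end": [600]})
        out = assign_state_containment(tracks, states)
        assert out["state"].iloc[0] == 7

    def test_matches_per_bp_oracle(self, rng):
        genome = {"cX": 200_000}
        edges = np.sort(rng.choice(np.arange(1000, 199_000), size=40, replace=False))
        bounds = np.concatenate([[0], edges, [200_000]])
        states = state_track([("cX", int(a), int(b), int(rng.integers(0, 10)))
                              for a, b in zip(bounds[:-1], bounds[1:])])
        tracks = pd.DataFrame({
            "chrom": "cX",
            "start": rng.integers(0, 190_000, size=1000)})
        tracks["end"] = tracks["start"] + rng.integers(200, 9_000, size=1000)
        got = assign_state_containment(tracks, states)["state"]
        oracle = containment_oracle(tracks, states, genome)
        # merged adjacent same-state blocks: oracle on the bp array is exact
        for g, o in zip(got, oracle):
            assert (pd.isna(g) and o is None) or g == o


class TestCompareGroups:
    def test_identical_groups_not_significant(self, rng):
        vals = rng.normal(size=200)
        out = compare_groups({"a": vals, "b": vals.copy()})
        assert out.pairwise["p_value"].iloc[0] > 0.8

    def test_shifted_group_detected(self, rng):
        a = rng.normal(size=200)
        out = compare_groups({"a": a, "b": a + 2.0})
        assert out.pairwise["p_value"].iloc[0] < 1e-3

    def test_omnibus_for_three_groups(self, rng):
        out = compare_groups({"a": rng.normal(size=50), "b": rng.normal(size=50),
                              "c": rng.normal(2, 1, size=50)})
        assert out.h_pvalue is not None and out.h_pvalue < 0.01

    def test_empty_group_error_names_group(self):
        with pytest.raises(ValueError, match="'b'"):
            compare_groups({"a": [1.0], "b": []})


class TestQuintileComposition:
    def test_proportions_sum_to_one(self, default_sim):
        from replidyn.annotation import brdu_intervals
        cfg, res = default_sim
        tracks = brdu_intervals(res.records)
        comp = quintile_composition(tracks, res.annotations.states, cfg.genome_dict())
        sums = comp.groupby("quintile", observed=True)["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_single_state_genome_degenerate(self):
        genome = {"c": 100_000}
        states = state_track([("c", 0, 100_000, 3)])
        tracks = pd.DataFrame({"chrom": "c", "start": np.arange(10) * 5000,
                               "end": np.arange(10) * 5000 + np.arange(1, 11) * 100})
        raw = quintile_composition(tracks, states, genome)
        assert (raw.loc[raw["state"] == 3, "proportion"] == 1.0).all()
        norm = quintile_composition(tracks, states, genome, normalize=True)
        assert np.allclose(norm.loc[norm["state"] == 3, "proportion"], 1.0)


def timing_track(rows):
    return AnnotationTrack("timing", pd.DataFrame(
        rows, columns=["chrom", "start", "end", "score", "group"]))


class TestTimingWindows:
    def test_dominant_group_by_max_overlap(self):
        genome = {"c": 30_000}
        track = timing_track([("c", 0, 12_000, 1.0, 0), ("c", 12_000, 30_000, 2.0, 3)])
        win = timing_windows(track, genome, 30_000)
        assert win["dominant_group"].iloc[0] == 3
        assert not win["tie"].iloc[0]

    def test_tie_breaks_to_lower_group_with_flag(self):
        genome = {"c": 30_000}
        track = timing_track([("c", 0, 15_000, 1.0, 2), ("c", 15_000, 30_000, 2.0, 1)])
        win = timing_windows(track, genome, 30_000)
        assert win["dominant_group"].iloc[0] == 1
        assert win["tie"].iloc[0]

    def test_windows_without_segments_excluded(self):
        genome = {"c": 90_000}
        track = timing_track([("c", 0, 10_000, 1.0, 0)])
        win = timing_windows(track, genome, 30_000)
        assert len(win) == 1 and win["start"].iloc[0] == 0

    def test_matches_per_bp_oracle(self, rng):
        genome = {"c": 300_000}
        edges = np.sort(rng.choice(np.arange(100, 299_900), size=60, replace=False))
        bounds = np.concatenate([[0], edges, [300_000]])
        rows = [("c", int(a), int(b), 1.0, int(rng.integers(0, 4)))
                for a, b in zip(bounds[:-1], bounds[1:])]
        track = timing_track(rows)
        win = timing_windows(track, genome, 30_000)
        arr = np.zeros(300_000, dtype=int)
        for _c, a, b, _s, g in rows:
            arr[a:b] = g
        for _, w in win.iterrows():
            seg = arr[w["start"]:w["end"]]
            counts = np.bincount(seg, minlength=4)
            assert w["dominant_group"] == counts.argmax()

    def test_track_assigned_to_greatest_overlap_window(self):
        wins = pd.DataFrame({"chrom": "c", "start": [0, 30_000], "end": [30_000, 60_000]})
        tracks = pd.DataFrame({"chrom": ["c"], "start": [25_000], "end": [45_000]})
        out = assign_track_to_window(tracks, wins)
        assert out["window_idx"].iloc[0] == 1  # 15 kb in window 1 vs 5 kb in window 0
        tie = pd.DataFrame({"chrom": ["c"], "start": [20_000], "end": [40_000]})
        out2 = assign_track_to_window(tie, wins)
        assert out2["window_idx"].iloc[0] == 0 and out2["window_tie"].iloc[0]


class TestTimingCorrelation:
    def test_perfect_identity(self):
        x = np.linspace(1, 100, 50)
        r, p, n, _ = timing_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_null_calibration(self, rng):
        x = rng.lognormal(0, 1, size=5000)
        y = rng.lognormal(0, 1, size=5000)
        r, p, n, _ = timing_correlation(y, x)
        assert abs(r) < 0.05

    def test_planted_negative_slope_recovered(self, rng):
        score = rng.lognormal(0, 0.5, size=500)
        length = 1e4 / score * rng.lognormal(0, 0.1, size=500)
        r, p, _, _ = timing_correlation(length, score)
        assert r < -0.5 and p < 1e-6

    def test_nonpositive_values_excluded(self):
        r, p, n, n_excl = timing_correlation([10, 20, 30, 40], [1.0, 2.0, 0.0, 3.0])
        assert n == 3 and n_excl == 1


class TestCategoryDensity:
    def test_density_arithmetic(self):
        part = pd.DataFrame({"chrom": "c", "start": [0], "end": [2_000_000],
                             "category": ["early"]})
        ev = pd.DataFrame({"chrom": "c",
                           "center": np.linspace(1000, 1_900_000, 10, dtype=int)})
        out = category_density(ev, part, "category")
        assert out.loc[0, "density"] == pytest.approx(0.5)

    def test_gap_centers_discarded_and_tallied(self):
        part = pd.DataFrame({"chrom": "c", "start": [0], "end": [1000],
                             "category": ["x"]})
        ev = pd.DataFrame({"chrom": "c", "center": [500, 5000]})
        out = category_density(ev, part, "category")
        assert out.loc[0, "count"] == 1
        assert out.attrs["n_discarded"] == 1

    def test_event_conservation_over_categories(self, default_sim):
        from replidyn.events import standardize_events
        cfg, res = default_sim
        std = standardize_events(res.origin_calls, "origin")
        part = res.annotations.states.records.assign(
            category=res.annotations.states.records["state"].map(STATE_CATEGORY))
        out = category_density(std, part, "category")
        recovered = (out["density"] * out["bp"] / 100_000).sum()
        assert round(recovered) + out.attrs["n_discarded"] == len(std)

    def test_timing_quartiles_cover_and_merge(self, default_sim):
        cfg, res = default_sim
        quart = timing_quartiles(res.annotations.timing)
        assert set(quart.records["group"]) == {0, 1, 2, 3}
        total = (quart.records["end"] - quart.records["start"]).sum()
        assert total == (res.annotations.timing.records["end"]
                         - res.annotations.timing.records["start"]).sum()
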