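"""Standing-point classification and quality-control filter tests."""

import numpy as np
import pandas as pd
import pytest

from nichepart.config import ConfigurationError, QCPolicy
from nichepart.raster import InputError
from nichepart.tracks import (average_consecutive_seasons,
                              classify_standing_points, density_filter,
                              exclude_nest_vicinity, mean_distance_to_nest,
                              process_individual, qc_filter, season_window,
                              UndefinedResultError)
from nichepart.types import NestSet, StandingPointSet

from conftest import make_fixseries, nest_xy_of


@pytest.fixture()
def policy():
    return QCPolicy()


def sps_from_xy(x, y, species="STE", speeds=None):
    n = len(x)
    return StandingPointSet(
        individual_id="b1", species=species, window="shared",
        points=pd.DataFrame({
            "x": np.asarray(x, float), "y": np.asarray(y, float),
            "timestamp": pd.date_range("2013-04-01", periods=n, freq="5min"),
            "ground_speed": speeds if speeds is not None else np.ones(n),
        }))


class TestSpeedClassification:
    def test_strict_threshold_boundary(self, policy):
        fs = make_fixseries([0, 1, 2], [0, 0, 0], [3.9, 4.0, 4.1])
        sps = classify_standing_points(fs, policy)
        assert len(sps) == 1
        assert sps.points["ground_speed"].iloc[0] == 3.9

    def test_all_fast_gives_empty_set(self, policy):
        fs = make_fixseries([0, 1], [0, 0], [5.0, 12.0])
        assert len(classify_standing_points(fs, policy)) == 0

    def test_no_speed_field_rejected(self, policy):
        fs = make_fixseries([0, 1], [0, 0], [0.0, 0.0])
        fs.fixes["ground_speed"] = np.nan
        with pytest.raises(InputError):
            classify_standing_points(fs, policy)

    def test_retained_fraction_matches_generator_bookkeeping(
            self, small_dataset, policy):
        fs = small_dataset.tracks[0]
        sps = classify_standing_points(fs, policy)
        slow_frac = (fs.fixes["ground_speed"] < 4.0).mean()
        assert len(sps) / len(fs) == pytest.approx(slow_frac, abs=1e-12)
        # and the slow fraction tracks the generating states
        state_frac = fs.fixes["sim_state"].isin(["forage", "nest"]).mean()
        assert len(sps) / len(fs) == pytest.approx(state_frac, abs=0.02)


class TestNestVicinity:
    def test_all_points_at_nest_removed(self, policy):
        sps = sps_from_xy(np.zeros(5), np.zeros(5))
        assert len(exclude_nest_vicinity(sps, (0.0, 0.0), policy)) == 0

    def test_boundary_point_retained(self, policy):
        # STE radius 1.5 km; a point exactly at the radius stays (strict <)
        sps = sps_from_xy([1500.0, 1499.9], [0.0, 0.0])
        out = exclude_nest_vicinity(sps, (0.0, 0.0), policy)
        assert out.points["x"].tolist() == [1500.0]

    def test_rings_inside_and_outside(self, policy):
        theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        x = np.concatenate([100 * np.cos(theta), 2000 * np.cos(theta)])
        y = np.concatenate([100 * np.sin(theta), 2000 * np.sin(theta)])
        out = exclude_nest_vicinity(sps_from_xy(x, y), (0.0, 0.0), policy)
        assert len(out) == 20
        assert np.hypot(out.points["x"], out.points["y"]).min() > 1500

    def test_unknown_species_rejected(self, policy):
        sps = sps_from_xy([0.0], [0.0], species="unknown")
        with pytest.raises(ConfigurationError):
            exclude_nest_vicinity(sps, (0.0, 0.0), policy)


class TestDensityFilter:
    def test_single_cell_keeps_everything(self, rng):
        x = rng.uniform(0, 400, 50)
        y = rng.uniform(0, 400, 50)
        for q in (0.0, 0.5, 1.0):
            assert len(density_filter(sps_from_xy(x, y), 500.0, q)) == 50

    def test_zero_quantile_is_identity(self, rng):
        x = rng.uniform(0, 50_000, 200)
        y = rng.uniform(0, 50_000, 200)
        assert len(density_filter(sps_from_xy(x, y), 500.0, 0.0)) == 200

    def test_corridor_cells_removed_patch_kept(self, rng):
        # dense foraging patch (36 grid cells, ~140 points each) plus a thin
        # sparse corridor: the nonzero-cell count median falls in the gap
        # between corridor and patch densities
        patch_x = rng.uniform(20_000, 23_000, 5000)
        patch_y = rng.uniform(20_000, 23_000, 5000)
        corr_x = rng.uniform(5_000, 19_000, 50)
        corr_y = rng.normal(20_000, 100, 50)
        sps = sps_from_xy(np.concatenate([patch_x, corr_x]),
                          np.concatenate([patch_y, corr_y]))
        out = density_filter(sps, 500.0, 0.5)
        kept_x = out.points["x"]
        assert (kept_x >= 19_000).mean() >= 0.99      # patch retained
        n_corr_kept = (kept_x < 19_000).sum()
        assert n_corr_kept <= 5                        # >=90% corridor gone

    def test_invalid_cell_rejected(self):
        with pytest.raises(ConfigurationError):
            density_filter(sps_from_xy([0.0], [0.0]), -5.0, 0.5)


class TestSeasonWindow:
    def test_shared_window_boundaries_inclusive(self, policy):
        ts = pd.to_datetime(["2013-03-24 10:00", "2013-03-25 10:00",
                             "2013-07-15 10:00", "2013-07-16 10:00"])
        fs = make_fixseries(np.arange(4), np.zeros(4), np.ones(4),
                            timestamps=ts)
        out = season_window(fs, "shared", policy)
        months = out.fixes["timestamp"].dt.strftime("%m-%d").tolist()
        assert months == ["03-25", "07-15"]

    def test_near_nest_species_whole_equals_shared(self, policy):
        # LLB's whole season nests inside the shared window, so both
        # windows give identical data
        ts = pd.date_range("2013-03-01", "2013-08-30", freq="7D")
        fs = make_fixseries(np.arange(len(ts)), np.zeros(len(ts)),
                            np.ones(len(ts)), species="LLB", timestamps=ts)
        whole = season_window(fs, "whole", policy)
        shared = season_window(fs, "shared", policy)
        pd.testing.assert_frame_equal(whole.fixes, shared.fixes)

    def test_commuting_species_whole_is_superset(self, policy):
        ts = pd.date_range("2013-03-01", "2013-08-30", freq="7D")
        fs = make_fixseries(np.arange(len(ts)), np.zeros(len(ts)),
                            np.ones(len(ts)), species="STE", timestamps=ts)
        assert len(season_window(fs, "whole", policy)) > \
            len(season_window(fs, "shared", policy))


class TestQCFilter:
    def _nests(self, flag=True):
        return NestSet(records=pd.DataFrame({
            "nest_id": ["n1"], "species": ["STE"], "year": [2013],
            "lon": [35.0], "lat": [31.0], "x": [0.0], "y": [0.0],
            "reached_chick_rearing": [flag]}))

    def test_min_points_boundary(self, policy):
        s50 = sps_from_xy(np.arange(50), np.zeros(50))
        s51 = sps_from_xy(np.arange(51), np.zeros(51))
        eligible, log = qc_filter([s50, s51], self._nests(), policy)
        assert [len(s) for s in eligible] == [51]
        assert log[0]["reason"] == "too_few_points"

    def test_failed_nest_excluded_regardless_of_points(self, policy):
        s = sps_from_xy(np.arange(100), np.zeros(100))
        eligible, log = qc_filter([s], self._nests(flag=False), policy,
                                  nest_of_individual={"b1": "n1"})
        assert eligible == []
        assert log[0]["reason"] == "no_chick_rearing"

    def test_two_season_averaging(self):
        assert average_consecutive_seasons({2012: 20.0, 2013: 30.0}) == 25.0
        # dissimilar seasons (no overlap) fall back to the first season
        assert average_consecutive_seasons(
            {2012: 20.0, 2013: 30.0},
            overlap_by_pair={(2012, 2013): 0.0}) == 20.0
        assert average_consecutive_seasons({2013: 12.0}) == 12.0


class TestMeanDistance:
    def test_ring_and_two_point_means(self):
        theta = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        ring = sps_from_xy(1000 * np.cos(theta), 1000 * np.sin(theta))
        assert mean_distance_to_nest(ring, (0, 0)) == pytest.approx(1.0)
        two = sps_from_xy([1000.0, 3000.0], [0.0, 0.0])
        assert mean_distance_to_nest(two, (0, 0)) == pytest.approx(2.0)

    def test_empty_set_rejected(self):
        sps = sps_from_xy([], [])
        with pytest.raises(UndefinedResultError):
            mean_distance_to_nest(sps, (0, 0))


class TestFilterComposition:
    def test_pipeline_equals_manual_composition(self, small_dataset,
                                                small_policy):
        fs = small_dataset.tracks[0]
        nest = nest_xy_of(small_dataset, fs)
        combined = process_individual(fs, nest, small_policy, "shared")
        manual = season_window(fs, "shared", small_policy)
        manual = classify_standing_points(manual, small_policy, "shared")
        manual = exclude_nest_vicinity(manual, nest, small_policy)
        manual = density_filter(manual, policy=small_policy)
        pd.testing.assert_frame_equal(combined.points, manual.points)
        assert combined.filters_applied == manual.filters_applied
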