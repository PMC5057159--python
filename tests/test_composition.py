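"""Habitat-use, hourly-activity and diet composition tests."""

import numpy as np
import pandas as pd
import pytest

from nichepart.composition import (CompositionMatrix, UndefinedRowError,
                                   availability, category_fractions,
                                   category_tests, diet_matrix,
                                   habitat_composition, hourly_activity,
                                   use_vs_availability)
from nichepart.config import QCPolicy
from nichepart.raster import HabitatRaster, InputError
from nichepart.spaceuse import UtilizationGrid, IsoplethRegion
from nichepart.types import StandingPointSet

from conftest import make_composition, make_fixseries


def uniform_raster(classes=("a", "b"), pattern=None, n=10, cell=100.0):
    if pattern is None:
        grid = np.zeros((n, n), dtype=int)
    else:
        grid = np.asarray(pattern, dtype=int)
    return HabitatRaster(classes=tuple(classes), grid=grid,
                         x0=0.0, y0=0.0, cell_m=cell)


def sps(x, y, species="LLB", ident="b1"):
    n = len(x)
    return StandingPointSet(
        individual_id=ident, species=species, window="shared",
        points=pd.DataFrame({"x": np.asarray(x, float),
                             "y": np.asarray(y, float),
                             "timestamp": pd.date_range("2013-04-01",
                                                        periods=n,
                                                        freq="5min"),
                             "ground_speed": np.ones(n)}))


class TestCompositionMatrix:
    def test_proportion_rows_must_sum_to_one(self):
        with pytest.raises(InputError):
            make_composition([[0.5, 0.4]], kind="proportion")

    def test_negative_values_rejected(self):
        with pytest.raises(InputError):
            make_composition([[1.0, -0.1]], kind="mean_count")

    def test_normalization_of_counts(self):
        cm = make_composition([[2.0, 6.0]], kind="mean_count")
        assert cm.to_proportions().values[0] == pytest.approx([0.25, 0.75])


class TestHabitatComposition:
    def test_single_class_row(self):
        r = uniform_raster()
        cm, _ = habitat_composition([sps([50, 150, 250], [50, 50, 50])], r)
        assert cm.values[0] == pytest.approx([1.0, 0.0])

    def test_forty_of_hundred_points(self):
        pattern = np.zeros((10, 10), dtype=int)
        pattern[:, :5] = 1                     # west half class "b"
        r = uniform_raster(pattern=pattern)
        x = np.concatenate([np.full(40, 250.0), np.full(60, 750.0)])
        y = np.full(100, 500.0)
        cm, _ = habitat_composition([sps(x, y)], r)
        assert cm.values[0] == pytest.approx([0.6, 0.4])

    def test_outside_points_logged_and_dropped(self):
        r = uniform_raster()
        cm, log = habitat_composition(
            [sps([500.0, -5000.0], [500.0, 500.0])], r)
        assert log["points_outside_raster"]["b1"] == 1
        assert cm.values[0] == pytest.approx([1.0, 0.0])
        with pytest.raises(InputError):
            habitat_composition([sps([-5000.0], [500.0])], r)

    def test_generator_preference_recovery(self, small_dataset, small_policy):
        # speed + nest-vicinity filters only: the corridor (density) filter
        # interacts with class-cell concentration and is tested separately
        from nichepart import tracks as T
        from conftest import nest_xy_of
        cfg = small_dataset.config
        sets = []
        for fs in small_dataset.tracks:
            clipped = T.season_window(fs, "shared", small_policy)
            s = T.classify_standing_points(clipped, small_policy, "shared")
            s = T.exclude_nest_vicinity(s, nest_xy_of(small_dataset, fs),
                                        small_policy)
            sets.append(s)
        cm, _ = habitat_composition(sets, small_dataset.landscape)
        for species in ("LLB", "STE"):
            rows = cm.rows_for_group(species)
            use = {c: cfg.species[species].habitat_use[c]
                   for c in cm.categories}
            mean_use = rows.mean(axis=0)
            for j, c in enumerate(cm.categories):
                assert mean_use[j] == pytest.approx(use[c], abs=0.03)


class TestAvailability:
    def test_uniform_and_half_rasters(self):
        assert availability(uniform_raster())[0] == 1.0
        pattern = np.zeros((10, 10), dtype=int)
        pattern[:5] = 1
        assert availability(uniform_raster(pattern=pattern)) == pytest.approx(
            [0.5, 0.5])

    def test_mask_restriction_and_empty_mask(self):
        pattern = np.zeros((10, 10), dtype=int)
        pattern[:5] = 1
        r = uniform_raster(pattern=pattern)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        assert availability(r, mask) == pytest.approx([0.0, 1.0])
        with pytest.raises(InputError):
            availability(r, np.zeros((10, 10), dtype=bool))


class TestUseVsAvailability:
    def test_all_units_at_availability(self):
        cm = make_composition(np.tile([0.3, 0.7], (3, 1)),
                              groups=["A"] * 3)
        rep = use_vs_availability(cm, np.array([0.3, 0.7]))
        assert rep["t"].abs().max() == pytest.approx(0.0, abs=1e-9)
        assert (rep["p"] == 1.0).all()

    def test_hand_computed_t_statistic(self):
        # units (0.5, 0.6, 0.7) vs availability 0.12:
        # t = (0.6 - 0.12) / (0.1 / sqrt(3)) = 8.3138...
        vals = np.array([[0.5, 0.5], [0.6, 0.4], [0.7, 0.3]])
        cm = make_composition(vals, groups=["A"] * 3)
        rep = use_vs_availability(cm, np.array([0.12, 0.88]))
        row = rep[(rep["category"] == "c0")].iloc[0]
        assert row["t"] == pytest.approx(0.48 / (0.1 / np.sqrt(3)), rel=1e-4)
        assert row["df"] == 2
        assert row["direction"] == "preference"

    def test_zero_variance_flagged(self):
        cm = make_composition(np.tile([0.9, 0.1], (3, 1)), groups=["A"] * 3)
        rep = use_vs_availability(cm, np.array([0.2, 0.8]))
        row = rep[rep["category"] == "c0"].iloc[0]
        assert np.isinf(row["t"]) and row["p"] == 0.0
        assert row["flag"] == "zero_variance"


def region_covering(x0, y0, x1, y1, cell=100.0):
    nx = int((x1 - x0) / cell)
    ny = int((y1 - y0) / cell)
    grid = UtilizationGrid(x0, y0, cell, np.full((ny, nx), 1.0 / (nx * ny)),
                           500.0)
    return IsoplethRegion(level=0.95, member=np.ones((ny, nx), dtype=bool),
                          grid=grid, area_km2=nx * ny * cell**2 / 1e6)


class TestHourlyActivity:
    def test_uniform_activity_gives_flat_bins(self):
        ts = pd.date_range("2013-04-01 07:00", "2013-04-01 18:55",
                           freq="5min")
        fs = make_fixseries(np.full(len(ts), 500.0), np.full(len(ts), 500.0),
                            np.ones(len(ts)), timestamps=ts)
        row = hourly_activity(fs, region_covering(0, 0, 1000, 1000))
        assert row == pytest.approx(np.full(12, 1 / 12), abs=1e-9)

    def test_concentrated_window(self):
        ts = pd.date_range("2013-04-01 11:00", "2013-04-01 14:59",
                           freq="5min")
        fs = make_fixseries(np.full(len(ts), 500.0), np.full(len(ts), 500.0),
                            np.ones(len(ts)), timestamps=ts)
        row = hourly_activity(fs, region_covering(0, 0, 1000, 1000))
        assert row[4:8].sum() == pytest.approx(1.0)       # bins 11..14
        assert row[:4].sum() == 0.0 and row[8:].sum() == 0.0

    def test_no_in_region_fixes_rejected(self):
        fs = make_fixseries([5000.0], [5000.0], [1.0],
                            timestamps=pd.to_datetime(["2013-04-01 12:00"]))
        with pytest.raises(UndefinedRowError):
            hourly_activity(fs, region_covering(0, 0, 1000, 1000))

    def test_midday_peak_species_recovers_peak_bin(self, small_dataset,
                                                   small_policy):
        # region = the individual's 95% isopleth of filtered standing
        # points (as in the pipeline), which excludes the nest area where
        # off-peak social fixes concentrate
        from nichepart import spaceuse as S, tracks as T
        from conftest import nest_xy_of
        fs = next(t for t in small_dataset.tracks if t.species == "STE")
        sps = T.process_individual(fs, nest_xy_of(small_dataset, fs),
                                   small_policy, "shared")
        region = S.isopleth(S.kde_ud(sps, h_m=500.0), 0.95)
        row = hourly_activity(fs, region)
        peak_hour = 7 + int(np.argmax(row))
        assert peak_hour in (11, 12, 13, 14)
        # and activity declines from the peak toward the day edges
        assert row.max() > 2 * min(row[0], row[-1])


def diet_frame(rows):
    return pd.DataFrame(rows, columns=["nest_id", "species", "year",
                                       "taxon", "count", "category",
                                       "subcategory"])


class TestDietMatrix:
    policy = QCPolicy()

    def test_seven_item_nest_year_excluded(self):
        df = diet_frame([
            ("n1", "LLB", 2012, "vole", 7, "mammal", "n/a"),
            ("n2", "LLB", 2012, "vole", 8, "mammal", "n/a"),
        ])
        cm, _, log = diet_matrix(df, self.policy)
        assert cm.unit_ids == ["n2"]
        reasons = {(e["nest_id"], e["reason"]) for e in log}
        assert ("n1", "too_few_items") in reasons
        assert ("n1", "no_retained_years") in reasons

    def test_multi_year_averaging(self):
        df = diet_frame([
            ("n1", "LLB", 2012, "x", 4, "mammal", "n/a"),
            ("n1", "LLB", 2012, "y", 6, "bird", "n/a"),
            ("n1", "LLB", 2013, "x", 8, "mammal", "n/a"),
            ("n1", "LLB", 2013, "y", 2, "bird", "n/a"),
        ])
        cm, _, _ = diet_matrix(df, self.policy)
        vals = dict(zip(cm.categories, cm.values[0]))
        assert vals == {"x": 6.0, "y": 4.0}

    def test_single_taxon_nest_proportion_row(self):
        df = diet_frame([("n1", "LLB", 2012, "x", 9, "mammal", "n/a")])
        cm, _, _ = diet_matrix(df, self.policy)
        assert cm.to_proportions().values[0] == pytest.approx([1.0])

    def test_filter_and_averaging_idempotent(self, small_dataset):
        cm1, _, _ = diet_matrix(small_dataset.diets, self.policy)
        # rebuild a diet table from the averaged matrix and re-apply
        rows = []
        for uid, group, vals in zip(cm1.unit_ids, cm1.groups, cm1.values):
            for taxon, v in zip(cm1.categories, vals):
                if v > 0:
                    rows.append((uid, group, 2013, taxon, v, "x", "y"))
        cm2, _, _ = diet_matrix(diet_frame(rows), self.policy)
        assert cm2.unit_ids == cm1.unit_ids
        np.testing.assert_allclose(cm2.values, cm1.values)

    def test_nonpositive_counts_rejected(self):
        df = diet_frame([("n1", "LLB", 2012, "x", 0, "mammal", "n/a")])
        with pytest.raises(InputError):
            diet_matrix(df, self.policy)


class TestCategoryAnalyses:
    def test_category_fractions_collapse(self):
        cm = make_composition([[2.0, 4.0, 4.0]], kind="mean_count",
                              categories=["skink", "snake1", "pigeon"])
        meta = pd.DataFrame({
            "taxon": ["skink", "snake1", "pigeon"],
            "category": ["reptile", "reptile", "bird"],
            "subcategory": ["lizard", "snake", "n/a"]})
        cat = category_fractions(cm, meta, "category")
        assert dict(zip(cat.categories, cat.values[0])) == pytest.approx(
            {"bird": 0.4, "reptile": 0.6})
        sub = category_fractions(cm, meta, "subcategory")
        assert dict(zip(sub.categories, sub.values[0])) == pytest.approx(
            {"lizard": 1 / 3, "snake": 2 / 3})

    def test_diet_direction_recovery(self, small_dataset):
        # generator weights the near-nest species to lizards and the
        # commuting species to snakes; the contrast test recovers this
        cm, meta, _ = diet_matrix(small_dataset.diets, QCPolicy())
        res = category_tests(cm, meta)
        inter = res["lizard_vs_snake_interaction"]
        assert inter["mean_diff_LLB"] > 0          # more lizards than snakes
        assert inter["mean_diff_STE"] < 0          # more snakes than lizards
        assert inter["p"] < 0.05
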