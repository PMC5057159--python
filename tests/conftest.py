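"""Shared fixtures: a scaled-down synthetic study for fast unit tests.

The small config keeps the full two-species structure (near-nest vs
commuting, uniform vs midday-peak, opposite habitat preferences, divergent
diets) on a shorter season with fewer individuals so most tests run in
well under a second.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
import pytest

from nichepart.config import QCPolicy, SimConfig
from nichepart import synthetic


def small_config(seed: int = 7) -> SimConfig:
    cfg = SimConfig(seed=seed)
    cfg.n_individuals_per_species = {"LLB": 3, "STE": 3}
    cfg.n_solar_per_species = {"LLB": 2, "STE": 2}
    cfg.n_nests_per_species = {"LLB": 12, "STE": 16}
    cfg.extent_km = 40.0
    cfg.cell_m = 200.0
    for sp in cfg.species.values():
        sp.season_start = (4, 10)
        sp.season_end = (5, 10)
    cfg.species["STE"].season_end = (5, 25)
    cfg.species["STE"].shared_pool_size = 4
    cfg.species["STE"].n_patches = 3
    cfg.species["STE"].n_late_patches = 1
    cfg.shared_window = ((4, 10), (5, 10))
    return cfg


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return synthetic.synthesize(small_cfg)


@pytest.fixture(scope="session")
def small_policy(small_cfg) -> QCPolicy:
    return QCPolicy(
        nest_radius_km={n: sp.nest_radius_km
                        for n, sp in small_cfg.species.items()},
        species_seasons={n: (sp.season_start, sp.season_end)
                         for n, sp in small_cfg.species.items()},
        shared_window=small_cfg.shared_window)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def nest_xy_of(dataset, fs):
    """Nest coordinates for a synthetic individual (generator convention:
    i-th individual of a species sits on the i-th successful nest)."""
    good = dataset.nests.for_species(fs.species)
    good = good[good["reached_chick_rearing"]]
    idx = int(fs.individual_id.rsplit("_", 1)[1]) - 2180
    nest = good.iloc[idx]
    return np.array([nest["x"], nest["y"]], dtype=float)


def make_fixseries(x, y, speeds, individual_id="bird", species="LLB",
                   start="2013-04-01 08:00:00", interval_s=300,
                   timestamps=None):
    """Minimal FixSeries from planar coordinates and speeds."""
    from nichepart.types import FixSeries
    n = len(x)
    if timestamps is None:
        timestamps = pd.date_range(start, periods=n,
                                   freq=f"{interval_s}s")
    return FixSeries(
        individual_id=individual_id, species=species,
        fixes=pd.DataFrame({
            "timestamp": pd.to_datetime(timestamps),
            "lon": np.zeros(n), "lat": np.zeros(n),
            "ground_speed": np.asarray(speeds, dtype=float),
            "heading": np.zeros(n),
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
        }))


def make_composition(values, groups=None, kind="proportion", ids=None,
                     categories=None):
    from nichepart.composition import CompositionMatrix
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return CompositionMatrix(
        unit_ids=ids or [f"u{i}" for i in range(n)],
        groups=groups or ["A"] * n,
        categories=categories or [f"c{j}" for j in range(k)],
        values=values, kind=kind)
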