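"""Synthetic two-species central-place-foraging study generator.

Generates a categorical landscape, nest sets, GPS tracks and per-nest diet
tables carrying the statistical structure the downstream analysis assumes:

* two species with distinct mean nest-to-foraging-patch distances (near-nest
  vs commuting), the commuting species reaching its patches via high-speed
  flight corridors;
* a 12 h duty cycle with 5-min (solar tag) or 90-min (regular tag) fix
  schedules, ground speed bimodal around the 4 m/s standing threshold;
* uniform vs midday-peaked diel foraging activity;
* habitat preference/avoidance realized by sampling foraging positions from
  land-cover classes at configured use proportions;
* multinomial diets from species-specific taxon probability vectors, with a
  configurable fraction of undersampled nests to exercise the diet filter.

The movement model is deliberately phenomenological: each fix is assigned a
behavioural state (forage / transit / nest) and a position and tag-reported
ground speed consistent with that state. Ground speed is written into the
fix record rather than derived from displacement, so the speed-threshold
classification downstream operates exactly on what a tag would report.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig, SpeciesParams
from .io import DEFAULT_ORIGIN, LocalProjection
from .raster import HabitatRaster, InputError
from .types import FixSeries, NestSet


@dataclass
class SyntheticDataset:
    config: SimConfig
    landscape: HabitatRaster
    nests: NestSet
    tracks: list[FixSeries]
    diets: pd.DataFrame
    projection: LocalProjection


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def generate_landscape(config: SimConfig,
                       rng: np.random.Generator | None = None) -> HabitatRaster:
    """IID categorical landscape whose realized class proportions match the
    configured availability (multinomial sampling error only)."""
    avail = np.asarray(config.availability, dtype=float)
    if (avail > 0).sum() < 1:
        raise ConfigurationError("at least one habitat class must be available")
    rng = rng if rng is not None else _rng(config, 0)
    n = int(round(config.extent_km * 1000 / config.cell_m))
    grid = rng.choice(len(avail), size=(n, n), p=avail).astype(int)
    return HabitatRaster(classes=tuple(config.habitat_classes), grid=grid,
                         x0=0.0, y0=0.0, cell_m=config.cell_m)


def generate_nests(config: SimConfig,
                   rng: np.random.Generator | None = None,
                   projection: LocalProjection = DEFAULT_ORIGIN) -> NestSet:
    """Nests scattered over a central breeding area, flagged with breeding
    outcome; a configured fraction fails before chick-rearing."""
    rng = rng if rng is not None else _rng(config, 1)
    extent_m = config.extent_km * 1000.0
    # central breeding block; commuting patches must still fit the landscape
    lo, hi = 0.35 * extent_m, 0.65 * extent_m
    rows = []
    for species in sorted(config.n_nests_per_species):
        n = config.n_nests_per_species[species]
        xs = rng.uniform(lo, hi, size=n)
        ys = rng.uniform(lo, hi, size=n)
        failed = rng.random(n) < config.frac_failed_nests
        for i in range(n):
            rows.append({
                "nest_id": f"{species}_nest_{i:03d}",
                "species": species,
                "year": config.year,
                "x": xs[i], "y": ys[i],
                "reached_chick_rearing": not failed[i],
            })
    df = pd.DataFrame(rows)
    df["lon"], df["lat"] = projection.inverse(df["x"].to_numpy(),
                                              df["y"].to_numpy())
    return NestSet(records=df)


def _duty_times(config: SimConfig, interval_min: float) -> np.ndarray:
    """Seconds-from-midnight of every fix slot in one duty-cycle day."""
    h0, m0 = (int(v) for v in config.duty_start.split(":"))
    h1, m1 = (int(v) for v in config.duty_end.split(":"))
    start, end = h0 * 3600 + m0 * 60, h1 * 3600 + m1 * 60
    step = interval_min * 60.0
    n = int(np.floor((end - start) / step)) + 1
    return start + step * np.arange(n)


def _diel_weight(sp: SpeciesParams, hours: np.ndarray) -> np.ndarray:
    if sp.diel_mode == "uniform":
        return np.ones_like(hours)
    peak = np.exp(-0.5 * ((hours - sp.peak_hour) / sp.peak_sd_hours) ** 2)
    # baseline floor: diurnal raptors stay active off-peak as well
    return sp.diel_floor + (1.0 - sp.diel_floor) * peak


def _season_days(year: int, start: tuple[int, int],
                 end: tuple[int, int]) -> list[datetime]:
    d0 = datetime(year, *start)
    d1 = datetime(year, *end)
    return [d0 + timedelta(days=i) for i in range((d1 - d0).days + 1)]


def _patch_cells_by_class(landscape: HabitatRaster, center: np.ndarray,
                          radius_m: float) -> list[np.ndarray]:
    """Cell centers within radius of a patch center, grouped by class."""
    xmin, ymin, xmax, ymax = landscape.extent
    cell = landscape.cell_m
    c0 = max(0, int((center[0] - radius_m - xmin) / cell))
    c1 = min(landscape.n_cols, int((center[0] + radius_m - xmin) / cell) + 1)
    rs0 = max(0, int((center[1] - radius_m - ymin) / cell))
    rs1 = min(landscape.n_rows, int((center[1] + radius_m - ymin) / cell) + 1)
    cols = np.arange(c0, c1)
    rows_south = np.arange(rs0, rs1)
    cx = xmin + (cols + 0.5) * cell
    cy = ymin + (rows_south + 0.5) * cell
    gx, gy = np.meshgrid(cx, cy)
    rows_top = landscape.n_rows - 1 - rows_south
    classes = landscape.grid[np.ix_(rows_top, cols)]
    inside = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 <= radius_m ** 2
    out = []
    for k in range(len(landscape.classes)):
        sel = inside & (classes == k)
        out.append(np.column_stack([gx[sel], gy[sel]]))
    return out


def _truncated_normal(rng, mean, sd, low, size):
    vals = rng.normal(mean, sd, size=size)
    bad = vals < low
    while bad.any():
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = vals < low
    return vals


def _draw_patches(sp: SpeciesParams, anchor_xy: np.ndarray, extent_m: float,
                  rng: np.random.Generator,
                  n_patches: int | None = None) -> np.ndarray:
    """Foraging-patch centers: distance ~ N(mean, sd) from the anchor,
    truncated away from the nest exclusion zone, kept on the map."""
    n_patches = sp.n_patches if n_patches is None else n_patches
    min_dist = (sp.nest_radius_km * 1000.0) + sp.patch_radius_m + 100.0
    patches = []
    while len(patches) < n_patches:
        d = _truncated_normal(rng, sp.patch_distance_km * 1000.0,
                              sp.patch_distance_sd_km * 1000.0,
                              min_dist, 1)[0]
        theta = rng.uniform(0, 2 * np.pi)
        p = anchor_xy + d * np.array([np.cos(theta), np.sin(theta)])
        margin = sp.patch_radius_m + 100.0
        if margin <= p[0] <= extent_m - margin and \
                margin <= p[1] <= extent_m - margin:
            patches.append(p)
    return np.asarray(patches)


def _simulate_individual(config: SimConfig, sp: SpeciesParams,
                         ind_id: str, nest_xy: np.ndarray,
                         landscape: HabitatRaster, interval_min: float,
                         rng: np.random.Generator,
                         projection: LocalProjection,
                         patches: np.ndarray | None = None) -> FixSeries:
    extent_m = config.extent_km * 1000.0
    if patches is None:
        patches = _draw_patches(sp, nest_xy, extent_m, rng)
    patch_cells = [_patch_cells_by_class(landscape, p, sp.patch_radius_m)
                   for p in patches]

    days = _season_days(config.year, sp.season_start, sp.season_end)
    slot_sec = _duty_times(config, interval_min)
    n_slots = len(slot_sec)
    n = len(days) * n_slots

    day_idx = np.repeat(np.arange(len(days)), n_slots)
    sec = np.tile(slot_sec, len(days))
    hours = sec / 3600.0

    # per-fix state: forage probability follows the diel activity mode
    w = _diel_weight(sp, hours)
    w_mean = _diel_weight(sp, _duty_times(config, interval_min) / 3600.0).mean()
    p_forage = np.minimum(0.92, sp.forage_frac * w / w_mean)
    nest_frac = max(0.0, 1.0 - sp.forage_frac - sp.transit_frac)
    denom = sp.transit_frac + nest_frac
    p_transit = (1.0 - p_forage) * (sp.transit_frac / denom if denom > 0 else 0.0)

    u = rng.random(n)
    state = np.where(u < p_forage, 0, np.where(u < p_forage + p_transit, 1, 2))

    # active patch per day; the last n_late_patches grounds are only used
    # after the shared breeding window closes
    n_early = sp.n_patches - sp.n_late_patches
    shared_end = datetime(config.year, *config.shared_window[1])
    day_patch = np.empty(len(days), dtype=int)
    for di, d in enumerate(days):
        hi = sp.n_patches if (sp.n_late_patches and d > shared_end) else n_early
        day_patch[di] = rng.integers(0, max(hi, 1))
    fix_patch = day_patch[day_idx]

    x = np.empty(n)
    y = np.empty(n)
    speed = np.empty(n)

    # --- foraging fixes: habitat-preference sampling inside the day's patch
    use = np.array([sp.habitat_use.get(c, 0.0) for c in landscape.classes])
    if use.sum() <= 0:
        use = np.ones(len(landscape.classes))
    use = use / use.sum()
    forage = state == 0
    f_class = rng.choice(len(use), size=int(forage.sum()), p=use)
    f_idx = np.nonzero(forage)[0]
    half = landscape.cell_m / 2.0
    for pi in range(sp.n_patches):
        for ci in range(len(use)):
            sel = f_idx[(fix_patch[f_idx] == pi) & (f_class == ci)]
            if len(sel) == 0:
                continue
            cand = patch_cells[pi][ci]
            if len(cand) == 0:        # class absent near patch: any cell
                cand = np.concatenate(
                    [c for c in patch_cells[pi] if len(c)], axis=0)
            pick = rng.integers(0, len(cand), size=len(sel))
            x[sel] = cand[pick, 0] + rng.uniform(-half, half, len(sel))
            y[sel] = cand[pick, 1] + rng.uniform(-half, half, len(sel))
    speed[forage] = np.abs(rng.normal(sp.forage_speed_ms,
                                      sp.forage_speed_sd_ms,
                                      int(forage.sum())))

    # --- transit fixes: along the nest-patch segment with lateral jitter
    transit = state == 1
    t_idx = np.nonzero(transit)[0]
    frac = rng.random(len(t_idx))
    seg = patches[fix_patch[t_idx]] - nest_xy
    seg_len = np.linalg.norm(seg, axis=1, keepdims=True)
    unit = seg / seg_len
    normal = np.column_stack([-unit[:, 1], unit[:, 0]])
    lateral = rng.normal(0.0, sp.corridor_halfwidth_m, len(t_idx))
    pos = nest_xy + seg * frac[:, None] + normal * lateral[:, None]
    x[t_idx] = pos[:, 0]
    y[t_idx] = pos[:, 1]
    speed[t_idx] = _truncated_normal(rng, sp.transit_speed_ms,
                                     sp.transit_speed_sd_ms, 4.05,
                                     len(t_idx))
    # occasional rests inside the corridor (slow fixes, sparse)
    rest = rng.random(len(t_idx)) < sp.corridor_rest_prob
    speed[t_idx[rest]] = rng.uniform(0.5, 3.5, int(rest.sum()))

    # --- nest fixes: social activity around the nest itself
    at_nest = state == 2
    n_nest = int(at_nest.sum())
    x[at_nest] = nest_xy[0] + rng.normal(0, 40.0, n_nest)
    y[at_nest] = nest_xy[1] + rng.normal(0, 40.0, n_nest)
    speed[at_nest] = np.abs(rng.normal(0.3, 0.3, n_nest))

    heading = rng.uniform(0.0, 360.0, n)
    base = np.array([np.datetime64(d) for d in days])
    ts = base[day_idx] + (sec * 1e6).astype("timedelta64[us]")

    lon, lat = projection.inverse(x, y)
    state_names = np.array(["forage", "transit", "nest"])
    fixes = pd.DataFrame({
        "timestamp": pd.to_datetime(ts).astype("datetime64[ns]"),
        "lon": lon, "lat": lat,
        "ground_speed": speed, "heading": heading,
        "x": x, "y": y,
        "sim_state": state_names[state],
    })
    return FixSeries(individual_id=ind_id, species=sp.name, fixes=fixes)


def generate_tracks(config: SimConfig, nests: NestSet,
                    landscape: HabitatRaster,
                    rng: np.random.Generator | None = None,
                    projection: LocalProjection = DEFAULT_ORIGIN
                    ) -> list[FixSeries]:
    """Simulate one FixSeries per tagged individual.

    Tagged individuals are assigned, per species, to the first nests that
    reached chick-rearing; the first ``n_solar_per_species`` carry a 5-min
    solar tag, the rest a 90-min regular tag.
    """
    rng = rng if rng is not None else _rng(config, 2)
    extent_m = config.extent_km * 1000.0
    tracks = []
    for species in sorted(config.species):
        sp = config.species[species]
        good = nests.for_species(species)
        good = good[good["reached_chick_rearing"]]
        n_ind = config.n_individuals_per_species[species]
        if len(good) < n_ind:
            raise InputError(f"not enough successful nests for {species}")
        n_solar = config.n_solar_per_species.get(species, n_ind)
        pool = None
        if sp.shared_patches:
            # species-level pool of foraging grounds; each individual uses a
            # subset, so conspecific ranges overlap partially, not totally
            anchor = good.iloc[:n_ind][["x", "y"]].to_numpy(dtype=float).mean(axis=0)
            pool = _draw_patches(sp, anchor, extent_m, rng,
                                 n_patches=max(sp.shared_pool_size,
                                               sp.n_patches))
        for i in range(n_ind):
            nest = good.iloc[i]
            nest_xy = np.array([nest["x"], nest["y"]], dtype=float)
            if not (0 <= nest_xy[0] <= extent_m and 0 <= nest_xy[1] <= extent_m):
                raise InputError(f"nest {nest['nest_id']} outside landscape")
            interval = (sp.fix_interval_min if i < n_solar
                        else config.regular_fix_interval_min)
            ind_id = f"{species}_{2180 + i}"
            own = None
            if pool is not None:
                sel = np.sort(rng.choice(len(pool), size=sp.n_patches,
                                         replace=False))
                own = pool[sel]
            tracks.append(_simulate_individual(
                config, sp, ind_id, nest_xy, landscape, interval, rng,
                projection, patches=own))
    return tracks


def taxon_metadata(config: SimConfig) -> pd.DataFrame:
    return pd.DataFrame(list(config.taxa),
                        columns=["taxon", "category", "subcategory"])


def generate_diets(config: SimConfig, nests: NestSet,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Multinomial per-nest-per-year diets from the species taxon vectors.

    A configured fraction of nest-years receives fewer than the minimum
    item count so the downstream diet filter has something to drop.
    """
    rng = rng if rng is not None else _rng(config, 3)
    meta = taxon_metadata(config).set_index("taxon")
    taxa = [t[0] for t in config.taxa]
    years = [config.year - config.n_years_diet + 1 + i
             for i in range(config.n_years_diet)]
    rows = []
    for species in sorted(config.species):
        sp = config.species[species]
        probs = np.array([sp.diet_probs.get(t, 0.0) for t in taxa])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"{species} diet probabilities do not sum to 1")
        for _, nest in nests.for_species(species).iterrows():
            if sp.diet_concentration is not None:
                nz = probs > 0
                alpha = sp.diet_concentration * probs[nz]
                nest_probs = np.zeros_like(probs)
                nest_probs[nz] = rng.dirichlet(alpha)
            else:
                nest_probs = probs
            for year in years:
                if rng.random() < config.frac_small_nests:
                    n_items = int(rng.integers(1, 8))
                else:
                    n_items = max(8, int(rng.poisson(sp.mean_items_per_nest)))
                counts = rng.multinomial(n_items, nest_probs)
                for t, c in zip(taxa, counts):
                    if c > 0:
                        rows.append({
                            "nest_id": nest["nest_id"], "species": species,
                            "year": year, "taxon": t, "count": int(c),
                            "category": meta.loc[t, "category"],
                            "subcategory": meta.loc[t, "subcategory"],
                        })
    return pd.DataFrame(rows)


def synthesize(config: SimConfig,
               projection: LocalProjection = DEFAULT_ORIGIN) -> SyntheticDataset:
    """Generate the full synthetic study (deterministic in config.seed)."""
    landscape = generate_landscape(config)
    nests = generate_nests(config, projection=projection)
    tracks = generate_tracks(config, nests, landscape, projection=projection)
    diets = generate_diets(config, nests)
    return SyntheticDataset(config=config, landscape=landscape, nests=nests,
                            tracks=tracks, diets=diets, projection=projection)
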