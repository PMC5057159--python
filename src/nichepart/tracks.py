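"""Foraging-point classification and quality control for GPS tracks.

The filter chain is fixed and order-sensitive:

    speed threshold -> nest-vicinity exclusion -> point-density (corridor)
    filter -> polygon-level QC

A fix is a *standing point* when its tag-reported ground speed is strictly
below the threshold (default 4 m/s). Standing points within the
species-specific nest radius (default 0.15 km near-nest / 1.5 km commuting)
are attributed to social interactions and removed. The density filter drops
points in sparse grid cells, which removes flight corridors. Polygon-level
QC drops individuals with too few points or whose nest failed before
chick-rearing, and averages per-individual summaries over two consecutive
eligible seasons.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np

from .config import ConfigurationError, QCPolicy
from .raster import InputError
from .types import FixSeries, NestSet, StandingPointSet


class UndefinedResultError(ValueError):
    """Raised when an operation has no defined result (e.g. empty input)."""


def classify_standing_points(fs: FixSeries, policy: QCPolicy,
                             window: str = "whole") -> StandingPointSet:
    """Retain exactly the fixes with ground speed strictly below threshold."""
    speeds = fs.fixes["ground_speed"]
    if speeds.isna().all():
        raise InputError(
            f"{fs.individual_id}: no ground-speed field; enable a "
            "displacement fallback explicitly before classifying")
    keep = speeds < policy.speed_threshold
    pts = fs.fixes[keep].reset_index(drop=True)
    return StandingPointSet(
        individual_id=fs.individual_id, species=fs.species, window=window,
        points=pts, filters_applied=[f"speed<{policy.speed_threshold}"])


def exclude_nest_vicinity(sps: StandingPointSet, nest_xy,
                          policy: QCPolicy) -> StandingPointSet:
    """Remove points strictly closer to the nest than the species radius."""
    if sps.species not in policy.nest_radius_km:
        raise ConfigurationError(
            f"no nest-exclusion radius configured for {sps.species!r}")
    radius_m = policy.nest_radius_km[sps.species] * 1000.0
    nest_xy = np.asarray(nest_xy, dtype=float)
    d = np.hypot(sps.points["x"] - nest_xy[0], sps.points["y"] - nest_xy[1])
    keep = d >= radius_m
    return sps.replace(sps.points[keep],
                       f"nest_vicinity>={policy.nest_radius_km[sps.species]}km")


def density_filter(sps: StandingPointSet, cell_m: float | None = None,
                   quantile_q: float | None = None,
                   policy: QCPolicy | None = None) -> StandingPointSet:
    """Keep points in grid cells at or above the q-th quantile of nonzero
    cell counts; sparse corridor cells fall below it and are removed."""
    if policy is not None:
        cell_m = policy.density_cell_m if cell_m is None else cell_m
        quantile_q = policy.density_quantile if quantile_q is None else quantile_q
    if cell_m is None or cell_m <= 0:
        raise ConfigurationError("density filter cell size must be positive")
    if quantile_q is None:
        quantile_q = 0.5
    if len(sps) == 0:
        raise InputError("density filter requires at least one point")
    ix = np.floor(sps.points["x"].to_numpy() / cell_m).astype(np.int64)
    iy = np.floor(sps.points["y"].to_numpy() / cell_m).astype(np.int64)
    cell_id = ix * 2_000_003 + iy          # injective for |ix| < 1e6 cells
    uniq, inverse, counts = np.unique(cell_id, return_inverse=True,
                                      return_counts=True)
    threshold = np.quantile(counts, quantile_q) if quantile_q > 0 else 0.0
    keep = counts[inverse] >= threshold
    return sps.replace(sps.points[keep],
                       f"density(cell={cell_m}m,q={quantile_q})")


def _window_bounds(year: int, window: tuple[tuple[int, int], tuple[int, int]]):
    (m0, d0), (m1, d1) = window
    return datetime(year, m0, d0), datetime(year, m1, d1, 23, 59, 59, 999999)


def season_window(fs: FixSeries, mode: str, policy: QCPolicy) -> FixSeries:
    """Clip a series to the shared window or the species' whole season.

    Boundary days are inclusive on both ends.
    """
    if mode == "shared":
        window = policy.shared_window
    elif mode == "whole":
        window = policy.species_seasons.get(fs.species, policy.shared_window)
    else:
        raise ConfigurationError(f"unknown season mode {mode!r}")
    ts = fs.fixes["timestamp"]
    keep = np.zeros(len(ts), dtype=bool)
    for year in ts.dt.year.unique():
        lo, hi = _window_bounds(int(year), window)
        keep |= ((ts >= lo) & (ts <= hi)).to_numpy()
    return FixSeries(individual_id=fs.individual_id, species=fs.species,
                     fixes=fs.fixes[keep].reset_index(drop=True))


def qc_filter(sets: list[StandingPointSet], nests: NestSet,
              policy: QCPolicy,
              nest_of_individual: dict[str, str] | None = None
              ) -> tuple[list[StandingPointSet], list[dict]]:
    """Apply polygon-level QC; returns (eligible sets, exclusion log).

    Exclusion reasons: ``too_few_points`` (< min_points) and
    ``no_chick_rearing`` (nest failed before chick-rearing). Each excluded
    set appears exactly once in the log.
    """
    eligible: list[StandingPointSet] = []
    log: list[dict] = []
    nest_status: dict[str, bool] = {}
    for _, row in nests.records.iterrows():
        nid = row["nest_id"]
        nest_status[nid] = nest_status.get(nid, True) and \
            bool(row["reached_chick_rearing"])
    for sps in sets:
        if len(sps) < policy.min_points:
            log.append({"individual_id": sps.individual_id,
                        "window": sps.window,
                        "reason": "too_few_points",
                        "detail": f"{len(sps)}<{policy.min_points}"})
            continue
        if policy.require_chick_rearing and nest_of_individual is not None:
            nid = nest_of_individual.get(sps.individual_id)
            if nid is not None and not nest_status.get(nid, True):
                log.append({"individual_id": sps.individual_id,
                            "window": sps.window,
                            "reason": "no_chick_rearing",
                            "detail": nid})
                continue
        sps.eligible = True
        sps.filters_applied = sps.filters_applied + ["qc"]
        eligible.append(sps)
    return eligible, log


def average_consecutive_seasons(values_by_season: dict[int, float],
                                overlap_by_pair: dict[tuple[int, int], float]
                                | None = None) -> float:
    """Per-individual summary over seasons: mean of two consecutive seasons
    when their foraging areas were similar (seasonal UDOI > 0), else the
    single (or first) season's value."""
    years = sorted(values_by_season)
    if len(years) == 1:
        return values_by_season[years[0]]
    y0, y1 = years[0], years[1]
    if overlap_by_pair is not None and overlap_by_pair.get((y0, y1), 1.0) <= 0:
        return values_by_season[y0]
    return 0.5 * (values_by_season[y0] + values_by_season[y1])


def mean_distance_to_nest(sps: StandingPointSet, nest_xy) -> float:
    """Mean Euclidean distance (km) from standing points to the nest."""
    if len(sps) == 0:
        raise UndefinedResultError(
            f"{sps.individual_id}: empty standing-point set")
    nest_xy = np.asarray(nest_xy, dtype=float)
    d = np.hypot(sps.points["x"] - nest_xy[0], sps.points["y"] - nest_xy[1])
    return float(d.mean()) / 1000.0


def process_individual(fs: FixSeries, nest_xy, policy: QCPolicy,
                       window: str = "shared") -> StandingPointSet:
    """The fixed filter chain for one individual:
    season window -> speed -> nest vicinity -> density."""
    clipped = season_window(fs, window, policy)
    sps = classify_standing_points(clipped, policy, window=window)
    sps = exclude_nest_vicinity(sps, nest_xy, policy)
    if len(sps) == 0:
        return sps
    return density_filter(sps, policy=policy)
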