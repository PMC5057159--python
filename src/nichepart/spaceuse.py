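"""Utilization distributions, 95% foraging areas, and UD overlap (UDOI).

The UD is a fixed-bandwidth isotropic bivariate Gaussian KDE (smoothing
factor h = kernel sigma, the adehabitat convention) evaluated at the centers
of a square grid and stored as per-cell probability masses (density x cell
area, renormalized to total mass 1). Kernels are truncated at 6h, where the
neglected mass is < 1e-8 of a kernel; the grid is padded 5h beyond the point
bounding box so edge truncation is negligible.

The isopleth region at level p is the smallest set of cells, in descending
density order, whose cumulative mass reaches p; cells tied with the
threshold density are all included (so a uniform UD's isopleth is its full
support). Area is cell count x cell area.

UDOI(1,2) = A_{1,2} * sum(m1 * m2) / cellArea, with A_{1,2} the area of
intersection of the two level-p isopleth regions; 0 when they are disjoint,
1 for identical uniform UDs, and > 1 is possible for concentrated joint use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ConfigurationError, QCPolicy
from .types import StandingPointSet

TRUNC_SIGMAS = 6.0
PAD_SIGMAS = 5.0


class QCError(ValueError):
    """Raised when an input fails a quality-control precondition."""


class GridError(ValueError):
    """Raised when two utilization grids are incompatible."""


@dataclass
class UtilizationGrid:
    """Discretized utilization distribution.

    ``masses[i, j]`` is the probability mass in the cell whose lower-left
    corner is (x0 + j*cell, y0 + i*cell): row index increases northwards.
    """

    x0: float
    y0: float
    cell_m: float
    masses: np.ndarray
    h_m: float

    @property
    def n_rows(self) -> int:
        return self.masses.shape[0]

    @property
    def n_cols(self) -> int:
        return self.masses.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xc = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_m
        yc = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_m
        return xc, yc

    def same_grid(self, other: "UtilizationGrid", tol: float = 1e-6) -> bool:
        return (abs(self.x0 - other.x0) < tol and
                abs(self.y0 - other.y0) < tol and
                abs(self.cell_m - other.cell_m) < tol and
                self.masses.shape == other.masses.shape)


@dataclass
class IsoplethRegion:
    level: float
    member: np.ndarray        # boolean cell mask on the source grid
    grid: UtilizationGrid
    area_km2: float

    def contains_points(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.grid.x0) / self.grid.cell_m).astype(int)
        row = np.floor((y - self.grid.y0) / self.grid.cell_m).astype(int)
        ok = (col >= 0) & (col < self.grid.n_cols) & \
             (row >= 0) & (row < self.grid.n_rows)
        out = np.zeros(x.shape, dtype=bool)
        out[ok] = self.member[row[ok], col[ok]]
        return out

    def boundary_geojson_geometry(self) -> dict:
        """Polygonized boundary (union of member cell squares) as GeoJSON
        geometry in planar coordinates."""
        from shapely.geometry import box, mapping
        from shapely.ops import unary_union
        g = self.grid
        rows, cols = np.nonzero(self.member)
        boxes = [box(g.x0 + c * g.cell_m, g.y0 + r * g.cell_m,
                     g.x0 + (c + 1) * g.cell_m, g.y0 + (r + 1) * g.cell_m)
                 for r, c in zip(rows, cols)]
        return mapping(unary_union(boxes))


def kde_ud(sps_or_xy, h_m: float, cell_m: float | None = None,
           bounds: tuple[float, float, float, float] | None = None,
           min_points: int = 1) -> UtilizationGrid:
    """Fixed-bandwidth Gaussian KDE UD on a grid.

    ``bounds`` (xmin, ymin, xmax, ymax) pins the grid for cross-individual
    comparison; otherwise the point bounding box padded by 5h is used.
    """
    if isinstance(sps_or_xy, StandingPointSet):
        xy = sps_or_xy.xy
    else:
        xy = np.asarray(sps_or_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < min_points:
        raise QCError(f"need at least {min_points} points, got {len(xy)}")
    if h_m <= 0:
        raise ConfigurationError("smoothing factor must be positive")
    if cell_m is None:
        cell_m = h_m / 5.0
    if cell_m > h_m / 5.0 + 1e-9:
        raise ConfigurationError(
            f"cell size {cell_m} too coarse for h={h_m} (need cell <= h/5)")

    if bounds is None:
        pad = PAD_SIGMAS * h_m
        xmin, ymin = xy.min(axis=0) - pad
        xmax, ymax = xy.max(axis=0) + pad
    else:
        xmin, ymin, xmax, ymax = bounds
    n_cols = int(np.ceil((xmax - xmin) / cell_m))
    n_rows = int(np.ceil((ymax - ymin) / cell_m))

    xc = xmin + (np.arange(n_cols) + 0.5) * cell_m
    yc = ymin + (np.arange(n_rows) + 0.5) * cell_m
    dens = np.zeros((n_rows, n_cols))
    trunc = TRUNC_SIGMAS * h_m
    inv2h2 = 1.0 / (2.0 * h_m * h_m)
    for px, py in xy:
        j0 = max(0, int(np.searchsorted(xc, px - trunc)))
        j1 = min(n_cols, int(np.searchsorted(xc, px + trunc)) + 1)
        i0 = max(0, int(np.searchsorted(yc, py - trunc)))
        i1 = min(n_rows, int(np.searchsorted(yc, py + trunc)) + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        gx = np.exp(-((xc[j0:j1] - px) ** 2) * inv2h2)
        gy = np.exp(-((yc[i0:i1] - py) ** 2) * inv2h2)
        dens[i0:i1, j0:j1] += np.outer(gy, gx)
    dens *= cell_m * cell_m / (2.0 * np.pi * h_m * h_m * len(xy))
    total = dens.sum()
    if total <= 0:
        raise QCError("all probability mass fell outside the grid bounds")
    return UtilizationGrid(x0=xmin, y0=ymin, cell_m=cell_m,
                           masses=dens / total, h_m=h_m)


def isopleth(ud: UtilizationGrid, level: float = 0.95) -> IsoplethRegion:
    """Smallest cell set (density-ranked, tie-inclusive) with mass >= level."""
    if not 0.0 < level < 1.0:
        raise ConfigurationError(f"isopleth level must be in (0,1), got {level}")
    flat = ud.masses.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level * csum[-1] - 1e-12))
    threshold = flat[order[k]]
    member = (ud.masses >= threshold) & (ud.masses > 0)
    area_km2 = member.sum() * (ud.cell_m ** 2) / 1e6
    return IsoplethRegion(level=level, member=member, grid=ud,
                          area_km2=float(area_km2))


def udoi(ud1: UtilizationGrid, ud2: UtilizationGrid,
         level: float = 0.95) -> float:
    """Utilization Distribution Overlap Index on a common grid."""
    if not ud1.same_grid(ud2):
        raise GridError("UDs are on different grids; resample first "
                        "(see kde_ud bounds=... or resample_pair)")
    r1 = isopleth(ud1, level)
    r2 = isopleth(ud2, level)
    inter = r1.member & r2.member
    if not inter.any():
        return 0.0
    area_m2 = inter.sum() * ud1.cell_m ** 2
    prod = float((ud1.masses * ud2.masses).sum()) / (ud1.cell_m ** 2)
    return float(area_m2 * prod)


def resample_pair(xy1: np.ndarray, xy2: np.ndarray, h_m: float,
                  cell_m: float | None = None
                  ) -> tuple[UtilizationGrid, UtilizationGrid]:
    """Evaluate two point sets' KDEs on their shared (union) grid."""
    pad = PAD_SIGMAS * h_m
    allxy = np.vstack([xy1, xy2])
    xmin, ymin = allxy.min(axis=0) - pad
    xmax, ymax = allxy.max(axis=0) + pad
    bounds = (xmin, ymin, xmax, ymax)
    return (kde_ud(xy1, h_m, cell_m, bounds=bounds),
            kde_ud(xy2, h_m, cell_m, bounds=bounds))


@dataclass
class OverlapMatrix:
    ids: list[str]
    species: list[str]
    values: np.ndarray          # symmetric, NaN diagonal
    level: float = 0.95

    def pair_groups(self) -> dict[str, np.ndarray]:
        """UDOI values split into within-species and between-species pairs."""
        labels = sorted(set(self.species))
        if len(labels) != 2:
            raise ConfigurationError("pair grouping expects exactly 2 species")
        a, b = labels
        groups: dict[str, list[float]] = {f"within_{a}": [],
                                          f"within_{b}": [],
                                          "between": []}
        for i, j in itertools.combinations(range(len(self.ids)), 2):
            v = self.values[i, j]
            if np.isnan(v):
                continue
            si, sj = self.species[i], self.species[j]
            if si == sj == a:
                groups[f"within_{a}"].append(v)
            elif si == sj == b:
                groups[f"within_{b}"].append(v)
            else:
                groups["between"].append(v)
        return {k: np.asarray(v) for k, v in groups.items()}


def overlap_matrix(ud_by_id: dict[str, UtilizationGrid],
                   species_by_id: dict[str, str],
                   level: float = 0.95) -> OverlapMatrix:
    """Pairwise UDOI between all individuals (UDs on a common grid).

    Equivalent to calling :func:`udoi` per pair, but each isopleth is
    computed once.
    """
    ids = sorted(ud_by_id)
    n = len(ids)
    members = {i: isopleth(ud_by_id[i], level).member for i in ids}
    vals = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        ud1, ud2 = ud_by_id[ids[i]], ud_by_id[ids[j]]
        if not ud1.same_grid(ud2):
            raise GridError("overlap_matrix requires a common grid")
        inter = members[ids[i]] & members[ids[j]]
        if not inter.any():
            v = 0.0
        else:
            area_m2 = inter.sum() * ud1.cell_m ** 2
            v = float(area_m2 * (ud1.masses * ud2.masses).sum()
                      / ud1.cell_m ** 2)
        vals[i, j] = vals[j, i] = v
    return OverlapMatrix(ids=ids, species=[species_by_id[i] for i in ids],
                         values=vals, level=level)


def group_udoi_test(om: OverlapMatrix) -> dict:
    """One-way ANOVA on arcsin-sqrt transformed UDOI across pair groups
    (within species A / within species B / between), with Bonferroni
    pairwise comparisons. UDOI may exceed 1 by definition; values are
    clipped to [0, 1] for the transform and exceedances counted."""
    groups = om.pair_groups()
    for name, vals in groups.items():
        if len(vals) < 2:
            raise QCError(f"pair group {name!r} has fewer than 2 pairs")
    exceed = int(sum((v > 1).sum() for v in groups.values()))
    tg = {k: np.arcsin(np.sqrt(np.clip(v, 0.0, 1.0)))
          for k, v in groups.items()}
    names = sorted(tg)
    samples = [tg[n] for n in names]
    if all(np.allclose(s, samples[0][0]) for s in samples):
        f_val, p_val = 0.0, 1.0
    else:
        f_val, p_val = stats.f_oneway(*samples)
    df_between = len(names) - 1
    df_within = sum(len(s) for s in samples) - len(names)
    pairwise = {}
    n_comp = len(names) * (len(names) - 1) // 2
    for a, b in itertools.combinations(names, 2):
        t, p = stats.ttest_ind(tg[a], tg[b], equal_var=False)
        pairwise[f"{a}|{b}"] = {
            "t": float(t),
            "p_bonferroni": float(min(1.0, p * n_comp)),
            "mean_diff": float(tg[a].mean() - tg[b].mean()),
        }
    return {
        "F": float(f_val), "p": float(p_val),
        "df": (df_between, df_within),
        "group_means_raw": {k: float(np.mean(v)) for k, v in groups.items()},
        "group_sd_raw": {k: float(np.std(v, ddof=1)) for k, v in groups.items()},
        "pairwise": pairwise,
        "udoi_exceedances_clipped": exceed,
    }


def individual_summary(sps: StandingPointSet, nest_xy, policy: QCPolicy,
                       cell_m: float | None = None) -> dict:
    """Per-individual mean nest distance and 95% areas at each h."""
    from .tracks import mean_distance_to_nest
    out = {"individual_id": sps.individual_id, "species": sps.species,
           "window": sps.window, "n_points": len(sps),
           "distance_km": mean_distance_to_nest(sps, nest_xy)}
    for h in policy.h_set:
        ud = kde_ud(sps, h_m=h, cell_m=cell_m, min_points=policy.min_points)
        out[f"area_km2_h{int(h)}"] = isopleth(ud).area_km2
    return out
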