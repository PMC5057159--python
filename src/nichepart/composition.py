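"""Composition matrices: habitat use, hourly foraging activity, and diet.

All three downstream statistics layers (overlap indices, null models,
community statistics) consume the same structure: a units x categories
matrix of non-negative values with species group labels, whose proportion
rows sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DAYTIME_HOURS, QCPolicy
from .raster import HabitatRaster, InputError
from .spaceuse import IsoplethRegion
from .types import FixSeries, StandingPointSet


class UndefinedRowError(ValueError):
    pass


@dataclass
class CompositionMatrix:
    unit_ids: list[str]
    groups: list[str]               # species label per unit
    categories: list[str]
    values: np.ndarray              # units x categories
    kind: str                       # "proportion" | "mean_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unit_ids), len(self.categories)):
            raise InputError("composition matrix shape mismatch")
        if (self.values < 0).any():
            raise InputError("composition values must be non-negative")
        if self.kind == "proportion":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = [self.unit_ids[i] for i in np.nonzero(
                    ~np.isclose(sums, 1.0, atol=1e-9))[0]]
                raise InputError(f"proportion rows do not sum to 1: {bad}")

    def to_proportions(self) -> "CompositionMatrix":
        if self.kind == "proportion":
            return self
        sums = self.values.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise InputError("cannot normalize an all-zero row")
        return CompositionMatrix(self.unit_ids, self.groups, self.categories,
                                 self.values / sums, "proportion")

    def rows_for_group(self, group: str) -> np.ndarray:
        sel = [i for i, g in enumerate(self.groups) if g == group]
        return self.values[sel]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.categories)
        df.insert(0, "unit_id", self.unit_ids)
        df.insert(1, "group", self.groups)
        return df


def habitat_composition(sets: list[StandingPointSet],
                        raster: HabitatRaster) -> tuple[CompositionMatrix, dict]:
    """Per-individual proportions of standing points per habitat class
    (point-in-cell lookup; no polygon-area weighting)."""
    rows, ids, groups = [], [], []
    outside_log = {}
    for sps in sets:
        classes = raster.sample(sps.points["x"].to_numpy(),
                                sps.points["y"].to_numpy())
        outside = int((classes < 0).sum())
        outside_log[sps.individual_id] = outside
        inside = classes[classes >= 0]
        if len(inside) == 0:
            raise InputError(
                f"{sps.individual_id}: all standing points outside raster")
        counts = np.bincount(inside, minlength=len(raster.classes)).astype(float)
        rows.append(counts / counts.sum())
        ids.append(sps.individual_id)
        groups.append(sps.species)
    cm = CompositionMatrix(ids, groups, list(raster.classes),
                           np.array(rows), "proportion")
    return cm, {"points_outside_raster": outside_log}


def availability(raster: HabitatRaster,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Habitat-class availability over the study area (cell fractions)."""
    return raster.class_proportions(mask)


def use_vs_availability(cm: CompositionMatrix, avail: np.ndarray) -> pd.DataFrame:
    """Per species x habitat class: one-sample t of individual use
    proportions against the availability constant, with direction."""
    avail = np.asarray(avail, dtype=float)
    if len(avail) != len(cm.categories):
        raise InputError("availability length mismatch")
    out = []
    for group in sorted(set(cm.groups)):
        rows = cm.rows_for_group(group)
        if rows.shape[0] < 2:
            raise InputError(f"group {group!r} has fewer than 2 units")
        for j, cat in enumerate(cm.categories):
            x = rows[:, j]
            if np.allclose(x.std(ddof=1), 0.0):
                if np.isclose(x.mean(), avail[j]):
                    t, p, flag = 0.0, 1.0, ""
                else:
                    t = np.inf if x.mean() > avail[j] else -np.inf
                    p, flag = 0.0, "zero_variance"
            else:
                t, p = stats.ttest_1samp(x, avail[j])
                flag = ""
            direction = ("preference" if x.mean() > avail[j]
                         else "avoidance" if x.mean() < avail[j] else "none")
            out.append({"species": group, "category": cat,
                        "mean_use": float(x.mean()),
                        "availability": float(avail[j]),
                        "t": float(t), "p": float(p), "df": len(x) - 1,
                        "direction": direction, "flag": flag})
    return pd.DataFrame(out)


def hourly_activity(fs: FixSeries, region: IsoplethRegion,
                    hours: tuple[int, ...] = DAYTIME_HOURS
                    ) -> np.ndarray:
    """Proportion of in-foraging-area fixes per daytime hour bin [h, h+1).

    The duty cycle only partially covers the hours before 07:00 and after
    19:00, so those fixes are outside the 07:00-19:00 bins and dropped.
    Intended for high-frequency (5-min) series.
    """
    inside = region.contains_points(fs.fixes["x"].to_numpy(),
                                    fs.fixes["y"].to_numpy())
    hod = fs.fixes["timestamp"].dt.hour.to_numpy()
    counts = np.array([(inside & (hod == h)).sum() for h in hours],
                      dtype=float)
    if counts.sum() == 0:
        raise UndefinedRowError(
            f"{fs.individual_id}: no in-region fixes in daytime hours")
    return counts / counts.sum()


def activity_matrix(series: list[FixSeries],
                    regions: dict[str, IsoplethRegion],
                    hours: tuple[int, ...] = DAYTIME_HOURS
                    ) -> CompositionMatrix:
    rows, ids, groups = [], [], []
    for fs in series:
        rows.append(hourly_activity(fs, regions[fs.individual_id], hours))
        ids.append(fs.individual_id)
        groups.append(fs.species)
    return CompositionMatrix(ids, groups, [f"h{h:02d}" for h in hours],
                             np.array(rows), "proportion")


def diet_matrix(diet: pd.DataFrame, policy: QCPolicy
                ) -> tuple[CompositionMatrix, pd.DataFrame, list[dict]]:
    """Per-nest (territory) diet matrix with the under-sampling filter.

    Nest-years with fewer than ``min_diet_items`` items are dropped; each
    retained nest's value per taxon is the mean count across its retained
    years. Returns (matrix of mean counts, taxon metadata, exclusion log).
    Reapplying filter + averaging to its own output changes nothing
    (idempotent).
    """
    required = {"nest_id", "species", "year", "taxon", "count"}
    if missing := required - set(diet.columns):
        raise InputError(f"diet table missing columns: {sorted(missing)}")
    if (diet["count"] <= 0).any():
        raise InputError("diet counts must be positive")

    year_totals = diet.groupby(["nest_id", "year"])["count"].sum()
    keep_years = year_totals[year_totals >= policy.min_diet_items].index
    log = [{"nest_id": nid, "year": int(yr), "reason": "too_few_items",
            "detail": int(year_totals.loc[(nid, yr)])}
           for nid, yr in year_totals.index if (nid, yr) not in set(keep_years)]
    kept = diet.set_index(["nest_id", "year"]).loc[
        diet.set_index(["nest_id", "year"]).index.isin(set(keep_years))
    ].reset_index()
    dropped_nests = set(diet["nest_id"]) - set(kept["nest_id"])
    for nid in sorted(dropped_nests):
        log.append({"nest_id": nid, "year": -1,
                    "reason": "no_retained_years", "detail": 0})
    if kept.empty:
        raise InputError("no nest-years retained by the diet filter")

    taxa = sorted(diet["taxon"].unique())
    per_year = kept.pivot_table(index=["nest_id", "year"], columns="taxon",
                                values="count", aggfunc="sum", fill_value=0)
    per_year = per_year.reindex(columns=taxa, fill_value=0)
    per_nest = per_year.groupby(level="nest_id").mean()

    species_of = kept.drop_duplicates("nest_id").set_index("nest_id")["species"]
    ids = list(per_nest.index)
    cm = CompositionMatrix(ids, [species_of[i] for i in ids], taxa,
                           per_nest.to_numpy(), "mean_count")
    meta_cols = [c for c in ("taxon", "category", "subcategory")
                 if c in diet.columns]
    meta = diet[meta_cols].drop_duplicates("taxon") if "category" in diet.columns \
        else pd.DataFrame({"taxon": taxa})
    return cm, meta.reset_index(drop=True), log


def category_fractions(cm: CompositionMatrix, meta: pd.DataFrame,
                       column: str = "category",
                       drop_empty: bool = True) -> CompositionMatrix:
    """Collapse a diet matrix's taxa into categories (or reptile
    subcategories) and return per-nest fractions.

    Units with no items in any mapped category (e.g. a nest with no
    reptiles when collapsing to snake/lizard) have an undefined fraction;
    they are dropped when ``drop_empty``, else raise.
    """
    if column not in meta.columns:
        raise InputError(f"taxon metadata lacks column {column!r}")
    mapping = meta.set_index("taxon")[column]
    unknown = set(cm.categories) - set(mapping.index)
    if unknown:
        raise InputError(f"taxa without metadata: {sorted(unknown)}")
    cats = sorted(c for c in mapping.unique() if c != "n/a")
    agg = np.zeros((len(cm.unit_ids), len(cats)))
    for j, taxon in enumerate(cm.categories):
        c = mapping[taxon]
        if c in cats:
            agg[:, [cats.index(c)]] += cm.values[:, [j]]
    sums = agg.sum(axis=1)
    nonzero = sums > 0
    if not nonzero.all():
        if not drop_empty:
            raise InputError("a nest has no items in any mapped category")
        agg = agg[nonzero]
    ids = [u for u, ok in zip(cm.unit_ids, nonzero) if ok]
    groups = [g for g, ok in zip(cm.groups, nonzero) if ok]
    return CompositionMatrix(ids, groups, cats,
                             agg / agg.sum(axis=1, keepdims=True),
                             "proportion")


def category_tests(diet_cm: CompositionMatrix, meta: pd.DataFrame) -> dict:
    """Diet-category contrasts between species.

    Per prey category: Welch two-sample t on per-nest fractions. Reptile
    composition: the species x (lizard vs snake) interaction tested as a
    Welch t on per-nest (lizard - snake) fraction differences.
    """
    groups = sorted(set(diet_cm.groups))
    if len(groups) != 2:
        raise InputError("category tests require exactly two species")
    a, b = groups
    catm = category_fractions(diet_cm, meta, "category")
    per_cat = {}
    for j, cat in enumerate(catm.categories):
        xa = catm.rows_for_group(a)[:, j]
        xb = catm.rows_for_group(b)[:, j]
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        per_cat[cat] = {"t": float(t), "p": float(p),
                        f"mean_{a}": float(xa.mean()),
                        f"mean_{b}": float(xb.mean())}
    subm = category_fractions(diet_cm, meta, "subcategory")
    out = {"per_category": per_cat, "species": (a, b)}
    if {"lizard", "snake"} <= set(subm.categories):
        li = subm.categories.index("lizard")
        si = subm.categories.index("snake")
        da = subm.rows_for_group(a)[:, li] - subm.rows_for_group(a)[:, si]
        db = subm.rows_for_group(b)[:, li] - subm.rows_for_group(b)[:, si]
        t, p = stats.ttest_ind(da, db, equal_var=False)
        out["lizard_vs_snake_interaction"] = {
            "t": float(t), "p": float(p),
            f"mean_diff_{a}": float(da.mean()),
            f"mean_diff_{b}": float(db.mean()),
        }
    return out
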