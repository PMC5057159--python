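"""File I/O: Movebank-style fix tables, GeoJSON nests, diet tables.

Geographic coordinates are projected to a local planar system in meters
with a simple equirectangular projection anchored at a reference origin
(by default the data centroid). At the spatial scale these analyses target
(tens to a couple of hundred km) the distance distortion of this projection
is far below the GPS error and the 100-500 m grid resolutions used
downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import InputError
from .types import FixSeries, NestSet

EARTH_RADIUS_M = 6_371_008.8

MOVEBANK_COLUMNS = {
    "individual": "individual-local-identifier",
    "taxon": "taxon",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "speed": "ground-speed",
    "heading": "heading",
}


class FormatError(ValueError):
    """Raised when an input file lacks required structure."""


@dataclass(frozen=True)
class LocalProjection:
    """Planar local projection centred on (lon0, lat0)."""

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = np.radians(lon - self.lon0) * EARTH_RADIUS_M * \
            math.cos(math.radians(self.lat0))
        y = np.radians(lat - self.lat0) * EARTH_RADIUS_M
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon0 + np.degrees(
            x / (EARTH_RADIUS_M * math.cos(math.radians(self.lat0))))
        lat = self.lat0 + np.degrees(y / EARTH_RADIUS_M)
        return lon, lat


# Planar origin used when synthesizing data (eastern Mediterranean foothills).
DEFAULT_ORIGIN = LocalProjection(lon0=34.95, lat0=31.70)


def read_fixes(path, projection: LocalProjection | None = None,
               species_map: dict[str, str] | None = None
               ) -> tuple[list[FixSeries], dict]:
    """Read a Movebank-style CSV into one FixSeries per individual.

    Returns (series_list, log). The log counts dropped rows: missing
    coordinates, unparseable timestamps, duplicated (individual, timestamp)
    rows, and out-of-order input.
    """
    df = pd.read_csv(path)
    required = [MOVEBANK_COLUMNS[k] for k in ("individual", "timestamp",
                                              "lon", "lat")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")

    log = {"rows_read": len(df), "missing_coordinates": 0,
           "bad_timestamps": 0, "duplicates": 0, "out_of_order": 0}

    coord_ok = df[MOVEBANK_COLUMNS["lon"]].notna() & \
        df[MOVEBANK_COLUMNS["lat"]].notna()
    log["missing_coordinates"] = int((~coord_ok).sum())
    df = df[coord_ok].copy()

    ts = pd.to_datetime(df[MOVEBANK_COLUMNS["timestamp"]], errors="coerce")
    log["bad_timestamps"] = int(ts.isna().sum())
    df = df[ts.notna()].copy()
    df["__ts"] = ts[ts.notna()]

    if projection is None:
        projection = LocalProjection(
            lon0=float(df[MOVEBANK_COLUMNS["lon"]].mean()),
            lat0=float(df[MOVEBANK_COLUMNS["lat"]].mean()))

    series: list[FixSeries] = []
    for ind_id, sub in df.groupby(MOVEBANK_COLUMNS["individual"], sort=True):
        if not sub["__ts"].is_monotonic_increasing:
            log["out_of_order"] += 1
        sub = sub.sort_values("__ts", kind="mergesort")
        dup = sub["__ts"].duplicated()
        log["duplicates"] += int(dup.sum())
        sub = sub[~dup]
        x, y = projection.forward(sub[MOVEBANK_COLUMNS["lon"]].to_numpy(),
                                  sub[MOVEBANK_COLUMNS["lat"]].to_numpy())
        taxon = ""
        if MOVEBANK_COLUMNS["taxon"] in sub.columns:
            taxon = str(sub[MOVEBANK_COLUMNS["taxon"]].iloc[0])
        species = (species_map or {}).get(str(ind_id), taxon)
        fixes = pd.DataFrame({
            "timestamp": sub["__ts"].to_numpy(),
            "lon": sub[MOVEBANK_COLUMNS["lon"]].to_numpy(dtype=float),
            "lat": sub[MOVEBANK_COLUMNS["lat"]].to_numpy(dtype=float),
            "ground_speed": sub.get(MOVEBANK_COLUMNS["speed"],
                                    pd.Series(np.nan, index=sub.index)
                                    ).to_numpy(dtype=float),
            "heading": sub.get(MOVEBANK_COLUMNS["heading"],
                               pd.Series(np.nan, index=sub.index)
                               ).to_numpy(dtype=float),
            "x": x,
            "y": y,
        })
        if "sim_state" in sub.columns:
            fixes["sim_state"] = sub["sim_state"].to_numpy()
        series.append(FixSeries(individual_id=str(ind_id), species=species,
                                fixes=fixes))
    return series, log


def write_fixes(series: list[FixSeries], path) -> None:
    """Write FixSeries to a Movebank-style CSV (ISO-8601 timestamps)."""
    frames = []
    for fs in series:
        out = pd.DataFrame({
            MOVEBANK_COLUMNS["individual"]: fs.individual_id,
            MOVEBANK_COLUMNS["taxon"]: fs.species,
            MOVEBANK_COLUMNS["timestamp"]:
                fs.fixes["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
            MOVEBANK_COLUMNS["lon"]: fs.fixes["lon"].round(7),
            MOVEBANK_COLUMNS["lat"]: fs.fixes["lat"].round(7),
            MOVEBANK_COLUMNS["speed"]: fs.fixes["ground_speed"].round(3),
            MOVEBANK_COLUMNS["heading"]: fs.fixes["heading"].round(2),
        })
        if "sim_state" in fs.fixes.columns:
            out["sim_state"] = fs.fixes["sim_state"].to_numpy()
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_nests_geojson(nests: NestSet, path) -> None:
    features = []
    for _, row in nests.records.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(float(row["lon"]), 7),
                                         round(float(row["lat"]), 7)]},
            "properties": {
                "nest_id": row["nest_id"],
                "species": row["species"],
                "year": int(row["year"]),
                "reached_chick_rearing": bool(row["reached_chick_rearing"]),
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  indent=1, sort_keys=True)


def read_nests_geojson(path, projection: LocalProjection) -> NestSet:
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj.get("features", []):
        lon, lat = feat["geometry"]["coordinates"]
        props = feat.get("properties", {})
        rows.append({"nest_id": props["nest_id"], "species": props["species"],
                     "year": int(props.get("year", 0)),
                     "lon": float(lon), "lat": float(lat),
                     "reached_chick_rearing":
                         bool(props.get("reached_chick_rearing", True))})
    if not rows:
        raise InputError(f"no nest features in {path}")
    df = pd.DataFrame(rows)
    df["x"], df["y"] = projection.forward(df["lon"].to_numpy(),
                                          df["lat"].to_numpy())
    return NestSet(records=df)


def read_diet_csv(path) -> pd.DataFrame:
    """Read a diet table CSV: nest_id, species, year, taxon, count
    [, category, subcategory]."""
    df = pd.read_csv(path)
    required = {"nest_id", "species", "year", "taxon", "count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"diet table missing columns: {sorted(missing)}")
    return df
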