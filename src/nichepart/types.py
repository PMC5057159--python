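"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FIX_COLUMNS = ["timestamp", "lon", "lat", "ground_speed", "heading", "x", "y"]


def ts_seconds(ts: pd.Series) -> np.ndarray:
    """Timestamps as float seconds since the epoch (resolution-safe)."""
    return ts.to_numpy().astype("datetime64[ns]").astype("int64") / 1e9


@dataclass
class FixSeries:
    """Time-ordered GPS fixes for one individual.

    ``fixes`` holds one row per fix with columns ``timestamp`` (tz-naive
    local time), ``lon``/``lat`` (degrees), ``ground_speed`` (m/s, as
    reported by the tag), ``heading`` (degrees) and projected planar
    coordinates ``x``/``y`` (m). Synthetic tracks additionally carry a
    ``sim_state`` column with the generating behavioural state.
    """

    individual_id: str
    species: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError(f"{self.individual_id}: timestamps not sorted")
        if (self.fixes["ground_speed"] < 0).any():
            raise ValueError(f"{self.individual_id}: negative ground speed")
        for col in ("x", "y"):
            if not np.isfinite(self.fixes[col]).all():
                raise ValueError(f"{self.individual_id}: non-finite {col}")

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class NestSet:
    """Nest records: one row per (nest_id, year) with species, coordinates
    and whether the pair reached the chick-rearing phase."""

    records: pd.DataFrame   # nest_id, species, year, lon, lat, x, y,
                            # reached_chick_rearing

    def __post_init__(self) -> None:
        dup = self.records.duplicated(subset=["nest_id", "year"])
        if dup.any():
            raise ValueError("duplicate (nest_id, year) nest records")

    def for_species(self, species: str, year: int | None = None) -> pd.DataFrame:
        sel = self.records[self.records["species"] == species]
        if year is not None:
            sel = sel[sel["year"] == year]
        return sel

    def nest_of(self, nest_id: str, year: int | None = None) -> pd.Series:
        sel = self.records[self.records["nest_id"] == nest_id]
        if year is not None:
            sel = sel[sel["year"] == year]
        if sel.empty:
            raise KeyError(f"no nest {nest_id!r} (year={year})")
        return sel.iloc[0]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class StandingPointSet:
    """Foraging standing points for one individual and season window.

    ``points`` columns: ``x``, ``y``, ``timestamp``, ``ground_speed`` (plus
    any columns carried through from the fixes). ``filters_applied`` records
    the provenance of every filter in application order.
    """

    individual_id: str
    species: str
    window: str                       # "whole" | "shared"
    points: pd.DataFrame
    filters_applied: list[str] = field(default_factory=list)
    eligible: bool = True

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points[["x", "y"]].to_numpy(dtype=float)

    def replace(self, points: pd.DataFrame, filter_name: str) -> "StandingPointSet":
        return StandingPointSet(
            individual_id=self.individual_id,
            species=self.species,
            window=self.window,
            points=points.reset_index(drop=True),
            filters_applied=self.filters_applied + [filter_name],
            eligible=self.eligible,
        )
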