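"""Configuration objects for simulation and quality control.

Two sympatric central-place foragers are modelled by default: a near-nest
forager ("LLB", a buzzard-like species foraging ~2.35 km from the nest)
and a commuting forager ("STE", an eagle-like species that reaches foraging
patches ~13 km away via flight corridors). All distances are metric; the
synthetic landscape lives in a planar coordinate system in meters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


SPEED_THRESHOLD_MS = 4.0          # standing-point rule: ground speed < 4 m/s
DEFAULT_MIN_POINTS = 51           # minimum standing points per polygon
DEFAULT_MIN_DIET_ITEMS = 8        # minimum prey items per nest-year
DEFAULT_SHARED_WINDOW = ((3, 25), (7, 15))   # Mar 25 - Jul 15, inclusive
DEFAULT_H_SET = (250.0, 500.0, 1000.0)       # KDE smoothing factors, m
DAYTIME_HOURS = tuple(range(7, 19))          # hour bins [07,19)
DUTY_CYCLE = ("06:55", "19:05")              # 12 h duty cycle


@dataclass
class SpeciesParams:
    """Movement, activity, habitat and diet parameters for one species."""

    name: str
    patch_distance_km: float            # mean nest-to-patch distance
    patch_distance_sd_km: float
    n_patches: int = 3
    patch_radius_m: float = 600.0
    shared_patches: bool = False        # species-level shared foraging grounds
    shared_pool_size: int = 6           # size of the species ground pool
    n_late_patches: int = 0             # grounds used only after the shared window
    transit_speed_ms: float = 10.0      # mean; must exceed 4 m/s
    transit_speed_sd_ms: float = 2.0
    forage_speed_ms: float = 1.0        # mean; must be below 4 m/s
    forage_speed_sd_ms: float = 0.8
    diel_mode: str = "uniform"          # "uniform" | "midday_peak"
    peak_hour: float = 13.0
    peak_sd_hours: float = 2.0
    diel_floor: float = 0.3             # baseline activity under the peak
    forage_frac: float = 0.55           # expected fraction of fixes foraging
    transit_frac: float = 0.15
    corridor_rest_prob: float = 0.02    # slow (<4 m/s) fixes inside corridors
    corridor_halfwidth_m: float = 200.0
    fix_interval_min: float = 5.0
    season_start: tuple[int, int] = (3, 25)   # (month, day)
    season_end: tuple[int, int] = (7, 15)
    nest_radius_km: float = 0.15        # nest-vicinity exclusion radius
    habitat_use: dict[str, float] = field(default_factory=dict)
    diet_probs: dict[str, float] = field(default_factory=dict)
    diet_concentration: float | None = 15.0   # Dirichlet alpha scale per nest
    mean_items_per_nest: float = 30.0

    def validate(self) -> None:
        if not self.forage_speed_ms < SPEED_THRESHOLD_MS < self.transit_speed_ms:
            raise ConfigurationError(
                f"{self.name}: forage speed mean ({self.forage_speed_ms}) must be "
                f"< {SPEED_THRESHOLD_MS} m/s < transit speed mean "
                f"({self.transit_speed_ms})"
            )
        if self.n_patches < 1 or self.patch_distance_km <= 0:
            raise ConfigurationError(f"{self.name}: patch configuration invalid")
        for label, probs in (("habitat_use", self.habitat_use),
                             ("diet_probs", self.diet_probs)):
            if probs:
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"{self.name}.{label} sums to {total!r}, not 1"
                    )
                if min(probs.values()) < 0:
                    raise ConfigurationError(f"{self.name}.{label} has negatives")
        if self.diel_mode not in ("uniform", "midday_peak"):
            raise ConfigurationError(f"unknown diel mode {self.diel_mode!r}")


# Habitat classes mirror the four most common land-cover types of a
# Mediterranean foothill landscape.
DEFAULT_HABITAT_CLASSES = (
    "mediterranean_rocky",
    "low_natural_vegetation",
    "cultivated_fields",
    "uncultivated_land",
)
DEFAULT_AVAILABILITY = (0.30, 0.12, 0.37, 0.21)

# Shared prey-taxon list with category / subcategory metadata.
# (taxon, category, subcategory)
DEFAULT_TAXA = (
    ("large_whip_snake", "reptile", "snake"),
    ("unidentified_colubrid", "reptile", "snake"),
    ("coin_snake", "reptile", "snake"),
    ("montpellier_snake", "reptile", "snake"),
    ("roughtail_rock_agama", "reptile", "lizard"),
    ("schneiders_skink", "reptile", "lizard"),
    ("starred_agama", "reptile", "lizard"),
    ("chameleon", "reptile", "lizard"),
    ("ocellated_skink", "reptile", "lizard"),
    ("domestic_pigeon", "bird", "n/a"),
    ("unidentified_bird", "bird", "n/a"),
    ("chukar_partridge", "bird", "n/a"),
    ("passerine_sp", "bird", "n/a"),
    ("social_vole", "mammal", "n/a"),
    ("black_rat", "mammal", "n/a"),
    ("brown_hare_juv", "mammal", "n/a"),
    ("hedgehog", "mammal", "n/a"),
    ("locust", "arthropod", "n/a"),
    ("scarab_beetle", "arthropod", "n/a"),
    ("mole_cricket", "arthropod", "n/a"),
)

# long tail of rare taxa (identified-to-species remains are mostly rare);
# 33 rare + 20 common = 53 taxa overall
_RARE_CYCLE = (("reptile", "lizard"), ("bird", "n/a"), ("reptile", "snake"),
               ("mammal", "n/a"), ("arthropod", "n/a"))
RARE_TAXA = tuple(
    (f"rare_{_RARE_CYCLE[i % 5][0]}_{i:02d}", *_RARE_CYCLE[i % 5])
    for i in range(33))
DEFAULT_TAXA = DEFAULT_TAXA + RARE_TAXA


def _with_rare_tail(main: dict[str, float], rare_indices: range,
                    rare_mass: float) -> dict[str, float]:
    """Scale the common-taxon vector and spread ``rare_mass`` uniformly
    over a species-specific subset of the rare tail."""
    out = {k: v * (1.0 - rare_mass) for k, v in main.items()}
    share = rare_mass / len(rare_indices)
    for i in rare_indices:
        out[RARE_TAXA[i][0]] = share
    return out


def _default_llb() -> SpeciesParams:
    # Opportunistic near-nest forager: prefers low natural vegetation (41%
    # use vs 12% availability), avoids cultivated fields (12% vs 37%);
    # diverse diet weighted to lizards and birds; uniform diel activity.
    return SpeciesParams(
        name="LLB",
        patch_distance_km=2.35,
        patch_distance_sd_km=0.62,
        n_patches=3,
        diel_mode="uniform",
        nest_radius_km=0.15,
        season_start=(3, 25),
        season_end=(7, 15),
        habitat_use={
            "mediterranean_rocky": 0.27,
            "low_natural_vegetation": 0.41,
            "cultivated_fields": 0.12,
            "uncultivated_land": 0.20,
        },
        diet_probs=_with_rare_tail({
            "large_whip_snake": 0.05,
            "unidentified_colubrid": 0.04,
            "coin_snake": 0.03,
            "montpellier_snake": 0.028,
            "roughtail_rock_agama": 0.13,
            "schneiders_skink": 0.11,
            "starred_agama": 0.05,
            "chameleon": 0.02,
            "ocellated_skink": 0.02,
            "domestic_pigeon": 0.10,
            "unidentified_bird": 0.09,
            "chukar_partridge": 0.05,
            "passerine_sp": 0.03,
            "social_vole": 0.06,
            "black_rat": 0.04,
            "brown_hare_juv": 0.03,
            "hedgehog": 0.022,
            "locust": 0.04,
            "scarab_beetle": 0.04,
            "mole_cricket": 0.02,
        }, rare_indices=range(0, 28), rare_mass=0.10),
        mean_items_per_nest=39.0,
    )


def _default_ste() -> SpeciesParams:
    # Snake-specialist commuting forager: prefers cultivated fields (59% use
    # vs 37% availability), avoids low natural vegetation (7% vs 12%);
    # midday-peaked diel activity; corridors to patches ~13 km out.
    return SpeciesParams(
        name="STE",
        patch_distance_km=13.03,
        patch_distance_sd_km=2.20,
        n_patches=4,
        patch_radius_m=1500.0,
        shared_patches=True,
        n_late_patches=1,
        diel_mode="midday_peak",
        peak_hour=13.0,
        peak_sd_hours=2.0,
        transit_frac=0.25,
        forage_frac=0.45,
        nest_radius_km=1.5,
        season_start=(3, 25),
        season_end=(8, 26),
        habitat_use={
            "mediterranean_rocky": 0.19,
            "low_natural_vegetation": 0.07,
            "cultivated_fields": 0.59,
            "uncultivated_land": 0.15,
        },
        diet_probs=_with_rare_tail({
            "large_whip_snake": 0.30,
            "unidentified_colubrid": 0.15,
            "coin_snake": 0.06,
            "montpellier_snake": 0.035,
            "roughtail_rock_agama": 0.065,
            "schneiders_skink": 0.083,
            "starred_agama": 0.04,
            "chameleon": 0.03,
            "ocellated_skink": 0.0,
            "domestic_pigeon": 0.03,
            "unidentified_bird": 0.03,
            "chukar_partridge": 0.0,
            "passerine_sp": 0.02,
            "social_vole": 0.04,
            "black_rat": 0.025,
            "brown_hare_juv": 0.012,
            "hedgehog": 0.0,
            "locust": 0.05,
            "scarab_beetle": 0.03,
            "mole_cricket": 0.0,
        }, rare_indices=range(15, 33), rare_mass=0.06),
        mean_items_per_nest=24.0,
    )


@dataclass
class SimConfig:
    """Full configuration for one synthetic study.

    Defaults emulate a two-species raptor system: ~2.35 vs ~13.03 km mean
    nest-to-foraging distances, a 12 h duty cycle (06:55-19:05), 5-min or
    90-min fix schedules, bimodal ground speed around the 4 m/s threshold,
    uniform vs midday-peaked diel activity, opposite habitat preferences,
    and partially overlapping multinomial diets.
    """

    seed: int = 0
    n_individuals_per_species: dict[str, int] = field(
        default_factory=lambda: {"LLB": 9, "STE": 8})
    n_solar_per_species: dict[str, int] = field(
        default_factory=lambda: {"LLB": 6, "STE": 2})
    regular_fix_interval_min: float = 90.0
    species: dict[str, SpeciesParams] = field(
        default_factory=lambda: {"LLB": _default_llb(), "STE": _default_ste()})
    # landscape
    extent_km: float = 40.0
    cell_m: float = 100.0
    habitat_classes: tuple[str, ...] = DEFAULT_HABITAT_CLASSES
    availability: tuple[float, ...] = DEFAULT_AVAILABILITY
    # duty cycle / schedule
    duty_start: str = DUTY_CYCLE[0]
    duty_end: str = DUTY_CYCLE[1]
    year: int = 2013
    n_years_diet: int = 3
    # nests / diets
    n_nests_per_species: dict[str, int] = field(
        default_factory=lambda: {"LLB": 37, "STE": 63})
    frac_small_nests: float = 0.12       # nest-years seeded with < 8 items
    frac_failed_nests: float = 0.1       # did not reach chick rearing
    taxa: tuple[tuple[str, str, str], ...] = DEFAULT_TAXA
    shared_window: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_SHARED_WINDOW

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        avail = np.asarray(self.availability, dtype=float)
        if len(avail) != len(self.habitat_classes):
            raise ConfigurationError("availability/classes length mismatch")
        if abs(avail.sum() - 1.0) > 1e-9 or (avail < 0).any():
            raise ConfigurationError(
                f"availability proportions must be non-negative and sum to 1, "
                f"got {avail.tolist()}"
            )
        if self.extent_km <= 0 or self.cell_m <= 0:
            raise ConfigurationError("landscape dimensions must be positive")
        for n in list(self.n_individuals_per_species.values()) + \
                list(self.n_nests_per_species.values()):
            if n <= 0:
                raise ConfigurationError("all counts must be positive")
        taxon_names = [t[0] for t in self.taxa]
        for sp in self.species.values():
            sp.validate()
            if sp.diet_probs and set(sp.diet_probs) - set(taxon_names):
                raise ConfigurationError(
                    f"{sp.name} diet references unknown taxa: "
                    f"{sorted(set(sp.diet_probs) - set(taxon_names))}"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "species" in raw:
            raw["species"] = {
                name: SpeciesParams(**params) if not isinstance(params, SpeciesParams)
                else params
                for name, params in raw["species"].items()
            }
        for key in ("habitat_classes", "availability"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "taxa" in raw:
            raw["taxa"] = tuple(tuple(t) for t in raw["taxa"])
        if "shared_window" in raw:
            raw["shared_window"] = tuple(tuple(t) for t in raw["shared_window"])
        return cls(**raw)


@dataclass
class QCPolicy:
    """Quality-control thresholds applied to tracking and diet data.

    The boundary conventions are strict: a fix is a standing point when its
    ground speed is strictly below ``speed_threshold``; a point is excluded
    when strictly closer to the nest than the species radius; a nest-year is
    dropped when it holds strictly fewer than ``min_diet_items`` items.
    """

    speed_threshold: float = SPEED_THRESHOLD_MS
    nest_radius_km: dict[str, float] = field(
        default_factory=lambda: {"LLB": 0.15, "STE": 1.5})
    min_points: int = DEFAULT_MIN_POINTS
    min_diet_items: int = DEFAULT_MIN_DIET_ITEMS
    shared_window: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_SHARED_WINDOW
    species_seasons: dict[str, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=lambda: {"LLB": ((3, 25), (7, 15)),
                                 "STE": ((3, 25), (8, 26))})
    require_chick_rearing: bool = True
    density_cell_m: float = 500.0
    density_quantile: float = 0.5
    h_set: tuple[float, ...] = DEFAULT_H_SET

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0 or self.min_points <= 0 \
                or self.min_diet_items <= 0 or self.density_cell_m <= 0:
            raise ConfigurationError("QC thresholds must be positive")
        if any(r <= 0 for r in self.nest_radius_km.values()):
            raise ConfigurationError("nest radii must be positive")

    @classmethod
    def from_yaml(cls, path) -> "QCPolicy":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("shared_window",):
            if key in raw:
                raw[key] = tuple(tuple(t) for t in raw[key])
        if "species_seasons" in raw:
            raw["species_seasons"] = {
                k: tuple(tuple(t) for t in v)
                for k, v in raw["species_seasons"].items()
            }
        if "h_set" in raw:
            raw["h_set"] = tuple(raw["h_set"])
        return cls(**raw)
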