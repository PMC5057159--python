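"""End-to-end orchestration: from raw (or synthetic) inputs to the report
tables.

Outputs written to the target directory:

* ``table1.csv`` — per-species mean +/- SE nest distance and 95% foraging
  areas at each smoothing factor, whole and shared season windows;
* ``table2.csv`` — qualitative four-axis segregation summary;
* ``overlap_report.csv`` — pairwise UDOI matrix and pair-group statistics;
* ``nullmodel_report.csv`` — Pianka overlaps with RA3 tail probabilities
  per axis;
* ``diet_report.csv`` — richness, breadth and diet-category contrasts;
* ``interaction_matrix.csv`` — dyadic attraction-repulsion indices;
* ``exclusions.csv`` and ``manifest.json`` — per-stage bookkeeping.

Every run is deterministic given the seed; all stage seeds derive from it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, composition, interaction, niche, spaceuse, tracks
from .config import QCPolicy, SimConfig
from .raster import HabitatRaster
from .synthetic import SyntheticDataset, synthesize
from .types import FixSeries, NestSet, ts_seconds


@dataclass
class PipelineOptions:
    """Scale and algorithm knobs for one full run (the ecological
    thresholds live in QCPolicy; these are the computational choices)."""

    udoi_h_m: float = 500.0
    kde_cell_m: float | None = None     # None -> h/5
    isopleth_level: float = 0.95
    n_perm_attraction: int = 199
    attraction_meet_dist_m: float = 500.0
    attraction_time_tol_s: float = 150.0
    n_perm_anosim: int = 999
    n_iter_ra3: int = 1000
    n_boot_rarefaction: int = 500
    nmds_starts: int = 10
    kmeans_k: int = 5
    kmeans_restarts: int = 10
    solar_interval_max_min: float = 15.0
    max_kmeans_points_per_individual: int = 2000


def _stage_seed(seed: int, stage: int) -> int:
    return int((seed * 10_007 + stage * 101) % (2**31 - 1))


def _species_pair(labels: list[str]) -> tuple[str, str]:
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"pipeline expects exactly 2 species, got {uniq}")
    return uniq[0], uniq[1]


def _is_solar(fs: FixSeries, max_interval_min: float) -> bool:
    ts = ts_seconds(fs.fixes["timestamp"])
    if len(ts) < 3:
        return False
    return float(np.median(np.diff(ts))) <= max_interval_min * 60.0


def run_analysis(track_list: list[FixSeries], nests: NestSet,
                 landscape: HabitatRaster, diets: pd.DataFrame,
                 policy: QCPolicy, options: PipelineOptions,
                 seed: int, out_dir: Path,
                 nest_of_individual: dict[str, str]) -> dict:
    """The analysis core shared by synthetic and file-based runs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": {}}
    exclusions: list[dict] = []
    results: dict = {}

    sp_a, sp_b = _species_pair([fs.species for fs in track_list])

    # ---------------- stage 1: trajectory processing --------------------
    sets_by_window: dict[str, list] = {}
    stage_counts: dict[str, dict] = {}
    for window in ("whole", "shared"):
        processed = []
        for fs in track_list:
            nest = nests.nest_of(nest_of_individual[fs.individual_id])
            sps = tracks.process_individual(
                fs, (nest["x"], nest["y"]), policy, window=window)
            stage_counts[f"{window}:{fs.individual_id}"] = {
                "fixes": len(fs), "standing_after_filters": len(sps),
                "filters": sps.filters_applied,
            }
            processed.append(sps)
        eligible, log = tracks.qc_filter(
            processed, nests, policy, nest_of_individual)
        for entry in log:
            exclusions.append({"stage": f"tracks:{window}", **entry})
        sets_by_window[window] = eligible
    manifest["stages"]["trajectory_processing"] = {
        "individuals_in": len(track_list),
        "eligible_whole": len(sets_by_window["whole"]),
        "eligible_shared": len(sets_by_window["shared"]),
        "per_individual": stage_counts,
    }

    # ---------------- stage 2: space use (table 1) ----------------------
    rows = []
    for window in ("whole", "shared"):
        for sps in sets_by_window[window]:
            nest = nests.nest_of(nest_of_individual[sps.individual_id])
            rows.append(spaceuse.individual_summary(
                sps, (nest["x"], nest["y"]), policy))
            rows[-1]["window"] = window
    indiv = pd.DataFrame(rows)
    agg_rows = []
    for species in (sp_a, sp_b):
        rec: dict = {"species": species}
        sub_w = indiv[(indiv["species"] == species) &
                      (indiv["window"] == "whole")]
        rec["n"] = len(sub_w)
        rec["distance_km_mean"] = sub_w["distance_km"].mean()
        rec["distance_km_se"] = sub_w["distance_km"].sem()
        for window in ("whole", "shared"):
            sub = indiv[(indiv["species"] == species) &
                        (indiv["window"] == window)]
            for h in policy.h_set:
                col = f"area_km2_h{int(h)}"
                rec[f"{col}_{window}_mean"] = sub[col].mean()
                rec[f"{col}_{window}_se"] = sub[col].sem()
        agg_rows.append(rec)
    table1 = pd.DataFrame(agg_rows)
    table1.to_csv(out_dir / "table1.csv", index=False, float_format="%.6f")
    indiv.to_csv(out_dir / "individual_summary.csv", index=False,
                 float_format="%.6f")
    results["table1"] = table1
    results["individual_summary"] = indiv

    # UDOI on the shared window, common grid at the headline h
    h = options.udoi_h_m
    cell = options.kde_cell_m or h / 5.0
    pts = {s.individual_id: s.xy for s in sets_by_window["shared"]}
    allxy = np.vstack(list(pts.values()))
    pad = spaceuse.PAD_SIGMAS * h
    bounds = (allxy[:, 0].min() - pad, allxy[:, 1].min() - pad,
              allxy[:, 0].max() + pad, allxy[:, 1].max() + pad)
    uds = {iid: spaceuse.kde_ud(xy, h_m=h, cell_m=cell, bounds=bounds)
           for iid, xy in pts.items()}
    species_by_id = {s.individual_id: s.species
                     for s in sets_by_window["shared"]}
    om = spaceuse.overlap_matrix(uds, species_by_id,
                                 level=options.isopleth_level)
    try:
        udoi_test = spaceuse.group_udoi_test(om)
    except spaceuse.QCError as err:
        udoi_test = {"F": float("nan"), "p": float("nan"),
                     "insufficient_data": str(err)}
    mat = pd.DataFrame(om.values, index=om.ids, columns=om.ids)
    mat.to_csv(out_dir / "overlap_report.csv", float_format="%.6f")
    with open(out_dir / "overlap_groups.json", "w") as fh:
        json.dump(udoi_test, fh, indent=1, sort_keys=True, default=str)
    results["udoi"] = {"matrix": om, "test": udoi_test}
    manifest["stages"]["space_use"] = {
        "individuals": len(uds), "h_m": h, "cell_m": cell,
        "udoi_anova_F": udoi_test["F"], "udoi_anova_p": udoi_test["p"],
    }

    # ---------------- stage 3: interaction ------------------------------
    year = int(nests.records["year"].max())
    nn = {}
    for mode, a, b in (("intra", sp_a, None), ("intra", sp_b, None),
                       ("inter", sp_a, sp_b), ("inter", sp_b, sp_a)):
        try:
            r = interaction.nn_distances(nests, mode, year, a, b)
            nn[f"{mode}_{a}" + (f"_{b}" if b else "")] = {
                "mean_km": r["mean_km"], "se_km": r["se_km"], "n": r["n"]}
        except interaction.InsufficientDataError:
            pass
    results["nn_distances"] = nn

    rng = np.random.default_rng(_stage_seed(seed, 3))
    km_xy, km_sp = [], []
    for sps in sets_by_window["shared"]:
        xy = sps.xy
        if len(xy) > options.max_kmeans_points_per_individual:
            pick = rng.choice(len(xy),
                              options.max_kmeans_points_per_individual,
                              replace=False)
            xy = xy[pick]
        km_xy.append(xy)
        km_sp.extend([sps.species] * len(xy))
    clusters = interaction.kmeans_clusters(
        np.vstack(km_xy), km_sp, k=options.kmeans_k,
        n_restarts=options.kmeans_restarts, seed=_stage_seed(seed, 4))
    results["clusters"] = clusters

    ids = [fs.individual_id for fs in track_list]
    att = pd.DataFrame(index=ids, columns=ids, dtype=object)
    for i in range(len(track_list)):
        for j in range(i + 1, len(track_list)):
            res = interaction.attraction_index(
                track_list[i], track_list[j],
                meet_dist_m=options.attraction_meet_dist_m,
                time_tol_s=options.attraction_time_tol_s,
                n_perm=options.n_perm_attraction,
                seed=_stage_seed(seed, 100 + i * len(track_list) + j))
            if res is not None:
                att.iloc[i, j] = round(res.index, 4)
                att.iloc[j, i] = round(res.index, 4)
    att.to_csv(out_dir / "interaction_matrix.csv")
    results["attraction"] = att
    manifest["stages"]["interaction"] = {
        "n_pairs": int(att.notna().sum().sum() // 2),
        "kmeans_k": options.kmeans_k,
        "cluster_composition": clusters.composition,
    }

    # ---------------- stage 4: composition ------------------------------
    habitat_cm, hab_log = composition.habitat_composition(
        sets_by_window["shared"], landscape)
    avail = composition.availability(landscape)
    uva = composition.use_vs_availability(habitat_cm, avail)
    uva.to_csv(out_dir / "habitat_use_vs_availability.csv", index=False,
               float_format="%.6f")
    results["habitat_cm"] = habitat_cm
    results["use_vs_availability"] = uva

    regions = {iid: spaceuse.isopleth(ud, options.isopleth_level)
               for iid, ud in uds.items()}
    solar = [fs for fs in track_list
             if _is_solar(fs, options.solar_interval_max_min)
             and fs.individual_id in regions]
    timing_cm = composition.activity_matrix(
        [tracks.season_window(fs, "shared", policy) for fs in solar],
        regions)
    results["timing_cm"] = timing_cm

    diet_cm, meta, diet_log = composition.diet_matrix(diets, policy)
    for entry in diet_log:
        exclusions.append({"stage": "diet", "individual_id": entry["nest_id"],
                           "window": str(entry["year"]),
                           "reason": entry["reason"],
                           "detail": entry["detail"]})
    results["diet_cm"] = diet_cm
    manifest["stages"]["composition"] = {
        "habitat_units": len(habitat_cm.unit_ids),
        "timing_units": len(timing_cm.unit_ids),
        "diet_nests": len(diet_cm.unit_ids),
        "diet_nest_years_dropped":
            sum(1 for e in diet_log if e["reason"] == "too_few_items"),
        "points_outside_raster": hab_log["points_outside_raster"],
    }

    # ---------------- stage 5: community + niche statistics -------------
    axes = {"habitat": habitat_cm, "timing": timing_cm,
            "diet": diet_cm.to_proportions()}
    null_rows = []
    stats_summary = {}
    similarity_by_axis = {}
    for k_ax, (axis, cmx) in enumerate(sorted(axes.items())):
        dm = community.bray_curtis(cmx)
        an = community.anosim(dm, n_perm=options.n_perm_anosim,
                              seed=_stage_seed(seed, 10 + k_ax))
        nm = community.nmds(dm, n_starts=options.nmds_starts,
                            seed=_stage_seed(seed, 20 + k_ax))
        sim = community.simper(cmx)
        between_d = dm.mean_between(sp_a, sp_b)
        similarity_by_axis[axis] = 1.0 - between_d
        ov = niche.group_overlap(cmx)
        stats_summary[axis] = {
            "anosim_R": an.R, "anosim_p": an.p, "nmds_stress": nm.stress,
            "between_dissimilarity_pct": 100 * between_d,
            "within_similarity_pct": {
                g: 100 * (1 - dm.mean_within(g)) for g in (sp_a, sp_b)},
            "pianka": ov,
            "simper_top": None if sim is None else sorted(
                zip(sim.categories, sim.between_contrib_pct),
                key=lambda t: -t[1])[:3],
        }
        for stat in ("between", f"within:{sp_a}", f"within:{sp_b}"):
            nm_res = niche.ra3_null(cmx, statistic=stat,
                                    n_iter=options.n_iter_ra3,
                                    seed=_stage_seed(seed, 30 + 3 * k_ax))
            null_rows.append({
                "axis": axis, "statistic": stat,
                "observed": nm_res.observed,
                "null_mean": float(nm_res.null.mean()),
                "p_high": nm_res.p_high, "p_low": nm_res.p_low,
                "n_iterations": nm_res.n_iterations,
                "algorithm": nm_res.algorithm,
            })
    null_df = pd.DataFrame(null_rows)
    null_df.to_csv(out_dir / "nullmodel_report.csv", index=False,
                   float_format="%.6f")
    results["null_models"] = null_df
    results["axis_stats"] = stats_summary

    # diet richness / breadth / category contrasts
    diet_rows = []
    rarefy = {}
    for species in (sp_a, sp_b):
        counts = diet_cm.rows_for_group(species)
        est = niche.rarefy_chao1(counts,
                                 n_boot=options.n_boot_rarefaction,
                                 seed=_stage_seed(seed, 40))
        rarefy[species] = est
        pooled = counts.sum(axis=0)
        diet_rows.append({
            "species": species, "n_nests": counts.shape[0],
            "s_obs": est.s_obs, "chao1": est.chao1,
            "levins_B": niche.levins(pooled / pooled.sum()),
        })
    common_m = min(r["n_nests"] for r in diet_rows)
    for r in diet_rows:
        mean, sd = rarefy[r["species"]].at(common_m)
        r[f"chao1_at_m{common_m}"] = mean
        r[f"chao1_sd_at_m{common_m}"] = sd
    diet_report = pd.DataFrame(diet_rows)
    diet_report.to_csv(out_dir / "diet_report.csv", index=False,
                       float_format="%.6f")
    cat_tests = composition.category_tests(diet_cm, meta)
    results["diet_report"] = diet_report
    results["category_tests"] = cat_tests
    results["rarefaction"] = rarefy

    # ---------------- stage 6: combined segregation score ---------------
    combined = niche.combined_similarity(similarity_by_axis)
    results["combined"] = combined

    dist = {r["species"]: r["distance_km_mean"] for _, r in table1.iterrows()}
    far = max(dist, key=dist.get)
    near = min(dist, key=dist.get)
    table2 = pd.DataFrame([
        {"axis": "geographic_foraging_area",
         near: f"forages near the nest ({dist[near]:.2f} km)",
         far: f"forages far from the nest ({dist[far]:.2f} km)"},
        {"axis": "foraging_habitat_type",
         near: _pref_summary(uva, near), far: _pref_summary(uva, far)},
        {"axis": "diel_foraging_timing",
         near: _timing_summary(timing_cm, near),
         far: _timing_summary(timing_cm, far)},
        {"axis": "diet",
         near: _diet_summary(cat_tests, near),
         far: _diet_summary(cat_tests, far)},
        {"axis": "combined_similarity_product",
         near: f"{combined['product_rounded']:.2f}",
         far: f"{combined['product_rounded']:.2f}"},
    ])
    table2.to_csv(out_dir / "table2.csv", index=False)
    results["table2"] = table2

    pd.DataFrame(exclusions).to_csv(out_dir / "exclusions.csv", index=False)
    manifest["stages"]["statistics"] = {
        "combined_similarity": combined,
        "per_axis": {ax: {k: v for k, v in s.items() if k != "pianka"}
                     for ax, s in stats_summary.items()},
    }
    manifest["n_exclusions"] = len(exclusions)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results


def _pref_summary(uva: pd.DataFrame, species: str) -> str:
    sub = uva[uva["species"] == species]
    pref = sub.loc[(sub["mean_use"] - sub["availability"]).idxmax(),
                   "category"]
    avoid = sub.loc[(sub["mean_use"] - sub["availability"]).idxmin(),
                    "category"]
    return f"prefers {pref}, avoids {avoid}"

def _timing_summary(timing_cm, species: str) -> str:
    rows = timing_cm.rows_for_group(species)
    if len(rows) == 0:
        return "no high-frequency individuals"
    mean = rows.mean(axis=0)
    ratio = mean.max() / mean.mean()
    peak = timing_cm.categories[int(mean.argmax())]
    if ratio < 1.25:
        return "uniform activity through daytime"
    return f"activity peaks around {peak}"

def _diet_summary(cat_tests: dict, species: str) -> str:
    inter = cat_tests.get("lizard_vs_snake_interaction")
    if inter is None:
        return "diet contrast unavailable"
    d = inter[f"mean_diff_{species}"]
    return ("consumes more lizards than snakes" if d > 0
            else "consumes more snakes than lizards")


def run_all(config: SimConfig | None = None, out_dir="outputs",
            seed: int | None = None, policy: QCPolicy | None = None,
            options: PipelineOptions | None = None,
            dataset: SyntheticDataset | None = None) -> dict:
    """Run the full pipeline on a synthetic study (deterministic in seed)."""
    if dataset is None:
        config = config or SimConfig()
        if seed is not None and seed != config.seed:
            config = _with_seed(config, seed)
        dataset = synthesize(config)
    config = dataset.config
    seed = config.seed if seed is None else seed
    policy = policy or QCPolicy(
        nest_radius_km={name: sp.nest_radius_km
                        for name, sp in config.species.items()},
        species_seasons={name: (sp.season_start, sp.season_end)
                         for name, sp in config.species.items()},
        shared_window=config.shared_window)
    options = options or PipelineOptions()

    nest_of_individual = {}
    for fs in dataset.tracks:
        species = fs.species
        good = dataset.nests.for_species(species)
        good = good[good["reached_chick_rearing"]]
        idx = int(fs.individual_id.rsplit("_", 1)[1]) - 2180
        nest_of_individual[fs.individual_id] = good.iloc[idx]["nest_id"]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = run_analysis(dataset.tracks, dataset.nests, dataset.landscape,
                           dataset.diets, policy, options, seed, out_dir,
                           nest_of_individual)
    # config digest for the manifest
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    results["manifest"]["config_sha256"] = hashlib.sha256(
        cfg_json.encode()).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=1, sort_keys=True,
                  default=str)
    return results


def _with_seed(config: SimConfig, seed: int) -> SimConfig:
    import copy
    cfg = copy.deepcopy(config)
    cfg.seed = seed
    return cfg


def table1_ratios(table1: pd.DataFrame, h_set=(250, 500, 1000)) -> dict:
    """Distance and area ratios (far-ranging / near-ranging species) from a
    Table-1-style per-species summary, rounded to 1 decimal."""
    t = table1.set_index("species")
    dist = t["distance_km_mean"]
    far = dist.idxmax()
    near = dist.idxmin()
    out = {"distance_ratio": round(float(dist[far] / dist[near]), 1)}
    for window in ("whole", "shared"):
        for h in h_set:
            col = f"area_km2_h{int(h)}_{window}_mean"
            if col in t.columns:
                out[f"area_ratio_{window}_h{int(h)}"] = round(
                    float(t.loc[far, col] / t.loc[near, col]), 1)
    return out
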