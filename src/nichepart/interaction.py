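"""Dyadic and community structure of individuals and nests.

Three analyses: nearest-neighbour nest distances (intra- and interspecific),
k-means clustering of foraging locations with per-cluster species
composition, and a dyadic attraction-repulsion index from paired GPS tracks.

The attraction index compares the observed number of space-time meetings of
two tracks with a null distribution obtained by circular time-shifts of one
track (which preserve each track's autocorrelation and spatial footprint).
The index is the rank of the observed count within the null, scaled to
[0, 1]: ~0.5 for mutually random movement, ->1 for attraction, ->0 for
repulsion/avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .raster import InputError
from .types import FixSeries, NestSet, ts_seconds


class InsufficientDataError(ValueError):
    pass


def nn_distances(nests: NestSet, mode: str, year: int,
                 species_a: str, species_b: str | None = None) -> dict:
    """Nearest-neighbour nest distances.

    mode="intra": for each nest of ``species_a``, distance to the nearest
    other nest of the same species. mode="inter": for each nest of
    ``species_a``, distance to the nearest nest of ``species_b`` (asymmetric
    by construction). Returns per-nest distances plus mean, SE and n.
    """
    focal = nests.for_species(species_a, year)
    if mode == "intra":
        target = focal
    elif mode == "inter":
        if species_b is None:
            raise InputError("inter mode requires species_b")
        target = nests.for_species(species_b, year)
    else:
        raise InputError(f"unknown mode {mode!r}")
    if len(focal) == 0 or len(target) < (2 if mode == "intra" else 1):
        raise InsufficientDataError(
            f"not enough nests for {mode} NN ({species_a}, year {year})")
    fxy = focal[["x", "y"]].to_numpy(dtype=float)
    txy = target[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(txy)
    if mode == "intra":
        d, _ = tree.query(fxy, k=2)
        dist = d[:, 1]          # first neighbour is the nest itself
    else:
        dist, _ = tree.query(fxy, k=1)
    dist_km = dist / 1000.0
    n = len(dist_km)
    return {
        "mode": mode, "species": species_a, "target": species_b or species_a,
        "year": year, "distances_km": dist_km,
        "mean_km": float(dist_km.mean()),
        "se_km": float(dist_km.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "n": n,
    }


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    composition: dict[int, dict[str, float]]   # cluster -> species fractions
    inertia: float


def kmeans_clusters(points_xy: np.ndarray, species_labels,
                    k: int = 5, n_restarts: int = 10,
                    seed: int | None = None) -> ClusterResult:
    """Euclidean k-means of foraging locations (best of seeded restarts),
    reporting each cluster's species composition."""
    points_xy = np.asarray(points_xy, dtype=float)
    species_labels = np.asarray(species_labels)
    if len(points_xy) < k:
        raise InputError(f"k={k} exceeds number of points ({len(points_xy)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assignments = km.fit_predict(points_xy)
    composition = {}
    for c in range(k):
        members = species_labels[assignments == c]
        frac = {}
        for sp in sorted(set(species_labels.tolist())):
            frac[sp] = float((members == sp).mean()) if len(members) else 0.0
        composition[c] = frac
    return ClusterResult(k=k, assignments=assignments,
                         centroids=km.cluster_centers_,
                         composition=composition,
                         inertia=float(km.inertia_))


@dataclass
class AttractionResult:
    pair: tuple[str, str]
    observed_meetings: int
    null_meetings: np.ndarray
    index: float                    # in [0,1]; 0.5 neutral
    n_permutations: int
    seed: int | None
    meet_dist_m: float
    time_tol_s: float

    @property
    def interpretation(self) -> str:
        if self.index <= 0.25:
            return "repulsion"
        if self.index >= 0.75:
            return "attraction"
        return "neutral"


def _count_meetings(ta: np.ndarray, xa: np.ndarray, ya: np.ndarray,
                    tb: np.ndarray, xb: np.ndarray, yb: np.ndarray,
                    meet_dist_m: float, time_tol_s: float) -> int:
    """Fix pairs of (a, b) within time_tol_s and meet_dist_m. tb sorted."""
    lo = np.searchsorted(tb, ta - time_tol_s, side="left")
    hi = np.searchsorted(tb, ta + time_tol_s, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return 0
    rep = np.repeat(np.arange(len(ta)), counts)
    # vectorized ragged ranges lo[i]..hi[i]
    ends = np.cumsum(counts)
    offs = np.arange(total) - np.repeat(ends - counts, counts) + rep_starts(lo, counts)
    dx = xa[rep] - xb[offs]
    dy = ya[rep] - yb[offs]
    return int(((dx * dx + dy * dy) <= meet_dist_m ** 2).sum())


def rep_starts(lo: np.ndarray, counts: np.ndarray) -> np.ndarray:
    return np.repeat(lo, counts)


def attraction_index(fs_a: FixSeries, fs_b: FixSeries,
                     meet_dist_m: float = 500.0, time_tol_s: float = 150.0,
                     n_perm: int = 999, seed: int | None = None,
                     min_shift_s: float = 86_400.0) -> AttractionResult | None:
    """Attraction-repulsion index for a pair of tracks.

    Null: circular time-shift of track b by a uniform offset (>= 1 day when
    the overlap span allows). When both tracks span multiple days the shift
    is quantized to whole days, so a duty-cycled (daytime-only) track keeps
    its time-of-day structure under the null — otherwise every diurnal pair
    would spuriously score as attracted simply because shifted fixes land at
    night when the partner has no fixes. Returns None when the two tracks
    were never observed in a common period (reported blank downstream).

    index = (#{null < obs} + 0.5 #{null == obs} + 0.5) / (n_perm + 1)
    """
    ta = ts_seconds(fs_a.fixes["timestamp"])
    tb = ts_seconds(fs_b.fixes["timestamp"])
    t0 = max(ta[0], tb[0])
    t1 = min(ta[-1], tb[-1])
    if t1 <= t0:
        return None
    sel_a = (ta >= t0) & (ta <= t1)
    sel_b = (tb >= t0) & (tb <= t1)
    ta, xa, ya = (ta[sel_a], fs_a.fixes["x"].to_numpy()[sel_a],
                  fs_a.fixes["y"].to_numpy()[sel_a])
    tb, xb, yb = (tb[sel_b], fs_b.fixes["x"].to_numpy()[sel_b],
                  fs_b.fixes["y"].to_numpy()[sel_b])
    if len(ta) == 0 or len(tb) == 0:
        return None

    obs = _count_meetings(ta, xa, ya, tb, xb, yb, meet_dist_m, time_tol_s)

    span = t1 - t0
    if span <= 0:
        return None
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    rel = tb - t0
    day = 86_400.0
    n_days = int(np.floor(span / day)) + 1
    # shifts are quantized to the track's sampling step: a continuous shift
    # would break the fix-schedule phase between the two tags and reduce
    # null meeting opportunities for any regularly scheduled pair
    step = float(np.median(np.diff(tb))) if len(tb) > 2 else time_tol_s
    step = max(step, 1.0)
    for i in range(n_perm):
        if span > 2 * min_shift_s and n_days >= 3:
            # whole-day circular shift over the covering day span
            period = n_days * day
            delta = day * float(rng.integers(1, n_days))
        else:
            period = span
            n_steps = max(int(np.floor(span / step)), 2)
            delta = step * float(rng.integers(1, n_steps))
        shifted = (rel + delta) % period
        order = np.argsort(shifted, kind="stable")
        null[i] = _count_meetings(ta, xa, ya,
                                  t0 + shifted[order], xb[order], yb[order],
                                  meet_dist_m, time_tol_s)
    below = int((null < obs).sum())
    ties = int((null == obs).sum())
    index = (below + 0.5 * ties + 0.5) / (n_perm + 1)
    return AttractionResult(
        pair=(fs_a.individual_id, fs_b.individual_id),
        observed_meetings=obs, null_meetings=null, index=float(index),
        n_permutations=n_perm, seed=seed,
        meet_dist_m=meet_dist_m, time_tol_s=time_tol_s)
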