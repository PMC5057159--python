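"""Niche overlap, breadth, richness estimation, null models, and the
combined multi-axis segregation score.

* Pianka's O_jk: symmetric overlap of two resource-proportion vectors.
* Levins' B = 1 / sum(p_i^2), unstandardized (1 for a single resource,
  k for uniform use of k resources).
* Chao1 richness from singleton/doubleton counts, with sample-based
  rarefaction (bootstrap over sampling units).
* RA3 null model: each iteration independently permutes every consumer
  row's utilization values across resource categories, retaining niche
  breadth while randomizing which categories are used; two tail
  probabilities are reported with the add-one convention.
* The combined segregation score is the product of per-axis Bray-Curtis
  similarities (1 - mean between-species dissimilarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import CompositionMatrix
from .config import ConfigurationError
from .raster import InputError


def pianka(p: np.ndarray, q: np.ndarray) -> float:
    """Pianka's niche-overlap index O_jk in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InputError("proportion vectors must have equal length")
    if (p < 0).any() or (q < 0).any():
        raise InputError("proportions must be non-negative")
    sp, sq = p.sum(), q.sum()
    if sp == 0 or sq == 0:
        raise InputError("zero vector has no defined overlap")
    p, q = p / sp, q / sq
    return float((p * q).sum() / np.sqrt((p * p).sum() * (q * q).sum()))


def levins(p: np.ndarray) -> float:
    """Levins' niche breadth B = 1 / sum(p_i^2) (unstandardized)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or p.sum() == 0:
        raise InputError("invalid proportion vector")
    p = p / p.sum()
    return float(1.0 / (p * p).sum())


def _pianka_matrix(values: np.ndarray) -> np.ndarray:
    """All pairwise Pianka overlaps: cosine similarity of the rows."""
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    if (norms == 0).any():
        raise InputError("zero vector has no defined overlap")
    xn = values / norms
    return np.clip(xn @ xn.T, 0.0, 1.0)


def group_overlap(cm: CompositionMatrix) -> dict:
    """Mean pairwise Pianka overlap within each group and between groups.

    The between-group overlap is reported both as the mean over all
    cross-group unit pairs and on the pooled (group-mean) proportion
    profiles; the pooled-profile variant is the headline value.
    """
    cmp_ = cm.to_proportions()
    groups = sorted(set(cmp_.groups))
    omat = _pianka_matrix(cmp_.values)
    idx = {g: [i for i, gg in enumerate(cmp_.groups) if gg == g]
           for g in groups}
    out: dict[str, float] = {}
    for g in groups:
        ia = idx[g]
        if len(ia) < 2:
            raise InputError(f"group {g!r} has fewer than 2 units")
        sub = omat[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        out[f"within_{g}"] = float(sub[iu].mean())
    if len(groups) == 2:
        a, b = groups
        out["between_pairs_mean"] = float(
            omat[np.ix_(idx[a], idx[b])].mean())
        out["between_pooled"] = pianka(cmp_.values[idx[a]].mean(axis=0),
                                       cmp_.values[idx[b]].mean(axis=0))
    return out


@dataclass
class NullModelResult:
    statistic: str
    observed: float
    null: np.ndarray
    p_high: float             # Pr(null >= observed), add-one convention
    p_low: float              # Pr(null <= observed)
    n_iterations: int
    seed: int | None
    algorithm: str = "RA3"
    degenerate: bool = False


def _overlap_statistic(values: np.ndarray, groups: list[str],
                       statistic: str) -> float:
    cmx = CompositionMatrix([str(i) for i in range(len(values))], list(groups),
                            [str(j) for j in range(values.shape[1])],
                            values, "mean_count")
    res = group_overlap(cmx)
    if statistic == "between":
        return res["between_pooled"]
    if statistic == "between_pairs":
        return res["between_pairs_mean"]
    if statistic.startswith("within:"):
        return res[f"within_{statistic.split(':', 1)[1]}"]
    raise ConfigurationError(f"unknown RA3 statistic {statistic!r}")


def ra3_null(cm: CompositionMatrix, statistic: str = "between",
             n_iter: int = 1000, seed: int | None = None) -> NullModelResult:
    """RA3 randomization null for a group-overlap statistic.

    ``statistic``: "between" (pooled-profile Pianka between the two
    groups), "between_pairs", or "within:<group>".
    """
    values = cm.values
    if values.shape[1] < 2:
        obs = _overlap_statistic(values, cm.groups, statistic)
        return NullModelResult(statistic=statistic, observed=obs,
                               null=np.full(n_iter, obs), p_high=1.0,
                               p_low=1.0, n_iterations=n_iter, seed=seed,
                               degenerate=True)
    obs = _overlap_statistic(values, cm.groups, statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        null[i] = _overlap_statistic(rng.permuted(values, axis=1),
                                     cm.groups, statistic)
    p_high = (1 + int((null >= obs - 1e-12).sum())) / (n_iter + 1)
    p_low = (1 + int((null <= obs + 1e-12).sum())) / (n_iter + 1)
    return NullModelResult(statistic=statistic, observed=float(obs),
                           null=null, p_high=float(p_high),
                           p_low=float(p_low), n_iterations=n_iter, seed=seed)


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), bias-corrected
    S_obs + F1(F1-1)/(2(F2+1)) when no doubletons."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise InputError("empty count vector")
    if (counts < 0).any():
        raise InputError("counts must be non-negative")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


@dataclass
class RichnessEstimate:
    s_obs: int
    f1: int
    f2: int
    chao1: float
    curve_m: np.ndarray           # sampling-unit counts 1..n
    curve_mean: np.ndarray
    curve_sd: np.ndarray
    n_boot: int
    seed: int | None

    def at(self, m: int) -> tuple[float, float]:
        """(mean, sd) of the rarefaction curve at m sampling units."""
        i = int(np.searchsorted(self.curve_m, m))
        if i >= len(self.curve_m) or self.curve_m[i] != m:
            raise InputError(f"m={m} outside the rarefaction curve")
        return float(self.curve_mean[i]), float(self.curve_sd[i])


def rarefy_chao1(unit_counts: np.ndarray, n_boot: int = 1000,
                 seed: int | None = None) -> RichnessEstimate:
    """Sample-based Chao1 rarefaction over sampling units (nests).

    For each m = 1..n units, the mean and SD of Chao1 computed on the
    pooled counts of ``n_boot`` random m-subsets drawn without replacement.
    Pooled counts are rounded to integers before the singleton/doubleton
    tally (per-nest values may be multi-year means).
    """
    unit_counts = np.atleast_2d(np.asarray(unit_counts, dtype=float))
    n = unit_counts.shape[0]
    if n < 2:
        raise InputError("rarefaction needs >= 2 sampling units")
    if n_boot < 2:
        raise ConfigurationError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    ms = np.arange(1, n + 1)
    means = np.empty(n)
    sds = np.empty(n)
    for mi, m in enumerate(ms):
        if m == n:
            pooled = np.rint(unit_counts.sum(axis=0))
            vals = np.full(n_boot, chao1(pooled))
        else:
            # vectorized bootstrap: random m-subsets via partial argsort
            idx = np.argsort(rng.random((n_boot, n)), axis=1)[:, :m]
            pooled = np.rint(unit_counts[idx].sum(axis=1))
            s_obs = (pooled > 0).sum(axis=1)
            f1 = (pooled == 1).sum(axis=1)
            f2 = (pooled == 2).sum(axis=1)
            vals = np.where(f2 > 0,
                            s_obs + f1 * f1 / (2.0 * np.maximum(f2, 1)),
                            s_obs + f1 * (f1 - 1) / 2.0)
        means[mi] = vals.mean()
        sds[mi] = vals.std(ddof=1)
    pooled = np.rint(unit_counts.sum(axis=0))
    return RichnessEstimate(
        s_obs=int((pooled > 0).sum()),
        f1=int((pooled == 1).sum()), f2=int((pooled == 2).sum()),
        chao1=float(chao1(pooled)),
        curve_m=ms, curve_mean=means, curve_sd=sds,
        n_boot=n_boot, seed=seed)


def combined_similarity(axis_values: dict[str, float]) -> dict:
    """Product of per-axis similarities (each in [0, 1]).

    ``axis_values`` maps axis labels (e.g. habitat, timing, diet) to
    between-species Bray-Curtis similarity, 1 - mean dissimilarity.
    Returns the raw product and the 2-decimal reporting value.
    """
    for axis, v in axis_values.items():
        if not 0.0 <= v <= 1.0:
            raise InputError(f"axis {axis!r} similarity {v} outside [0,1]")
    product = 1.0
    for v in axis_values.values():
        product *= v
    return {"axes": dict(axis_values), "product": product,
            "product_rounded": round(product, 2)}
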