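"""Community statistics applied identically to habitat, timing and diet
composition matrices: Bray-Curtis dissimilarity, non-metric MDS with
Kruskal stress-1, ANOSIM (Global R with permutation p), SIMPER
decomposition, and threshold similarity grouping (UPGMA).

No pre-transformation (square-root etc.) is applied by default; a
``transform`` hook exists on :func:`bray_curtis` because comparable
community-statistics software commonly square-root transforms abundances,
which changes every similarity value downstream.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .composition import CompositionMatrix
from .raster import InputError


class ConvergenceError(RuntimeError):
    pass


@dataclass
class DissimilarityMatrix:
    unit_ids: list[str]
    groups: list[str]
    matrix: np.ndarray            # symmetric, zero diagonal, values in [0,1]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-12):
            raise InputError("dissimilarity matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise InputError("dissimilarity diagonal not zero")
        if m.min() < -1e-12 or m.max() > 1 + 1e-9:
            raise InputError("Bray-Curtis values must lie in [0,1]")
        self.matrix = m

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def mean_between(self, group_a: str, group_b: str) -> float:
        ia = [i for i, g in enumerate(self.groups) if g == group_a]
        ib = [i for i, g in enumerate(self.groups) if g == group_b]
        return float(self.matrix[np.ix_(ia, ib)].mean())

    def mean_within(self, group: str) -> float:
        ia = [i for i, g in enumerate(self.groups) if g == group]
        sub = self.matrix[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        return float(sub[iu].mean())


def bray_curtis(cm: CompositionMatrix, transform=None) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis d(x,y) = sum|x-y| / sum(x+y)."""
    x = cm.values
    if (x.sum(axis=1) == 0).any():
        raise InputError("Bray-Curtis undefined for all-zero rows")
    if transform is not None:
        x = transform(x)
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(list(cm.unit_ids), list(cm.groups), d)


def kruskal_stress(coords: np.ndarray, dm: DissimilarityMatrix) -> float:
    """Kruskal stress-1 of a configuration against dissimilarity ranks:
    sqrt(sum (d - dhat)^2 / sum d^2), dhat the monotone (isotonic)
    regression of configuration distances on dissimilarity order."""
    d = pdist(coords)
    delta = dm.condensed
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression()
    dhat_sorted = iso.fit_transform(np.arange(len(order)), d[order])
    dhat = np.empty_like(d)
    dhat[order] = dhat_sorted
    denom = float((d ** 2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((d - dhat) ** 2).sum()) / denom)


@dataclass
class NmdsResult:
    coords: np.ndarray
    stress: float                 # Kruskal stress-1
    dims: int
    n_starts: int
    seed: int | None


def nmds(dm: DissimilarityMatrix, dims: int = 2, n_starts: int = 20,
         seed: int | None = None, max_iter: int = 1000,
         tol: float = 1e-9) -> NmdsResult:
    """Non-metric MDS: best Kruskal stress-1 over seeded random starts.

    ``tol`` is the SMACOF stress-decrement stopping tolerance; the tight
    default is needed for near-zero-stress configurations to actually
    reach stress < 1e-3 rather than stalling early.
    """
    n = len(dm.unit_ids)
    if n < dims + 1:
        raise InputError(f"nMDS in {dims}-D needs at least {dims + 1} units")
    best_coords, best_stress = None, np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        rs = int(rng.integers(0, 2**31 - 1))
        model = MDS(n_components=dims, metric=False,
                    dissimilarity="precomputed", n_init=1,
                    max_iter=max_iter, eps=tol, random_state=rs,
                    normalized_stress=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            coords = model.fit_transform(dm.matrix)
        s = kruskal_stress(coords, dm)
        if s < best_stress:
            best_stress, best_coords = s, coords
    if best_coords is None or not np.isfinite(best_stress):
        raise ConvergenceError("nMDS failed to converge in any start")
    return NmdsResult(coords=best_coords, stress=float(best_stress),
                      dims=dims, n_starts=n_starts, seed=seed)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int | None
    null_R: np.ndarray


def _anosim_r(ranks_sq: np.ndarray, labels: np.ndarray, m: int) -> float:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = ranks_sq[iu][same[iu]]
    between = ranks_sq[iu][~same[iu]]
    return float((between.mean() - within.mean()) / (m / 2.0))


def anosim(dm: DissimilarityMatrix, n_perm: int = 999,
           seed: int | None = None) -> AnosimResult:
    """ANOSIM Global R with permutation p (add-one convention, midranks).

    R = (mean between-group rank - mean within-group rank) / (M/2),
    M = n(n-1)/2; p = (1 + #{perm R >= observed}) / (n_perm + 1).
    """
    labels = np.asarray(dm.groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise InputError("ANOSIM needs >= 2 groups with >= 2 units each")
    n = len(labels)
    m = n * (n - 1) // 2
    ranks = rankdata(dm.condensed)          # midranks for ties
    ranks_sq = squareform(ranks)
    obs = _anosim_r(ranks_sq, labels, m)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _anosim_r(ranks_sq, rng.permutation(labels), m)
    p = (1 + int((null >= obs - 1e-12).sum())) / (n_perm + 1)
    return AnosimResult(R=obs, p=float(p), n_permutations=n_perm, seed=seed,
                        null_R=null)


def anosim_exact(dm: DissimilarityMatrix) -> tuple[float, float]:
    """Observed R and exact p by enumerating all distinct label
    assignments (small n only)."""
    labels = np.asarray(dm.groups)
    n = len(labels)
    m = n * (n - 1) // 2
    ranks_sq = squareform(rankdata(dm.condensed))
    obs = _anosim_r(ranks_sq, labels, m)
    uniq = sorted(set(labels.tolist()))
    n_a = int((labels == uniq[0]).sum())
    ge = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        perm = np.array([uniq[0] if i in combo else uniq[1] for i in range(n)])
        total += 1
        if _anosim_r(ranks_sq, perm, m) >= obs - 1e-12:
            ge += 1
    return obs, ge / total


@dataclass
class SimperResult:
    categories: list[str]
    between_contrib_pct: np.ndarray      # sums to 100
    overall_between_dissim_pct: float
    within_similarity_pct: dict[str, float]
    within_typicality_pct: dict[str, np.ndarray]


def simper(cm: CompositionMatrix, group_a: str | None = None,
           group_b: str | None = None) -> SimperResult | None:
    """SIMPER decomposition of average Bray-Curtis dissimilarity between two
    groups, and of within-group similarity, into per-category contributions.

    Returns None when the two groups are identical (overall dissimilarity
    zero, contributions undefined).
    """
    groups = sorted(set(cm.groups))
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise InputError("simper needs exactly two groups")
        group_a, group_b = groups
    xa = cm.rows_for_group(group_a)
    xb = cm.rows_for_group(group_b)
    if len(xa) == 0 or len(xb) == 0:
        raise InputError("simper groups must be non-empty")

    # between-group: mean over cross pairs of the per-category BC terms
    contrib = np.zeros(cm.values.shape[1])
    for x in xa:
        for y in xb:
            tot = (x + y).sum()
            contrib += np.abs(x - y) / tot
    contrib = contrib / (len(xa) * len(xb)) * 100.0
    overall = float(contrib.sum())
    if overall <= 1e-12:
        return None
    pct = contrib / overall * 100.0

    # within-group: similarity 1 - d decomposes as sum 2*min(x,y)/sum(x+y)
    within_sim = {}
    within_typ = {}
    for g, rows in ((group_a, xa), (group_b, xb)):
        terms = np.zeros(cm.values.shape[1])
        n_pairs = 0
        for x, y in itertools.combinations(rows, 2):
            tot = (x + y).sum()
            terms += 2.0 * np.minimum(x, y) / tot
            n_pairs += 1
        if n_pairs:
            terms = terms / n_pairs * 100.0
        sim = float(terms.sum())
        within_sim[g] = sim
        within_typ[g] = terms / sim * 100.0 if sim > 0 else terms
    return SimperResult(categories=list(cm.categories),
                        between_contrib_pct=pct,
                        overall_between_dissim_pct=overall,
                        within_similarity_pct=within_sim,
                        within_typicality_pct=within_typ)


def similarity_groups(dm: DissimilarityMatrix,
                      threshold_pct: float) -> np.ndarray:
    """UPGMA partition cut at a similarity threshold (percent).

    Units whose group-average similarity exceeds the threshold share a
    cluster; threshold 0 gives one cluster, 100 singletons (absent exact
    duplicates). Returns integer labels aligned with unit order.
    """
    if not 0.0 <= threshold_pct <= 100.0:
        raise InputError("similarity threshold must be in [0, 100]")
    z = linkage(dm.condensed, method="average")
    cut = 1.0 - threshold_pct / 100.0
    return fcluster(z, t=cut, criterion="distance")
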