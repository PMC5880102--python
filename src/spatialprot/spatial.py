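"""Sample-level correlation/hierarchical clustering and protein-level fuzzy
c-means soft clustering of spatial abundance profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Sample correlation & hierarchical clustering
# ---------------------------------------------------------------------------

def sample_correlation(pm, min_proteins: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples over proteins complete in
    both members of each pair.  Diagonal is 1.  Pairs with fewer than
    ``min_proteins`` complete proteins or a zero-variance member are NaN —
    undefined, never silently 0."""
    values = pm.values if hasattr(pm, "values") and hasattr(pm, "n_peptides") else pm
    corr = values.corr(method="pearson", min_periods=min_proteins)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` lists (members_a, members_b, height) with members as sorted
    leaf-label tuples; ``leaf_order`` is the display order."""

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]


def hcluster(corr: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering on distance d = 1 - r with average (UPGMA) or
    single/complete linkage.  Ties broken by lexicographically smallest merged
    pair, so the result is deterministic."""
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    labels = list(corr.index)
    d = 1.0 - corr.to_numpy(dtype=float)
    bad = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if not np.isfinite(d[i, j])
    ]
    if bad:
        raise ValueError(f"NA distances between sample pairs: {bad}")

    clusters: dict[tuple[str, ...], list[int]] = {
        (lab,): [i] for i, lab in enumerate(labels)
    }
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    def cluster_dist(ia: list[int], ib: list[int]) -> float:
        cross = d[np.ix_(ia, ib)]
        if linkage == "average":
            return float(cross.mean())
        if linkage == "single":
            return float(cross.min())
        return float(cross.max())

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                dist = cluster_dist(clusters[keys[x]], clusters[keys[y]])
                cand = (dist, keys[x], keys[y])
                if best is None or cand < best:
                    best = cand
        dist, ka, kb = best
        merged = tuple(sorted(ka + kb))
        merges.append((ka, kb, dist))
        clusters[merged] = clusters.pop(ka) + clusters.pop(kb)

    # leaf order: unfold merges, lexicographically smaller branch first
    order_of: dict[tuple[str, ...], list[str]] = {}
    for ka, kb, _ in merges:
        la = order_of.pop(ka, list(ka))
        lb = order_of.pop(kb, list(kb))
        first, second = (la, lb) if ka <= kb else (lb, la)
        order_of[tuple(sorted(ka + kb))] = first + second
    leaf_order = next(iter(order_of.values())) if order_of else labels
    return Dendrogram(merges=merges, leaf_order=leaf_order)


# ---------------------------------------------------------------------------
# Spatial profiles
# ---------------------------------------------------------------------------

def standardize_profiles(
    pm, sectors: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-protein z-scored profiles across ``sectors`` (mean 0, sd 1 with
    ddof=1).  Proteins incomplete across sectors or with zero sd are dropped
    and reported."""
    values = pm.values if hasattr(pm, "values") and hasattr(pm, "n_peptides") else pm
    missing = [s for s in sectors if s not in values.columns]
    if missing:
        raise ValueError(f"sectors not present in matrix: {missing}")
    sub = values[sectors].dropna()
    sd = sub.std(axis=1, ddof=1)
    dropped = list(sub.index[sd == 0.0]) + [
        p for p in values.index if p not in sub.index
    ]
    keep = sub.loc[sd > 0.0]
    standardized = keep.sub(keep.mean(axis=1), axis=0).div(sd[sd > 0.0], axis=0)
    return standardized, dropped


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class FuzzyClustering:
    """Soft clustering result: centroids (c x S), membership (protein x c)."""

    centroids: np.ndarray
    membership: pd.DataFrame
    m: float
    objective: float
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def min_centroid_distance(self) -> float:
        c = len(self.centroids)
        if c < 2:
            return np.inf
        dists = [
            float(np.linalg.norm(self.centroids[i] - self.centroids[j]))
            for i in range(c)
            for j in range(i + 1, c)
        ]
        return min(dists)


def _fcm_once(
    x: np.ndarray, c: int, m: float, tol: float, max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    n = len(x)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    history: list[float] = []
    converged = False
    it = 0
    centroids = np.zeros((c, x.shape[1]))
    for it in range(1, max_iter + 1):
        um = u**m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        history.append(float((um * d2).sum()))
        # membership update; points coincident with a centroid get full
        # membership split among the zero-distance centroids
        zero = d2 <= 0.0
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            u_new[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < tol:
            converged = True
            break
    um = u**m
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    history.append(float((um * d2).sum()))
    return centroids, u, history, it, converged


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    n_restarts: int = 10,
) -> FuzzyClustering:
    """Fuzzy c-means with the standard alternating updates
    u_ik = 1 / sum_j (||x_i - c_k|| / ||x_i - c_j||)^(2/(m-1)) and
    c_k = sum_i u_ik^m x_i / sum_i u_ik^m, from seeded random membership
    initializations; the best of ``n_restarts`` runs (by objective) is kept.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if c < 1:
        raise ValueError("c must be >= 1")
    x = profiles.to_numpy(dtype=float)
    if len(x) <= c:
        raise ValueError(f"need more proteins ({len(x)}) than clusters ({c})")
    if c == 1:
        centroid = x.mean(axis=0, keepdims=True)
        u = np.ones((len(x), 1))
        obj = float(((x - centroid) ** 2).sum())
        return FuzzyClustering(
            centroids=centroid,
            membership=pd.DataFrame(u, index=profiles.index, columns=["c1"]),
            m=m, objective=obj, objective_history=[obj], n_iter=0, converged=True,
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        result = _fcm_once(x, c, m, tol, max_iter, rng)
        if best is None or result[2][-1] < best[2][-1]:
            best = result
    centroids, u, history, n_iter, converged = best
    membership = pd.DataFrame(
        u, index=profiles.index, columns=[f"c{k + 1}" for k in range(c)]
    )
    return FuzzyClustering(
        centroids=centroids, membership=membership, m=m,
        objective=history[-1], objective_history=history,
        n_iter=n_iter, converged=converged,
    )


@dataclass
class ElbowResult:
    c_star: int
    curve: dict[int, float]  # c -> min centroid distance (inf at c = 1)
    floor: float


def select_c_elbow(
    profiles: pd.DataFrame,
    c_range: tuple[int, int],
    m: float = 2.0,
    seed: int = 0,
    floor: float = 0.1,
    n_restarts: int = 10,
) -> ElbowResult:
    """Elbow selection: fit each c in ``c_range`` and record the minimum
    pairwise centroid distance; ``c_star`` is the largest c whose minimum
    centroid distance exceeds ``floor`` (c=1 is recorded as +inf)."""
    lo, hi = c_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid c_range {c_range}")
    curve: dict[int, float] = {}
    for c in range(lo, hi + 1):
        if c >= len(profiles):
            break
        fit = fuzzy_cmeans(profiles, c, m=m, seed=seed, n_restarts=n_restarts)
        curve[c] = fit.min_centroid_distance()
    eligible = [c for c, dist in curve.items() if dist > floor]
    c_star = max(eligible) if eligible else min(curve)
    return ElbowResult(c_star=c_star, curve=curve, floor=floor)
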