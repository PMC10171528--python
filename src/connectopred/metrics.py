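"""Weighted graph measures for connectomes: the 20-measure battery.

Nine node measures, three edge measures and eight global measures are
computed on each subject's weighted undirected connectome. Distances follow
the inverse-weight convention: the length of an edge with weight w is 1/w,
and all-pairs shortest paths are obtained with the Floyd-Warshall algorithm,
so strong connections are short. Clustering uses Onnela's geometric-mean
formulation; modules come from Newman's leading-eigenvector spectral
bipartitioning with Kernighan-Lin refinement; small-world propensity combines
clustering and path-length deviations from weighted lattice and random nulls;
the core size is the core block of a two-block core-periphery partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, floyd_warshall

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "ModulePartition",
    "NODE_MEASURES",
    "EDGE_MEASURES",
    "GLOBAL_MEASURES",
    "N_MEASURES",
    "shortest_path_lengths",
    "community_partition",
    "node_metrics",
    "edge_metrics",
    "global_metrics",
    "small_world_propensity",
    "core_periphery_size",
    "core_periphery_quality",
    "subject_metrics",
]

NODE_MEASURES = [
    "node_degree",
    "within_module_degree",
    "node_strength",
    "clustering_coefficient",
    "eigenvector_centrality",
    "betweenness_centrality",
    "participation_coefficient",
    "node_eccentricity",
    "local_efficiency",
]
EDGE_MEASURES = [
    "edge_betweenness_centrality",
    "matching_index",
    "path_transitivity",
]
GLOBAL_MEASURES = [
    "average_clustering_coefficient",
    "characteristic_path_length",
    "small_world_propensity",
    "global_efficiency",
    "assortativity",
    "modularity_statistic",
    "transitivity",
    "core_size",
]
#: total count of measures in the battery (9 node + 3 edge + 8 global)
N_MEASURES = len(NODE_MEASURES) + len(EDGE_MEASURES) + len(GLOBAL_MEASURES)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path lengths; infinite across components."""

    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")


@dataclass(frozen=True)
class ModulePartition:
    """Module labels and the weighted Newman-Girvan modularity Q."""

    labels: np.ndarray
    Q: float
    algorithm_seed: int = 0

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.labels).size)


def _lengths(W: np.ndarray) -> np.ndarray:
    """Edge lengths 1/w; zero marks an absent edge for scipy's csgraph."""
    L = np.zeros(W.shape, dtype=float)  # C-contiguous for in-place csgraph
    nz = W > 0
    L[nz] = 1.0 / W[nz]
    return L


def shortest_path_lengths(conn) -> DistanceMatrix:
    """Floyd-Warshall all-pairs shortest paths on inverse-weight lengths."""
    D = floyd_warshall(_lengths(conn.W), directed=False)
    return DistanceMatrix(D=D)


def _graph(W: np.ndarray) -> nx.Graph:
    G = nx.from_numpy_array(W)
    for _, _, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    return G


# ---------------------------------------------------------------------------
# Community structure (Newman's spectral method)
# ---------------------------------------------------------------------------


def modularity(W: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity of a hard partition."""
    m2 = W.sum()
    if m2 <= 0:
        raise ValueError("modularity undefined for an edgeless graph")
    s = W.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    B = W - np.outer(s, s) / m2
    return float(B[same].sum() / m2)


def _kl_refine(Bg: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style refinement of a spectral bipartition.

    Repeated sweeps: every node is moved exactly once per sweep in order of
    steepest gain; the best prefix of the move sequence is kept.
    """
    n = len(sign)
    sign = sign.copy()
    best = float(sign @ Bg @ sign)
    improved = True
    while improved:
        improved = False
        s = sign.copy()
        free = np.ones(n, dtype=bool)
        trace, vals = [], []
        cur = float(s @ Bg @ s)
        for _ in range(n):
            # gain of flipping node v: -4 s_v (Bg s)_v + 4 Bg_vv
            g = -4.0 * s * (Bg @ s) + 4.0 * np.diag(Bg)
            g[~free] = -np.inf
            v = int(np.argmax(g))
            cur += g[v]
            s[v] = -s[v]
            free[v] = False
            trace.append(v)
            vals.append(cur)
        k = int(np.argmax(vals))
        if vals[k] > best + 1e-12:
            for v in trace[: k + 1]:
                sign[v] = -sign[v]
            best = vals[k]
            improved = True
    return sign


def community_partition(conn, seed: int = 0) -> ModulePartition:
    """Newman leading-eigenvector modules with Kernighan-Lin refinement.

    Recursively bipartitions along the leading eigenvector of the generalised
    modularity matrix until no split increases Q. Deterministic: eigenvector
    sign is fixed by its largest-magnitude component.
    """
    W = np.asarray(conn.W, dtype=float)
    m2 = W.sum()
    if m2 <= 0:
        raise ValueError("cannot partition an edgeless graph")
    n = W.shape[0]
    s = W.sum(axis=1)
    B = W - np.outer(s, s) / m2

    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        g = stack.pop()
        if g.size < 2:
            continue
        Bg = B[np.ix_(g, g)]
        Bg = Bg - np.diag(Bg.sum(axis=1))
        vals, vecs = np.linalg.eigh(Bg)
        u = vecs[:, -1]
        if vals[-1] <= 1e-12:
            continue
        u = u * np.sign(u[np.argmax(np.abs(u))] or 1.0)
        sign = np.where(u >= 0, 1.0, -1.0)
        sign = _kl_refine(Bg, sign)
        dq = float(sign @ Bg @ sign)
        if dq <= 1e-12 or np.all(sign == sign[0]):
            continue
        sub = g[sign < 0]
        labels[sub] = next_label
        next_label += 1
        stack.append(g[sign > 0])
        stack.append(sub)

    # compact labels in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return ModulePartition(
        labels=labels, Q=modularity(W, labels), algorithm_seed=seed
    )


# ---------------------------------------------------------------------------
# Node measures
# ---------------------------------------------------------------------------


def _onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering: geometric mean of max-normalised triangle
    weights over the number of possible triangles at each node."""
    k = (W > 0).sum(axis=1)
    wmax = W.max(initial=0.0)
    if wmax == 0:
        return np.zeros(W.shape[0])
    A = np.cbrt(W / wmax)
    cyc = np.diag(A @ A @ A)
    denom = k * (k - 1)
    out = np.zeros(W.shape[0])
    nz = denom > 0
    out[nz] = cyc[nz] / denom[nz]
    return out


def _eigenvector_centrality(W: np.ndarray) -> np.ndarray:
    """Leading eigenvector of W on the largest connected component,
    nonnegative, unit L2 norm; zero on the remaining nodes."""
    ncomp, comp = connected_components(W > 0, directed=False)
    sizes = np.bincount(comp)
    giant = np.flatnonzero(comp == np.argmax(sizes))
    out = np.zeros(W.shape[0])
    if giant.size == 1:
        out[giant] = 1.0
        return out
    sub = W[np.ix_(giant, giant)]
    _, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron-Frobenius: leading eigenvector is nonnegative
    out[giant] = v / np.linalg.norm(v)
    return out


def _local_efficiency(W: np.ndarray) -> np.ndarray:
    """Efficiency of each node's neighbourhood subgraph: mean inverse
    shortest-path length (inverse-weight metric) over neighbour pairs."""
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(W[i] > 0)
        if nb.size < 2:
            continue
        sub = W[np.ix_(nb, nb)]
        D = floyd_warshall(_lengths(sub), directed=False)
        iu = np.triu_indices(nb.size, k=1)
        with np.errstate(divide="ignore"):
            inv = 1.0 / D[iu]
        out[i] = inv.mean()
    return out


def node_metrics(conn, dist: DistanceMatrix, partition: ModulePartition) -> pd.DataFrame:
    """The nine node measures, one row per region.

    Within-module degree is the z-score of a node's binary degree to nodes of
    its own module; participation is 1 minus the sum of squared per-module
    strength fractions. Eccentricity on disconnected graphs is the maximum
    *finite* distance (NaN for fully isolated nodes).
    """
    W = np.asarray(conn.W, dtype=float)
    n = W.shape[0]
    D = dist.D
    labels = partition.labels

    A = (W > 0).astype(float)
    degree = A.sum(axis=1)
    strength = W.sum(axis=1)

    # within-module binary degree, z-scored inside each module
    wmd = np.zeros(n)
    for m in np.unique(labels):
        idx = np.flatnonzero(labels == m)
        kin = A[np.ix_(idx, idx)].sum(axis=1)
        sd = kin.std()
        wmd[idx] = (kin - kin.mean()) / sd if sd > 0 else 0.0

    # participation over module strength fractions
    part = np.zeros(n)
    nzs = strength > 0
    for m in np.unique(labels):
        kim = W[:, labels == m].sum(axis=1)
        part[nzs] += (kim[nzs] / strength[nzs]) ** 2
    part = np.clip(np.where(nzs, 1.0 - part, 0.0), 0.0, 1.0)  # float guard

    G = _graph(W)
    btw = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([btw[i] for i in range(n)])

    offdiag = D + np.diag(np.full(n, np.nan))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fin = np.where(np.isfinite(offdiag), offdiag, np.nan)
        ecc = np.nanmax(fin, axis=1)

    return pd.DataFrame(
        {
            "node_degree": degree,
            "within_module_degree": wmd,
            "node_strength": strength,
            "clustering_coefficient": _onnela_clustering(W),
            "eigenvector_centrality": _eigenvector_centrality(W),
            "betweenness_centrality": betweenness,
            "participation_coefficient": part,
            "node_eccentricity": ecc,
            "local_efficiency": _local_efficiency(W),
        },
        index=list(conn.region_labels),
    )


# ---------------------------------------------------------------------------
# Edge measures
# ---------------------------------------------------------------------------


def matching_index_matrix(W: np.ndarray) -> np.ndarray:
    """Weighted Jaccard overlap of two nodes' neighbourhoods, excluding the
    pair itself: sum of elementwise minima over sum of elementwise maxima."""
    n = W.shape[0]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            lo = np.minimum(W[i, mask], W[j, mask]).sum()
            hi = np.maximum(W[i, mask], W[j, mask]).sum()
            if hi > 0:
                M[i, j] = M[j, i] = lo / hi
    return M


def _reconstruct_path(pred: np.ndarray, i: int, j: int) -> list[int] | None:
    if pred[i, j] < 0 and i != j:
        return None
    path = [j]
    while path[-1] != i:
        path.append(int(pred[i, path[-1]]))
        if len(path) > pred.shape[0]:
            raise RuntimeError("predecessor matrix is not a shortest-path tree")
    return path[::-1]


def edge_metrics(conn, dist: DistanceMatrix) -> dict[str, np.ndarray]:
    """Edge betweenness, matching index and path transitivity matrices.

    Path transitivity of a pair is the density of matching indices among the
    nodes of their shortest path (the pair's own matching index when the path
    is a direct edge; zero for disconnected pairs).
    """
    W = np.asarray(conn.W, dtype=float)
    n = W.shape[0]

    G = _graph(W)
    ebc = nx.edge_betweenness_centrality(G, weight="length", normalized=False)
    EB = np.zeros((n, n))
    for (i, j), v in ebc.items():
        EB[i, j] = EB[j, i] = v

    MI = matching_index_matrix(W)

    _, pred = floyd_warshall(_lengths(W), directed=False, return_predecessors=True)
    PT = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            path = _reconstruct_path(pred, i, j)
            if path is None:
                continue
            if len(path) == 2:
                PT[i, j] = PT[j, i] = MI[i, j]
                continue
            vals = [
                MI[path[u], path[v]]
                for u in range(len(path))
                for v in range(u + 1, len(path))
            ]
            PT[i, j] = PT[j, i] = float(np.mean(vals))

    return {
        "edge_betweenness_centrality": EB,
        "matching_index": MI,
        "path_transitivity": PT,
    }


# ---------------------------------------------------------------------------
# Global measures
# ---------------------------------------------------------------------------


def characteristic_path_length(D: np.ndarray, warn: bool = True) -> float:
    """Mean shortest-path length over finite off-diagonal pairs."""
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    fin = np.isfinite(d)
    if not fin.all() and warn:
        log.warning("graph is disconnected; path length over finite pairs only")
    if not fin.any():
        return np.inf
    return float(d[fin].mean())


def global_efficiency(D: np.ndarray) -> float:
    """Mean inverse shortest-path length over distinct pairs (0 across
    components)."""
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D[iu]
    return float(inv.mean())


def strength_assortativity(W: np.ndarray) -> float:
    """Pearson correlation of endpoint strengths over edges (both
    orientations); NaN when strength variance at edge ends is zero."""
    s = W.sum(axis=1)
    i, j = np.nonzero(np.triu(W, k=1))
    if i.size == 0:
        return np.nan
    x = np.concatenate([s[i], s[j]])
    y = np.concatenate([s[j], s[i]])
    sx = x.std()
    if sx == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / sx**2)


def weighted_transitivity(W: np.ndarray) -> float:
    """Ratio form: total geometric-mean triangle intensity over total number
    of connected triples."""
    wmax = W.max(initial=0.0)
    if wmax == 0:
        return 0.0
    A = np.cbrt(W / wmax)
    k = (W > 0).sum(axis=1)
    denom = (k * (k - 1)).sum()
    if denom == 0:
        return 0.0
    return float(np.trace(A @ A @ A) / denom)


def global_metrics(
    conn,
    dist: DistanceMatrix,
    partition: ModulePartition,
    swp: float,
    core_size: int | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """The eight global measures as a named scalar vector."""
    W = np.asarray(conn.W, dtype=float)
    if core_size is None:
        core_size = core_periphery_size(conn, seed=seed)
    return {
        "average_clustering_coefficient": float(_onnela_clustering(W).mean()),
        "characteristic_path_length": characteristic_path_length(dist.D),
        "small_world_propensity": float(swp),
        "global_efficiency": global_efficiency(dist.D),
        "assortativity": strength_assortativity(W),
        "modularity_statistic": float(partition.Q),
        "transitivity": weighted_transitivity(W),
        "core_size": int(core_size),
    }


# ---------------------------------------------------------------------------
# Small-world propensity
# ---------------------------------------------------------------------------


def _clustering_and_path_length(W: np.ndarray) -> tuple[float, float]:
    C = float(_onnela_clustering(W).mean())
    D = floyd_warshall(_lengths(W), directed=False)
    return C, characteristic_path_length(D, warn=False)


def _lattice_null(n: int, weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Place the observed weights on a ring lattice: nearest pairs first,
    strongest weights on the shortest ring distances."""
    iu, ju = np.triu_indices(n, k=1)
    ring = np.minimum(ju - iu, n - (ju - iu))
    order = np.lexsort((rng.permutation(iu.size), ring))[: weights.size]
    w = np.sort(weights)[::-1]
    M = np.zeros((n, n))
    M[iu[order], ju[order]] = w
    return M + M.T


def _random_null(n: int, weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Place the observed weights on uniformly random node pairs."""
    iu, ju = np.triu_indices(n, k=1)
    pos = rng.choice(iu.size, size=weights.size, replace=False)
    M = np.zeros((n, n))
    M[iu[pos], ju[pos]] = rng.permutation(weights)
    return M + M.T


def _delta(num: float, den: float) -> float:
    if abs(den) < 1e-12:
        d = 0.0 if num <= 0 else 1.0
    else:
        d = num / den
    return float(np.clip(d, 0.0, 1.0))


def small_world_propensity(conn, n_nulls: int = 10, seed: int = 0) -> float:
    """Small-world propensity phi = 1 - sqrt((dC^2 + dL^2) / 2).

    dC measures the clustering deficit relative to a weighted ring-lattice
    null; dL the path-length excess relative to a weight-shuffled random
    null. Both are clamped to [0, 1]; phi near 1 means lattice-like
    clustering with random-like path length.
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    W = np.asarray(conn.W, dtype=float)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = W[iu][W[iu] > 0]
    if weights.size == 0:
        raise ValueError("small-world propensity undefined for edgeless graph")
    C_obs, L_obs = _clustering_and_path_length(W)

    rng = np.random.default_rng(seed)
    CL, LL, CR, LR = [], [], [], []
    for _ in range(n_nulls):
        c, l = _clustering_and_path_length(_lattice_null(n, weights, rng))
        CL.append(c)
        LL.append(l)
        c, l = _clustering_and_path_length(_random_null(n, weights, rng))
        CR.append(c)
        LR.append(l)
    C_latt, L_latt = float(np.mean(CL)), float(np.mean(LL))
    C_rand, L_rand = float(np.mean(CR)), float(np.mean(LR))

    dC = _delta(C_latt - C_obs, C_latt - C_rand)
    dL = _delta(L_obs - L_rand, L_latt - L_rand)
    return float(1.0 - np.sqrt((dC**2 + dL**2) / 2.0))


# ---------------------------------------------------------------------------
# Core-periphery
# ---------------------------------------------------------------------------


def core_periphery_quality(W: np.ndarray, core: np.ndarray) -> float:
    """Quality of a two-block core-periphery split: mean-centred weights are
    rewarded on pairs touching the core and penalised on periphery pairs."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    B = w - w.mean()
    touch = core[iu] | core[ju]
    return float(B[touch].sum() - B[~touch].sum())


def core_periphery_size(conn, seed: int = 0, n_restarts: int = 20) -> int:
    """Size of the core under a seeded steepest-ascent search.

    Single-node flips are applied while they strictly increase the quality;
    quality-neutral flips are accepted only when they grow the core, so fully
    tied landscapes (e.g. complete graphs) resolve to the all-core solution.
    """
    W = np.asarray(conn.W, dtype=float)
    n = W.shape[0]
    if W.sum() <= 0:
        raise ValueError("core-periphery undefined for edgeless graph")
    B = W - np.triu(W, k=1)[np.triu_indices(n, k=1)].mean() * (
        1 - np.eye(n)
    )  # off-diagonal mean-centred weights, zero diagonal
    rng = np.random.default_rng(seed)

    def climb(core: np.ndarray) -> tuple[float, np.ndarray]:
        core = core.copy()
        while True:
            r = B @ (~core).astype(float)  # B has zero diagonal
            gain = np.where(core, -2.0 * r, 2.0 * r)
            v = int(np.argmax(gain))
            if gain[v] > 1e-10:
                core[v] = ~core[v]
                continue
            # quality-neutral growth of the core
            neutral = (~core) & (np.abs(gain) <= 1e-10)
            if neutral.any():
                core[np.flatnonzero(neutral)[0]] = True
                continue
            return core_periphery_quality(W, core), core

    starts = [np.ones(n, dtype=bool), np.zeros(n, dtype=bool)]
    starts += [rng.random(n) < rng.uniform(0.1, 0.9) for _ in range(n_restarts)]
    best_q, best_core = -np.inf, None
    for s in starts:
        q, c = climb(s)
        if q > best_q + 1e-10 or (
            abs(q - best_q) <= 1e-10 and c.sum() > best_core.sum()
        ):
            best_q, best_core = q, c
    return int(best_core.sum())


# ---------------------------------------------------------------------------
# Convenience: full battery for one subject
# ---------------------------------------------------------------------------


def subject_metrics(
    conn, seed: int = 0, swp_nulls: int = 10
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, float]]:
    """Compute the node, edge and global tables for one connectome."""
    dist = shortest_path_lengths(conn)
    part = community_partition(conn, seed=seed)
    nodes = node_metrics(conn, dist, part)
    edges = edge_metrics(conn, dist)
    swp = small_world_propensity(conn, n_nulls=swp_nulls, seed=seed)
    glob = global_metrics(conn, dist, part, swp, seed=seed)
    return nodes, edges, glob
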