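"""Independent brute-force oracles for the graph-metric battery.

Everything here is deliberately naive: exhaustive simple-path enumeration for
distances and betweenness, triple loops for clustering and transitivity,
power iteration for the leading eigenvector, and full 2^n searches for
core-periphery and two-block modularity. These implementations share no code
with the package and exist only to check it on tiny graphs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

RTOL = 1e-10


def enumerate_shortest_paths(W: np.ndarray, i: int, j: int):
    """All shortest simple paths i -> j under the 1/w length convention.

    Returns (distance, list of paths as node tuples); (inf, []) when
    disconnected.
    """
    n = W.shape[0]
    best = [math.inf]
    found: list[tuple[int, ...]] = []

    def dfs(node, visited, length, path):
        if length > best[0] * (1 + RTOL) + 1e-12:
            return
        if node == j:
            if length < best[0] * (1 - RTOL):
                best[0] = length
                found.clear()
            if abs(length - best[0]) <= best[0] * RTOL + 1e-12:
                best[0] = min(best[0], length)
                found.append(tuple(path))
            return
        for k in range(n):
            if W[node, k] > 0 and k not in visited:
                visited.add(k)
                path.append(k)
                dfs(k, visited, length + 1.0 / W[node, k], path)
                path.pop()
                visited.remove(k)

    dfs(i, {i}, 0.0, [i])
    return best[0], found


def all_pairs(W: np.ndarray):
    """Distance matrix plus the shortest-path lists for every pair."""
    n = W.shape[0]
    D = np.zeros((n, n))
    paths = {}
    for i in range(n):
        for j in range(i + 1, n):
            d, ps = enumerate_shortest_paths(W, i, j)
            D[i, j] = D[j, i] = d
            paths[(i, j)] = ps
    return D, paths


def betweenness(W: np.ndarray, paths) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for (i, j), ps in paths.items():
        if not ps:
            continue
        for p in ps:
            for v in p[1:-1]:
                out[v] += 1.0 / len(ps)
    return out


def edge_betweenness(W: np.ndarray, paths) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros((n, n))
    for (i, j), ps in paths.items():
        if not ps:
            continue
        for p in ps:
            for a, b in zip(p[:-1], p[1:]):
                out[a, b] += 1.0 / len(ps)
                out[b, a] += 1.0 / len(ps)
    return out


def onnela_clustering(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = W.max()
    out = np.zeros(n)
    for i in range(n):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += ((W[i, j] / wmax) * (W[i, h] / wmax) * (W[j, h] / wmax)) ** (1 / 3)
        out[i] = s / (k * (k - 1))
    return out


def eigenvector_centrality(W: np.ndarray) -> np.ndarray:
    """Power iteration on the (assumed connected) graph; the diagonal shift
    keeps the dominant eigenvalue unique on bipartite graphs without changing
    eigenvectors."""
    n = W.shape[0]
    A = W + np.eye(n) * (W.sum(axis=1).max() + 1.0)
    v = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(200_000):
        nv = A @ v
        nv /= np.linalg.norm(nv)
        if np.abs(nv - v).max() < 1e-14:
            v = nv
            break
        v = nv
    return np.abs(v)


def participation(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = W[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for m in set(labels.tolist()):
            kim = sum(W[i, j] for j in range(n) if labels[j] == m)
            acc += (kim / k) ** 2
        out[i] = 1 - acc
    return out


def within_module_degree_z(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for m in set(labels.tolist()):
        idx = [i for i in range(n) if labels[i] == m]
        kin = [sum(1 for j in idx if j != i and W[i, j] > 0) for i in idx]
        mu = np.mean(kin)
        sd = np.std(kin)
        for pos, i in enumerate(idx):
            out[i] = (kin[pos] - mu) / sd if sd > 0 else 0.0
    return out


def eccentricity(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        fin = [D[i, j] for j in range(n) if j != i and math.isfinite(D[i, j])]
        if fin:
            out[i] = max(fin)
    return out


def local_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if W[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = W[np.ix_(nb, nb)]
        Ds, _ = all_pairs(sub)
        vals = []
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                vals.append(0.0 if math.isinf(Ds[a, b]) else 1.0 / Ds[a, b])
        out[i] = float(np.mean(vals))
    return out


def matching_index(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for k in range(n):
                if k in (i, j):
                    continue
                num += min(W[i, k], W[j, k])
                den += max(W[i, k], W[j, k])
            if den > 0:
                out[i, j] = out[j, i] = num / den
    return out


def path_transitivity(W: np.ndarray, paths) -> np.ndarray:
    """Defined via the unique shortest path; only valid when paths are
    unique (continuous random weights)."""
    n = W.shape[0]
    MI = matching_index(W)
    out = np.zeros((n, n))
    for (i, j), ps in paths.items():
        if not ps:
            continue
        p = ps[0]
        if len(p) == 2:
            val = MI[i, j]
        else:
            vals = [
                MI[p[a], p[b]]
                for a in range(len(p))
                for b in range(a + 1, len(p))
            ]
            val = float(np.mean(vals))
        out[i, j] = out[j, i] = val
    return out


def characteristic_path_length(D: np.ndarray) -> float:
    vals = [
        D[i, j]
        for i in range(D.shape[0])
        for j in range(i + 1, D.shape[0])
        if math.isfinite(D[i, j])
    ]
    return float(np.mean(vals))


def global_efficiency(D: np.ndarray) -> float:
    n = D.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            vals.append(0.0 if math.isinf(D[i, j]) else 1.0 / D[i, j])
    return float(np.mean(vals))


def assortativity(W: np.ndarray) -> float:
    n = W.shape[0]
    s = W.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                xs += [s[i], s[j]]
                ys += [s[j], s[i]]
    x, y = np.array(xs), np.array(ys)
    if x.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def transitivity(W: np.ndarray) -> float:
    n = W.shape[0]
    wmax = W.max()
    num = 0.0
    den = 0.0
    for i in range(n):
        k = int((W[i] > 0).sum())
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    num += ((W[i, j] / wmax) * (W[i, h] / wmax) * (W[j, h] / wmax)) ** (1 / 3)
    return num / den if den > 0 else 0.0


def modularity(W: np.ndarray, labels: np.ndarray) -> float:
    m2 = W.sum()
    s = W.sum(axis=1)
    q = 0.0
    n = W.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i, j] - s[i] * s[j] / m2
    return q / m2


def best_two_block_modularity(W: np.ndarray):
    """Exhaustive search over all 2-block partitions; returns (labels, Q)."""
    n = W.shape[0]
    best_q, best_lab = -np.inf, None
    for bits in range(2 ** (n - 1)):  # node 0 fixed in block 0
        lab = np.array([0] + [(bits >> k) & 1 for k in range(n - 1)])
        q = modularity(W, lab)
        if q > best_q:
            best_q, best_lab = q, lab
    return best_lab, best_q


def exhaustive_core_sizes(W: np.ndarray, quality) -> set[int]:
    """Sizes of all quality-maximising core assignments (2^n search)."""
    n = W.shape[0]
    best_q = -np.inf
    sizes: set[int] = set()
    for bits in range(2**n):
        core = np.array([(bits >> k) & 1 for k in range(n)], dtype=bool)
        q = quality(W, core)
        if q > best_q + 1e-10:
            best_q, sizes = q, {int(core.sum())}
        elif abs(q - best_q) <= 1e-10:
            sizes.add(int(core.sum()))
    return sizes


def wilcoxon_exact(a, b):
    """Exact permutation distribution of the rank-sum of the first sample
    (midranks). Returns (one-sided lower p, one-sided upper p, two-sided p)."""
    from scipy.stats import rankdata

    a, b = np.asarray(a, float), np.asarray(b, float)
    na = a.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w_obs = ranks[:na].sum()
    n = pooled.size
    mu = na * (n + 1) / 2.0
    sums = [ranks[list(c)].sum() for c in itertools.combinations(range(n), na)]
    sums = np.array(sums)
    p_low = float(np.mean(sums <= w_obs + 1e-12))
    p_high = float(np.mean(sums >= w_obs - 1e-12))
    p_two = float(np.mean(np.abs(sums - mu) >= abs(w_obs - mu) - 1e-12))
    return p_low, p_high, p_two
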