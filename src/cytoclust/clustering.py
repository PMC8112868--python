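"""Stage-2 unsupervised clustering.

Three routes, all deterministic under a fixed seed on one thread:

* self-organizing map + consensus metaclustering of the SOM codebook
  (labels retained for every K in 2..maxK, with elbow diagnostics),
* exact-kNN Jaccard graph + Louvain community detection,
* k-means (Lloyd, k-means++ seeding, multiple restarts).

The SOM inner loop is JIT-compiled with numba when available and falls back
to pure numpy otherwise.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .core import ClusterAssignments, Experiment, marker_matrix

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SomModel:
    grid: tuple[int, int]
    codes: np.ndarray  # (x_dim * y_dim, n_markers)
    rlen: int
    alpha: tuple[float, float]
    radius: float
    seed: int | None
    mode: str = "online"

    @property
    def n_nodes(self) -> int:
        return self.codes.shape[0]


def _grid_coords(x_dim: int, y_dim: int) -> np.ndarray:
    gx, gy = np.meshgrid(np.arange(x_dim), np.arange(y_dim), indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]).astype(np.float64)


def _som_online_py(data, codes, grid_d2, order, rlen, a0, a1, radius0):
    n = data.shape[0]
    total = rlen * n
    step = 0
    for r in range(rlen):
        for ii in range(n):
            x = data[order[r, ii]]
            d = codes - x
            bmu = int(np.argmin(np.einsum("ij,ij->i", d, d)))
            frac = step / total
            alpha = a0 + (a1 - a0) * frac
            radius = radius0 * (1.0 - frac)
            if radius < 1e-9:
                codes[bmu] += alpha * (x - codes[bmu])
            else:
                h = np.exp(-grid_d2[bmu] / (2.0 * radius * radius))
                h[grid_d2[bmu] > (3.0 * radius) ** 2] = 0.0
                codes += (alpha * h)[:, None] * (x - codes)
            step += 1
    return codes


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _som_online_nb(data, codes, grid_d2, order, rlen, a0, a1, radius0):  # pragma: no cover
        n, dim = data.shape
        m = codes.shape[0]
        total = rlen * n
        step = 0
        for r in range(rlen):
            for ii in range(n):
                i = order[r, ii]
                # best matching unit
                best = 0
                best_d = 1e300
                for j in range(m):
                    s = 0.0
                    for k in range(dim):
                        t = codes[j, k] - data[i, k]
                        s += t * t
                    if s < best_d:
                        best_d = s
                        best = j
                frac = step / total
                alpha = a0 + (a1 - a0) * frac
                radius = radius0 * (1.0 - frac)
                if radius < 1e-9:
                    for k in range(dim):
                        codes[best, k] += alpha * (data[i, k] - codes[best, k])
                else:
                    cut = (3.0 * radius) ** 2
                    two_s2 = 2.0 * radius * radius
                    for j in range(m):
                        g = grid_d2[best, j]
                        if g > cut:
                            continue
                        h = alpha * math.exp(-g / two_s2)
                        for k in range(dim):
                            codes[j, k] += h * (data[i, k] - codes[j, k])
                step += 1
        return codes


def _nearest_node(data: np.ndarray, codes: np.ndarray) -> np.ndarray:
    # chunked to bound memory on large inputs
    out = np.empty(len(data), dtype=np.int64)
    cc = np.einsum("ij,ij->i", codes, codes)
    for start in range(0, len(data), 65536):
        block = data[start : start + 65536]
        d = cc[None, :] - 2.0 * block @ codes.T
        out[start : start + 65536] = np.argmin(d, axis=1)
    return out


def train_som(
    m: np.ndarray,
    x_dim: int = 10,
    y_dim: int = 10,
    rlen: int = 10,
    seed: int | None = None,
    alpha: tuple[float, float] = (0.05, 0.01),
    radius: float | None = None,
    mode: str = "online",
) -> tuple[SomModel, np.ndarray]:
    """Train a SOM and map every cell to its nearest code.

    Online mode: codes are initialised from a seeded random sample of cells,
    then updated over ``rlen`` passes with the learning rate falling linearly
    ``alpha[0] -> alpha[1]`` and a Gaussian neighborhood whose radius shrinks
    linearly from ``ceil(2/3 * grid diagonal)`` to 0.  Batch mode recomputes
    codes as neighborhood-weighted means once per pass (with zero radius this
    is exactly Lloyd's k-means update).

    Returns ``(model, node_of_cell)`` with 0-based node indices.
    """
    data = np.ascontiguousarray(m, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got {data.ndim}-D")
    if not np.isfinite(data).all():
        raise ValueError("SOM input contains non-finite values")
    n, dim = data.shape
    n_nodes = x_dim * y_dim
    if n < n_nodes:
        warnings.warn(
            f"fewer cells ({n}) than SOM nodes ({n_nodes}); grid may be sparse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n, size=n_nodes, replace=n < n_nodes)
    codes = data[init_idx].copy()

    gc = _grid_coords(x_dim, y_dim)
    grid_d2 = squareform(pdist(gc, "sqeuclidean"))
    if radius is None:
        radius = float(math.ceil((2.0 / 3.0) * math.hypot(x_dim - 1, y_dim - 1)))

    if mode == "online":
        order = np.stack([rng.permutation(n) for _ in range(rlen)]).astype(np.int64)
        fn = _som_online_nb if _HAVE_NUMBA else _som_online_py
        codes = fn(data, codes, grid_d2, order, rlen, alpha[0], alpha[1], float(radius))
    elif mode == "batch":
        for it in range(rlen):
            r = radius * (1.0 - it / max(rlen, 1))
            assign = _nearest_node(data, codes)
            if r < 1e-9:
                for j in range(n_nodes):
                    mask = assign == j
                    if mask.any():
                        codes[j] = data[mask].mean(axis=0)
            else:
                h = np.exp(-grid_d2 / (2.0 * r * r))  # (nodes, nodes)
                w = h[:, assign]  # (nodes, cells)
                denom = w.sum(axis=1)
                num = w @ data
                ok = denom > 0
                codes[ok] = num[ok] / denom[ok, None]
    else:
        raise ValueError(f"unknown SOM mode {mode!r}")

    node_of_cell = _nearest_node(data, codes)
    model = SomModel(
        grid=(x_dim, y_dim),
        codes=codes,
        rlen=rlen,
        alpha=alpha,
        radius=float(radius),
        seed=seed,
        mode=mode,
    )
    return model, node_of_cell


# ---------------------------------------------------------------------------
# consensus metaclustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Stability of node partitions across subsampled hierarchical runs."""

    consensus: dict[int, np.ndarray]  # K -> (nodes, nodes) co-clustering freq
    labels_by_k: dict[int, np.ndarray]  # K -> node labels 1..K
    co_sample_count: np.ndarray  # times each pair was subsampled together
    areas: dict[int, float] = field(default_factory=dict)  # A(K)
    deltas: dict[int, float] = field(default_factory=dict)  # delta area

    @property
    def ks(self) -> list[int]:
        return sorted(self.consensus)


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values over [0, 1]."""
    xs = np.sort(values)
    grid = np.concatenate([[0.0], xs, [1.0]])
    area = 0.0
    n = len(xs)
    for i in range(len(grid) - 1):
        cdf = np.searchsorted(xs, grid[i], side="right") / n
        area += (grid[i + 1] - grid[i]) * cdf
    return float(area)


def _relabel_by_size(labels: np.ndarray, sizes: np.ndarray | None = None) -> np.ndarray:
    """Relabel 1..K by decreasing cluster size (ties broken by old label)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if sizes is None:
        sizes = np.array([(labels == u).sum() for u in uniq])
    order = sorted(range(len(uniq)), key=lambda i: (-sizes[i], uniq[i]))
    mapping = {int(uniq[i]): rank + 1 for rank, i in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels])


def consensus_metacluster(
    codes: np.ndarray,
    maxK: int,
    reps: int = 100,
    p_item: float = 0.9,
    seed: int | None = None,
) -> ConsensusResult:
    """Consensus clustering of SOM codes for every K in 2..maxK.

    Each rep subsamples ``ceil(p_item * n)`` nodes, clusters them
    hierarchically (Euclidean, average linkage) and cuts at each K;
    ``consensus(i, j)`` is the co-clustering count over the co-sampling
    count (0 where a pair was never co-sampled).  The final node partition
    at each K is average-linkage hierarchical clustering of
    ``1 - consensus``.
    """
    codes = np.asarray(codes, dtype=float)
    n = codes.shape[0]
    if maxK >= n:
        raise ValueError(f"maxK must be < number of nodes ({n}), got {maxK}")
    if maxK < 2:
        raise ValueError(f"maxK must be >= 2, got {maxK}")
    rng = np.random.default_rng(seed)
    n_sub = int(math.ceil(p_item * n))

    ks = list(range(2, maxK + 1))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        co_sample[np.ix_(idx, idx)] += 1
        Z = linkage(codes[idx], method="average", metric="euclidean")
        for k in ks:
            labs = fcluster(Z, t=k, criterion="maxclust")
            for c in np.unique(labs):
                mem = idx[labs == c]
                co_cluster[k][np.ix_(mem, mem)] += 1

    never = co_sample == 0
    if never[np.triu_indices(n, 1)].any():
        warnings.warn(
            f"{int(never[np.triu_indices(n, 1)].sum())} node pairs were never "
            "co-sampled (consensus reported as 0); increase reps or p_item",
            stacklevel=2,
        )
    consensus: dict[int, np.ndarray] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    deltas: dict[int, float] = {}
    iu = np.triu_indices(n, 1)
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2
        consensus[k] = C
        dist = 1.0 - C
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        labels_by_k[k] = _relabel_by_size(fcluster(Z, t=k, criterion="maxclust"))
        areas[k] = _cdf_area(C[iu])
    for k in ks:
        if k == 2:
            deltas[k] = areas[k]
        else:
            prev = areas[k - 1]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else float("inf")
    return ConsensusResult(consensus, labels_by_k, co_sample, areas, deltas)


def elbow_data(cr: ConsensusResult):
    """Table of K -> (area under consensus CDF, relative delta area)."""
    import pandas as pd

    if len(cr.ks) < 2:
        raise ValueError("need >= 2 values of K for an elbow table")
    return pd.DataFrame(
        {
            "K": cr.ks,
            "area": [cr.areas[k] for k in cr.ks],
            "delta_area": [cr.deltas[k] for k in cr.ks],
        }
    )


# ---------------------------------------------------------------------------
# cell-level clusterings
# ---------------------------------------------------------------------------

def flowsom_cluster(
    exp: Experiment,
    x_dim: int = 10,
    y_dim: int = 10,
    maxK: int = 20,
    rlen: int = 10,
    reps: int = 100,
    p_item: float = 0.9,
    seed: int | None = None,
    name: str = "som_consensus",
) -> ClusterAssignments:
    """SOM + consensus metaclustering ensemble on the clustering markers.

    Cell labels for every K in 2..maxK are stored (a cell's label is the
    metacluster of its SOM node, renumbered 1..K by decreasing cell count).
    """
    m, markers = marker_matrix(exp, "clustering")
    model, node_of_cell = train_som(m, x_dim, y_dim, rlen=rlen, seed=seed)
    cr = consensus_metacluster(model.codes, maxK=maxK, reps=reps, p_item=p_item, seed=seed)
    labels_by_k: dict[int, np.ndarray] = {}
    for k, node_labels in cr.labels_by_k.items():
        cell_labels = node_labels[node_of_cell]
        # stable names: renumber by decreasing cell count
        uniq = np.unique(cell_labels)
        sizes = np.array([(cell_labels == u).sum() for u in uniq])
        order = sorted(range(len(uniq)), key=lambda i: (-sizes[i], uniq[i]))
        mapping = {int(uniq[i]): rank + 1 for rank, i in enumerate(order)}
        labels_by_k[k] = np.array([mapping[int(l)] for l in cell_labels])
    ca = ClusterAssignments(
        algorithm="som_consensus",
        params={
            "x_dim": x_dim,
            "y_dim": y_dim,
            "maxK": maxK,
            "rlen": rlen,
            "reps": reps,
            "p_item": p_item,
            "seed": seed,
            "markers": markers,
        },
        labels_by_k=labels_by_k,
        node_of_cell=node_of_cell,
        model={"som": model, "consensus": cr},
    )
    exp.add_clustering(name, ca)
    return ca


def knn_jaccard_graph(m: np.ndarray, k: int):
    """Exact kNN (Euclidean) -> Jaccard-weighted shared-neighbor graph.

    Candidate edges join every pair that is kNN-linked in either direction
    or shares at least one neighbor; the weight is
    ``|N(i) & N(j)| / |N(i) | N(j)|`` over the two k-neighbor sets (self
    excluded) and zero-weight pairs are dropped.  Returns ``(edges,
    weights)`` with edges as (i, j), i < j.
    """
    from itertools import combinations

    from sklearn.neighbors import NearestNeighbors

    n = len(m)
    if k >= n:
        raise ValueError(f"k must be < number of cells ({n}), got {k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(m)
    _, idx = nn.kneighbors(m)
    neigh = [set(int(j) for j in row) - {i} for i, row in enumerate(idx)]
    pairs: set[tuple[int, int]] = set()
    in_neighbors: dict[int, list[int]] = {}
    for i, row in enumerate(neigh):
        for j in row:
            pairs.add((min(i, j), max(i, j)))
            in_neighbors.setdefault(j, []).append(i)
    for members in in_neighbors.values():  # pairs sharing a neighbor
        for a, b in combinations(sorted(members), 2):
            pairs.add((a, b))
    edges, weights = [], []
    for i, j in sorted(pairs):
        inter = len(neigh[i] & neigh[j])
        if inter > 0:
            edges.append((i, j))
            weights.append(inter / len(neigh[i] | neigh[j]))
    return edges, weights


def graph_cluster(
    exp: Experiment,
    k: int = 30,
    seed: int | None = None,
    name: str = "graph_community",
) -> ClusterAssignments:
    """PhenoGraph-style clustering: kNN Jaccard graph + Louvain communities."""
    import igraph as ig

    m, markers = marker_matrix(exp, "clustering")
    edges, weights = knn_jaccard_graph(m, k)
    g = ig.Graph(n=exp.n_cells, edges=edges)
    if seed is not None:
        random.seed(seed)  # python-igraph draws from the stdlib RNG
    part = g.community_multilevel(weights=weights)
    labels = _relabel_by_size(np.asarray(part.membership) + 1)
    n_comm = int(labels.max())
    ca = ClusterAssignments(
        algorithm="graph_community",
        params={"k": k, "seed": seed, "markers": markers, "modularity": part.modularity},
        labels_by_k={n_comm: labels},
    )
    exp.add_clustering(name, ca)
    return ca


def kmeans_cluster(
    exp: Experiment,
    k: int,
    seed: int | None = None,
    n_starts: int = 10,
    name: str = "kmeans",
) -> ClusterAssignments:
    """k-means (Lloyd, k-means++ init, best of ``n_starts`` by within-SS)."""
    from sklearn.cluster import KMeans

    m, markers = marker_matrix(exp, "clustering")
    if k > exp.n_cells:
        raise ValueError(f"k ({k}) exceeds number of cells ({exp.n_cells})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_starts,
        algorithm="lloyd",
        random_state=None if seed is None else int(seed),
    ).fit(m)
    labels = _relabel_by_size(km.labels_ + 1)
    # reorder centroids to match the relabelling
    old_for_new = {}
    for old in np.unique(km.labels_ + 1):
        new = labels[km.labels_ + 1 == old][0]
        old_for_new[int(new)] = int(old) - 1
    centroids = np.vstack([km.cluster_centers_[old_for_new[i + 1]] for i in range(k)])
    ca = ClusterAssignments(
        algorithm="kmeans",
        params={
            "k": k,
            "seed": seed,
            "n_starts": n_starts,
            "markers": markers,
            "inertia": float(km.inertia_),
            "centroids": centroids,
        },
        labels_by_k={k: labels},
    )
    exp.add_clustering(name, ca)
    return ca
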