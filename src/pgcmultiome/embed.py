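"""Normalization, PCA, TF-IDF/LSI, SNN clustering, weighted multimodal
neighbors and MST pseudotime.

RNA normalization is ln-counts-per-10k (a deterministic variance-reducing
transform); ATAC uses the TF-IDF + truncated-SVD (LSI) convention, whose
first component tracks sequencing depth and is therefore flagged so
downstream steps default to components 2..n. Clustering builds a shared
nearest-neighbor (Jaccard) graph and optimizes RB-configuration modularity
at a given resolution with a seeded optimizer. Pseudotime is a minimum
spanning tree over cluster centroids in the joint latent space, rooted at
the cluster holding the most user-supplied root cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from sklearn.neighbors import NearestNeighbors

from .core import CountMatrix, ValidationError


# ---------------------------------------------------------------------------
# normalization and reductions


def lognormalize(counts: sp.spmatrix | np.ndarray, scale: float = 1e4) -> sp.csr_matrix:
    """x' = ln(1 + count * scale / cell_total); all-zero cells stay zero."""
    X = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    inv = np.divide(scale, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
    X = X @ sp.diags(inv)
    X.data = np.log1p(X.data)
    return sp.csr_matrix(X)


@dataclass
class LatentSpace:
    coords: np.ndarray  # cells x dims
    modality: str
    default_dims: list[int] = field(default_factory=list)
    explained_variance: np.ndarray | None = None
    feature_names: list[str] | None = None
    depth_component_flagged: bool = False


def select_hvg(normalized: sp.spmatrix, feature_ids: list[str], n_hvg: int) -> list[str]:
    X = sp.csr_matrix(normalized)
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = sq - mean**2
    order = np.argsort(-var, kind="mergesort")
    return [feature_ids[i] for i in order[: min(n_hvg, len(feature_ids))]]


def pca(
    normalized: sp.spmatrix,
    feature_ids: list[str],
    n_hvg: int = 2000,
    n_comp: int = 50,
    clip: float = 10.0,
) -> LatentSpace:
    """PCA on scaled top-variance genes.

    Genes are centered and unit-scaled (clipped at +/- ``clip``); components
    are ordered by decreasing explained variance with the sign convention
    that the largest-magnitude loading is positive.
    """
    hvg = select_hvg(normalized, feature_ids, n_hvg)
    fi = {f: i for i, f in enumerate(feature_ids)}
    X = sp.csr_matrix(normalized)[[fi[g] for g in hvg], :].toarray()
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    n_comp = min(n_comp, min(Z.shape) - 1)
    if n_comp < 2:
        raise ValidationError("matrix too small for PCA")
    # full SVD on genes x cells (deterministic)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp, :]
    # sign convention: largest-|loading| positive
    for k in range(n_comp):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
            Vt[k, :] *= -1
    coords = (Vt * S[:, None]).T  # cells x comps
    ev = S**2 / Z.shape[1]
    return LatentSpace(
        coords, "rna", list(range(n_comp)), ev, hvg
    )


def tfidf_lsi(
    atac: sp.spmatrix,
    n_comp: int = 30,
    depth_corr_threshold: float = 0.7,
    seed: int = 0,
) -> LatentSpace:
    """TF-IDF transform followed by truncated SVD (LSI).

    TF = count/cell_total, IDF = n_cells/detection_count,
    transform = ln(1 + TF*IDF*1e4). Component 1 is flagged when its
    |Pearson r| with log cell depth exceeds the threshold, so defaults use
    components 2..n.
    """
    X = sp.csr_matrix(atac, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    det = np.asarray((X > 0).sum(axis=1)).ravel()
    n_cells = X.shape[1]
    zero_det = det == 0
    idf = np.zeros(X.shape[0])
    idf[~zero_det] = n_cells / det[~zero_det]
    inv_tot = np.divide(1.0, totals, out=np.zeros_like(totals), where=totals > 0)
    T = sp.diags(idf) @ X @ sp.diags(inv_tot)
    T.data = np.log1p(T.data * 1e4)
    n_comp = min(n_comp, min(T.shape) - 1)
    # deterministic truncated SVD via eigendecomposition is costly; use
    # scipy's Lanczos with a fixed start vector
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(T.shape))
    from scipy.sparse.linalg import svds

    U, S, Vt = svds(sp.csr_matrix(T), k=n_comp, v0=v0)
    order = np.argsort(-S)
    U, S, Vt = U[:, order], S[order], Vt[order, :]
    for k in range(n_comp):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
            Vt[k, :] *= -1
    coords = (Vt * S[:, None]).T
    logdepth = np.log1p(totals)
    r = np.corrcoef(coords[:, 0], logdepth)[0, 1] if coords.shape[0] > 2 else 0.0
    flagged = bool(abs(r) > depth_corr_threshold)
    dims = list(range(1, n_comp)) if flagged else list(range(n_comp))
    return LatentSpace(coords, "atac", dims, S**2 / n_cells, None, flagged)


# ---------------------------------------------------------------------------
# SNN graph clustering


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    resolution: float
    modularity: float


def _knn(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    return idx[:, 1:], dist[:, 1:]  # drop self


def snn_graph(coords: np.ndarray, k: int = 20) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: edge weight = Jaccard of the two
    cells' kNN sets, kept only for pairs that are kNN of each other's
    neighborhoods (the union of the kNN edges)."""
    n = coords.shape[0]
    idx, _ = _knn(coords, k)
    indptr = np.arange(0, n * k + 1, k)
    knn = sp.csr_matrix(
        (np.ones(n * k), idx.ravel(), indptr), shape=(n, n)
    )
    both = knn + knn.T
    both.data[:] = 1.0
    shared = (knn @ knn.T).multiply(both > 0)
    shared = shared.tocoo()
    jac = shared.data / (2 * k - shared.data)
    g = sp.coo_matrix((jac, (shared.row, shared.col)), shape=(n, n)).tocsr()
    g.setdiag(0)
    g.eliminate_zeros()
    return g


def snn_cluster(
    latent: LatentSpace | np.ndarray,
    dims: list[int] | None = None,
    k: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
) -> ClusterAssignment:
    """kNN -> SNN Jaccard graph -> seeded RB-configuration modularity
    optimization at the given resolution; labels are relabeled by
    decreasing cluster size."""
    coords = latent.coords if isinstance(latent, LatentSpace) else np.asarray(latent)
    if dims is None and isinstance(latent, LatentSpace):
        dims = latent.default_dims
    if dims is not None:
        coords = coords[:, dims]
    n = coords.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be < n_cells={n}")
    g = snn_graph(coords, k)

    import igraph
    import leidenalg

    coo = sp.triu(g, k=1).tocoo()
    graph = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.array(part.membership)
    # relabel by decreasing cluster size, ties by lowest original label
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    return ClusterAssignment(labels, resolution, float(part.quality()))


# ---------------------------------------------------------------------------
# weighted joint neighbors


def weighted_joint_neighbors(
    rna_latent: LatentSpace | np.ndarray,
    atac_latent: LatentSpace | np.ndarray,
    k: int = 20,
    eps: float = 1e-8,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-cell modality weights and a joint kNN graph.

    For modality m: d_within(i) = distance from cell i to the mean of its
    own-modality kNN in m's latent space; d_cross(i) = distance to the mean
    of its kNN found in the OTHER modality's space. The informativeness
    s_m = max(eps, d_cross - d_within) is normalized into weights summing
    to 1. Joint distance blends per-modality distances scaled by the
    distance to each cell's k-th neighbor.
    """
    L1 = rna_latent.coords[:, rna_latent.default_dims] if isinstance(rna_latent, LatentSpace) else np.asarray(rna_latent)
    L2 = atac_latent.coords[:, atac_latent.default_dims] if isinstance(atac_latent, LatentSpace) else np.asarray(atac_latent)
    if L1.shape[0] != L2.shape[0]:
        raise ValidationError("modalities cover different cell sets")
    n = L1.shape[0]
    idx1, dist1 = _knn(L1, k)
    idx2, dist2 = _knn(L2, k)

    def informativeness(L: np.ndarray, own_idx: np.ndarray, cross_idx: np.ndarray) -> np.ndarray:
        within = np.linalg.norm(L - L[own_idx].mean(axis=1), axis=1)
        cross = np.linalg.norm(L - L[cross_idx].mean(axis=1), axis=1)
        return np.maximum(eps, cross - within)

    s1 = informativeness(L1, idx1, idx2)
    s2 = informativeness(L2, idx2, idx1)
    w1 = s1 / (s1 + s2)
    w2 = 1.0 - w1

    sigma1 = np.maximum(dist1[:, -1], eps)
    sigma2 = np.maximum(dist2[:, -1], eps)
    # joint kNN over the union of both modality neighborhoods
    cand = np.concatenate([idx1, idx2], axis=1)
    d1 = _pair_dists(L1, cand)
    d2 = _pair_dists(L2, cand)
    joint = w1[:, None] * d1 / sigma1[:, None] + w2[:, None] * d2 / sigma2[:, None]
    joint_idx = np.empty((n, k), dtype=int)
    joint_dist = np.empty((n, k))
    for i in range(n):
        cands, first = np.unique(cand[i], return_index=True)
        dd = joint[i][first]
        keep = cands != i
        cands, dd = cands[keep], dd[keep]
        o = np.argsort(dd, kind="mergesort")[:k]
        # pad with repeats if the union is short (rare at small n)
        sel = o if len(o) == k else np.resize(o, k)
        joint_idx[i] = cands[sel]
        joint_dist[i] = dd[sel]
    weights = pd.DataFrame({"w_rna": w1, "w_atac": w2})
    return weights, joint_idx, joint_dist


def _pair_dists(L: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.linalg.norm(L[:, None, :] - L[idx], axis=2)


def joint_embedding(
    rna_latent: LatentSpace, atac_latent: LatentSpace, weights: pd.DataFrame
) -> np.ndarray:
    """Weight-blended concatenation of the standardized per-modality
    latents: a simple joint space for centroid geometry and 2-D hooks."""
    A = rna_latent.coords[:, rna_latent.default_dims]
    B = atac_latent.coords[:, atac_latent.default_dims]

    def stdz(M: np.ndarray) -> np.ndarray:
        s = M.std()
        return M / s if s > 0 else M

    wa = weights["w_rna"].to_numpy()[:, None]
    wb = weights["w_atac"].to_numpy()[:, None]
    return np.concatenate([stdz(A) * wa, stdz(B) * wb], axis=1)


# ---------------------------------------------------------------------------
# MST pseudotime


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray
    root_cluster: int
    mst_edges: list[tuple[int, int]]
    branch_nodes: list[int]
    terminal_nodes: list[int]


def mst_pseudotime(
    joint: np.ndarray,
    clusters: np.ndarray,
    root_cells: np.ndarray,
) -> PseudotimeResult:
    """Cluster-centroid MST pseudotime.

    Centroids are computed in the joint latent space; the MST of their
    complete Euclidean graph defines the trajectory backbone. The root is
    the centroid of the cluster holding the most root cells. A cell's
    pseudotime is the tree path length from the root to its cluster
    centroid plus its signed scalar projection onto the incoming MST edge
    (root-cluster cells project onto the root's first outgoing edge).
    Branch nodes are MST vertices of degree >= 3; terminal nodes are
    non-root leaves.
    """
    root_cells = np.asarray(root_cells)
    if root_cells.size == 0:
        raise ValidationError("root_cells must be non-empty")
    labels = np.asarray(clusters)
    uniq = np.unique(labels)
    cent = np.stack([joint[labels == c].mean(axis=0) for c in uniq])
    ncl = len(uniq)
    lab_of = {c: i for i, c in enumerate(uniq)}

    root_counts = pd.Series(labels[root_cells]).value_counts()
    root_cluster = int(root_counts.index[0])
    r = lab_of[root_cluster]

    if ncl == 1:
        # single cluster: pseudotime from projection onto the first
        # principal direction of the cells, anchored at the root side
        d = joint - cent[0]
        if joint.shape[0] > 1:
            _, _, Vt = np.linalg.svd(d, full_matrices=False)
            proj = d @ Vt[0]
            if np.mean(proj[root_cells]) > 0:
                proj = -proj
            pt = proj - proj.min()
        else:
            pt = np.zeros(joint.shape[0])
        return PseudotimeResult(pt, root_cluster, [], [], [])

    D = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=2)
    mst = minimum_spanning_tree(D)
    mst = mst + mst.T
    dist_from_root = shortest_path(mst, indices=r)
    mcoo = sp.triu(mst, k=1).tocoo()
    edges = list(zip(mcoo.row.tolist(), mcoo.col.tolist()))
    deg = np.zeros(ncl, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    branch = [int(uniq[i]) for i in range(ncl) if deg[i] >= 3]
    terminal = [int(uniq[i]) for i in range(ncl) if deg[i] == 1 and i != r]

    # parent of each node on the path to the root
    parent = np.full(ncl, -1, dtype=int)
    order = np.argsort(dist_from_root)
    adj = {i: [] for i in range(ncl)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    for i in order[1:]:
        parent[i] = min(
            (j for j in adj[i] if dist_from_root[j] < dist_from_root[i]),
            key=lambda j: dist_from_root[j],
            default=-1,
        )

    pt = np.zeros(joint.shape[0])
    for c in uniq:
        i = lab_of[c]
        mask = labels == c
        cells = joint[mask]
        if i == r:
            nxt = min(adj[r], key=lambda j: dist_from_root[j] if j != r else np.inf, default=None)
            if nxt is None:
                pt[mask] = 0.0
                continue
            edge = cent[nxt] - cent[r]
            proj = (cells - cent[r]) @ edge / np.linalg.norm(edge)
            pt[mask] = np.maximum(0.0, proj)
        else:
            p = parent[i]
            edge = cent[i] - cent[p]
            norm = np.linalg.norm(edge)
            proj = (cells - cent[i]) @ edge / norm if norm > 0 else 0.0
            pt[mask] = dist_from_root[i] + proj
    pt = pt - pt.min()
    return PseudotimeResult(pt, root_cluster, edges, branch, terminal)


def embed_2d(joint: np.ndarray, seed: int = 0) -> np.ndarray:
    """Visualization hook: 2-D embedding of the joint space (PCA
    projection; swap in UMAP if desired). No analysis depends on it."""
    X = joint - joint.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    return X @ Vt[:2].T
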