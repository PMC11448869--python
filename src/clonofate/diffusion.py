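"""Adaptive-kernel diffusion operator, imputation, diffusion maps, clustering.

The operator is built on a kNN graph in PCA space with a per-cell adaptive
Gaussian bandwidth: ``sigma_i`` is the distance to the ``ka``-th nearest
neighbor, the kernel is ``K_ij = exp(-(d_ij/sigma_i)^2)`` on neighbor
pairs, symmetrized as ``(K + K^T)/2`` with self-affinity 1 on the
diagonal, and row-normalized into the row-stochastic operator ``P``.
Imputation applies ``P^t`` to the expression matrix (iteratively, never
densifying the power).  Each row ``A_i`` of ``P`` is the unit-normalized
local diffusion neighborhood of cell ``i`` — the ingredient of the
clonotype neighborhood-weight statistic.

Community detection follows the Phenograph recipe: a shared-neighbor
graph with Jaccard edge weights over the k nearest-neighbor lists,
partitioned by seeded modularity optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances
from sklearn.neighbors import NearestNeighbors

from .core import CellMatrix, ConfigError


@dataclass
class GraphParams:
    """Diffusion-graph parameters.

    k : neighbors per cell (default 30).
    ka : index of the neighbor whose distance sets the adaptive bandwidth
        sigma_i (default 10).
    t : diffusion time — the power applied to the operator (default 4).
    n_pcs : PCA dimensions for the distance space (default 20).
    """

    k: int = 30
    ka: int = 10
    t: int = 4
    n_pcs: int = 20

    def __post_init__(self) -> None:
        if not 1 <= self.ka <= self.k:
            raise ConfigError(f"need 1 <= ka <= k; got ka={self.ka}, k={self.k}")
        if self.t < 0:
            raise ConfigError("t must be >= 0")
        if self.n_pcs < 1:
            raise ConfigError("n_pcs must be >= 1")


def pca_reduce(cm_or_X, n_pcs: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Top-``n_pcs`` PCA scores of the log layer (genes centered).

    Returns ``(scores, explained_variance_ratio)``.  The sign convention
    is deterministic: each component is flipped so its largest-magnitude
    loading is positive.
    """
    if isinstance(cm_or_X, CellMatrix):
        if cm_or_X.layer_log is None:
            raise ValueError("normalize() before pca_reduce()")
        X = cm_or_X.layer_log
    else:
        X = np.asarray(cm_or_X, dtype=float)
    if n_pcs > min(X.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(dims)={min(X.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.sign(
        pca.components_[np.arange(n_pcs), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    return scores * flip, pca.explained_variance_ratio_


class DiffusionOperator(BaseEstimator, TransformerMixin):
    """Adaptive Gaussian-kernel diffusion operator on a kNN graph.

    ``fit(X)`` builds the graph on the rows of ``X`` (typically PCA
    scores); ``transform(Y)`` imputes by applying ``P^t`` to ``Y``.

    Attributes (after fit)
    ----------------------
    neighbors_ : (n, k) int array of neighbor indices (self excluded).
    distances_ : (n, k) Euclidean distances to those neighbors.
    sigmas_ : adaptive bandwidths, the distance to the ka-th neighbor.
    K_ : symmetric sparse affinity with unit diagonal.
    P_ : row-stochastic sparse operator (rows sum to 1).
    """

    def __init__(self, k: int = 30, ka: int = 10, t: int = 4):
        self.k = k
        self.ka = ka
        self.t = t

    def fit(self, X, y=None):
        params = GraphParams(k=self.k, ka=self.ka, t=self.t)
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < self.k + 1:
            raise ValueError(f"need at least k+1={self.k + 1} cells, got {n}")
        nn = NearestNeighbors(n_neighbors=self.k + 1).fit(X)
        dist, idx = nn.kneighbors(X)
        # drop the self column; with tied (duplicate) points the self match
        # may appear elsewhere or, in pathological ties, not at all — always
        # remove exactly one column per row
        self_col = idx == np.arange(n)[:, None]
        keep = ~self_col
        for i in np.flatnonzero(self_col.sum(axis=1) != 1):
            extra = np.flatnonzero(self_col[i])
            keep[i] = True
            keep[i, extra[0] if len(extra) else -1] = False
        dist = dist[keep].reshape(n, self.k)
        idx = idx[keep].reshape(n, self.k)

        sigmas = dist[:, self.ka - 1].copy()
        degenerate = sigmas <= 0
        if degenerate.any():
            smallest_pos = np.where(dist > 0, dist, np.inf).min(axis=1)
            if not np.isfinite(smallest_pos[degenerate]).all():
                raise ValueError("all neighbor distances are zero (identical points)")
            sigmas[degenerate] = smallest_pos[degenerate]
            warnings.warn(
                f"{int(degenerate.sum())} cells had sigma=0 (duplicate points); "
                "substituted smallest positive neighbor distance"
            )

        vals = np.exp(-((dist / sigmas[:, None]) ** 2))
        rows = np.repeat(np.arange(n), self.k)
        K = sp.csr_matrix((vals.ravel(), (rows, idx.ravel())), shape=(n, n))
        K = (K + K.T) * 0.5
        K = K + sp.identity(n, format="csr")
        degrees = np.asarray(K.sum(axis=1)).ravel()
        P = sp.diags(1.0 / degrees) @ K

        self.n_cells_ = n
        self.params_ = params
        self.neighbors_ = idx
        self.distances_ = dist
        self.sigmas_ = sigmas
        self.K_ = K.tocsr()
        self.P_ = P.tocsr()
        self.degrees_ = degrees
        return self

    # -- imputation -----------------------------------------------------
    def transform(self, X, t: int | None = None) -> np.ndarray:
        """Impute by diffusion: return ``P^t · X`` (iterative products)."""
        t = self.t if t is None else t
        if t < 0:
            raise ValueError("t must be >= 0")
        Y = np.asarray(X, dtype=float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        if Y.shape[0] != self.n_cells_:
            raise ValueError(
                f"X has {Y.shape[0]} rows but the graph has {self.n_cells_} cells"
            )
        for _ in range(t):
            Y = self.P_ @ Y
        return Y.ravel() if squeeze else Y

    # -- spectral pieces ------------------------------------------------
    def connected_components(self) -> tuple[int, np.ndarray]:
        return sp.csgraph.connected_components(self.K_, directed=False)[:2]

    def diffusion_map(self, n_dcs: int = 10) -> "DiffusionMap":
        """Eigendecomposition of ``P`` via its symmetric conjugate.

        The trivial unit eigenvalue is dropped.  On a disconnected graph a
        map is computed per component (with a warning), mirroring
        per-sample usage on heterogeneous cohorts.
        """
        n_comp, comp_labels = self.connected_components()
        if n_comp > 1:
            warnings.warn(
                f"graph has {n_comp} connected components; computing per-component maps"
            )
            psis = np.zeros((self.n_cells_, n_dcs))
            lam = np.zeros(n_dcs)
            for c in range(n_comp):
                members = np.flatnonzero(comp_labels == c)
                if len(members) < 3:
                    raise ValueError("a connected component is too small for a map")
                Ksub = self.K_[members][:, members]
                dsub = np.asarray(Ksub.sum(axis=1)).ravel()
                Psub = sp.diags(1.0 / dsub) @ Ksub
                ev, vecs = _eig_stochastic(Psub.tocsr(), n_dcs, degrees=dsub)
                m = min(n_dcs, vecs.shape[1])
                psis[members, :m] = vecs[:, :m]
                lam[:m] = np.maximum(lam[:m], ev[:m])
            return DiffusionMap(
                eigenvalues=lam, components=psis, component_labels=comp_labels
            )
        evals, vecs = _eig_stochastic(self.P_, n_dcs, degrees=self.degrees_)
        return DiffusionMap(
            eigenvalues=evals,
            components=vecs,
            component_labels=comp_labels,
        )


def _eig_stochastic(
    P: sp.csr_matrix, n_dcs: int, degrees: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Nontrivial eigenpairs of a row-stochastic P via the symmetric
    conjugate D^{1/2} P D^{-1/2}; returns (eigenvalues, right eigenvectors),
    both with the trivial lambda=1 pair removed and sorted descending.

    For P = D^{-1}K with K symmetric, the stationary distribution is
    proportional to the degrees (row sums of K); pass them when known to
    skip the power iteration."""
    n = P.shape[0]
    if degrees is not None:
        pi = np.asarray(degrees, dtype=float)
        pi = pi / pi.sum()
    else:
        pi = _stationary_distribution(P)
    d_half = np.sqrt(pi)
    S = sp.diags(d_half) @ P @ sp.diags(1.0 / d_half)
    S = (S + S.T) * 0.5  # clean numerical asymmetry
    k = min(n_dcs + 1, n - 1)
    if n <= 200:
        ev, vecs = np.linalg.eigh(S.toarray())
        ev, vecs = ev[::-1], vecs[:, ::-1]
    else:
        ev, vecs = spla.eigsh(S, k=k, which="LA")
        order = np.argsort(-ev)
        ev, vecs = ev[order], vecs[:, order]
    ev, vecs = ev[: k + 1], vecs[:, : k + 1]
    # drop the trivial component (eigenvalue 1)
    ev, vecs = ev[1:], vecs[:, 1:]
    keep = min(n_dcs, len(ev))
    ev, vecs = ev[:keep], vecs[:, :keep]
    psi = vecs / d_half[:, None]
    # normalize under the stationary inner product <u,v>_pi = sum pi u v
    norms = np.sqrt((pi[:, None] * psi**2).sum(axis=0))
    psi = psi / norms
    # deterministic sign: largest-|entry| coordinate positive
    sign = np.sign(psi[np.argmax(np.abs(psi), axis=0), np.arange(psi.shape[1])])
    sign[sign == 0] = 1.0
    return ev, psi * sign


def _stationary_distribution(P: sp.csr_matrix) -> np.ndarray:
    """Stationary distribution of the reversible operator: for P built by
    row-normalizing a symmetric K, pi is proportional to the row sums of K,
    recovered here by power iteration for generality."""
    n = P.shape[0]
    pi = np.full(n, 1.0 / n)
    for _ in range(10_000):
        new = pi @ P
        if np.abs(new - pi).max() < 1e-14:
            pi = new
            break
        pi = new
    return np.asarray(pi).ravel() / pi.sum()


@dataclass
class DiffusionMap:
    """Nontrivial diffusion components of the operator.

    ``eigenvalues`` are sorted descending with the trivial lambda=1
    dropped; ``components`` (psi) are orthonormal under the stationary
    inner product.  ``multiscale()`` weights psi_l by lambda_l/(1-lambda_l),
    summing the contribution of all diffusion times.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    component_labels: np.ndarray | None = None

    @property
    def n_dcs(self) -> int:
        return self.components.shape[1]

    def eigengaps(self) -> np.ndarray:
        return -np.diff(self.eigenvalues)

    def multiscale(self) -> np.ndarray:
        lam = np.clip(self.eigenvalues, None, 1 - 1e-12)
        return self.components * (lam / (1 - lam))[None, :]


def diffusion_distance(
    dmap: DiffusionMap,
    labels=None,
    method: str = "centroid",
) -> np.ndarray:
    """Pairwise Euclidean distances in multiscale diffusion coordinates.

    Without ``labels``: the cell–cell distance matrix.  With labels: one
    distance per group pair — the distance between group centroids
    (default) or the mean over cross-group cell pairs
    (``method='mean_pairwise'``).
    """
    coords = dmap.multiscale()
    if labels is None:
        return pairwise_distances(coords)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    for g in groups:
        if (labels == g).sum() == 0:  # pragma: no cover - unique() precludes
            raise ValueError(f"label {g!r} has no cells")
    if method == "centroid":
        centroids = np.stack([coords[labels == g].mean(axis=0) for g in groups])
        return pairwise_distances(centroids)
    if method == "mean_pairwise":
        out = np.zeros((len(groups), len(groups)))
        for i, gi in enumerate(groups):
            for j, gj in enumerate(groups):
                D = pairwise_distances(coords[labels == gi], coords[labels == gj])
                if i == j:
                    m = D.shape[0]
                    out[i, j] = D.sum() / (m * (m - 1)) if m > 1 else 0.0
                else:
                    out[i, j] = D.mean()
        return out
    raise ValueError(f"unknown method {method!r}")


# ----------------------------------------------------------------------
# Phenograph-style community detection


def _jaccard_graph(neighbor_idx: np.ndarray) -> ig.Graph:
    """Shared-neighbor graph: edge weight = Jaccard overlap of the two
    cells' (self-inclusive) neighbor lists, over all kNN edges."""
    n, k = neighbor_idx.shape
    sets = [set(row) | {i} for i, row in enumerate(neighbor_idx)]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in neighbor_idx[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if a == b or (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            w = inter / union
            if w > 0:
                edges.append((a, b))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


class GraphClusterer(BaseEstimator):
    """Phenograph-style clustering: kNN → Jaccard SNN graph → seeded
    modularity community detection.

    Parameters
    ----------
    k : neighbors for the kNN graph (default 30 — captures small discrete
        populations at the cost of over-splitting continuous regions).
    metric : distance metric for the kNN search.
    resolution : modularity resolution (1.0 = plain modularity).
    random_state : partition seed; fixed seed ⇒ identical labels.
    """

    def __init__(self, k: int = 30, metric: str = "euclidean",
                 resolution: float = 1.0, random_state: int = 0):
        self.k = k
        self.metric = metric
        self.resolution = resolution
        self.random_state = random_state

    def fit_predict(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.k >= n:
            raise ValueError(f"k={self.k} must be < n_cells={n}")
        nn = NearestNeighbors(n_neighbors=min(self.k + 1, n), metric=self.metric).fit(X)
        idx = nn.kneighbors(X, return_distance=False)
        # drop self column
        mask = idx != np.arange(n)[:, None]
        cleaned = np.empty((n, idx.shape[1] - 1), dtype=int)
        for i in range(n):
            row = idx[i][mask[i]]
            cleaned[i] = row[: idx.shape[1] - 1]
        graph = _jaccard_graph(cleaned)
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=self.resolution,
            seed=int(self.random_state),
        )
        self.labels_ = np.asarray(part.membership, dtype=int)
        self.modularity_ = part.quality()
        return self.labels_

    def fit(self, X, y=None):
        self.fit_predict(X)
        return self


# ----------------------------------------------------------------------
# functional wrappers (thin, estimator-backed)


def build_affinity(X_red, params: GraphParams | None = None, **kw) -> DiffusionOperator:
    params = params or GraphParams(**kw)
    return DiffusionOperator(k=params.k, ka=params.ka, t=params.t).fit(X_red)


def impute(graph: DiffusionOperator, X, t: int | None = None) -> np.ndarray:
    return graph.transform(X, t=t)


def diffusion_map(graph: DiffusionOperator, n_dcs: int = 10) -> DiffusionMap:
    return graph.diffusion_map(n_dcs=n_dcs)


def cluster_cells(X, k: int = 30, seed: int = 0, metric: str = "euclidean",
                  resolution: float = 1.0) -> np.ndarray:
    return GraphClusterer(
        k=k, metric=metric, resolution=resolution, random_state=seed
    ).fit_predict(X)
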