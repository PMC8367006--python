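"""Spectral manifold learning: bespoke Laplacian Eigenmaps with a Nystrom
out-of-sample extension, library-backed baseline embeddings, and an
intrinsic-dimension estimator.

Laplacian Eigenmaps builds a union-symmetrized k-nearest-neighbor graph on
the training points, weights its edges either uniformly ("simple-minded")
or with the heat kernel exp(-||x_i - x_j||^2 / (2 sigma^2)), and solves the
generalized eigenproblem L f = lambda D f with L = D - W and D the diagonal
degree matrix. The eigenvector of the zero eigenvalue (constant on a
connected graph) is dropped; the next m eigenvectors give the embedding
coordinates y_i = (f_1(i), ..., f_m(i)).

New points are mapped without re-solving the eigenproblem via the row
identity of the eigenproblem itself: since W f = (1 - lambda) D f on the
training set, a new point x with weights w_i to its nearest training
points embeds as

    y_j(x) = sum_i w_i f_j(i) / (d(x) (1 - lambda_j)),   d(x) = sum_i w_i,

which reproduces every training point's own coordinate exactly when fed its
stored weight row -- the testable anchor of this Nystrom variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.manifold import Isomap, LocallyLinearEmbedding
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborGraph",
    "SpectralModel",
    "GraphConnectivityError",
    "SingularExtensionError",
    "build_knn_graph",
    "weight_matrix",
    "spectral_embed",
    "LaplacianEigenmaps",
    "nystrom_extend",
    "make_embedder",
    "pca_embed",
    "lda_embed",
    "lle_embed",
    "isomap_embed",
    "estimate_intrinsic_dim",
]


class SingularExtensionError(RuntimeError):
    """A retained eigenvalue equals 1, making the Nystrom denominator zero."""


class GraphConnectivityError(RuntimeError):
    """The neighbor graph is not connected, so the embedding is undefined.

    Raised instead of silently embedding components separately; the usual
    remedies are a larger ``n_neighbors`` or, in windowed analyses, a longer
    window (sub-100 ms windows are known to disconnect at study scale).
    """


@dataclass
class NeighborGraph:
    """Union-symmetrized k-NN graph with edge distances.

    ``adjacency`` and ``distances`` are symmetric CSR matrices over the same
    sparsity pattern (no self-edges); ``connected`` is precomputed.
    """

    n_points: int
    n_neighbors: int
    adjacency: sparse.csr_matrix
    distances: sparse.csr_matrix
    connected: bool


def build_knn_graph(X: np.ndarray, n_neighbors: int) -> NeighborGraph:
    """Build the graph with an edge i-j iff i is among the n nearest
    neighbors of j or vice versa (Euclidean metric, ties to lower index)."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"build_knn_graph: need N > n_neighbors, got N={n}, n_neighbors={n_neighbors}")
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)  # no self-edges
    order = np.argsort(d, axis=1, kind="stable")[:, :n_neighbors]
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = order.reshape(-1)
    adj = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(np.float64)  # union symmetrization
    np.fill_diagonal(d, 0.0)
    dist = adj.multiply(d).tocsr()
    n_comp, _ = connected_components(adj, directed=False)
    return NeighborGraph(n, n_neighbors, adj.tocsr(), dist, connected=(n_comp == 1))


def weight_matrix(
    graph: NeighborGraph, scheme: str = "simple", sigma: float | None = None
) -> sparse.csr_matrix:
    """Edge weights: ``simple`` gives W_ij = 1 on edges; ``heat`` gives
    W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))."""
    if scheme == "simple":
        return graph.adjacency.copy()
    if scheme == "heat":
        if sigma is None or sigma <= 0:
            raise ValueError("weight_matrix: heat kernel requires sigma > 0")
        rows, cols = graph.adjacency.nonzero()
        d = np.asarray(graph.distances[rows, cols]).ravel()
        vals = np.exp(-(d**2) / (2.0 * sigma**2))
        return sparse.csr_matrix((vals, (rows, cols)), shape=graph.adjacency.shape)
    raise ValueError(f"weight_matrix: unknown scheme {scheme!r}")


@dataclass
class SpectralModel:
    """A fitted spectral embedding with everything Nystrom extension needs."""

    training_points: np.ndarray
    graph: NeighborGraph
    weight_scheme: str
    sigma: float | None
    W: sparse.csr_matrix
    degrees: np.ndarray
    eigenvalues: np.ndarray  # smallest nonzero first, zero eigenvalue excluded
    eigenvectors: np.ndarray  # columns f_j, normalized f^T D f = 1
    m: int

    @property
    def embedding(self) -> np.ndarray:
        """Training coordinates y_i = (f_1(i), ..., f_m(i))."""
        return self.eigenvectors

    @property
    def laplacian(self) -> sparse.csr_matrix:
        return sparse.diags(self.degrees) - self.W


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-|entry| coordinate made positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def spectral_embed(
    W: sparse.spmatrix | np.ndarray,
    m: int,
    *,
    X: np.ndarray | None = None,
    graph: NeighborGraph | None = None,
    weight_scheme: str = "simple",
    sigma: float | None = None,
) -> SpectralModel:
    """Solve L f = lambda D f and keep the m smallest nonzero eigenpairs.

    The generalized problem is reduced to the symmetric normalized form
    S = D^{-1/2} L D^{-1/2} (whose spectrum lies in [0, 2]); eigenvectors are
    mapped back by f = D^{-1/2} u, which makes f^T D f = 1 automatic. The
    zero eigenvalue's constant eigenvector is dropped. Disconnected graphs
    are a hard error.
    """
    W = sparse.csr_matrix(W)
    n = W.shape[0]
    if not 1 <= m <= n - 1:
        raise ValueError(f"spectral_embed: need 1 <= m <= N-1, got m={m}, N={n}")
    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        raise GraphConnectivityError(
            f"neighbor graph has {n_comp} connected components; increase n_neighbors "
            "or use a longer window (the zero eigenvalue is degenerate on a "
            "disconnected graph and the embedding is undefined)"
        )
    degrees = np.asarray(W.sum(axis=0)).ravel()  # column sums; W symmetric
    d_isqrt = 1.0 / np.sqrt(degrees)
    S = sparse.diags(d_isqrt) @ (sparse.diags(degrees) - W) @ sparse.diags(d_isqrt)
    # Dense symmetric solve: training sets here are at most a few thousand
    # points, where LAPACK is both faster and more accurate than iterative
    # sparse solvers near the zero eigenvalue.
    vals, vecs = sla.eigh(np.asarray(S.todense()), subset_by_index=(0, m))
    if vals[0] > 1e-6:
        raise RuntimeError("spectral_embed: zero eigenvalue missing from a connected graph")
    f = _fix_signs(d_isqrt[:, None] * vecs[:, 1:])
    return SpectralModel(
        training_points=np.asarray(X) if X is not None else np.empty((n, 0)),
        graph=graph if graph is not None else build_knn_graph_from_W(W),
        weight_scheme=weight_scheme,
        sigma=sigma,
        W=W,
        degrees=degrees,
        eigenvalues=np.maximum(vals[1:], 0.0),
        eigenvectors=f,
        m=m,
    )


def build_knn_graph_from_W(W: sparse.csr_matrix) -> NeighborGraph:
    """Wrap an explicit weight matrix as a graph (used when W is given raw)."""
    adj = (W != 0).astype(np.float64).tocsr()
    n_comp, _ = connected_components(adj, directed=False)
    deg = int(np.asarray(adj.sum(axis=1)).max()) if adj.nnz else 0
    return NeighborGraph(W.shape[0], deg, adj, adj.copy(), connected=(n_comp == 1))


def _extension_weights(model: SpectralModel, X_new: np.ndarray) -> np.ndarray:
    """Dense (n_new x N) weight rows: each new point is connected to its
    n_neighbors nearest training points under the model's scheme."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    Xtr = model.training_points
    if Xtr.size == 0:
        raise ValueError("nystrom_extend: model was fitted without training points stored")
    if X_new.shape[1] != Xtr.shape[1]:
        raise ValueError(
            f"nystrom_extend: feature dimension {X_new.shape[1]} != training {Xtr.shape[1]}"
        )
    d = cdist(X_new, Xtr)
    order = np.argsort(d, axis=1, kind="stable")[:, : model.graph.n_neighbors]
    W_rows = np.zeros_like(d)
    rows = np.repeat(np.arange(X_new.shape[0]), order.shape[1])
    cols = order.reshape(-1)
    if model.weight_scheme == "heat":
        W_rows[rows, cols] = np.exp(-(d[rows, cols] ** 2) / (2.0 * model.sigma**2))
    else:
        W_rows[rows, cols] = 1.0
    return W_rows


def extend_from_weight_rows(model: SpectralModel, W_rows: np.ndarray) -> np.ndarray:
    """Apply the Nystrom row identity to explicit weight rows."""
    one_minus = 1.0 - model.eigenvalues
    if np.any(np.abs(one_minus) < 1e-12):
        raise SingularExtensionError(
            "nystrom_extend: an eigenvalue equals 1; extension is singular"
        )
    W_rows = np.atleast_2d(W_rows)
    d = W_rows.sum(axis=1)
    if np.any(d <= 0):
        bad = np.flatnonzero(d <= 0)
        raise SingularExtensionError(
            f"nystrom_extend: zero total weight for point(s) {bad.tolist()}"
        )
    return (W_rows @ model.eigenvectors) / d[:, None] / one_minus[None, :]


def nystrom_extend(model: SpectralModel, X_new: np.ndarray) -> np.ndarray:
    """Embed new points into a fitted model's coordinate system."""
    return extend_from_weight_rows(model, _extension_weights(model, X_new))


class LaplacianEigenmaps:
    """Estimator-style wrapper around the spectral pipeline.

    Parameters
    ----------
    n_components : int
        Embedding dimension m.
    n_neighbors : int
        Graph neighborhood size (study default 8).
    weights : {"simple", "heat"}
        Edge weighting scheme.
    sigma : float
        Heat-kernel bandwidth; equivalently the RBF kernel with
        gamma = 1 / (2 sigma^2). Ignored for simple-minded weights.
    """

    def __init__(self, n_components: int = 2, n_neighbors: int = 8,
                 weights: str = "simple", sigma: float = 1.0):
        if weights not in ("simple", "heat"):
            raise ValueError(f"unknown weight scheme {weights!r}")
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.weights = weights
        self.sigma = sigma

    def fit(self, X: np.ndarray, y=None) -> "LaplacianEigenmaps":
        X = np.asarray(X, dtype=np.float64)
        graph = build_knn_graph(X, self.n_neighbors)
        W = weight_matrix(graph, self.weights, self.sigma if self.weights == "heat" else None)
        self.model_ = spectral_embed(
            W, self.n_components, X=X, graph=graph,
            weight_scheme=self.weights, sigma=self.sigma,
        )
        self.embedding_ = self.model_.embedding
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).embedding_

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("LaplacianEigenmaps: fit before transform")
        return nystrom_extend(self.model_, X_new)


# ---------------------------------------------------------------------------
# Baseline embeddings (library-backed; each exposes an out-of-sample
# transform: projection for PCA/LDA, built-in extensions for LLE/ISOMAP).
# ---------------------------------------------------------------------------

class _LDAAdapter:
    """LDA restricted to <= n_classes - 1 components, with transform."""

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X, y):
        n_classes = len(np.unique(y))
        if self.n_components > n_classes - 1:
            raise ValueError(
                f"LDA supports at most n_classes - 1 = {n_classes - 1} components, "
                f"got {self.n_components}"
            )
        self._est = LinearDiscriminantAnalysis(n_components=self.n_components).fit(X, y)
        self.embedding_ = self._est.transform(X)
        return self

    def fit_transform(self, X, y):
        return self.fit(X, y).embedding_

    def transform(self, X_new):
        return self._est.transform(X_new)


class _SkAdapter:
    """Uniform fit/fit_transform/transform facade over sklearn embedders."""

    def __init__(self, est):
        self._est = est

    def fit(self, X, y=None):
        self.embedding_ = self._est.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X_new):
        return self._est.transform(X_new)


def make_embedder(
    kind: str,
    n_components: int,
    n_neighbors: int = 8,
    weights: str = "simple",
    sigma: float = 1.0,
    random_state: int = 0,
):
    """Factory for the supported dimensionality-reduction methods."""
    if kind == "le":
        return LaplacianEigenmaps(n_components, n_neighbors, weights, sigma)
    if kind == "pca":
        return _SkAdapter(PCA(n_components=n_components, random_state=random_state))
    if kind == "lda":
        return _LDAAdapter(n_components)
    if kind == "lle":
        return _SkAdapter(
            LocallyLinearEmbedding(
                n_neighbors=n_neighbors, n_components=n_components, random_state=random_state
            )
        )
    if kind == "isomap":
        return _SkAdapter(Isomap(n_neighbors=n_neighbors, n_components=n_components))
    raise ValueError(f"make_embedder: unknown kind {kind!r}")


def pca_embed(X, m, random_state: int = 0):
    return make_embedder("pca", m, random_state=random_state).fit_transform(X)


def lda_embed(X, labels, m):
    return make_embedder("lda", m).fit_transform(X, labels)


def lle_embed(X, n_neighbors, m, random_state: int = 0):
    return make_embedder("lle", m, n_neighbors, random_state=random_state).fit_transform(X)


def isomap_embed(X, n_neighbors, m):
    return make_embedder("isomap", m, n_neighbors).fit_transform(X)


def estimate_intrinsic_dim(X: np.ndarray, n_neighbors: int = 10) -> float:
    """Maximum-likelihood intrinsic dimension (Levina-Bickel estimator).

    For each point the per-point MLE at neighborhood size k is
    [ (1/(k-1)) sum_{j<k} log(T_k / T_j) ]^{-1} with T_j the distance to the
    j-th neighbor; per-point inverses are averaged (the standard
    stabilization) and the result averaged over k in
    [n_neighbors - 2, n_neighbors]. Zero distances from duplicate points are
    floored at a small epsilon.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not (n > n_neighbors >= 2):
        raise ValueError("estimate_intrinsic_dim: need N > n_neighbors >= 2")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    dist = np.maximum(dist[:, 1:], 1e-12)  # drop self, floor duplicates
    estimates = []
    for k in range(max(3, n_neighbors - 2), n_neighbors + 1):
        log_ratios = np.log(dist[:, k - 1 : k] / dist[:, : k - 1])
        inv = log_ratios.sum(axis=1) / (k - 1)
        estimates.append(1.0 / inv.mean())
    return float(np.mean(estimates))
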