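"""Unsupervised spectral regression (SR) and kernel spectral regression (KSR).

Dimensionality reduction in two stages: (1) build a p-nearest-neighbour
affinity graph over the samples and solve the graph eigenproblem
W v = lambda D v for its leading nontrivial eigenvectors ("responses");
(2) regress the samples onto the responses -- with ridge (L2), lasso (L1) or
a Gaussian-kernel ridge -- so new points can be embedded through the learned
map instead of re-solving a dense eigenproblem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist, pdist
from sklearn.neighbors import NearestNeighbors

__all__ = ["AffinityGraph", "EmbeddingModel", "knn_graph", "graph_responses",
           "fit_linear", "fit_kernel", "embed", "gaussian_kernel",
           "median_kernel_width"]


@dataclass
class AffinityGraph:
    """Symmetrized p-NN graph: 0-1 weight matrix W, degree matrix diagonal D."""

    W: np.ndarray
    D: np.ndarray  # diagonal entries, D_ii = sum_j W_ji
    p: int


@dataclass
class EmbeddingModel:
    """Learned spectral-regression map.

    ``coefficients`` has one column per embedding dimension.  In linear mode
    a new point x embeds as a^T x; in kernel mode as K(x, training)^T a with
    a Gaussian kernel of width ``kernel_width``.
    """

    responses: np.ndarray
    coefficients: np.ndarray
    mode: str  # {"linear", "kernel"}
    alpha: float = 0.0
    beta: float = 0.0
    kernel_width: float | None = None
    training_points: np.ndarray | None = None


def knn_graph(X: np.ndarray, p: int, weight: str = "binary") -> AffinityGraph:
    """Symmetrized p-nearest-neighbour graph.

    An edge joins i and j iff i is among j's p nearest Euclidean neighbours
    or vice versa; the diagonal is zero and neighbour ties are resolved by
    sample index.  ``weight="binary"`` puts weight 1 on every edge (scale
    equivariant); ``weight="heat"`` uses exp(-d_ij^2 / (2 t^2)) with t the
    median pairwise distance, so edges forced onto a distant outlier by the
    kNN rule carry almost no weight.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if p >= N:
        raise ValueError(f"p={p} must be smaller than the sample count N={N}")
    if weight not in ("binary", "heat"):
        raise ValueError(f"unknown weight scheme {weight!r}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in data")
    nn = NearestNeighbors(n_neighbors=p + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    if weight == "heat":
        t = median_kernel_width(X)
    W = np.zeros((N, N))
    for i in range(N):
        for d, j in zip(dist[i], idx[i]):
            if j != i:
                W[i, j] = np.exp(-d**2 / (2 * t**2)) if weight == "heat" else 1.0
    W = np.maximum(W, W.T)
    D = W.sum(axis=0)
    return AffinityGraph(W=W, D=D, p=p)


def _connected_components(W: np.ndarray) -> list[np.ndarray]:
    N = W.shape[0]
    seen = np.zeros(N, dtype=bool)
    comps = []
    for s in range(N):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(W[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(np.array(sorted(comp)))
    return comps


def _fix_sign(v: np.ndarray) -> np.ndarray:
    nz = np.nonzero(np.abs(v) > 1e-12)[0]
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def graph_responses(graph: AffinityGraph, M: int,
                    scheme: str = "normalized") -> tuple[np.ndarray, np.ndarray]:
    """Leading nontrivial graph-eigenproblem responses.

    ``scheme="normalized"`` solves W v = lambda D v and returns the M
    eigenvectors of largest eigenvalue after excluding the trivial constant
    eigenvector (lambda = 1) of each connected component; eigenvectors are
    D-orthonormal.  ``scheme="laplacian"`` takes the smallest nontrivial
    eigenvectors of the unnormalized Laplacian L = D - W instead; these
    differ on graphs with very uneven degrees -- a vertex tied to the rest
    only by near-zero weights dominates the smallest Laplacian eigenvector,
    whereas under degree normalization its mode moves to the middle of the
    spectrum.  Sign convention: first nonzero entry positive.  On a
    disconnected graph responses are assembled per component.
    """
    if scheme not in ("normalized", "laplacian"):
        raise ValueError(f"unknown response scheme {scheme!r}")
    W, D = graph.W, graph.D
    N = W.shape[0]
    if len(_connected_components(W)) > 1:
        import warnings

        warnings.warn("affinity graph is disconnected; component-contrast "
                      "responses are retained", stacklevel=2)
    if scheme == "normalized":
        mask = D > 0
        if mask.sum() < 2:
            raise ValueError("graph has no nontrivial spectral responses")
        Wm = W[np.ix_(mask, mask)]
        Dm = D[mask]
        s = 1.0 / np.sqrt(Dm)  # symmetric reduction D^-1/2 W D^-1/2
        S = Wm * s[:, None] * s[None, :]
        # deflate only the global constant (eigenvector D^1/2 * 1 at
        # lambda = 1); per-component constants beyond it are genuine
        # component-contrast responses
        q = np.sqrt(Dm)
        q = q / np.linalg.norm(q)
        S = (S + S.T) / 2 - np.outer(q, q)
        lam, U = scipy.linalg.eigh(S)
        order = np.argsort(lam)[::-1]
        n_avail = min(M, len(lam) - 1)
        V = np.zeros((N, n_avail))
        lams = np.empty(n_avail)
        for m in range(n_avail):
            u = U[:, order[m]]
            v = s * u
            v = v / np.sqrt(np.sum(Dm * v**2))
            full = np.zeros(N)
            full[mask] = v
            V[:, m] = _fix_sign(full)
            lams[m] = lam[order[m]]
        return V, lams
    # unnormalized Laplacian: shift the constant eigenvector's eigenvalue
    # past the spectrum so the smallest remaining modes are the responses
    L = np.diag(D) - W
    shift = 2.0 * D.max() + 1.0
    ones = np.full(N, 1.0 / np.sqrt(N))
    Ls = (L + L.T) / 2 + shift * np.outer(ones, ones)
    lam, U = scipy.linalg.eigh(Ls)
    n_avail = min(M, N - 1)
    V = np.empty((N, n_avail))
    for m in range(n_avail):
        V[:, m] = _fix_sign(U[:, m])
    return V, lam[:n_avail]


def _coordinate_descent_enet(X: np.ndarray, v: np.ndarray, alpha: float, beta: float,
                             tol: float = 1e-8, max_passes: int = 10_000) -> np.ndarray:
    """Cyclic coordinate descent for 0.5-free elastic-net objective
    sum_i (a^T x_i - v_i)^2 + alpha*||a||_2^2 + beta*||a||_1."""
    N, L = X.shape
    a = np.zeros(L)
    col_sq = (X**2).sum(axis=0)
    r = v.copy()  # residual v - X a
    for _ in range(max_passes):
        max_delta = 0.0
        for j in range(L):
            if col_sq[j] == 0 and alpha == 0:
                continue
            aj = a[j]
            rho = X[:, j] @ r + col_sq[j] * aj
            denom = col_sq[j] + alpha
            z = rho
            # soft-threshold at beta/2 (gradient of sum of squares is 2*)
            thr = beta / 2.0
            if z > thr:
                new = (z - thr) / denom
            elif z < -thr:
                new = (z + thr) / denom
            else:
                new = 0.0
            if new != aj:
                r -= X[:, j] * (new - aj)
                a[j] = new
                max_delta = max(max_delta, abs(new - aj))
        if max_delta < tol:
            break
    return a


def fit_linear(X: np.ndarray, responses: np.ndarray, alpha: float = 0.0,
               beta: float = 0.0) -> EmbeddingModel:
    """Penalized least-squares regression of graph responses on the samples.

    Per embedding dimension solves
    min_a sum_i (a^T x_i - v_i)^2 + alpha ||a||_2^2 + beta ||a||_1.
    With beta = 0 the ridge normal equations are solved in closed form;
    beta > 0 uses cyclic coordinate descent, shrinking some coefficients to
    exactly zero.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("penalties must be nonnegative")
    X = np.asarray(X, dtype=float)
    V = np.atleast_2d(np.asarray(responses, dtype=float))
    if V.shape[0] != X.shape[0]:
        V = V.T
    if V.shape[0] != X.shape[0]:
        raise ValueError("responses must have one row per sample")
    N, L = X.shape
    if beta == 0.0:
        G = X.T @ X + alpha * np.eye(L)
        if alpha == 0.0 and L > N:
            # minimum-norm interpolating solution
            A = X.T @ np.linalg.solve(X @ X.T + 1e-12 * np.eye(N), V)
        else:
            A = np.linalg.solve(G, X.T @ V)
    else:
        A = np.column_stack([
            _coordinate_descent_enet(X, V[:, m], alpha, beta) for m in range(V.shape[1])
        ])
    return EmbeddingModel(responses=V, coefficients=A, mode="linear",
                          alpha=alpha, beta=beta)


def gaussian_kernel(A: np.ndarray, B: np.ndarray, eta: float) -> np.ndarray:
    """Gaussian kernel matrix K_ij = exp(-||a_i - b_j||^2 / (2 eta^2))."""
    if eta <= 0:
        raise ValueError("kernel width must be positive")
    d2 = cdist(A, B, "sqeuclidean")
    return np.exp(-d2 / (2.0 * eta**2))


def median_kernel_width(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance (the median heuristic)."""
    d = pdist(np.asarray(X, dtype=float))
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def fit_kernel(X: np.ndarray, responses: np.ndarray, alpha: float = 0.0,
               eta: float | None = None) -> EmbeddingModel:
    """Kernel (Gaussian) spectral regression: solve (K + alpha I) a = v.

    ``eta`` defaults to the median pairwise distance of the training set.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    X = np.asarray(X, dtype=float)
    V = np.atleast_2d(np.asarray(responses, dtype=float))
    if V.shape[0] != X.shape[0]:
        V = V.T
    if V.shape[0] != X.shape[0]:
        raise ValueError("responses must have one row per sample")
    if eta is None:
        eta = median_kernel_width(X)
    K = gaussian_kernel(X, X, eta)
    N = K.shape[0]
    reg = alpha
    if reg == 0.0 and np.linalg.cond(K) > 1e12:
        reg = 1e-10  # near-singular kernel (e.g. eta -> inf collapses K to rank 1)
    A = np.linalg.solve(K + reg * np.eye(N), V)
    return EmbeddingModel(responses=V, coefficients=A, mode="kernel",
                          alpha=alpha, kernel_width=float(eta), training_points=X.copy())


def embed(model: EmbeddingModel, X_new: np.ndarray) -> np.ndarray:
    """Map new samples through the fitted regression: Z = X a (linear) or
    Z = K(X_new, training) a (kernel)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if model.mode == "linear":
        if X_new.shape[1] != model.coefficients.shape[0]:
            raise ValueError("dimension mismatch with training data")
        return X_new @ model.coefficients
    if model.training_points is None or model.kernel_width is None:
        raise ValueError("kernel model is missing training state")
    if X_new.shape[1] != model.training_points.shape[1]:
        raise ValueError("dimension mismatch with training data")
    K = gaussian_kernel(X_new, model.training_points, model.kernel_width)
    return K @ model.coefficients
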