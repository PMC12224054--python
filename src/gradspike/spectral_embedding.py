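"""Graph-Laplacian spectral embedding of waveform features.

An affinity graph is built over spikes — either a Gaussian kernel
``s_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`` or a union-symmetrized
binary kNN graph — the (unnormalized) Laplacian ``L = D - S`` is formed,
and the eigenvectors of its d smallest nonzero eigenvalues give the
embedding coordinates.  This is the spectral arm of the sorting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform


class DisconnectedGraphError(ValueError):
    """The affinity graph has more than one connected component."""


@dataclass
class AffinityGraph:
    """Symmetric nonnegative pairwise weights over the spike set."""

    S: np.ndarray
    kind: str  # "gaussian" | "knn"
    sigma: Optional[float] = None
    k_nn: Optional[int] = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if not np.allclose(S, S.T):
            raise ValueError("S must be symmetric")
        if np.any(S < 0):
            raise ValueError("S must be nonnegative")
        self.S = S

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class SpectralConfig:
    """Hyperparameters of the spectral embedding.

    ``n_components`` defaults to 2 — more dimensions were not observed to
    change the clustering outcome.  ``k_nn=None`` means the automatic
    setting ``max(n // 10, 2)``, raised to the smallest value at which the
    kNN graph is connected (well-separated clusters disconnect at small k;
    an explicit ``k_nn`` never bridges silently).  ``sigma=None`` means the median pairwise
    distance.
    """

    n_components: int = 2
    affinity: str = "knn"  # "knn" | "gaussian"
    k_nn: Optional[int] = None
    sigma: Optional[float] = None
    laplacian: str = "unnormalized"  # "unnormalized" | "symmetric"

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.affinity not in ("knn", "gaussian"):
            raise ValueError("affinity must be 'knn' or 'gaussian'")
        if self.laplacian not in ("unnormalized", "symmetric"):
            raise ValueError("laplacian must be 'unnormalized' or 'symmetric'")


def auto_knn(n: int) -> int:
    """Automatic neighbor count: n/10, floored, never below 2."""
    return max(n // 10, 2)


def gaussian_affinity(X: np.ndarray, sigma: Optional[float] = None) -> AffinityGraph:
    """Dense Gaussian-kernel affinity; ``sigma=None`` uses the median distance."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    d = pdist(X, "sqeuclidean")
    if sigma is None:
        sigma = float(np.median(np.sqrt(d)))
        if sigma == 0:
            sigma = 1.0  # all points coincide; any scale gives S = 1
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    S = squareform(np.exp(-d / (2.0 * sigma ** 2)))
    np.fill_diagonal(S, 1.0)
    return AffinityGraph(S, "gaussian", sigma=sigma)


def knn_affinity(X: np.ndarray, k_nn: Optional[int] = None) -> AffinityGraph:
    """Binary kNN graph, symmetrized by union; raises if disconnected."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_nn is None:
        k_nn = auto_knn(n)
    if not 1 <= k_nn < n:
        raise ValueError(f"k_nn must be in [1, {n - 1}]")
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    # ties broken by lower index via stable argsort
    nbrs = np.argsort(D, axis=1, kind="stable")[:, :k_nn]
    S = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k_nn)
    S[rows, nbrs.ravel()] = 1.0
    S = np.maximum(S, S.T)  # union symmetrization
    n_comp, _ = connected_components(S, directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(
            f"kNN graph with k={k_nn} has {n_comp} components; increase k_nn"
        )
    return AffinityGraph(S, "knn", k_nn=k_nn)


def graph_laplacian(g: AffinityGraph, flavor: str = "unnormalized") -> np.ndarray:
    """``L = D - S`` (or the symmetric-normalized variant).

    ``D`` is diagonal with the row sums of ``S``.  Unnormalized rows sum to
    zero, so the constant vector is always a 0-eigenvector.
    """
    S = g.S.copy()
    np.fill_diagonal(S, 0.0)  # self-affinity does not affect L = D - S
    deg = S.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError(
            f"isolated vertices: {np.flatnonzero(deg == 0).tolist()}"
        )
    if flavor == "unnormalized":
        return np.diag(deg) - S
    if flavor == "symmetric":
        inv_sqrt = 1.0 / np.sqrt(deg)
        return np.eye(g.n) - inv_sqrt[:, None] * S * inv_sqrt[None, :]
    raise ValueError(f"unknown Laplacian flavor {flavor!r}")


def spectral_embed(X: np.ndarray, cfg: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Embed rows of ``X`` into ``cfg.n_components`` Laplacian eigenvectors.

    The trivial constant eigenvector is dropped; columns are ordered by
    ascending eigenvalue and sign-fixed so each column's largest-|value|
    entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if cfg.n_components >= n:
        raise ValueError("n_components must be < n_points")
    if cfg.affinity == "knn":
        if cfg.k_nn is None:
            g = knn_affinity(X, _min_connected_knn(X, auto_knn(n)))
        else:
            g = knn_affinity(X, cfg.k_nn)
    else:
        g = gaussian_affinity(X, cfg.sigma)
    L = graph_laplacian(g, cfg.laplacian)
    # dense symmetric solve: deterministic and exact enough at pipeline sizes
    vals, vecs = eigh(L, subset_by_index=(0, cfg.n_components))
    Y = vecs[:, 1:cfg.n_components + 1]  # drop the constant 0-eigenvector
    return _fix_signs(Y)


def _min_connected_knn(X: np.ndarray, k_start: int) -> int:
    """Smallest neighbor count >= k_start whose union-kNN graph connects.

    Connectivity is monotone in k, so bisection is exact.  Overshooting
    (e.g. by doubling) would coarsen the graph and blur fine cluster
    structure, which matters because well-separated spike clusters
    routinely disconnect at the n/10 starting point.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")

    def connected(k: int) -> bool:
        S = np.zeros((n, n))
        rows = np.repeat(np.arange(n), k)
        S[rows, order[:, :k].ravel()] = 1.0
        S = np.maximum(S, S.T)
        return connected_components(S, directed=False)[0] == 1

    lo, hi = k_start, n - 1
    if connected(lo):
        return lo
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(mid):
            hi = mid
        else:
            lo = mid + 1
    return lo


def _fix_signs(Y: np.ndarray) -> np.ndarray:
    """Make the largest-|value| entry of each column positive."""
    idx = np.argmax(np.abs(Y), axis=0)
    signs = np.sign(Y[idx, np.arange(Y.shape[1])])
    signs[signs == 0] = 1.0
    return Y * signs
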