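"""UMAP built from first principles: fuzzy simplicial graph + cross-entropy SGD.

The high-dimensional neighborhood structure is encoded as a fuzzy graph.
For every point the distance to its nearest neighbor ``rho_i`` and a local
scale ``sigma_i`` (solving ``sum_j exp(-max(0, d_ij - rho_i)/sigma_i) =
log2(k)`` by bisection) calibrate membership strengths
``w_ij = exp(-max(0, d_ij - rho_i)/sigma_i)``, which are (optionally
row-normalized and) symmetrized via ``p_ij = w_ij + w_ji - w_ij w_ji``.  The low-dimensional
layout minimizes the fuzzy cross-entropy between ``P`` and the similarities
``q_ij = (1 + ||y_i - y_j||^2)^-1`` by gradient descent with the gradient

    grad_i C = 4 sum_j (p_ij - q_ij) (y_i - y_j) (1 + ||y_i - y_j||^2)^-1

The layout stage offers two optimizers: the deterministic full-pairs
gradient exactly as written above, and a stochastic per-edge scheme (the
default) that samples positive edges in proportion to p_ij and applies the
exact attractive/repulsive cross-entropy terms with uniform negative
sampling.  This is the UMAP arm of the sorting pipeline; exact kNN is used
throughout (no approximate index), so the graph stage is fully
deterministic and only the layout depends on the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class FuzzyGraph:
    """Symmetrized fuzzy membership matrix with its calibration byproducts."""

    P: np.ndarray
    rho: np.ndarray
    sigma: np.ndarray
    k: int
    unattainable: np.ndarray  # points where the log2(k) target had no root

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if not np.allclose(P, P.T):
            raise ValueError("P must be symmetric")
        if P.min() < 0 or P.max() > 1 + 1e-9:
            raise ValueError("P entries must lie in [0, 1]")
        self.P = P


@dataclass(frozen=True)
class UmapConfig:
    """Tunables of the embedding.

    ``n_neighbors`` defaults to 150, the midpoint of the 100-200 range that
    works well for spike data; it is clamped to n//2 (with a warning) on
    small inputs.  The default optimizer is stochastic (``negative_samples``
    = 5): per epoch each positive edge fires with probability p_ij/max(p),
    pulling its endpoints together with the exact attractive cross-entropy
    gradient, and each fired edge pushes ``negative_samples`` uniformly
    drawn points away with the exact (regularized) repulsive gradient.
    ``negative_samples=0`` selects the deterministic full-pairs gradient
    4 sum_j (p-q)(y_i-y_j) q instead; it is cheap and exactly
    permutation-equivariant, but its repulsion vanishes for coincident
    points, so clusters that the 2-D initialization overlaps cannot
    untangle — use it on small or well-spread problems only.  ``min_dist``
    is accepted for interface compatibility but has no effect: the
    low-dimensional kernel is exactly (1 + r^2)^-1.

    ``normalize_weights=True`` row-normalizes the directed memberships
    before symmetrization; off by default because it shrinks every p_ij to
    ~1/k, starving the attraction term and blurring cluster structure.
    """

    n_neighbors: int = 150
    n_components: int = 2
    learning_rate: float = 1.0
    n_epochs: int = 500
    seed: int = 0
    init: str = "pca"  # "pca" | "random"
    negative_samples: int = 5  # 0 = deterministic full-pairs gradient
    normalize_weights: bool = False
    min_dist: float = 0.1  # accepted, inert (kernel is fixed)

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.init not in ("pca", "random"):
            raise ValueError("init must be 'pca' or 'random'")


# ---------------------------------------------------------------------------
# fuzzy graph construction
# ---------------------------------------------------------------------------

def knn_distances(X: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Exact Euclidean k-nearest neighbors (self excluded, ties by lower index).

    Returns ``(neighbors, distances)``, both ``(n, k)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}]")
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    nbrs = np.argsort(D, axis=1, kind="stable")[:, :k]
    dists = np.take_along_axis(D, nbrs, axis=1)
    return nbrs, dists


def local_scales(distances: np.ndarray, k: int,
                 tol: float = 1e-5, max_iter: int = 100,
                 bracket: Tuple[float, float] = (1e-6, 1e3),
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point (rho_i, sigma_i) calibrating the membership kernel.

    ``rho_i`` is the nearest-neighbor distance.  ``sigma_i`` solves
    ``sum_j exp(-max(0, d_ij - rho_i) / sigma_i) = log2(k)`` by bisection;
    when no root exists in the bracket (e.g. every neighbor sits exactly at
    ``rho_i``, making the sum constant) the point is flagged and sigma falls
    back to the closest achievable end — the bracket midpoint in the
    constant-sum case.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    target = np.log2(k)
    rho = distances.min(axis=1)
    sigma = np.empty(n)
    unattainable = np.zeros(n, dtype=bool)
    lo0, hi0 = bracket
    for i in range(n):
        excess = np.maximum(0.0, distances[i] - rho[i])

        def f(s: float) -> float:
            return float(np.exp(-excess / s).sum())

        f_lo, f_hi = f(lo0), f(hi0)
        if abs(f_hi - f_lo) < _EPS:  # constant sum: no sigma can move it
            unattainable[i] = True
            sigma[i] = 0.5 * (lo0 + hi0)
            continue
        if f_lo >= target:  # already above target at the smallest scale
            unattainable[i] = True
            sigma[i] = lo0
            continue
        if f_hi <= target:  # cannot reach the target even at the largest scale
            unattainable[i] = True
            sigma[i] = hi0
            continue
        lo, hi = lo0, hi0
        mid = 0.5 * (lo + hi)
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            val = f(mid)
            if abs(val - target) < tol:
                break
            if val > target:
                hi = mid
            else:
                lo = mid
        sigma[i] = mid
    return rho, sigma, unattainable


def membership_strengths(distances: np.ndarray, neighbors: np.ndarray,
                         rho: np.ndarray, sigma: np.ndarray,
                         normalize: bool = True) -> np.ndarray:
    """Directed membership matrix ``w_ij = exp(-max(0, d_ij - rho_i)/sigma_i)``.

    Returned dense ``(n, n)`` with zeros outside each point's neighbor list;
    rows are normalized to sum to 1 unless ``normalize=False``.
    """
    n = distances.shape[0]
    w_vals = np.exp(-np.maximum(0.0, distances - rho[:, None]) / sigma[:, None])
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), neighbors.shape[1])
    W[rows, neighbors.ravel()] = w_vals.ravel()
    if normalize:
        W /= W.sum(axis=1, keepdims=True)
    return W


def symmetrize(W: np.ndarray) -> np.ndarray:
    """Fuzzy-union symmetrization ``p_ij = w_ij + w_ji - w_ij w_ji``."""
    P = W + W.T - W * W.T
    np.fill_diagonal(P, 0.0)
    return P


def fuzzy_graph(X: np.ndarray, k: int, normalize: bool = True) -> FuzzyGraph:
    """Build the symmetrized fuzzy graph over the rows of ``X``."""
    nbrs, dists = knn_distances(X, k)
    rho, sigma, flags = local_scales(dists, k)
    W = membership_strengths(dists, nbrs, rho, sigma, normalize=normalize)
    return FuzzyGraph(symmetrize(W), rho, sigma, k, flags)


# ---------------------------------------------------------------------------
# low-dimensional similarity, loss, optimization
# ---------------------------------------------------------------------------

def low_dim_similarity(y_i: np.ndarray, y_j: np.ndarray) -> float:
    """Student-style kernel ``q = (1 + ||y_i - y_j||^2)^-1``; 1 iff equal."""
    d2 = float(np.sum((np.asarray(y_i, float) - np.asarray(y_j, float)) ** 2))
    return 1.0 / (1.0 + d2)


def _pairwise_q(Y: np.ndarray) -> np.ndarray:
    d2 = cdist(Y, Y, "sqeuclidean")
    return 1.0 / (1.0 + d2)


def cross_entropy(P: np.ndarray, Y: np.ndarray) -> float:
    """Fuzzy cross-entropy between ``P`` and the layout similarities.

    ``C = sum_{i != j} p log(p/q) + (1-p) log((1-p)/(1-q))`` with q clamped
    away from {0, 1}; zero iff Q matches P on every pair.
    """
    Q = np.clip(_pairwise_q(Y), _EPS, 1.0 - _EPS)
    P = np.asarray(P, dtype=float)
    mask = ~np.eye(P.shape[0], dtype=bool)
    p, q = P[mask], Q[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        attract = np.where(p > 0, p * (np.log(np.maximum(p, _EPS)) - np.log(q)), 0.0)
        repel = np.where(p < 1,
                         (1 - p) * (np.log(np.maximum(1 - p, _EPS)) - np.log(1 - q)),
                         0.0)
    return float(np.sum(attract + repel))


def _full_gradient(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact all-pairs gradient 4 sum_j (p - q) (y_i - y_j) q."""
    Q = _pairwise_q(Y)
    M = (P - Q) * Q
    np.fill_diagonal(M, 0.0)
    # sum_j M_ij (y_i - y_j) = (row_sum M)_i y_i - (M @ Y)_i
    return 4.0 * (M.sum(axis=1)[:, None] * Y - M @ Y)


def _init_embedding(X: np.ndarray, cfg: UmapConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.init == "random":
        return 10.0 * rng.standard_normal((X.shape[0], cfg.n_components))
    Xc = X - X.mean(axis=0)
    # deterministic PCA via SVD with sign convention
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:cfg.n_components].T
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    Y = Xc @ (V * signs)
    # normalize the layout scale to match the random init (std 10): too
    # small an init puts all q near 1 and the repulsion term explodes
    spread = Y.std()
    if spread > 0:
        Y = Y / spread * 10.0
    return Y


def optimize_embedding(P: np.ndarray, cfg: UmapConfig,
                       X: Optional[np.ndarray] = None,
                       return_loss: bool = False,
                       initial_layout: Optional[np.ndarray] = None):
    """Gradient-descend the layout for ``cfg.n_epochs`` epochs.

    The learning rate decays linearly from ``cfg.learning_rate`` to 0.
    ``initial_layout`` overrides the configured initialization when given.
    Same seed and config give identical output.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    rng = np.random.default_rng(cfg.seed)
    if initial_layout is not None:
        Y = np.array(initial_layout, dtype=float)
    elif X is None:
        if cfg.init == "pca":
            raise ValueError("PCA init needs the feature matrix X")
        Y = _init_embedding(np.zeros((n, 1)), cfg, rng)
    else:
        Y = _init_embedding(np.asarray(X, dtype=float), cfg, rng)
    Y = np.ascontiguousarray(Y, dtype=float)

    m = cfg.negative_samples
    losses = []
    if m > 0:
        iu, ju = np.nonzero(np.triu(P, 1))
        pw = P[iu, ju]
        prob = pw / pw.max() if len(pw) else pw
    for t in range(cfg.n_epochs):
        eta = cfg.learning_rate * (1.0 - t / cfg.n_epochs)
        if m == 0:
            Y = Y - eta * _full_gradient(P, Y)
        else:
            Y = _sampled_epoch(Y, iu, ju, prob, m, eta, rng)
        if not np.all(np.isfinite(Y)):
            raise FloatingPointError(
                "embedding diverged (non-finite coordinates); "
                "try a smaller learning_rate"
            )
        if return_loss:
            losses.append(cross_entropy(P, Y))
    if return_loss:
        return Y, np.array(losses)
    return Y


_GRAD_CLIP = 4.0
_REP_EPS = 1e-3


def _sampled_epoch(Y: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                   prob: np.ndarray, m: int, eta: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One stochastic epoch over the positive edges.

    Each edge fires with probability proportional to its membership; a
    fired edge applies the exact attractive term of the cross-entropy
    gradient (coefficient 2q) to both endpoints and, per negative sample,
    the exact repulsive term 2q/(eps + r^2) to its head — the 1/r^2 growth
    at small distances is what separates clusters a 2-D init overlaps.
    Updates are clipped for stability, as is standard for this optimizer.
    """
    n = Y.shape[0]
    Y = Y.copy()
    sel = rng.random(len(iu)) < prob
    i, j = iu[sel], ju[sel]
    diff = Y[i] - Y[j]
    q = 1.0 / (1.0 + np.sum(diff ** 2, axis=1))
    coef = np.clip(2.0 * q, None, _GRAD_CLIP)
    upd = (eta * coef[:, None]) * diff
    np.subtract.at(Y, i, upd)
    np.add.at(Y, j, upd)
    for _ in range(m):
        jn = rng.integers(0, n, size=len(i))
        diff = Y[i] - Y[jn]
        r2 = np.sum(diff ** 2, axis=1)
        coef = np.clip(2.0 / ((_REP_EPS + r2) * (1.0 + r2)), None, _GRAD_CLIP)
        np.add.at(Y, i, (eta * coef[:, None]) * diff)
    return Y


def clamp_neighbors(k: int, n: int) -> int:
    """Clamp the neighbor count to n//2 on small inputs (with a warning)."""
    if n < 2 * k:
        clamped = max(2, n // 2)
        logger.warning("n_neighbors=%d too large for n=%d; clamped to %d",
                       k, n, clamped)
        return clamped
    return k


def umap_embed(X: np.ndarray, cfg: UmapConfig = UmapConfig()) -> np.ndarray:
    """Full pipeline: exact kNN, fuzzy graph, symmetrize, optimize layout."""
    X = np.asarray(X, dtype=float)
    k = clamp_neighbors(cfg.n_neighbors, X.shape[0])
    graph = fuzzy_graph(X, k, normalize=cfg.normalize_weights)
    return optimize_embedding(graph.P, cfg, X=X)
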