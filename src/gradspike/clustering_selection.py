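"""Agglomerative clustering, silhouette scoring and the joint model search.

The sorter couples three choices — the gradient order applied to the
waveforms, the embedding hyperparameter, and the number of clusters — and
picks the combination with the best mean silhouette on the embedded points.
With spectral embedding this is the GSA pipeline; with UMAP it is the GUA
pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .gradient import GradientConfig, nth_gradient
from .io_formats import WaveformSet
from .spectral_embedding import SpectralConfig, auto_knn, spectral_embed
from .umap_embedding import UmapConfig, clamp_neighbors, umap_embed

logger = logging.getLogger(__name__)

DEFAULT_ORDERS = range(0, 11)
DEFAULT_KS = range(2, 21)


@dataclass
class ClusterLabels:
    """Flat cluster assignment: integer labels in [0, k)."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if len(present) != self.k:
            raise ValueError("every cluster must be nonempty")


@dataclass
class SelectionResult:
    """Outcome of the silhouette grid search."""

    best_order: int
    best_k: int
    best_hyper: Optional[int]
    best_score: float
    grid: Dict[Tuple[int, int, Optional[int]], float] = field(default_factory=dict)
    failed_cells: list = field(default_factory=list)


@dataclass
class SortResult:
    """Labels plus everything needed to reproduce them."""

    labels: ClusterLabels
    selection: SelectionResult
    embedding: np.ndarray
    method_name: str  # "GSA-Spike" | "GUA-Spike"
    seed: int


def agglomerative_cluster(points: np.ndarray, k: int,
                          linkage: str = "ward") -> ClusterLabels:
    """Bottom-up hierarchical clustering cut at ``k`` flat clusters.

    Starting from singletons, the pair of clusters minimizing the linkage
    criterion (Ward by default; single/complete/average also supported,
    always with Euclidean distances) merges at each step until ``k``
    clusters remain.  Deterministic for distinct merge costs.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == n:
        return ClusterLabels(np.arange(n), n)
    Z = _scipy_linkage(points, method=linkage, metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel to 0..k-1 in order of first appearance, for determinism
    _, labels = np.unique(raw, return_inverse=True)
    remap = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return ClusterLabels(out, len(remap))


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette ``(b - a) / max(a, b)`` over all points.

    ``a(i)`` is the mean distance to the point's own cluster (self
    excluded), ``b(i)`` the smallest mean distance to any other cluster.
    Singleton clusters contribute 0.  Requires at least 2 clusters.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = points.shape[0]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if n < 3:
        raise ValueError("silhouette needs at least 3 points")
    D = squareform(pdist(points))
    scores = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(masks[c].sum()) for c in uniq}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            continue  # singleton convention: s = 0
        a = D[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != own)
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def default_hyper_grid(method: str, n: int, max_k: int = 2) -> list:
    """Neighbor-count sweep for the silhouette search (log-spaced, <=3 values).

    Small neighbor counts resolve fine cluster structure, large ones favor
    the global layout; silhouette picks the winner among them — the same
    selection principle that chooses the cluster count.
    """
    if method == "umap":
        return [v for v in (15, 50, 150) if 2 <= v < n] or [2]
    # spectral: two fixed values plus the auto (grow-until-connected)
    vals = [v for v in (15, 50) if 2 <= v < n]
    return vals + [None]


def _embed(features: np.ndarray, method: str, hyper: Optional[int],
           seed: int, umap_epochs: int = 500,
           max_k: int = 2) -> np.ndarray:
    if method == "spectral":
        return _spectral_subspace(features, hyper, max_k)
    if method == "umap":
        k = hyper if hyper is not None else 150
        cfg = UmapConfig(n_neighbors=k, seed=seed, n_epochs=umap_epochs)
        return umap_embed(features, cfg)
    raise ValueError(f"unknown method {method!r}")


def _spectral_subspace(features: np.ndarray, hyper: Optional[int],
                       max_k: int) -> np.ndarray:
    """Laplacian eigenvectors up to the eigengap, floored at 2 dimensions.

    All candidate cluster counts are scored in one common subspace whose
    dimension comes from the largest gap in the low eigenvalue spectrum —
    the classic spectral-clustering heuristic.  Slicing per candidate k
    instead lets a coarse cut hide fine structure in a low-dimensional
    slice and score a near-perfect silhouette; a fixed overlarge subspace
    instead drowns every cut in uninformative within-cluster eigenvectors.
    The 2-D floor keeps silhouettes comparable (1-D scores are
    systematically inflated); its price is that the spectral arm cannot
    prefer k=2 over splitting one of two clean blobs, an overcounting bias
    on very small unit counts that the UMAP arm does not share.
    """
    from scipy.linalg import eigh

    from .spectral_embedding import (
        _fix_signs, _min_connected_knn, auto_knn, graph_laplacian,
        knn_affinity,
    )

    n = features.shape[0]
    k_nn = hyper if hyper is not None else _min_connected_knn(
        features, auto_knn(n))
    g = knn_affinity(features, k_nn)
    L = graph_laplacian(g)
    d_max = min(max(max_k - 1, 2), n - 2)
    vals, vecs = eigh(L, subset_by_index=(0, d_max))
    E = _fix_signs(vecs[:, 1:])
    gaps = np.diff(vals[1:])
    d = int(np.argmax(gaps)) + 1 if len(gaps) else 1
    return E[:, :max(2, d)]


def select_model(ws: WaveformSet, method: str = "spectral",
                 orders: Iterable[int] = DEFAULT_ORDERS,
                 ks: Iterable[int] = DEFAULT_KS,
                 hyper_grid: Optional[Sequence[Optional[int]]] = None,
                 seed: int = 0,
                 linkage: str = "ward",
                 umap_epochs: int = 500,
                 min_cluster_size: Optional[int] = None) -> SelectionResult:
    """Joint silhouette grid search over (gradient order, k, hyperparameter).

    For each order the waveforms are differentiated, embedded once per
    hyperparameter value, clustered at every candidate ``k`` and scored by
    mean silhouette on the embedded points.  Selection then proceeds in
    three marginalized stages: the gradient order with the highest
    silhouette averaged over every (hyperparameter, k) cell — failed or
    degenerate cells counting 0 — then the cluster count with the highest
    average across hyperparameters at that order, then the argmax
    hyperparameter.  Averaging over the k scan is what identifies an
    informative order: an over-differentiated order collapses smooth units
    into one tight blob that scores spectacularly at the wrong k and poorly
    (or not at all) everywhere else, whereas an informative order scores
    well across the scan.  Ties break toward lower order, lower k, lower
    hyperparameter.
    Cells that fail (e.g. a disconnected kNN graph) are recorded and
    excluded rather than aborting the search, as are degenerate cuts
    containing a cluster smaller than ``min_cluster_size`` (default 2):
    a singleton cluster is no neuron, yet a single outlier split off into
    its own cluster inflates everyone else's silhouette toward 1 and would
    otherwise hijack the argmax.
    """
    orders = list(orders)
    ks = [k for k in ks if 2 <= k < ws.n_spikes]
    if not orders or not ks:
        raise ValueError("orders and ks must be nonempty (with 2 <= k < n)")
    if hyper_grid is None:
        hyper_grid = default_hyper_grid(method, ws.n_spikes, max(ks))
    if min_cluster_size is None:
        min_cluster_size = 2
    grid: Dict[Tuple[int, int, Optional[int]], float] = {}
    failed = []
    for order in orders:
        grads = nth_gradient(ws, GradientConfig(order=order))
        features = grads.waveforms
        for hyper in hyper_grid:
            try:
                emb = _embed(features, method, hyper, seed, umap_epochs,
                             max_k=max(ks))
            except Exception as exc:
                failed.append(((order, None, hyper), str(exc)))
                continue
            for k in ks:
                try:
                    cl = agglomerative_cluster(emb, k, linkage=linkage)
                    smallest = np.bincount(cl.labels).min()
                    if smallest < min_cluster_size:
                        failed.append(((order, k, hyper),
                                       f"degenerate cut: cluster of {smallest}"))
                        continue
                    score = silhouette(emb, cl.labels)
                except Exception as exc:
                    failed.append(((order, k, hyper), str(exc)))
                    continue
                grid[(order, k, hyper)] = score
    if not grid:
        raise RuntimeError("every grid cell failed; nothing to select")
    n_cells = len(hyper_grid) * len(ks)  # failed cells count 0 in the mean
    order_means = {
        o: sum(grid.get((o, k, h), 0.0) for h in hyper_grid for k in ks) / n_cells
        for o in orders
    }
    b_order = min(order_means, key=lambda o: (-order_means[o], o))
    k_means = {
        k: sum(grid.get((b_order, k, h), 0.0) for h in hyper_grid) / len(hyper_grid)
        for k in ks
    }
    b_k = min(k_means, key=lambda k: (-k_means[k], k))
    hyper_scores = {h: grid[(b_order, b_k, h)] for h in hyper_grid
                    if (b_order, b_k, h) in grid}
    if not hyper_scores:
        raise RuntimeError(
            f"no surviving cell at order {b_order}, k {b_k}; grid too sparse")
    b_hyper = min(hyper_scores,
                  key=lambda h: (-hyper_scores[h], -1 if h is None else h))
    b_score = hyper_scores[b_hyper]
    logger.info("selected order=%d k=%d hyper=%s silhouette=%.4f",
                b_order, b_k, b_hyper, b_score)
    return SelectionResult(b_order, b_k, b_hyper, b_score, grid, failed)


def sort_spikes(ws: WaveformSet, method: str = "spectral",
                orders: Iterable[int] = DEFAULT_ORDERS,
                ks: Iterable[int] = DEFAULT_KS,
                hyper_grid: Optional[Sequence[Optional[int]]] = None,
                seed: int = 0,
                linkage: str = "ward",
                umap_epochs: int = 500,
                min_cluster_size: Optional[int] = None) -> SortResult:
    """Run the full sorter: grid search, then final embed + cluster.

    ``method='spectral'`` is the GSA pipeline, ``method='umap'`` the GUA
    pipeline.  Identical input, config and seed give identical output.
    """
    if ws.n_spikes < 3:
        raise ValueError("need at least 3 spikes to sort")
    sel = select_model(ws, method, orders, ks, hyper_grid, seed,
                       linkage, umap_epochs, min_cluster_size)
    grads = nth_gradient(ws, GradientConfig(order=sel.best_order))
    emb = _embed(grads.waveforms, method, sel.best_hyper, seed, umap_epochs,
                 max_k=max(list(ks)))
    labels = agglomerative_cluster(emb, sel.best_k, linkage=linkage)
    name = "GSA-Spike" if method == "spectral" else "GUA-Spike"
    return SortResult(labels, sel, emb, name, seed)
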