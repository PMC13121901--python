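"""Embeddings and clusterings with distinct inductive biases.

Three clusterers feed the consensus stage: a self-organizing-map
metaclusterer (conservative, needs a population-count estimate), a
kNN-graph modularity community detector (density-area oriented), and a
density-peak assigner that follows the density gradient to the nearest
peak (rare-population oriented). Clustering always operates on the
full-dimensional transformed event vectors; the 2-D embeddings (t-SNE
and UMAP here) are computed for visualization and for the
cross-embedding island-consistency diagnostic only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import AgglomerativeClustering
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError, TooFewEventsError
from .io_model import EventMatrix, Scale

KNOWN_EMBEDDINGS = ("tsne", "umap")
UNAVAILABLE_EMBEDDINGS = ("trimap", "pacmap")  # recognized ids without a backend here


@dataclass
class EmbeddingSet:
    layouts: dict[str, np.ndarray]
    seed: int
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        n = {v.shape[0] for v in self.layouts.values()}
        if len(n) > 1:
            raise ParameterError("embeddings cover different event counts")
        for name, v in self.layouts.items():
            if v.ndim != 2 or v.shape[1] != 2 or not np.isfinite(v).all():
                raise ParameterError(f"embedding {name} is not a finite n x 2 layout")


@dataclass
class ClusteringResult:
    method: str
    labels: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        uniq = np.unique(self.labels)
        if uniq.size and not np.array_equal(uniq, np.arange(uniq.size)):
            # renumber to contiguous ids from 0
            remap = {c: i for i, c in enumerate(uniq)}
            self.labels = np.array([remap[c] for c in self.labels])

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def embed_suite(
    m: EventMatrix,
    algorithms: tuple[str, ...] = KNOWN_EMBEDDINGS,
    seed: int = 0,
    params: dict[str, dict] | None = None,
) -> EmbeddingSet:
    """One 2-D layout per requested algorithm, at library defaults.

    Supported ids: ``tsne`` (scikit-learn) and ``umap`` (umap-learn).
    Deterministic given ``seed``.
    """
    if m.scale is not Scale.transformed:
        raise ParameterError("embed_suite expects transformed-scale events")
    if m.n_events < 50:
        raise TooFewEventsError("embedding needs at least 50 events")
    params = params or {}
    layouts: dict[str, np.ndarray] = {}
    records: dict[str, dict] = {}
    for alg in algorithms:
        kw = dict(params.get(alg, {}))
        if alg == "tsne":
            model = TSNE(n_components=2, random_state=seed, init="pca", **kw)
            layouts[alg] = np.asarray(model.fit_transform(m.values), dtype=np.float64)
            records[alg] = {"random_state": seed, **kw}
        elif alg == "umap":
            import umap  # deferred: numba compilation is slow to import

            model = umap.UMAP(n_components=2, random_state=seed, **kw)
            layouts[alg] = np.asarray(model.fit_transform(m.values), dtype=np.float64)
            records[alg] = {"random_state": seed, **kw}
        elif alg in UNAVAILABLE_EMBEDDINGS:
            raise ParameterError(
                f"embedding backend for {alg!r} is not available in this build")
        else:
            raise ParameterError(f"unknown embedding algorithm {alg!r}")
    return EmbeddingSet(layouts=layouts, seed=seed, params=records)


def _som_train(
    x: np.ndarray, rows: int, cols: int, seed: int, epochs: int = 10
) -> np.ndarray:
    """Batch-train a rows x cols SOM; returns the (rows*cols, d) codebook."""
    rng = np.random.default_rng(seed)
    n, d = x.shape
    codebook = x[rng.choice(n, size=rows * cols, replace=n < rows * cols)].copy()
    gy, gx = np.mgrid[0:rows, 0:cols]
    grid = np.column_stack([gy.ravel(), gx.ravel()]).astype(np.float64)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
    sigma0, sigma1 = max(rows, cols) / 2.0, 0.5
    for e in range(epochs):
        sigma = sigma0 * (sigma1 / sigma0) ** (e / max(epochs - 1, 1))
        d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1) \
            if n * rows * cols * d <= 2e8 else None
        if d2 is None:  # chunked BMU search for large inputs
            bmu = np.empty(n, dtype=np.int64)
            step = max(1, int(2e8 // (rows * cols * d)))
            for s in range(0, n, step):
                blk = ((x[s:s + step, None, :] - codebook[None, :, :]) ** 2).sum(-1)
                bmu[s:s + step] = blk.argmin(1)
        else:
            bmu = d2.argmin(1)
        h = np.exp(-grid_d2 / (2 * sigma**2))  # (nodes, nodes) neighborhood
        w = h[:, bmu]  # (nodes, n)
        denom = w.sum(1, keepdims=True)
        nz = denom[:, 0] > 0
        codebook[nz] = (w[nz] @ x) / denom[nz]
    return codebook


def som_cluster(
    m: EventMatrix,
    grid: tuple[int, int] = (10, 10),
    k_meta: int = 7,
    seed: int = 0,
) -> ClusteringResult:
    """SOM metaclustering: train a map, agglomerate its codebook into
    ``k_meta`` metaclusters (Ward linkage), events inherit their
    best-matching node's metacluster."""
    rows, cols = grid
    if k_meta < 1:
        raise ParameterError("k_meta must be >= 1")
    if k_meta > rows * cols:
        raise ParameterError("k_meta cannot exceed the number of SOM nodes")
    x = np.asarray(m.values, dtype=np.float64)
    codebook = _som_train(x, rows, cols, seed)
    agg = AgglomerativeClustering(n_clusters=k_meta, linkage="ward")
    node_meta = agg.fit_predict(codebook)
    nn = NearestNeighbors(n_neighbors=1).fit(codebook)
    bmu = nn.kneighbors(x, return_distance=False)[:, 0]
    return ClusteringResult(
        method="som_meta", labels=node_meta[bmu],
        params={"grid": grid, "k_meta": k_meta}, seed=seed)


def graph_community_cluster(
    m: EventMatrix, k_neighbors: int = 30, seed: int = 0
) -> ClusteringResult:
    """kNN graph (Euclidean), shared-neighbour Jaccard edge weights,
    modularity-maximizing Leiden community detection."""
    import igraph
    import leidenalg

    n = m.n_events
    if k_neighbors >= n:
        raise ParameterError("k_neighbors must be < n_events")
    if n < 3:
        raise TooFewEventsError("graph clustering needs at least 3 events")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(m.values)
    idx = nn.kneighbors(m.values, return_distance=False)[:, 1:]
    src = np.repeat(np.arange(n), k_neighbors)
    dst = idx.ravel()
    a, b = np.minimum(src, dst), np.maximum(src, dst)
    edges = np.unique(np.column_stack([a, b]), axis=0)
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    weights = np.asarray(g.similarity_jaccard(pairs=[tuple(e) for e in edges]))
    weights = np.maximum(weights, 1e-12)
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition,
        weights=list(weights), seed=seed, n_iterations=2)
    return ClusteringResult(
        method="graph_community", labels=np.asarray(part.membership),
        params={"k_neighbors": k_neighbors}, seed=seed)


def density_peak_cluster(m: EventMatrix, k_neighbors: int = 30) -> ClusteringResult:
    """Follow the density gradient to the nearest density peak.

    Per-event density is the inverse mean distance to the k nearest
    neighbours; each event links to its nearest higher-density neighbour
    within its neighbour list, events with none are peaks, and clusters
    are the trees rooted at peaks. Deterministic; density ties are
    broken by event index (lower index counts as denser).
    """
    n = m.n_events
    if k_neighbors >= n:
        raise ParameterError("k_neighbors must be < n_events")
    if n < 2:
        raise TooFewEventsError("density-peak clustering needs >= 2 events")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(m.values)
    dist, idx = nn.kneighbors(m.values)
    dist, idx = dist[:, 1:], idx[:, 1:]
    mean_d = dist.mean(axis=1)
    density = 1.0 / np.maximum(mean_d, 1e-300)

    order = np.arange(n)
    # "denser" = higher density, ties to lower index
    nb_denser = (density[idx] > density[:, None]) | (
        (density[idx] == density[:, None]) & (idx < order[:, None]))
    has_parent = nb_denser.any(axis=1)
    first = nb_denser.argmax(axis=1)  # neighbours are distance-ordered
    parent = np.where(has_parent, idx[order, first], order)

    root = parent.copy()
    for _ in range(64):  # path halving; converges in O(log depth)
        nxt = root[root]
        if np.array_equal(nxt, root):
            break
        root = nxt
    return ClusteringResult(
        method="density_peak",
        labels=np.unique(root, return_inverse=True)[1],
        params={"k_neighbors": k_neighbors})


def detect_islands(
    layout: np.ndarray,
    bandwidth: float = 1.0,
    density_quantile: float = 0.25,
    grid_size: int = 256,
) -> np.ndarray:
    """Segment a 2-D layout into density islands.

    A gridded KDE (histogram smoothed with a Gaussian of ``bandwidth``
    layout units) scores every event; events at or above the
    ``density_quantile`` of event densities are foreground, and islands
    are connected components of the foreground grid cells. Background
    events get label -1. ``density_quantile`` 0 is the degenerate
    no-background convention: every event belongs to one island.
    """
    layout = np.asarray(layout, dtype=np.float64)
    if layout.ndim != 2 or layout.shape[1] != 2:
        raise ParameterError("layout must be n x 2")
    n = layout.shape[0]
    if density_quantile <= 0:
        return np.zeros(n, dtype=np.int64)
    lo = layout.min(axis=0) - 3 * bandwidth
    hi = layout.max(axis=0) + 3 * bandwidth
    span = np.maximum(hi - lo, 1e-12)
    cell = span / grid_size
    ij = np.clip(((layout - lo) / cell).astype(np.int64), 0, grid_size - 1)
    hist = np.zeros((grid_size, grid_size))
    np.add.at(hist, (ij[:, 0], ij[:, 1]), 1.0)
    sigma_cells = bandwidth / cell
    dens = ndimage.gaussian_filter(hist, sigma=sigma_cells)
    ev_dens = dens[ij[:, 0], ij[:, 1]]
    thr = np.quantile(ev_dens, density_quantile)
    fg_cells = dens >= thr
    comp, _ = ndimage.label(fg_cells)
    labels = comp[ij[:, 0], ij[:, 1]].astype(np.int64) - 1  # 0 -> background
    labels[ev_dens < thr] = -1
    # renumber islands that actually contain events
    uniq = np.unique(labels[labels >= 0])
    remap = {c: i for i, c in enumerate(uniq)}
    out = np.array([remap.get(c, -1) for c in labels], dtype=np.int64)
    return out
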