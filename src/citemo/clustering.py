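"""kNN-graph Leiden clustering and a shared UMAP embedding.

Cells are clustered per modality on their low-dimensional representation
using community detection on a Jaccard-weighted k-nearest-neighbour graph
(the PhenoGraph construction).  A single 2-D UMAP embedding is computed
from the multimodal representation and reused to display the RNA, ADT and
multimodal cluster labels side by side, so subpopulations can be compared
across modalities on the same coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse
from sklearn.neighbors import NearestNeighbors

from .io_screening import ValidationError
from .reduction import LowDimRep


@dataclass
class ClusterAssignment:
    """Per-cell integer labels, relabelled 0..C-1 by decreasing cluster size."""

    labels: np.ndarray
    modality: str
    cell_barcodes: list[str]
    params: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValidationError("labels must form a contiguous 0..C-1 set")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class Embedding:
    """Cells x 2 coordinates from a single shared UMAP run."""

    coords: np.ndarray
    source: str
    seed: int
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("embedding must be cells x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite embedding coordinates")


def build_knn_graph(
    rep: LowDimRep,
    k_neighbors: int = 30,
    metric: str = "euclidean",
    jaccard: bool = True,
) -> ig.Graph:
    """Undirected kNN graph over cells, Jaccard-weighted by neighbor-set overlap.

    Each cell is linked to its ``k_neighbors`` nearest neighbours in the
    representation space; edge weights are the Jaccard similarity of the two
    endpoint neighbour sets (``jaccard=False`` keeps plain unit weights).
    """
    n = rep.n_cells
    if k_neighbors >= n:
        raise ValidationError(f"k_neighbors={k_neighbors} must be < {n} cells")
    pts = rep.components.T  # cells x k
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1, metric=metric).fit(pts)
    _, idx = nn.kneighbors(pts)
    # self may not be first among exact duplicates; drop it explicitly
    neigh = np.empty((n, k_neighbors), dtype=np.int64)
    for i in range(n):
        row = idx[i][idx[i] != i][:k_neighbors]
        if len(row) < k_neighbors:  # all-duplicate corner case
            row = np.concatenate([row, idx[i][: k_neighbors - len(row)]])
        neigh[i] = row

    rows = np.repeat(np.arange(n), k_neighbors)
    adj = scipy.sparse.csr_matrix(
        (np.ones(n * k_neighbors), (rows, neigh.ravel())), shape=(n, n)
    )
    union_edges = ((adj + adj.T) > 0).tocoo()
    mask = union_edges.row < union_edges.col
    src, dst = union_edges.row[mask], union_edges.col[mask]
    if jaccard:
        shared = np.asarray(adj[src].multiply(adj[dst]).sum(axis=1)).ravel()
        weights = shared / (2 * k_neighbors - shared)
    else:
        weights = np.ones(len(src))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = weights.tolist()
    return g


def leiden_cluster(
    graph: ig.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    modality: str = "multimodal",
    cell_barcodes: list[str] | None = None,
) -> ClusterAssignment:
    """Leiden community detection; deterministic for a fixed seed.

    Labels are renumbered by decreasing cluster size so the presentation is
    stable across runs.
    """
    if graph.vcount() == 0:
        raise ValidationError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.asarray(part.membership)
    labels = relabel_by_size(raw)
    return ClusterAssignment(
        labels,
        modality,
        cell_barcodes or [str(i) for i in range(len(labels))],
        {"k_neighbors": None, "resolution": resolution, "seed": seed},
    )


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Bijective renumbering with 0 the largest cluster; ties by old label."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels])


def merge_clusters(assignment: ClusterAssignment, pairs: list[tuple[int, int]]) -> ClusterAssignment:
    """Apply explicit manual merge directives (never automatic)."""
    labels = assignment.labels.copy()
    for a, b in pairs:
        keep, drop = min(a, b), max(a, b)
        labels[labels == drop] = keep
    # restore contiguity, then size ordering
    labels = relabel_by_size(labels)
    return ClusterAssignment(
        labels, assignment.modality, assignment.cell_barcodes,
        {**assignment.params, "merged": [list(p) for p in pairs]},
    )


def umap_embed(
    rep: LowDimRep,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.5,
) -> Embedding:
    """2-D UMAP of the multimodal representation, shared by all modality views."""
    if rep.k < 2:
        raise ValidationError("UMAP needs a representation with >= 2 components")
    if rep.n_cells < n_neighbors:
        raise ValidationError(
            f"n_neighbors={n_neighbors} exceeds the {rep.n_cells} cells"
        )
    import umap  # deferred: numba compilation is slow to import

    emb = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    ).fit_transform(rep.components.T)
    return Embedding(emb, rep.modality, seed, rep.cell_barcodes)
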