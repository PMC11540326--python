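"""Nearest-neighbor genomic relationship graphs.

Individuals are vertices; an edge joins an individual to each of its K
nearest neighbors in Euclidean distance over allele dosages. Directed
neighbor lists are symmetrized by union, matching standard KNN-graph
practice and keeping the normalized propagation operator symmetric.

The module also owns the train/validation/test vertex split, the
cross-partition edge zeroing used to prevent information leaking between
partitions during transductive training, and the random sub-graph
partitioning that the sub-sampling ensemble trains on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .snp_data import MarkerMatrix

__all__ = [
    "NeighborGraph",
    "DataSplit",
    "Subgraph",
    "SubgraphBatch",
    "knn_graph",
    "augment_adjacency",
    "normalize_adjacency",
    "split_vertices",
    "zero_cross_partition_edges",
    "sample_subgraphs",
    "induced_subgraph",
    "export_edge_list",
    "degree_summary",
    "export_graphml",
]


@dataclass
class NeighborGraph:
    """Sparse undirected graph with self-loop augmentation.

    ``adjacency`` is the binary symmetric matrix A (zero diagonal);
    ``augmented`` is A + I; ``degrees`` the row sums of the augmented
    matrix. ``distances`` stores the Euclidean distance for each edge of A
    (the weight matrix of the construction); it is kept for reporting but
    plays no role in propagation, which is binary.
    """

    adjacency: sp.csr_matrix
    K: int = 0
    distances: sp.csr_matrix | None = None
    vertex_ids: list[str] | None = None
    augmented: sp.csr_matrix = field(init=False, repr=False)
    degrees: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency, dtype=float)
        A.setdiag(0.0)
        A.eliminate_zeros()
        if (abs(A - A.T) > 0).nnz:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A
        self.augmented = (A + sp.identity(A.shape[0], format="csr")).tocsr()
        self.degrees = np.asarray(self.augmented.sum(axis=1)).ravel()

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Undirected edge count (each pair counted once)."""
        return self.adjacency.nnz // 2


@dataclass
class DataSplit:
    """Disjoint train/validation/test vertex index sets."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("train/val/test sets must be pairwise disjoint")

    def labels(self, n: int) -> np.ndarray:
        """Per-vertex partition label: 0 train, 1 val, 2 test, -1 unassigned."""
        lab = np.full(n, -1, dtype=int)
        lab[self.train_idx] = 0
        lab[self.val_idx] = 1
        lab[self.test_idx] = 2
        return lab


@dataclass
class Subgraph:
    vertex_indices: np.ndarray  # indices into the parent graph
    graph: NeighborGraph  # induced structure over those vertices


@dataclass
class SubgraphBatch:
    subgraphs: list[Subgraph]

    @property
    def n_subgraphs(self) -> int:
        return len(self.subgraphs)


def _pairwise_sq_distances(X: np.ndarray) -> np.ndarray:
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def knn_graph(
    m: MarkerMatrix | np.ndarray,
    K: int = 3,
    standardize: bool = False,
    vertex_ids: list[str] | None = None,
) -> NeighborGraph:
    """Build the K-nearest-neighbor graph on Euclidean marker distance.

    Each vertex lists its K nearest other vertices (self excluded); the
    directed lists are symmetrized by union. Distance ties are broken by
    lower vertex index, so construction is deterministic. With
    ``standardize`` each marker is scaled to zero mean / unit variance
    before distances are taken (off by default: raw dosages).
    """
    if isinstance(m, MarkerMatrix):
        if m.has_missing:
            raise ValueError("impute missing dosages before graph construction")
        X = np.asarray(m.dosages, dtype=float)
        vertex_ids = vertex_ids or list(m.individual_ids)
    else:
        X = np.asarray(m, dtype=float)
    n = X.shape[0]
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must be in [1, n-1] = [1, {n - 1}], got {K}")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    d2 = _pairwise_sq_distances(X)
    np.fill_diagonal(d2, np.inf)  # self never a neighbor candidate
    # lexicographic (distance, index) order => ties to the lower index
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
    nbr = order[:, :K]

    rows = np.repeat(np.arange(n), K)
    cols = nbr.ravel()
    A = sp.coo_matrix((np.ones(n * K), (rows, cols)), shape=(n, n)).tocsr()
    A = ((A + A.T) > 0).astype(float)  # union symmetrization

    D = A.copy()
    np.fill_diagonal(d2, 0.0)
    D.data = np.sqrt(d2[A.nonzero()])
    return NeighborGraph(adjacency=A, K=K, distances=D, vertex_ids=vertex_ids)


def augment_adjacency(g: NeighborGraph) -> NeighborGraph:
    """Return a graph with Ã = A + I and degrees materialized.

    NeighborGraph computes these on construction; the operation exists so
    augmentation is an explicit, testable step of the pipeline.
    """
    return NeighborGraph(
        adjacency=g.adjacency.copy(), K=g.K, distances=g.distances, vertex_ids=g.vertex_ids
    )


def normalize_adjacency(g: NeighborGraph) -> sp.csr_matrix:
    """Symmetric degree normalization D̃^(-1/2) Ã D̃^(-1/2) of the augmented matrix."""
    d = g.degrees
    assert np.all(d >= 1), "augmented graph cannot have a zero-degree vertex"
    inv_sqrt = 1.0 / np.sqrt(d)
    Dinv = sp.diags(inv_sqrt)
    return (Dinv @ g.augmented @ Dinv).tocsr()


def split_vertices(
    n: int,
    test_n: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> DataSplit:
    """Random disjoint train/validation/test split.

    ``test_n`` vertices are drawn for the test set first; the remainder is
    split ``train_fraction`` : (1 - ``train_fraction``) into train and
    validation. Index arrays are returned sorted; the assignment is
    reproducible under ``seed``.
    """
    if not 0 < test_n < n:
        raise ValueError(f"test_n must be in (0, n), got {test_n} for n={n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = perm[:test_n]
    rest = perm[test_n:]
    n_train = int(round(train_fraction * rest.size))
    return DataSplit(
        train_idx=np.sort(rest[:n_train]),
        val_idx=np.sort(rest[n_train:]),
        test_idx=np.sort(test),
        seed=seed,
    )


def zero_cross_partition_edges(g: NeighborGraph, s: DataSplit) -> NeighborGraph:
    """Remove every edge whose endpoints lie in different partitions.

    Train<->val, train<->test and val<->test edges are zeroed in both
    directions; within-partition edges are untouched. Augmentation and
    degrees are recomputed, so the result is block-diagonal over the
    partitions (isolated vertices keep their self-loop). Idempotent.
    """
    lab = s.labels(g.n_vertices)
    A = g.adjacency.tocoo()
    li, lj = lab[A.row], lab[A.col]
    keep = ~((li >= 0) & (lj >= 0) & (li != lj))
    A2 = sp.coo_matrix(
        (A.data[keep], (A.row[keep], A.col[keep])), shape=A.shape
    ).tocsr()
    D2 = None
    if g.distances is not None:
        D = g.distances.tocoo()
        li, lj = lab[D.row], lab[D.col]
        keepd = ~((li >= 0) & (lj >= 0) & (li != lj))
        D2 = sp.coo_matrix(
            (D.data[keepd], (D.row[keepd], D.col[keepd])), shape=D.shape
        ).tocsr()
    return NeighborGraph(adjacency=A2, K=g.K, distances=D2, vertex_ids=g.vertex_ids)


def induced_subgraph(g: NeighborGraph, vertices: np.ndarray) -> NeighborGraph:
    """Sub-graph over ``vertices`` keeping only edges internal to the set."""
    idx = np.asarray(vertices, dtype=int)
    A = g.adjacency[idx][:, idx].tocsr()
    D = g.distances[idx][:, idx].tocsr() if g.distances is not None else None
    ids = [g.vertex_ids[i] for i in idx] if g.vertex_ids is not None else None
    return NeighborGraph(adjacency=A, K=g.K, distances=D, vertex_ids=ids)


def sample_subgraphs(
    g: NeighborGraph,
    s: DataSplit,
    n_subgraphs: int = 10,
    policy: str = "disjoint_partition",
    seed: int = 0,
) -> SubgraphBatch:
    """Randomly split the training vertices into sub-graphs.

    ``disjoint_partition`` (default, the ensemble's sampling scheme)
    shuffles the training vertices under ``seed`` and slices them into
    ``n_subgraphs`` near-equal disjoint units whose union is the whole
    training set. ``with_replacement`` draws units of the same size
    independently, so units may overlap. Each unit's induced sub-graph
    keeps only edges with both endpoints inside the unit.
    """
    if policy not in ("disjoint_partition", "with_replacement"):
        raise ValueError(f"unknown sampling policy {policy!r}")
    train = np.asarray(s.train_idx, dtype=int)
    if not 1 <= n_subgraphs <= train.size:
        raise ValueError(
            f"n_subgraphs must be in [1, |train|={train.size}], got {n_subgraphs}"
        )
    rng = np.random.default_rng(seed)
    subgraphs: list[Subgraph] = []
    if policy == "disjoint_partition":
        units = np.array_split(rng.permutation(train), n_subgraphs)
    else:
        size = int(np.ceil(train.size / n_subgraphs))
        units = [rng.choice(train, size=size, replace=False) for _ in range(n_subgraphs)]
    for unit in units:
        unit = np.sort(unit)
        subgraphs.append(Subgraph(vertex_indices=unit, graph=induced_subgraph(g, unit)))
    return SubgraphBatch(subgraphs=subgraphs)


def export_edge_list(g: NeighborGraph, path) -> None:
    """Write a TSV edge list (source_id, target_id, distance), one row per undirected edge."""
    ids = g.vertex_ids or [str(i) for i in range(g.n_vertices)]
    A = sp.triu(g.adjacency, k=1).tocoo()
    dist = g.distances
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\tdistance\n")
        for i, j in zip(A.row, A.col):
            d = dist[i, j] if dist is not None else ""
            fh.write(f"{ids[i]}\t{ids[j]}\t{d}\n")


def degree_summary(g: NeighborGraph) -> dict:
    """Vertex/edge/degree report for a graph (degrees of A, without self-loops)."""
    deg = np.asarray(g.adjacency.sum(axis=1)).ravel()
    return {
        "n_vertices": int(g.n_vertices),
        "n_edges": int(g.n_edges),
        "degree_min": int(deg.min()) if deg.size else 0,
        "degree_max": int(deg.max()) if deg.size else 0,
        "degree_mean": float(deg.mean()) if deg.size else 0.0,
    }


def export_graphml(g: NeighborGraph, path) -> None:
    """GraphML export (via networkx) for external visualization."""
    import networkx as nx

    ids = g.vertex_ids or [str(i) for i in range(g.n_vertices)]
    G = nx.Graph()
    G.add_nodes_from(ids)
    A = sp.triu(g.adjacency, k=1).tocoo()
    for i, j in zip(A.row, A.col):
        attrs = {}
        if g.distances is not None:
            attrs["distance"] = float(g.distances[i, j])
        G.add_edge(ids[i], ids[j], **attrs)
    nx.write_graphml(G, path)
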