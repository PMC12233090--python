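"""Hybrid-graph construction: MNN edges from (R)PCA projections plus filtering.

The graph over all nR + nQ cells unions three edge sets:

* inter-dataset edges A^RQ — mutual K-nearest-neighbor (MNN) pairs found in
  reciprocal-PCA space, where each dataset is projected into the other's
  principal-component space;
* intra-dataset edges A^RR and A^QQ — MNN pairs within each dataset in its
  own PCA space.

Because intra-dataset edges are far more reliable than cross-modality ones,
the inter-dataset set is then filtered: reference cells are scored by local
label purity, query cells receive an estimated type from their scored
reference neighbors, that estimate is smoothed by a multi-hop plurality vote
over the query's own graph, and every inter-dataset edge whose endpoints
disagree in type is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_preprocess import StandardizedMatrix

UNKNOWN = "Unknown"

#: edge provenance tags
INTER = "inter"
INTRA_REF = "intra_ref"
INTRA_QUERY = "intra_query"


@dataclass
class BipartiteAdjacency:
    """Reference <-> query connection set (MNN pairs)."""

    pairs: np.ndarray  # (n_pairs, 2) int array of (ref_index, query_index)
    n_ref: int
    n_query: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if len(self.pairs):
            self.pairs = np.unique(self.pairs, axis=0)
            if self.pairs[:, 0].min() < 0 or self.pairs[:, 0].max() >= self.n_ref:
                raise ValueError("reference index out of range")
            if self.pairs[:, 1].min() < 0 or self.pairs[:, 1].max() >= self.n_query:
                raise ValueError("query index out of range")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.pairs}


@dataclass
class IntraAdjacency:
    """Undirected within-dataset connection set; no self-loops."""

    pairs: np.ndarray  # (n_edges, 2) with i < j
    n_cells: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if len(self.pairs):
            lo = self.pairs.min(axis=1)
            hi = self.pairs.max(axis=1)
            if np.any(lo == hi):
                raise ValueError("self-loops are not allowed")
            self.pairs = np.unique(np.column_stack([lo, hi]), axis=0)
            if lo.min() < 0 or hi.max() >= self.n_cells:
                raise ValueError("cell index out of range")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.pairs}

    def to_sparse(self) -> sp.csr_matrix:
        """Symmetric boolean adjacency matrix."""
        if not len(self.pairs):
            return sp.csr_matrix((self.n_cells, self.n_cells), dtype=bool)
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        data = np.ones(2 * len(i), dtype=bool)
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_cells, self.n_cells))

    def neighbor_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_cells)]
        for i, j in self.pairs:
            out[int(i)].append(int(j))
            out[int(j)].append(int(i))
        return out


@dataclass
class ReferenceScores:
    """Per-reference-cell label-purity score u_r in [0, 1]."""

    u: np.ndarray


@dataclass
class HybridGraph:
    """Union graph over nR + nQ nodes (reference block first)."""

    n_ref: int
    n_query: int
    edges: np.ndarray        # (n_edges, 2) global node indices, i < j
    provenance: np.ndarray   # parallel array of tags

    @property
    def n_nodes(self) -> int:
        return self.n_ref + self.n_query

    def __len__(self) -> int:
        return len(self.edges)

    def to_sparse(self) -> sp.csr_matrix:
        n = self.n_nodes
        if not len(self.edges):
            return sp.csr_matrix((n, n), dtype=float)
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(i), dtype=float)
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        A = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        A.data[:] = 1.0  # collapse any duplicate provenance into a simple edge
        return A

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tprovenance\n")
            for (a, b), tag in zip(self.edges, self.provenance):
                fh.write(f"{a}\t{b}\t{tag}\n")


def _as_cells_matrix(X: StandardizedMatrix | np.ndarray) -> np.ndarray:
    """Genes x cells input -> cells x genes sample matrix for sklearn."""
    if isinstance(X, StandardizedMatrix):
        X = X.matrix
    return np.asarray(X, dtype=float).T


def pca_project(
    X: StandardizedMatrix | np.ndarray, n_components: int, seed: int = 0
) -> np.ndarray:
    """Project cells into their own PCA space; returns (n_cells, n_components)."""
    S = _as_cells_matrix(X)
    n_components = _check_components(n_components, S.shape)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    return pca.fit_transform(S)


def rpca_project(
    Xr: StandardizedMatrix | np.ndarray,
    Xq: StandardizedMatrix | np.ndarray,
    n_components: int,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Reciprocal PCA: each dataset projected into the other's PC space.

    Returns two coordinate systems for cross-dataset neighbor search:
    ``((ref_in_ref_space, query_in_ref_space), (ref_in_query_space,
    query_in_query_space))``.
    """
    R = _as_cells_matrix(Xr)
    Q = _as_cells_matrix(Xq)
    if R.shape[1] != Q.shape[1]:
        raise ValueError("reference and query must share the same gene axis")
    n_components = _check_components(n_components, R.shape)
    n_components = _check_components(n_components, Q.shape)
    pca_r = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    ref_in_ref = pca_r.fit_transform(R)
    query_in_ref = pca_r.transform(Q)
    pca_q = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    query_in_query = pca_q.fit_transform(Q)
    ref_in_query = pca_q.transform(R)
    return (ref_in_ref, query_in_ref), (ref_in_query, query_in_query)


def _check_components(n_components: int, shape: tuple[int, int]) -> int:
    limit = min(shape)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > limit:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)={limit}"
        )
    return n_components


def _knn_indices(source: np.ndarray, targets: np.ndarray, K: int) -> np.ndarray:
    """For each source row, indices of its K nearest target rows (Euclidean, exact)."""
    nn = NearestNeighbors(n_neighbors=K, algorithm="brute", metric="euclidean")
    nn.fit(targets)
    return nn.kneighbors(source, return_distance=False)


def mnn_pairs(emb_a: np.ndarray, emb_b: np.ndarray, K: int) -> BipartiteAdjacency:
    """Mutual K-nearest-neighbor pairs between two point sets in a common space.

    Pair ``(i, j)`` is included iff ``j`` is among the K nearest b-points of
    ``a_i`` and ``i`` is among the K nearest a-points of ``b_j``.
    """
    emb_a = np.asarray(emb_a, dtype=float)
    emb_b = np.asarray(emb_b, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    Ka = min(K, len(emb_b))
    Kb = min(K, len(emb_a))
    if Ka < K or Kb < K:
        warnings.warn(f"K={K} clipped to opposing set size")
    ab = _knn_indices(emb_a, emb_b, Ka)  # for each a: K nearest b
    ba = _knn_indices(emb_b, emb_a, Kb)  # for each b: K nearest a
    in_ba = [set(row) for row in ba]
    pairs = [
        (i, int(j))
        for i in range(len(emb_a))
        for j in ab[i]
        if i in in_ba[int(j)]
    ]
    pairs_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return BipartiteAdjacency(pairs=pairs_arr, n_ref=len(emb_a), n_query=len(emb_b))


def intra_mnn(emb: np.ndarray, K: int) -> IntraAdjacency:
    """Undirected mutual-KNN graph within one point set, self excluded."""
    emb = np.asarray(emb, dtype=float)
    n = len(emb)
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 2:
        warnings.warn("fewer than 2 cells: empty intra-dataset adjacency")
        return IntraAdjacency(pairs=np.empty((0, 2), dtype=int), n_cells=n)
    Keff = min(K, n - 1)
    if Keff < K:
        warnings.warn(f"K={K} clipped to {Keff} (only {n} cells)")
    idx = _knn_indices(emb, emb, Keff + 1)  # self is usually its own nearest neighbor
    # drop self from each distance-ordered list (ties may hide it), keep Keff
    neigh = [set([int(j) for j in row if j != i][:Keff]) for i, row in enumerate(idx)]
    pairs = [
        (i, j)
        for i in range(n)
        for j in neigh[i]
        if j > i and i in neigh[j]
    ]
    return IntraAdjacency(pairs=np.asarray(pairs, dtype=int).reshape(-1, 2), n_cells=n)


def build_inter_graph(
    Xr: StandardizedMatrix,
    Xq: StandardizedMatrix,
    *,
    n_components: int = 30,
    k_inter: int = 5,
    seed: int = 0,
    combine: str = "union",
) -> BipartiteAdjacency:
    """RPCA projection followed by MNN in both projected spaces.

    The pair sets found in the reference-PC and query-PC coordinate systems
    are combined by union (default) or intersection.
    """
    (r_in_r, q_in_r), (r_in_q, q_in_q) = rpca_project(Xr, Xq, n_components, seed=seed)
    in_ref_space = mnn_pairs(r_in_r, q_in_r, k_inter)
    in_query_space = mnn_pairs(r_in_q, q_in_q, k_inter)
    a, b = in_ref_space.as_set(), in_query_space.as_set()
    if combine == "union":
        merged = a | b
    elif combine == "intersection":
        merged = a & b
    else:
        raise ValueError(f"combine must be 'union' or 'intersection', got {combine!r}")
    pairs = np.asarray(sorted(merged), dtype=int).reshape(-1, 2)
    return BipartiteAdjacency(pairs=pairs, n_ref=Xr.n_cells, n_query=Xq.n_cells)


def build_intra_graph(
    X: StandardizedMatrix, *, n_components: int = 30, k_intra: int = 10, seed: int = 0
) -> IntraAdjacency:
    """PCA then mutual-KNN within one dataset."""
    n_components = min(n_components, min(X.n_cells, X.n_genes))
    emb = pca_project(X, n_components, seed=seed)
    return intra_mnn(emb, k_intra)


def score_reference_cells(arr: IntraAdjacency, labels: Sequence[str]) -> ReferenceScores:
    """Label purity of each reference cell's neighborhood in A^RR.

    u_r = fraction of r's neighbors sharing r's label, 0 for isolated cells.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != arr.n_cells:
        raise ValueError("labels must cover all reference cells")
    u = np.zeros(arr.n_cells, dtype=float)
    neigh = arr.neighbor_lists()
    for r in range(arr.n_cells):
        if neigh[r]:
            same = sum(1 for i in neigh[r] if labels[i] == labels[r])
            u[r] = same / len(neigh[r])
    return ReferenceScores(u=u)


def type_order_of(labels: Sequence[str]) -> list[str]:
    """Deterministic (sorted) ordering of the reference type set T_R."""
    return sorted(set(np.asarray(labels, dtype=object)))


def estimate_query_types(
    arq: BipartiteAdjacency,
    labels: Sequence[str],
    u: ReferenceScores,
    type_order: Optional[list[str]] = None,
) -> np.ndarray:
    """Estimated type per query cell from scored reference neighbors.

    Each query cell's per-type score is the sum of u over its reference
    neighbors of that type; the argmax wins (ties broken by the sorted type
    ordering), and cells with zero total score — including isolated cells —
    are "Unknown".
    """
    labels = np.asarray(labels, dtype=object)
    types = type_order if type_order is not None else type_order_of(labels)
    t_index = {t: k for k, t in enumerate(types)}
    scores = np.zeros((arq.n_query, len(types)), dtype=float)
    for i, j in arq.pairs:
        scores[j, t_index[labels[i]]] += u.u[i]
    out = np.empty(arq.n_query, dtype=object)
    best = scores.argmax(axis=1)  # argmax takes smallest index on ties
    maxval = scores.max(axis=1) if len(types) else np.zeros(arq.n_query)
    for q in range(arq.n_query):
        out[q] = types[best[q]] if maxval[q] > 0 else UNKNOWN
    return out


def refine_query_types(
    aqq: IntraAdjacency,
    kq: Sequence[str],
    hops: int = 4,
    type_order: Optional[list[str]] = None,
) -> np.ndarray:
    """Refine estimated query types by a plurality vote over <=hops-neighborhoods.

    The neighborhood of q is every query cell reachable within ``hops`` edges
    of A^QQ, excluding q itself.  "Unknown" estimates vote as their own
    candidate: a query region whose initial estimates are mostly Unknown is
    the signature of a cell type absent from the reference, and propagating
    that status protects novel clusters from being merged into a reference
    type through spurious cross-dataset connections.  Ties favor real types
    (then the sorted type ordering); with no neighborhood at all (isolated
    cell or hops=0) the original estimate is kept.
    """
    kq = np.asarray(kq, dtype=object)
    if len(kq) != aqq.n_cells:
        raise ValueError("estimated types must cover all query cells")
    types = type_order if type_order is not None else sorted(set(kq) - {UNKNOWN})
    candidates = list(types) + [UNKNOWN]  # Unknown last: ties keep a real type
    t_index = {t: k for k, t in enumerate(candidates)}
    n = aqq.n_cells
    out = kq.copy()
    if hops <= 0 or n == 0 or len(aqq) == 0:
        return out
    A = aqq.to_sparse()
    reach = A.copy().astype(bool)
    frontier = A.astype(bool)
    for _ in range(hops - 1):
        frontier = (frontier @ A).astype(bool)
        reach = (reach + frontier).astype(bool)
    reach = sp.lil_matrix(reach)
    reach.setdiag(False)
    reach = reach.tocsr()
    vote_idx = np.array([t_index[t] for t in kq], dtype=int)
    for q in range(n):
        neigh = reach.indices[reach.indptr[q]: reach.indptr[q + 1]]
        if len(neigh) == 0:
            continue
        counts = np.zeros(len(candidates), dtype=int)
        for j in neigh:
            counts[vote_idx[j]] += 1
        out[q] = candidates[int(counts.argmax())]  # ties -> smallest index
    return out


def filter_inter_connections(
    arq: BipartiteAdjacency,
    ref_labels: Sequence[str],
    kq_prime: Sequence[str],
) -> BipartiteAdjacency:
    """Drop inter-dataset pairs whose endpoint types disagree (A^RQ -> A^RQ').

    A pair (i, j) survives iff the reference label k_R(i) equals the refined
    query estimate k_Q'(j); pairs with an "Unknown" query endpoint are
    removed.
    """
    ref_labels = np.asarray(ref_labels, dtype=object)
    kq_prime = np.asarray(kq_prime, dtype=object)
    keep = [
        (i, j)
        for i, j in arq.pairs
        if kq_prime[j] != UNKNOWN and ref_labels[i] == kq_prime[j]
    ]
    if len(arq) and not keep:
        warnings.warn(
            "all inter-dataset connections were filtered out; "
            "training proceeds without the hard regularization term"
        )
    return BipartiteAdjacency(
        pairs=np.asarray(keep, dtype=int).reshape(-1, 2),
        n_ref=arq.n_ref,
        n_query=arq.n_query,
    )


def assemble_hybrid_graph(
    arq_f: BipartiteAdjacency, arr: IntraAdjacency, aqq: IntraAdjacency
) -> HybridGraph:
    """Union the filtered inter edges and both intra edge sets over nR+nQ nodes.

    Query node indices are offset by nR; every edge carries a provenance tag.
    """
    n_ref = arr.n_cells
    n_query = aqq.n_cells
    if arq_f.n_ref != n_ref or arq_f.n_query != n_query:
        raise ValueError("inconsistent index spaces between edge sets")
    edges = []
    tags = []
    for i, j in arq_f.pairs:
        edges.append((i, n_ref + j))
        tags.append(INTER)
    for i, j in arr.pairs:
        edges.append((i, j))
        tags.append(INTRA_REF)
    for i, j in aqq.pairs:
        edges.append((n_ref + i, n_ref + j))
        tags.append(INTRA_QUERY)
    return HybridGraph(
        n_ref=n_ref,
        n_query=n_query,
        edges=np.asarray(edges, dtype=int).reshape(-1, 2),
        provenance=np.asarray(tags, dtype=object),
    )


def build_and_filter(
    Xr: StandardizedMatrix,
    Xq: StandardizedMatrix,
    ref_labels: Sequence[str],
    *,
    n_components: int = 30,
    k_inter: int = 5,
    k_intra: int = 10,
    hops: int = 4,
    seed: int = 0,
) -> tuple[HybridGraph, BipartiteAdjacency, BipartiteAdjacency, IntraAdjacency, IntraAdjacency]:
    """Full graph stage: build A^RQ, A^RR, A^QQ, filter, assemble A^H.

    Returns ``(hybrid, arq_raw, arq_filtered, arr, aqq)``.
    """
    arq = build_inter_graph(Xr, Xq, n_components=n_components, k_inter=k_inter, seed=seed)
    arr = build_intra_graph(Xr, n_components=n_components, k_intra=k_intra, seed=seed)
    aqq = build_intra_graph(Xq, n_components=n_components, k_intra=k_intra, seed=seed)
    types = type_order_of(ref_labels)
    u = score_reference_cells(arr, ref_labels)
    kq = estimate_query_types(arq, ref_labels, u, type_order=types)
    kq_prime = refine_query_types(aqq, kq, hops=hops, type_order=types)
    arq_f = filter_inter_connections(arq, ref_labels, kq_prime)
    hybrid = assemble_hybrid_graph(arq_f, arr, aqq)
    return hybrid, arq, arq_f, arr, aqq
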