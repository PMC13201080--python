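"""Exact and approximate k-nearest-neighbor search over embeddings.

The exact backend is a self-contained brute-force search (the oracle);
the approximate backend wraps NNDescent. Both exclude a query's own row
and the opposite orientation of the same read, break ties by smaller row
index, and emit the same :class:`~overlapnn.graph.NeighborTable` schema.

Cosine distance is the default metric: it ignores vector magnitude, which
makes neighbor search robust to reads of very different lengths.
"""

from __future__ import annotations

import numpy as np

from .dimred import Embeddings
from .graph import NeighborTable, OrientedRead

__all__ = [
    "cosine_distance",
    "exact_knn",
    "ann_knn",
    "recall_at_k",
    "AnnBackendUnavailable",
]

METRICS = ("cosine", "euclidean")


class AnnBackendUnavailable(RuntimeError):
    """The NNDescent backend cannot be imported; use exact_knn instead."""


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - <u, v> / (||u|| ||v||); zero-norm inputs get the maximal
    distance 1."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 1.0
    return float(1.0 - (u @ v) / (nu * nv))


def _normalize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    return x / safe[:, None], zero


def _partner_row(row_ids: list[OrientedRead]) -> np.ndarray:
    """For each row, the row index of the same read's other orientation
    (-1 when absent)."""
    lookup: dict[OrientedRead, int] = {rid: i for i, rid in enumerate(row_ids)}
    out = np.full(len(row_ids), -1, dtype=np.int64)
    for i, rid in enumerate(row_ids):
        out[i] = lookup.get(rid.partner(), -1)
    return out


def exact_knn(
    embeddings: Embeddings,
    k: int,
    metric: str = "cosine",
    block: int = 2048,
) -> NeighborTable:
    """Brute-force true k-nearest neighbors under cosine or Euclidean
    distance.

    Self and own-opposite-orientation rows are ineligible; ties are broken
    by smaller row index. If fewer than k eligible vertices exist, all are
    returned and the queries flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    x = embeddings.matrix
    n = x.shape[0]
    row_ids = embeddings.row_ids
    partner = _partner_row(row_ids)
    if metric == "cosine":
        xn, zero = _normalize_rows(x)
    else:
        sq = np.einsum("ij,ij->i", x, x)
    flagged: set[int] = set()
    k_eff = min(k, max(0, n - 2))
    if k_eff < k:
        flagged.update(rid.read_index for rid in row_ids)
    lists: list[list[tuple[OrientedRead, float]]] = []
    for start in range(0, n, block):
        stop = min(start + block, n)
        if metric == "cosine":
            dist = 1.0 - xn[start:stop] @ xn.T
            if zero.any():
                dist[:, zero] = 1.0
                dist[zero[start:stop], :] = 1.0
            np.clip(dist, 0.0, 2.0, out=dist)
        else:
            dist = sq[start:stop, None] + sq[None, :] - 2.0 * (x[start:stop] @ x.T)
            np.maximum(dist, 0.0, out=dist)
            np.sqrt(dist, out=dist)
        for local, row in enumerate(range(start, stop)):
            d = dist[local]
            d[row] = np.inf
            if partner[row] >= 0:
                d[partner[row]] = np.inf
            order = np.argsort(d, kind="stable")[:k_eff]
            lists.append([(row_ids[j], float(d[j])) for j in order])
        if metric == "cosine" and zero[start:stop].any():
            for local, row in enumerate(range(start, stop)):
                if zero[row]:
                    flagged.add(row_ids[row].read_index)
    return NeighborTable(
        k=k,
        queries=list(row_ids),
        neighbor_lists=lists,
        read_names=embeddings.read_names,
        flagged=flagged,
    )


def ann_knn(
    embeddings: Embeddings,
    k: int,
    n_trees: int = 600,
    seed: int = 0,
    metric: str = "cosine",
) -> NeighborTable:
    """Approximate k-NN via NNDescent, with the exact table's schema and
    exclusion rules.

    Neighbors are over-fetched (k + 2) so that dropping the self row and
    the own-opposite-orientation row still leaves k candidates. Reported
    distances are recomputed directly from the embeddings, so they agree
    with :func:`cosine_distance` exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    try:
        from pynndescent import NNDescent
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise AnnBackendUnavailable(
            "pynndescent is not installed; use exact_knn as the backend instead"
        ) from exc
    x = embeddings.matrix
    n = x.shape[0]
    row_ids = embeddings.row_ids
    partner = _partner_row(row_ids)
    n_fetch = min(k + 2, n)
    index = NNDescent(
        x,
        metric=metric,
        n_neighbors=n_fetch,
        n_trees=n_trees,
        random_state=seed,
    )
    inds, _ = index.neighbor_graph
    if metric == "cosine":
        xn, zero = _normalize_rows(x)
    else:
        sq = np.einsum("ij,ij->i", x, x)
    lists: list[list[tuple[OrientedRead, float]]] = []
    flagged: set[int] = set()
    for row in range(n):
        cand = [int(j) for j in inds[row] if j != row and j != partner[row] and j >= 0]
        if metric == "cosine":
            if zero[row]:
                d = np.ones(len(cand))
                flagged.add(row_ids[row].read_index)
            else:
                d = 1.0 - xn[cand] @ xn[row]
                d[zero[cand]] = 1.0
                np.clip(d, 0.0, 2.0, out=d)
        else:
            diff = sq[cand] + sq[row] - 2.0 * (x[cand] @ x[row])
            d = np.sqrt(np.maximum(diff, 0.0))
        order = sorted(range(len(cand)), key=lambda t: (d[t], cand[t]))[:k]
        lists.append([(row_ids[cand[t]], float(d[t])) for t in order])
    return NeighborTable(
        k=k,
        queries=list(row_ids),
        neighbor_lists=lists,
        read_names=embeddings.read_names,
        flagged=flagged,
    )


def recall_at_k(approx: NeighborTable, exact: NeighborTable) -> float:
    """Mean fraction of the exact top-k recovered by the approximate table."""
    if approx.queries != exact.queries:
        raise ValueError("neighbor tables cover different query sets")
    if approx.k != exact.k:
        raise ValueError(f"k mismatch: {approx.k} vs {exact.k}")
    if not approx.queries:
        raise ValueError("empty neighbor tables")
    total = 0.0
    for a_list, e_list in zip(approx.neighbor_lists, exact.neighbor_lists):
        a_set = {nb for nb, _ in a_list}
        e_set = {nb for nb, _ in e_list}
        total += len(a_set & e_set) / approx.k
    return total / len(approx.queries)
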