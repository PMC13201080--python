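"""Oriented overlap graphs and the candidate-overlap table format.

A dataset of ``n`` reads yields ``2n`` oriented reads: each read considered
as given (``+``) or as its reverse complement (``-``). Overlap graphs,
reference graphs and neighbor tables all share this vertex universe.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

__all__ = [
    "OrientedRead",
    "NeighborTable",
    "OverlapGraph",
    "build_overlap_graph",
    "write_candidates",
    "read_candidates",
    "CandidateParseError",
]

FORWARD = "+"
REVERSE = "-"


class OrientedRead(NamedTuple):
    """A read index paired with an orientation flag.

    ``orientation`` is ``"+"`` for the read as given and ``"-"`` for its
    reverse complement.
    """

    read_index: int
    orientation: str

    def partner(self) -> "OrientedRead":
        """The opposite orientation of the same read."""
        return OrientedRead(self.read_index, REVERSE if self.orientation == FORWARD else FORWARD)


def edge_key(u: OrientedRead, v: OrientedRead) -> tuple[OrientedRead, OrientedRead]:
    """Canonical (sorted) form of an undirected oriented-read pair."""
    return (u, v) if u <= v else (v, u)


@dataclass
class NeighborTable:
    """Ranked top-k neighbor lists, one per oriented read.

    ``queries`` and ``neighbor_lists`` are parallel: ``neighbor_lists[i]``
    holds ``(neighbor, distance)`` pairs for ``queries[i]``, sorted by
    ascending distance (rank 1 first). A query never lists itself or the
    opposite orientation of its own read.
    """

    k: int
    queries: list[OrientedRead]
    neighbor_lists: list[list[tuple[OrientedRead, float]]]
    read_names: list[str] | None = None
    flagged: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.queries) != len(self.neighbor_lists):
            raise ValueError("queries and neighbor_lists must be parallel")

    def __len__(self) -> int:
        return len(self.queries)

    def truncated(self, j: int) -> "NeighborTable":
        """Keep only the top-``j`` neighbors per query (j <= k)."""
        if j > self.k:
            raise ValueError(f"cannot truncate to {j} > k={self.k}")
        return NeighborTable(
            k=j,
            queries=list(self.queries),
            neighbor_lists=[lst[:j] for lst in self.neighbor_lists],
            read_names=self.read_names,
            flagged=set(self.flagged),
        )

    def name_of(self, idx: int) -> str:
        if self.read_names is not None:
            return self.read_names[idx]
        return str(idx)


@dataclass
class OverlapGraph:
    """Undirected overlap graph over 2n oriented-read vertices.

    Edges come from the union of the directed neighbor lists; each edge
    carries the best (lowest) rank and distance at which it was reported
    from either direction. With full neighbor lists of length k the edge
    count lies in [k·n, 2k·n]: every directed pair contributes, mutual
    pairs collapse to one edge.
    """

    n_reads: int
    k: int
    edges: dict[tuple[OrientedRead, OrientedRead], tuple[int, float]]
    read_names: list[str] | None = None

    @property
    def n_vertices(self) -> int:
        return 2 * self.n_reads

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def vertices(self) -> Iterable[OrientedRead]:
        for i in range(self.n_reads):
            yield OrientedRead(i, FORWARD)
            yield OrientedRead(i, REVERSE)


def build_overlap_graph(neighbors: NeighborTable, n_reads: int | None = None) -> OverlapGraph:
    """Union the directed neighbor lists of a :class:`NeighborTable` into an
    undirected :class:`OverlapGraph`.

    An edge {u, v} exists iff v appears in u's list or u appears in v's.
    """
    if n_reads is None:
        n_reads = 1 + max(
            (q.read_index for q in neighbors.queries),
            default=-1,
        )
        for lst in neighbors.neighbor_lists:
            for nb, _ in lst:
                if nb.read_index >= n_reads:
                    n_reads = nb.read_index + 1
    edges: dict[tuple[OrientedRead, OrientedRead], tuple[int, float]] = {}
    for query, lst in zip(neighbors.queries, neighbors.neighbor_lists):
        for rank0, (nb, dist) in enumerate(lst):
            if nb == query or nb == query.partner():
                continue  # defensive; tables should already exclude these
            key = edge_key(query, nb)
            rank = rank0 + 1
            prev = edges.get(key)
            if prev is None:
                edges[key] = (rank, dist)
            else:
                edges[key] = (min(prev[0], rank), min(prev[1], dist))
    return OverlapGraph(n_reads=n_reads, k=neighbors.k, edges=edges, read_names=neighbors.read_names)


# ---------------------------------------------------------------------------
# Candidate-table serialization
# ---------------------------------------------------------------------------

_HEADER = ["query_id", "query_orient", "target_id", "target_orient", "rank", "distance"]


class CandidateParseError(ValueError):
    """Raised when a candidate TSV row cannot be parsed; names the line."""


def _names_sidecar(path: str | os.PathLike) -> str:
    return f"{os.fspath(path)}.names.tsv"


def write_candidates(neighbors: NeighborTable, path: str | os.PathLike) -> None:
    """Write the candidate-overlap table as TSV.

    One row per (query, neighbor): query name, query orientation, target
    name, target orientation, rank (1-based) and distance (6 decimals).
    A sidecar ``<path>.names.tsv`` maps read names back to row indices so
    the table round-trips without the original input.
    """
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for query, lst in zip(neighbors.queries, neighbors.neighbor_lists):
            qname = neighbors.name_of(query.read_index)
            for rank0, (nb, dist) in enumerate(lst):
                fh.write(
                    f"{qname}\t{query.orientation}\t{neighbors.name_of(nb.read_index)}"
                    f"\t{nb.orientation}\t{rank0 + 1}\t{dist:.6f}\n"
                )
    n_reads = 0
    for q in neighbors.queries:
        n_reads = max(n_reads, q.read_index + 1)
    for lst in neighbors.neighbor_lists:
        for nb, _ in lst:
            n_reads = max(n_reads, nb.read_index + 1)
    with open(_names_sidecar(path), "w") as fh:
        fh.write("name\tread_index\n")
        for i in range(n_reads):
            fh.write(f"{neighbors.name_of(i)}\t{i}\n")


def read_candidates(path: str | os.PathLike) -> NeighborTable:
    """Inverse of :func:`write_candidates` (distances to 1e-6)."""
    path = os.fspath(path)
    name_to_idx: dict[str, int] = {}
    sidecar = _names_sidecar(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            header = fh.readline()
            for line in fh:
                name, idx = line.rstrip("\n").split("\t")
                name_to_idx[name] = int(idx)

    def idx_of(name: str) -> int:
        if name not in name_to_idx:
            name_to_idx[name] = len(name_to_idx)
        return name_to_idx[name]

    queries: list[OrientedRead] = []
    lists: list[list[tuple[OrientedRead, float]]] = []
    by_query: dict[OrientedRead, list[tuple[OrientedRead, float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise CandidateParseError(f"{path}:1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise CandidateParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            qname, qor, tname, tor, rank_s, dist_s = fields
            if qor not in "+-" or tor not in "+-":
                raise CandidateParseError(f"{path}:{lineno}: bad orientation")
            try:
                rank = int(rank_s)
                dist = float(dist_s)
            except ValueError as exc:
                raise CandidateParseError(f"{path}:{lineno}: {exc}") from None
            query = OrientedRead(idx_of(qname), qor)
            target = OrientedRead(idx_of(tname), tor)
            if query not in by_query:
                by_query[query] = []
                queries.append(query)
            lst = by_query[query]
            if rank != len(lst) + 1:
                raise CandidateParseError(f"{path}:{lineno}: rank {rank} out of order")
            lst.append((target, dist))
    lists = [by_query[q] for q in queries]
    k = max((len(lst) for lst in lists), default=0)
    names: list[str] | None = None
    if name_to_idx:
        names = [""] * (max(name_to_idx.values()) + 1)
        for name, idx in name_to_idx.items():
            names[idx] = name
    return NeighborTable(k=k, queries=queries, neighbor_lists=lists, read_names=names)
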