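"""Reference overlap graphs and graph-quality metrics.

An overlap graph is scored against a reference graph over the same 2n
oriented-read vertices. Reference edges come either from the genomic
intervals reads were simulated from, or from read-to-reference alignments
(PAF) after removing ambiguously aligned reads (length >= 5 kb, aligned
fraction >= 50%, MAPQ >= 30).

Four metrics summarize graph quality:

* **error rate** — incorrect edges / total edges (an edge is correct iff
  present in the reference);
* **mean overlap size** — arithmetic mean over *all* edges of the
  reference overlap size, counting incorrect edges as zero;
* **#COC** — per-vertex degree counting only correct edges (a vertex with
  none is a *singleton*);
* **#CC** — connected components of the correct-edge subgraph.

Reads removed by the alignment filters keep their vertices (|V| stays 2n)
but can contribute only incorrect edges; they are excluded from the #CC
count and the low-connectivity denominator so that filtered and unfiltered
datasets remain comparable — both conventions are reported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .graph import FORWARD, REVERSE, OrientedRead, OverlapGraph, edge_key

__all__ = [
    "ReferenceGraph",
    "GraphMetrics",
    "oriented_interval_edges",
    "reference_from_paf",
    "score_graph",
    "low_connectivity_curve",
    "PafParseError",
    "GraphScoringError",
]


class PafParseError(ValueError):
    """Raised for malformed PAF input; names the offending line."""


class GraphScoringError(ValueError):
    """Raised when metrics are undefined (e.g. zero-edge graph)."""


@dataclass
class ReferenceGraph:
    """Ground-truth oriented overlap edges with sizes.

    ``edges`` maps the canonical (sorted) oriented pair to the overlap size
    in bp. ``retained`` is the set of read indices passing the alignment
    filters; edges only join retained reads.
    """

    n_reads: int
    edges: dict[tuple[OrientedRead, OrientedRead], int]
    retained: set[int]
    read_names: list[str]
    min_overlap: int = 1

    @property
    def n_vertices(self) -> int:
        return 2 * self.n_reads

    @property
    def mean_overlap_size(self) -> float:
        if not self.edges:
            return 0.0
        return float(np.mean(list(self.edges.values())))


def oriented_interval_edges(
    intervals: Sequence[tuple[int, int, int, str]],
    min_overlap: int = 1,
) -> dict[tuple[OrientedRead, OrientedRead], int]:
    """Oriented edges for every interval pair intersecting >= ``min_overlap``.

    ``intervals`` holds ``(read_index, start, end, strand)`` with 0-based
    half-open coordinates on a shared axis. Same-strand pairs yield
    (A+, B+) and (A-, B-); opposite strands yield (A+, B-) and (A-, B+).
    Touching intervals (intersection 0) never overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    order = sorted(range(len(intervals)), key=lambda i: intervals[i][1])
    edges: dict[tuple[OrientedRead, OrientedRead], int] = {}
    for oi, i in enumerate(order):
        idx_a, start_a, end_a, strand_a = intervals[i]
        for j in order[oi + 1 :]:
            idx_b, start_b, end_b, strand_b = intervals[j]
            if start_b >= end_a:  # sorted by start: no later interval can reach back
                break
            size = min(end_a, end_b) - start_b
            if size < min_overlap or idx_a == idx_b:
                continue
            if strand_a == strand_b:
                pairs = (
                    (OrientedRead(idx_a, FORWARD), OrientedRead(idx_b, FORWARD)),
                    (OrientedRead(idx_a, REVERSE), OrientedRead(idx_b, REVERSE)),
                )
            else:
                pairs = (
                    (OrientedRead(idx_a, FORWARD), OrientedRead(idx_b, REVERSE)),
                    (OrientedRead(idx_a, REVERSE), OrientedRead(idx_b, FORWARD)),
                )
            for u, v in pairs:
                key = edge_key(u, v)
                prev = edges.get(key)
                if prev is None or size > prev:
                    edges[key] = size
    return edges


@dataclass
class _PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tstart: int
    tend: int
    mapq: int
    alnlen: int


def _parse_paf(path: str | os.PathLike) -> list[_PafRecord]:
    records = []
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise PafParseError(f"{path}:{lineno}: expected >= 12 columns, got {len(fields)}")
            # skip secondary records when the tp:A tag is present
            tp = next((f[5:] for f in fields[12:] if f.startswith("tp:A:")), None)
            if tp is not None and tp != "P":
                continue
            try:
                records.append(
                    _PafRecord(
                        qname=fields[0],
                        qlen=int(fields[1]),
                        qstart=int(fields[2]),
                        qend=int(fields[3]),
                        strand=fields[4],
                        tname=fields[5],
                        tstart=int(fields[7]),
                        tend=int(fields[8]),
                        mapq=int(fields[11]),
                        alnlen=int(fields[10]),
                    )
                )
            except ValueError as exc:
                raise PafParseError(f"{path}:{lineno}: {exc}") from None
    return records


def reference_from_paf(
    paf: str | os.PathLike,
    min_read_len: int = 5000,
    min_aligned_frac: float = 0.5,
    min_mapq: int = 30,
    min_overlap: int = 1,
    read_names: Sequence[str] | None = None,
) -> ReferenceGraph:
    """Build a reference graph from all-vs-reference PAF alignments.

    One primary alignment is kept per read (highest MAPQ, ties broken by
    longer alignment). Reads are filtered out unless read length >=
    ``min_read_len``, aligned fraction >= ``min_aligned_frac`` and MAPQ >=
    ``min_mapq``; filtered reads keep their vertices but have no reference
    edges. Retained reads aligned to the same target sequence with interval
    intersection >= ``min_overlap`` get oriented edges under the strand
    rule of :func:`oriented_interval_edges`.

    ``read_names`` fixes the vertex universe and index order; by default it
    is the order of first appearance in the PAF.
    """
    records = _parse_paf(paf)
    best: dict[str, _PafRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.qname not in best:
            order.append(rec.qname)
            best[rec.qname] = rec
        else:
            cur = best[rec.qname]
            if (rec.mapq, rec.alnlen) > (cur.mapq, cur.alnlen):
                best[rec.qname] = rec
    if read_names is None:
        read_names = order
    name_to_idx = {name: i for i, name in enumerate(read_names)}
    unknown = [q for q in best if q not in name_to_idx]
    if unknown:
        raise ValueError(f"PAF contains {len(unknown)} read names outside the given universe, e.g. {unknown[0]!r}")
    retained: set[int] = set()
    by_target: dict[str, list[tuple[int, int, int, str]]] = {}
    for qname, rec in best.items():
        if rec.qlen < min_read_len:
            continue
        if rec.qlen <= 0 or (rec.qend - rec.qstart) / rec.qlen < min_aligned_frac:
            continue
        if rec.mapq < min_mapq:
            continue
        idx = name_to_idx[qname]
        retained.add(idx)
        by_target.setdefault(rec.tname, []).append((idx, rec.tstart, rec.tend, rec.strand))
    edges: dict[tuple[OrientedRead, OrientedRead], int] = {}
    for intervals in by_target.values():
        edges.update(oriented_interval_edges(intervals, min_overlap=min_overlap))
    return ReferenceGraph(
        n_reads=len(read_names),
        edges=edges,
        retained=retained,
        read_names=list(read_names),
        min_overlap=min_overlap,
    )


@dataclass
class GraphMetrics:
    """The four overlap-graph quality statistics plus their ingredients."""

    error_rate: float
    mean_overlap_size: float
    coc: dict[OrientedRead, int]
    n_singletons: int
    n_cc: int
    n_cc_all: int
    n_edges: int
    n_correct_edges: int
    n_vertices: int
    n_vertices_retained: int

    def to_dict(self) -> dict:
        coc_values = np.array(sorted(self.coc.values()), dtype=float)
        return {
            "error_rate": self.error_rate,
            "mean_overlap_size": self.mean_overlap_size,
            "mean_coc": float(coc_values.mean()) if coc_values.size else 0.0,
            "n_singletons": self.n_singletons,
            "n_cc": self.n_cc,
            "n_cc_all": self.n_cc_all,
            "n_edges": self.n_edges,
            "n_correct_edges": self.n_correct_edges,
            "n_vertices": self.n_vertices,
            "n_vertices_retained": self.n_vertices_retained,
        }


def score_graph(graph: OverlapGraph, reference: ReferenceGraph) -> GraphMetrics:
    """Score an overlap graph against a reference graph.

    An edge is correct iff present in the reference. See the module
    docstring for metric definitions and the filtered-read conventions.
    """
    if graph.n_reads != reference.n_reads:
        raise ValueError(
            f"vertex universes differ: {graph.n_reads} vs {reference.n_reads} reads"
        )
    if graph.n_edges == 0:
        raise GraphScoringError("metrics are undefined for a graph with zero edges")
    n_correct = 0
    size_sum = 0
    coc: dict[OrientedRead, int] = {v: 0 for v in graph.vertices()}
    correct_graph = nx.Graph()
    retained_vertices = [
        OrientedRead(i, o) for i in sorted(reference.retained) for o in (FORWARD, REVERSE)
    ]
    correct_graph.add_nodes_from(retained_vertices)
    for key in graph.edges:
        size = reference.edges.get(key)
        if size is not None:
            n_correct += 1
            size_sum += size
            u, v = key
            coc[u] += 1
            coc[v] += 1
            correct_graph.add_edge(u, v)
    n_edges = graph.n_edges
    retained_set = reference.retained
    singletons = sum(
        1 for v, d in coc.items() if d == 0 and v.read_index in retained_set
    )
    n_cc = nx.number_connected_components(correct_graph)
    # alternative convention: all 2n vertices count, filtered ones as isolates
    n_cc_all = n_cc + sum(
        2 for i in range(graph.n_reads) if i not in retained_set
    )
    return GraphMetrics(
        error_rate=1.0 - n_correct / n_edges,
        mean_overlap_size=size_sum / n_edges,
        coc=coc,
        n_singletons=singletons,
        n_cc=n_cc,
        n_cc_all=n_cc_all,
        n_edges=n_edges,
        n_correct_edges=n_correct,
        n_vertices=graph.n_vertices,
        n_vertices_retained=2 * len(retained_set),
    )


def low_connectivity_curve(
    metrics: GraphMetrics,
    thresholds: Sequence[int],
    retained: set[int] | None = None,
) -> list[float]:
    """Fraction of vertices with #COC below each threshold.

    The denominator is the retained vertices when ``retained`` is given
    (filtered reads would otherwise be guaranteed low-connectivity),
    otherwise all vertices.
    """
    if retained is not None:
        values = [d for v, d in metrics.coc.items() if v.read_index in retained]
    else:
        values = list(metrics.coc.values())
    if not values:
        return [0.0 for _ in thresholds]
    arr = np.array(values)
    return [float((arr < t).mean()) for t in thresholds]
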