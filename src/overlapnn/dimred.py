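"""Sparse random projection with IDF weighting fused into one matrix.

The projection R is the Achlioptas/Li very-sparse scheme: i.i.d. entries
+s with probability density/2, -s with probability density/2, else 0,
with s = sqrt(1 / (density * d)) and default density 1/sqrt(m). Inner
products are preserved in expectation, so cosine geometry survives the
projection up to O(1/sqrt(d)) noise.

Because IDF weighting and projection are both linear, they fuse into a
single reusable matrix diag(w) @ R; feature batches are streamed through
it so the full feature matrix is never materialized, and the result is
independent of how reads are partitioned into batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from sklearn.random_projection import SparseRandomProjection

from .features import FeatureBatch, IdfWeights
from .graph import OrientedRead

__all__ = [
    "ProjectionMatrix",
    "WeightedProjection",
    "Embeddings",
    "srp_matrix",
    "fuse",
    "project_stream",
    "save_embeddings",
    "load_embeddings",
]


@dataclass
class ProjectionMatrix:
    """Sparse m x d random projection; nonzeros are exactly {+s, -s}."""

    entries: sp.csr_matrix
    density: float
    seed: int

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def d(self) -> int:
        return self.entries.shape[1]

    @property
    def scale(self) -> float:
        return float(np.sqrt(1.0 / (self.density * self.d)))


@dataclass
class WeightedProjection:
    """diag(idf_weights) @ ProjectionMatrix, applied identically to every batch."""

    entries: sp.csr_matrix

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def d(self) -> int:
        return self.entries.shape[1]


@dataclass
class Embeddings:
    """Dense low-dimensional embeddings, one row per oriented read."""

    matrix: np.ndarray
    row_ids: list[OrientedRead]
    read_names: list[str] | None = None

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


def srp_matrix(m: int, d: int, density: float | None = None, seed: int = 0) -> ProjectionMatrix:
    """Generate the m x d sparse random projection matrix.

    ``density`` defaults to 1/sqrt(m). Deterministic per seed.
    """
    if m < 1 or d < 1:
        raise ValueError("m and d must be >= 1")
    if density is None:
        density = 1.0 / np.sqrt(m)
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    srp = SparseRandomProjection(n_components=d, density=density, random_state=seed)
    srp.fit(sp.csr_matrix((1, m)))
    entries = sp.csr_matrix(srp.components_.T)
    return ProjectionMatrix(entries=entries, density=float(density), seed=seed)


def fuse(projection: ProjectionMatrix, idf: IdfWeights) -> WeightedProjection:
    """Pre-multiply the projection by the IDF weights: diag(w) @ R.

    Exact row scaling, so X @ fused == (X * w) @ R for any feature
    matrix X up to float round-off.
    """
    if len(idf) != projection.m:
        raise ValueError(
            f"IDF length {len(idf)} does not match projection rows {projection.m}"
        )
    entries = sp.csr_matrix(projection.entries.multiply(idf.weights[:, None]))
    return WeightedProjection(entries=entries)


def project_stream(
    batches: Iterable[FeatureBatch],
    wp: WeightedProjection | ProjectionMatrix,
    read_names: list[str] | None = None,
) -> Embeddings:
    """Project a stream of feature batches through the (weighted) matrix.

    Each row's product is computed independently, so the concatenated
    result is bitwise identical for any partition of the reads into
    batches.
    """
    matrix = wp.entries
    blocks: list[np.ndarray] = []
    row_ids: list[OrientedRead] = []
    for batch in batches:
        if batch.rows.shape[1] != matrix.shape[0]:
            raise ValueError(
                f"batch has {batch.rows.shape[1]} columns, projection expects {matrix.shape[0]}"
            )
        blocks.append(np.asarray((batch.rows @ matrix).todense(), dtype=np.float64))
        row_ids.extend(batch.row_ids)
    if blocks:
        out = np.vstack(blocks)
    else:
        out = np.empty((0, matrix.shape[1]), dtype=np.float64)
    return Embeddings(matrix=out, row_ids=row_ids, read_names=read_names)


def save_embeddings(emb: Embeddings, prefix: str) -> None:
    """Persist embeddings: ``<prefix>.mat.npy`` plus a ``<prefix>.rows.tsv``
    sidecar of (row, read_index, orientation, name)."""
    np.save(f"{prefix}.mat.npy", emb.matrix)
    with open(f"{prefix}.rows.tsv", "w") as fh:
        fh.write("row\tread_index\torientation\tname\n")
        for row, rid in enumerate(emb.row_ids):
            name = emb.read_names[rid.read_index] if emb.read_names else str(rid.read_index)
            fh.write(f"{row}\t{rid.read_index}\t{rid.orientation}\t{name}\n")


def load_embeddings(prefix: str) -> Embeddings:
    matrix = np.load(f"{prefix}.mat.npy")
    row_ids: list[OrientedRead] = []
    names: dict[int, str] = {}
    with open(f"{prefix}.rows.tsv") as fh:
        fh.readline()
        for line in fh:
            row, idx, orient, name = line.rstrip("\n").split("\t")
            row_ids.append(OrientedRead(int(idx), orient))
            names[int(idx)] = name
    read_names = [names[i] for i in range(len(names))] if names else None
    return Embeddings(matrix=matrix, row_ids=row_ids, read_names=read_names)
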