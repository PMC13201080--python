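"""Diagnostic statistics for the pipeline's two fidelity claims.

* Distance preservation: how faithfully the sparse random projection
  preserves pairwise cosine distances of the IDF-weighted feature rows,
  summarized as Pearson R² over read pairs sampled to span the distance
  range.
* CF~DF surrogacy: how closely a k-mer's collection frequency (total
  occurrences) tracks its document frequency (number of reads containing
  it) on log scale, summarized as the least-squares R² — the justification
  for weighting by inverse *collection* frequency.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .features import KmerAlphabet, KmerCountTable

__all__ = [
    "pairwise_cosine_distances",
    "stratified_pair_sample",
    "distance_preservation_r2",
    "cf_df_r2",
]


def pairwise_cosine_distances(x) -> np.ndarray:
    """Dense matrix of pairwise cosine distances between the rows of ``x``
    (dense array or scipy sparse). Zero-norm rows sit at distance 1 from
    everything."""
    if sp.issparse(x):
        x = sp.csr_matrix(x, dtype=np.float64)
        norms = np.sqrt(np.asarray(x.multiply(x).sum(axis=1)).ravel())
        zero = norms == 0
        inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, norms))
        xn = sp.diags(inv) @ x
        gram = np.asarray((xn @ xn.T).todense())
    else:
        x = np.asarray(x, dtype=np.float64)
        norms = np.linalg.norm(x, axis=1)
        zero = norms == 0
        xn = x / np.where(zero, 1.0, norms)[:, None]
        gram = xn @ xn.T
    dist = 1.0 - gram
    if zero.any():
        dist[zero, :] = 1.0
        dist[:, zero] = 1.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def stratified_pair_sample(
    distances: np.ndarray,
    n_pairs: int = 10_000,
    n_bins: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample row pairs stratified across the distance range.

    Bins the upper-triangle distances into ``n_bins`` equal-width bins and
    draws up to ``n_pairs / n_bins`` pairs from each, so sparse distance
    regimes (true overlaps) are represented alongside the unrelated-pair
    bulk. Returns parallel (i, j) index arrays.
    """
    n = distances.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = distances[iu, ju]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        bins = np.zeros(vals.size, dtype=np.int64)
        n_bins = 1
    else:
        bins = np.minimum(((vals - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1)
    rng = np.random.default_rng(seed)
    per_bin = max(1, n_pairs // n_bins)
    keep: list[np.ndarray] = []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if members.size == 0:
            continue
        take = min(per_bin, members.size)
        keep.append(rng.choice(members, size=take, replace=False))
    idx = np.concatenate(keep)
    return iu[idx], ju[idx]


def distance_preservation_r2(
    feature_rows,
    embedding_rows: np.ndarray,
    n_pairs: int = 10_000,
    n_bins: int = 50,
    seed: int = 0,
) -> tuple[float, int]:
    """Pearson R² between pre- and post-projection cosine distances.

    Pairs are sampled to span the pre-projection distance range. Returns
    ``(r_squared, n_pairs_used)``.
    """
    pre = pairwise_cosine_distances(feature_rows)
    post = pairwise_cosine_distances(embedding_rows)
    i, j = stratified_pair_sample(pre, n_pairs=n_pairs, n_bins=n_bins, seed=seed)
    r = np.corrcoef(pre[i, j], post[i, j])[0, 1]
    return float(r * r), int(i.size)


def cf_df_r2(table: KmerCountTable, alphabet: KmerAlphabet | None = None, min_count: int = 1) -> tuple[float, int]:
    """Least-squares R² of log CF vs log DF.

    Restricted to the alphabet's k-mers when given, otherwise to all
    k-mers with CF >= ``min_count``. Returns ``(r_squared, n_kmers)``.
    """
    if table.df is None:
        raise ValueError("count table lacks document frequencies (track_df=True)")
    if alphabet is not None:
        pos = np.searchsorted(table.codes, alphabet.codes)
        cf = table.cf[pos].astype(np.float64)
        df = table.df[pos].astype(np.float64)
    else:
        keep = table.cf >= min_count
        cf = table.cf[keep].astype(np.float64)
        df = table.df[keep].astype(np.float64)
    r = np.corrcoef(np.log(cf), np.log(df))[0, 1]
    return float(r * r), int(cf.size)
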