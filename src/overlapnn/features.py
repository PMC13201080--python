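"""Canonical k-mer counting, alphabet sampling, IDF weighting and sparse
feature construction.

Counting is strand-symmetric: every window is folded to its *canonical*
form (the lexicographically smaller of the k-mer and its reverse
complement), so a k-mer's count reflects the combined frequency of both
strands. The inverse-document-frequency weight of alphabet k-mer ``j`` is

    idf(j) = ln(|N| / c_j)

where ``|N|`` is the number of reads and ``c_j`` the k-mer's collection
frequency (CF, total occurrences) — CF serves as a surrogate for the
document frequency (DF, number of reads containing the k-mer), which it
tracks almost exactly on log scale for long-read data.

Feature rows are built per *oriented* read: the ``+`` row counts literal
matches of alphabet k-mer strings in the read as given, the ``-`` row
counts matches in its reverse complement. Because alphabet entries are
canonical strings, the two rows differ and orientation is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from numpy.lib.stride_tricks import sliding_window_view

from .graph import FORWARD, REVERSE, OrientedRead

__all__ = [
    "revcomp",
    "canonical",
    "count_kmers",
    "filter_and_sample",
    "idf_weights",
    "featurize_batch",
    "iter_feature_batches",
    "KmerCountTable",
    "KmerAlphabet",
    "IdfWeights",
    "FeatureBatch",
    "EmptyAlphabetError",
    "SCHEMES",
]

SCHEMES = ("binary", "tf", "raw_tf", "idf", "tf_idf")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte value -> 2-bit base code; 255 marks non-ACGT
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


class EmptyAlphabetError(ValueError):
    """No k-mers survive filtering/sampling."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """The lexicographically smaller of ``kmer`` and its reverse complement.

    Idempotent. Raises :class:`ValueError` on non-ACGT characters (callers
    skip such windows).
    """
    upper = kmer.upper()
    if any(c not in "ACGT" for c in upper):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    rc = revcomp(upper)
    return upper if upper <= rc else rc


def encode(seq: str) -> np.ndarray:
    """2-bit encode a DNA string; non-ACGT bases become 255."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _CODE_BASE[codes].tobytes().decode("ascii")


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 big-endian integer code of every k-window, plus validity mask.

    Numeric order of codes equals lexicographic order of the k-mer strings
    (A<C<G<T), which keeps canonicalization a plain elementwise minimum.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    valid = sliding_window_view(codes < 4, k).all(axis=1)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    win = sliding_window_view(codes, k).astype(np.uint64)
    vals = win @ powers
    return vals, valid


def kmer_code(kmer: str) -> int:
    codes = encode(kmer)
    if (codes > 3).any():
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    vals, _ = _window_codes(codes, len(kmer))
    return int(vals[0])


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(k - 1, -1, -1):
        out.append("ACGT"[(code >> (2 * shift)) & 3])
    return "".join(out)


def _canonical_window_codes(seq: str, k: int) -> np.ndarray:
    """Canonical codes of all valid k-windows of ``seq``."""
    fwd_codes = encode(seq)
    fwd, valid = _window_codes(fwd_codes, k)
    rc_all, _ = _window_codes(encode(revcomp(seq)), k)
    rc = rc_all[::-1]  # window i of seq <-> window L-k-i of revcomp(seq)
    canon = np.minimum(fwd, rc)
    return canon[valid]


@dataclass
class KmerCountTable:
    """Collection frequencies of canonical k-mers across a read set.

    ``codes`` is the sorted integer code of every observed canonical k-mer,
    with ``cf[i]`` its total occurrence count (both strands) and, when
    tracked, ``df[i]`` the number of reads containing it. ``n_reads`` is
    |N| in the IDF formula.
    """

    k: int
    codes: np.ndarray
    cf: np.ndarray
    n_reads: int
    df: np.ndarray | None = None

    def __len__(self) -> int:
        return self.codes.size

    @property
    def counts(self) -> dict[str, int]:
        """Canonical k-mer string -> CF (built on demand)."""
        return {code_to_kmer(int(c), self.k): int(n) for c, n in zip(self.codes, self.cf)}

    @property
    def document_frequencies(self) -> dict[str, int]:
        if self.df is None:
            raise ValueError("document frequencies were not tracked")
        return {code_to_kmer(int(c), self.k): int(n) for c, n in zip(self.codes, self.df)}

    def cf_of(self, kmer: str) -> int:
        code = kmer_code(canonical(kmer))
        pos = np.searchsorted(self.codes, np.uint64(code))
        if pos >= self.codes.size or self.codes[pos] != code:
            raise KeyError(kmer)
        return int(self.cf[pos])


def count_kmers(
    reads: Iterable[str | tuple[str, str]],
    k: int,
    track_df: bool = False,
) -> KmerCountTable:
    """Count canonical k-mers across a stream of reads.

    ``reads`` yields sequences or ``(read_id, sequence)`` pairs. Windows
    containing non-ACGT characters are skipped. With ``track_df`` the
    per-read presence counts (document frequencies) are recorded as well.
    """
    code_chunks: list[np.ndarray] = []
    count_chunks: list[np.ndarray] = []
    n_reads = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        n_reads += 1
        canon = _canonical_window_codes(seq, k)
        if canon.size == 0:
            continue
        uniq, cnt = np.unique(canon, return_counts=True)
        code_chunks.append(uniq)
        count_chunks.append(cnt.astype(np.int64))
    if not code_chunks:
        return KmerCountTable(
            k=k,
            codes=np.empty(0, dtype=np.uint64),
            cf=np.empty(0, dtype=np.int64),
            n_reads=n_reads,
            df=np.empty(0, dtype=np.int64) if track_df else None,
        )
    all_codes = np.concatenate(code_chunks)
    all_counts = np.concatenate(count_chunks)
    uniq, inverse = np.unique(all_codes, return_inverse=True)
    cf = np.bincount(inverse, weights=all_counts).astype(np.int64)
    df = np.bincount(inverse).astype(np.int64) if track_df else None
    return KmerCountTable(k=k, codes=uniq, cf=cf, n_reads=n_reads, df=df)


def read_kmer_dump(path: str, k: int, n_reads: int) -> KmerCountTable:
    """Import an external counter's text dump (``kmer count`` per line).

    K-mers are canonicalized on import; counts of a k-mer and its reverse
    complement are merged.
    """
    acc: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"expected 'kmer count' lines in {path}: {line!r}")
            kmer, cnt = parts
            if len(kmer) != k:
                raise ValueError(f"k-mer {kmer!r} does not have length {k}")
            code = kmer_code(canonical(kmer))
            acc[code] = acc.get(code, 0) + int(cnt)
    codes = np.array(sorted(acc), dtype=np.uint64)
    cf = np.array([acc[int(c)] for c in codes], dtype=np.int64)
    return KmerCountTable(k=k, codes=codes, cf=cf, n_reads=n_reads)


@dataclass
class KmerAlphabet:
    """An ordered, sampled set of canonical k-mers defining feature columns.

    Columns are 0-based, contiguous, and ordered by the (lexicographically
    sorted) k-mer codes.
    """

    k: int
    codes: np.ndarray  # sorted uint64 canonical k-mer codes

    def __len__(self) -> int:
        return self.codes.size

    @property
    def kmers(self) -> list[str]:
        return [code_to_kmer(int(c), self.k) for c in self.codes]

    @property
    def index(self) -> dict[str, int]:
        return {kmer: i for i, kmer in enumerate(self.kmers)}


def filter_and_sample(
    table: KmerCountTable,
    min_count: int = 2,
    fraction: float = 0.15,
    seed: int = 0,
) -> KmerAlphabet:
    """Drop low-frequency k-mers, then uniformly sample an alphabet.

    Keeps k-mers with CF >= ``min_count`` (removing noise from sequencing
    errors), sorts survivors lexicographically, then samples
    ``max(1, floor(fraction * n_survivors))`` of them without replacement
    with a generator seeded by ``seed``. The resulting alphabet is sorted;
    identical arguments give identical alphabets.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(table) == 0:
        raise EmptyAlphabetError("k-mer table is empty")
    survivors = table.codes[table.cf >= min_count]
    if survivors.size == 0:
        raise EmptyAlphabetError(
            f"no k-mers with count >= {min_count}; lower min_count or check input"
        )
    size = max(1, int(fraction * survivors.size))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(survivors.size, size=size, replace=False)
    return KmerAlphabet(k=table.k, codes=np.sort(survivors[chosen]))


@dataclass
class IdfWeights:
    """Per-column IDF weights: ``weights[j] = ln(n_reads / cf_j)``."""

    weights: np.ndarray

    def __len__(self) -> int:
        return self.weights.size


def idf_weights(table: KmerCountTable, alphabet: KmerAlphabet) -> IdfWeights:
    """IDF weight of every alphabet column, from collection frequencies.

    A k-mer occurring once per read on average (c_j = |N|) gets weight 0;
    weights strictly decrease as c_j grows. Raises if an alphabet k-mer is
    missing from the table.
    """
    if table.n_reads < 1:
        raise ValueError("IDF undefined for an empty read set")
    pos = np.searchsorted(table.codes, alphabet.codes)
    ok = (pos < table.codes.size) & (table.codes[np.minimum(pos, table.codes.size - 1)] == alphabet.codes)
    if not ok.all():
        missing = code_to_kmer(int(alphabet.codes[np.flatnonzero(~ok)[0]]), alphabet.k)
        raise ValueError(f"alphabet k-mer {missing} absent from count table")
    cf = table.cf[pos].astype(np.float64)
    return IdfWeights(weights=np.log(table.n_reads / cf))


@dataclass
class FeatureBatch:
    """Sparse feature rows for both orientations of each read in a batch.

    Rows are interleaved: row ``2i`` is read i's ``+`` row, row ``2i+1``
    its ``-`` row. ``flagged`` lists reads whose rows are all-zero (shorter
    than k, or sharing no k-mer with the alphabet).
    """

    rows: sp.csr_matrix
    row_ids: list[OrientedRead]
    scheme: str
    flagged: set[int] = field(default_factory=set)


def _oriented_hits(seq: str, alphabet: KmerAlphabet) -> tuple[np.ndarray, np.ndarray]:
    """Columns and occurrence counts of alphabet k-mers literally present
    in ``seq`` (no canonicalization of read windows — orientation matters)."""
    codes, valid = _window_codes(encode(seq), alphabet.k)
    codes = codes[valid]
    if codes.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pos = np.searchsorted(alphabet.codes, codes)
    pos_c = np.minimum(pos, alphabet.codes.size - 1)
    hit = alphabet.codes[pos_c] == codes
    cols, counts = np.unique(pos_c[hit], return_counts=True)
    return cols.astype(np.int64), counts.astype(np.int64)


def featurize_batch(
    reads: Sequence[tuple[str, str]],
    alphabet: KmerAlphabet,
    scheme: str = "binary",
    idf: IdfWeights | None = None,
    read_offset: int = 0,
) -> FeatureBatch:
    """Build the sparse feature rows for a batch of reads.

    For each ``(read_id, sequence)`` two rows are produced: the ``+`` row
    from literal matches of alphabet k-mers in the sequence, the ``-`` row
    from matches in its reverse complement. Entry semantics per scheme:
    ``binary`` presence, ``raw_tf`` occurrence count, ``tf`` count divided
    by total alphabet-k-mer occurrences in that oriented read, ``idf`` /
    ``tf_idf`` the binary / tf value scaled by the column's IDF weight
    (exact-mode path; the streamed pipeline applies IDF inside the fused
    projection instead).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme in ("idf", "tf_idf"):
        if idf is None:
            raise ValueError(f"scheme {scheme!r} requires IDF weights")
        if len(idf) != len(alphabet):
            raise ValueError("IDF weight length does not match alphabet size")
    row_idx: list[np.ndarray] = []
    col_idx: list[np.ndarray] = []
    values: list[np.ndarray] = []
    row_ids: list[OrientedRead] = []
    flagged: set[int] = set()
    for i, (read_id, seq) in enumerate(reads):
        index = read_offset + i
        for j, oriented_seq in ((0, seq), (1, revcomp(seq))):
            row = 2 * i + j
            row_ids.append(OrientedRead(index, FORWARD if j == 0 else REVERSE))
            cols, counts = _oriented_hits(oriented_seq, alphabet)
            if cols.size == 0:
                flagged.add(index)
                continue
            if scheme == "binary":
                vals = np.ones(cols.size)
            elif scheme == "raw_tf":
                vals = counts.astype(np.float64)
            elif scheme == "tf":
                vals = counts / counts.sum()
            elif scheme == "idf":
                vals = idf.weights[cols]
            else:  # tf_idf
                vals = (counts / counts.sum()) * idf.weights[cols]
            row_idx.append(np.full(cols.size, row, dtype=np.int64))
            col_idx.append(cols)
            values.append(vals)
    shape = (2 * len(reads), len(alphabet))
    if row_idx:
        rows = sp.csr_matrix(
            (np.concatenate(values), (np.concatenate(row_idx), np.concatenate(col_idx))),
            shape=shape,
        )
    else:
        rows = sp.csr_matrix(shape)
    return FeatureBatch(rows=rows, row_ids=row_ids, scheme=scheme, flagged=flagged)


def iter_feature_batches(
    reads: Sequence[tuple[str, str]],
    alphabet: KmerAlphabet,
    scheme: str = "binary",
    idf: IdfWeights | None = None,
    batch_size: int = 100_000,
) -> Iterator[FeatureBatch]:
    """Stream :class:`FeatureBatch` objects of ``batch_size`` reads each."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    for start in range(0, len(reads), batch_size):
        yield featurize_batch(
            reads[start : start + batch_size],
            alphabet,
            scheme=scheme,
            idf=idf,
            read_offset=start,
        )
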