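"""Synthetic genomes and error-bearing long reads with ground truth.

Emulates a long-read sequencing experiment end to end: a random genome
with controllable repeat content, reads of 10-30 kb sampled at 10-50x
depth from either strand, per-base substitution/insertion/deletion errors
at 1-9%, and a truth table recording the error-free source interval and
strand of every read. The truth table in turn defines the ground-truth
overlap graph used for evaluation.

All coordinates are 0-based half-open (BED/PAF convention): intervals that
merely touch do not overlap.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluate import ReferenceGraph, oriented_interval_edges
from .features import _CODE_BASE, encode, revcomp

__all__ = [
    "SyntheticGenome",
    "TruthRead",
    "generate_genome",
    "simulate_reads",
    "truth_reference_graph",
    "write_fastq",
    "write_truth",
    "read_truth",
    "error_rates_from_accuracy",
]

MIN_READ_LEN = 500


@dataclass
class SyntheticGenome:
    """A random genome with annotated repeats.

    ``repeat_annotations`` holds ``(start, end, source_start)`` triples:
    the half-open interval [start, end) is a copy of the earlier segment
    beginning at ``source_start``.
    """

    sequence: str
    repeat_annotations: list[tuple[int, int, int]]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def repeat_bases(self) -> int:
        return sum(end - start for start, end, _ in self.repeat_annotations)


@dataclass
class TruthRead:
    """Ground-truth placement of a simulated read.

    ``ref_start``/``ref_end`` delimit the error-free source interval on the
    genome; ``length`` is the emitted read length, which can differ from
    the interval length when indels are simulated.
    """

    read_id: str
    ref_start: int
    ref_end: int
    strand: str
    length: int


def generate_genome(
    length: int,
    repeat_fraction: float = 0.2,
    repeat_unit_len: int = 2000,
    seed: int = 0,
    repeat_families: int | None = None,
) -> SyntheticGenome:
    """Generate an i.i.d.-uniform genome with interspersed repeat copies.

    The genome is laid out in blocks of ``repeat_unit_len``; a fixed number
    of blocks — ``round(repeat_fraction * length / repeat_unit_len)`` — are
    copies of earlier segments, so the annotated repeat span is
    ``repeat_fraction * length`` up to one block of rounding. The first
    block is always background (a copy needs earlier material).

    With ``repeat_families=None`` every repeat block copies an independent,
    uniformly chosen earlier position (single-copy repeats). Setting
    ``repeat_families=f`` draws all copies from only ``f`` source segments,
    emulating high-multiplicity repeat families (transposable elements,
    segmental duplications) whose k-mers recur across many loci — the
    regime that makes overlap detection hard in repeat-rich regions.
    Deterministic for a fixed seed.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= repeat_fraction <= 1:
        raise ValueError(f"repeat_fraction must be in [0, 1], got {repeat_fraction}")
    if repeat_unit_len >= length:
        raise ValueError("repeat_unit_len must be smaller than length")
    if repeat_families is not None and repeat_families < 1:
        raise ValueError("repeat_families must be >= 1 when given")
    rng = np.random.default_rng(seed)
    n_blocks = -(-length // repeat_unit_len)  # ceil
    n_repeat = min(int(round(repeat_fraction * length / repeat_unit_len)), n_blocks - 1)
    repeat_blocks = set(rng.choice(np.arange(1, n_blocks), size=n_repeat, replace=False).tolist()) if n_repeat else set()
    family_of = (
        rng.integers(0, repeat_families, size=n_blocks)
        if repeat_families is not None
        else None
    )
    family_anchor: dict[int, int] = {}
    background_starts: list[int] = []
    chunks: list[np.ndarray] = []
    annotations: list[tuple[int, int, int]] = []
    pos = 0
    codes_so_far = np.empty(0, dtype=np.uint8)
    for block in range(n_blocks):
        unit = min(repeat_unit_len, length - pos)
        if block in repeat_blocks:
            if family_of is None:
                source_start = int(rng.integers(0, pos - unit + 1))
            else:
                fam = int(family_of[block])
                if fam not in family_anchor:
                    # anchor the family on a completed background block
                    family_anchor[fam] = int(
                        background_starts[int(rng.integers(0, len(background_starts)))]
                    )
                source_start = family_anchor[fam]
            chunk = codes_so_far[source_start : source_start + unit].copy()
            annotations.append((pos, pos + unit, source_start))
        else:
            chunk = rng.integers(0, 4, size=unit, dtype=np.uint8)
            if unit == repeat_unit_len:
                background_starts.append(pos)
        chunks.append(chunk)
        codes_so_far = np.concatenate([codes_so_far, chunk])
        pos += unit
    sequence = _CODE_BASE[codes_so_far].tobytes().decode("ascii")
    return SyntheticGenome(sequence=sequence, repeat_annotations=annotations)


def error_rates_from_accuracy(accuracy: float) -> tuple[float, float, float]:
    """Split a per-base error budget ``1 - accuracy`` into substitution,
    insertion and deletion rates (half substitutions, a quarter each
    indel class)."""
    if not 0 < accuracy <= 1:
        raise ValueError("accuracy must be in (0, 1]")
    err = 1.0 - accuracy
    return 0.5 * err, 0.25 * err, 0.25 * err


def _apply_errors(
    codes: np.ndarray,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent per-base substitution, then insertion/deletion."""
    n = codes.size
    out = codes.copy()
    if sub_rate > 0:
        mask = rng.random(n) < sub_rate
        if mask.any():
            # add 1..3 mod 4: always a *different* base
            out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)) % 4
    if ins_rate > 0 or del_rate > 0:
        r = rng.random(n)
        del_mask = r < del_rate
        ins_mask = (r >= del_rate) & (r < del_rate + ins_rate)
        counts = np.ones(n, dtype=np.int64) - del_mask + ins_mask
        expanded = np.repeat(out, counts)
        if ins_mask.any():
            # position of the duplicated slot following each insertion site
            slot = np.cumsum(counts)[ins_mask] - 1
            expanded[slot] = rng.integers(0, 4, size=int(ins_mask.sum()), dtype=np.uint8)
        out = expanded
    return out


def simulate_reads(
    genome: SyntheticGenome,
    depth: float = 30.0,
    mean_len: int = 20_000,
    len_sd: int | None = None,
    sub_rate: float = 0.025,
    ins_rate: float = 0.0125,
    del_rate: float = 0.0125,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[TruthRead]]:
    """Sample error-bearing reads from a genome until the requested depth.

    Read lengths follow a truncated normal (``len_sd`` defaults to 15% of
    ``mean_len``, floor 500 bp, cap at genome length); start positions and
    strands are uniform. Errors are applied after extraction, so the truth
    record holds the error-free source interval. Total emitted bases land
    within ~10% of ``depth * len(genome)``. Deterministic per seed.

    Returns ``(reads, truth)`` with ``reads`` a list of
    ``(read_id, sequence)`` pairs parallel to ``truth``.
    """
    glen = len(genome)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if mean_len > glen:
        raise ValueError(f"mean_len {mean_len} exceeds genome length {glen}")
    for name, rate in (("sub_rate", sub_rate), ("ins_rate", ins_rate), ("del_rate", del_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if len_sd is None:
        len_sd = max(1, int(0.15 * mean_len))
    rng = np.random.default_rng(seed)
    genome_codes = encode(genome.sequence)
    target_bases = depth * glen
    min_len = min(MIN_READ_LEN, glen)
    reads: list[tuple[str, str]] = []
    truth: list[TruthRead] = []
    total = 0
    i = 0
    while total < target_bases:
        length = int(np.clip(rng.normal(mean_len, len_sd), min_len, glen))
        start = int(rng.integers(0, glen - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = genome_codes[start : start + length]
        if strand == "-":
            fragment = 3 - fragment[::-1]
        emitted = _apply_errors(fragment, sub_rate, ins_rate, del_rate, rng)
        seq = _CODE_BASE[emitted].tobytes().decode("ascii")
        read_id = f"read{i:06d}"
        reads.append((read_id, seq))
        truth.append(
            TruthRead(
                read_id=read_id,
                ref_start=start,
                ref_end=start + length,
                strand=strand,
                length=len(seq),
            )
        )
        total += len(seq)
        i += 1
    return reads, truth


def truth_reference_graph(truth: Sequence[TruthRead], min_overlap: int = 1) -> ReferenceGraph:
    """Ground-truth overlap graph from simulated read placements.

    For every pair of reads whose source intervals intersect by at least
    ``min_overlap`` bases, oriented edges are added: (A+, B+) and (A-, B-)
    when strands match, (A+, B-) and (A-, B+) otherwise. Edge size is the
    interval-intersection length. All reads are retained (no filters apply
    to simulated truth).
    """
    if not truth:
        raise ValueError("truth table is empty")
    intervals = [(i, t.ref_start, t.ref_end, t.strand) for i, t in enumerate(truth)]
    edges = oriented_interval_edges(intervals, min_overlap=min_overlap)
    return ReferenceGraph(
        n_reads=len(truth),
        edges=edges,
        retained=set(range(len(truth))),
        read_names=[t.read_id for t in truth],
        min_overlap=min_overlap,
    )


# ---------------------------------------------------------------------------
# Text output
# ---------------------------------------------------------------------------


def _open_text(path: str | os.PathLike, mode: str):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | os.PathLike, quality: str = "I") -> None:
    """Write reads as FASTQ with a constant Phred+33 quality character."""
    with _open_text(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality * len(seq)}\n")


def write_truth(truth: Sequence[TruthRead], path: str | os.PathLike) -> None:
    """Write the truth table as TSV (read_id, ref_start, ref_end, strand, length)."""
    with _open_text(path, "w") as fh:
        fh.write("read_id\tref_start\tref_end\tstrand\tlength\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.ref_start}\t{t.ref_end}\t{t.strand}\t{t.length}\n")


def read_truth(path: str | os.PathLike) -> list[TruthRead]:
    """Read a truth TSV written by :func:`write_truth`."""
    truth: list[TruthRead] = []
    with _open_text(path, "r") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["read_id", "ref_start", "ref_end", "strand", "length"]:
            raise ValueError(f"{path}: not a truth table (header {header!r})")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            truth.append(
                TruthRead(
                    read_id=fields[0],
                    ref_start=int(fields[1]),
                    ref_end=int(fields[2]),
                    strand=fields[3],
                    length=int(fields[4]),
                )
            )
    return truth
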