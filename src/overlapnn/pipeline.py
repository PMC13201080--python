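"""End-to-end orchestration: reads in, candidate overlaps and metrics out.

``run_overlap`` executes the full detection pipeline — canonical k-mer
counting, low-frequency filtering, alphabet sampling, IDF weighting,
fused sparse random projection streamed over batches, k-NN search — and
writes the candidate TSV plus a JSON run log. ``run_evaluate`` scores a
candidate table against a truth table or PAF reference. ``run_simulate``
wraps the synthetic-read generator.
"""

from __future__ import annotations

import gzip
import json
import os
import time
from dataclasses import asdict, dataclass, field, fields

from . import dimred, evaluate, features, knn, simulate
from .graph import NeighborTable, build_overlap_graph, read_candidates, write_candidates

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PRESETS",
    "run_overlap",
    "run_evaluate",
    "run_simulate",
    "read_sequences",
]

# platform presets: k-mer size tracks the platform's error profile
PRESETS = {"hifi": 31, "ont": 13, "cyclone": 11}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration surface of the overlap pipeline.

    Defaults follow the recommended large-genome settings: 20 output
    neighbors, 1,000 embedding dimensions, 15% k-mer sampling, 600
    NNDescent trees, batches of 100,000 reads. ``k_mer_size`` defaults to
    the ONT preset (13); use 31 for HiFi and 11 for CycloneSEQ.
    ``density=None`` means the SRP default 1/sqrt(alphabet size).
    """

    k_mer_size: int = 13
    min_count: int = 2
    sampling_fraction: float = 0.15
    dims: int = 1000
    density: float | None = None
    n_neighbors: int = 20
    n_trees: int = 600
    batch_size: int = 100_000
    metric: str = "cosine"
    scheme: str = "idf"
    seed: int = 0
    backend: str = "nndescent"

    def __post_init__(self) -> None:
        if self.k_mer_size < 3:
            raise ValueError("k_mer_size must be >= 3")
        if self.k_mer_size > 31:
            raise ValueError("k_mer_size must be <= 31 (64-bit k-mer codes)")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.density is not None and not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.dims < 1 or self.n_neighbors < 1 or self.batch_size < 1:
            raise ValueError("dims, n_neighbors and batch_size must be >= 1")
        if self.metric not in knn.METRICS:
            raise ValueError(f"metric must be one of {knn.METRICS}")
        if self.scheme not in features.SCHEMES:
            raise ValueError(f"scheme must be one of {features.SCHEMES}")
        if self.backend not in ("exact", "nndescent"):
            raise ValueError("backend must be 'exact' or 'nndescent'")

    def to_file(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            for f in fields(self):
                value = getattr(self, f.name)
                fh.write(f"{f.name} = {'' if value is None else value}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f for f in fields(cls)}
        with open(os.fspath(path)) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                if value == "":
                    kwargs[key] = None
                elif key in ("sampling_fraction", "density"):
                    kwargs[key] = float(value)
                elif key in ("metric", "scheme", "backend"):
                    kwargs[key] = value
                else:
                    kwargs[key] = int(value)
        return cls(**kwargs)


def read_sequences(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA/FASTQ (plain or gzipped) into (name, sequence) pairs."""
    from Bio import SeqIO

    path = os.fspath(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            return []
        else:
            raise PipelineError(f"input: {path} is neither FASTA nor FASTQ")
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def run_overlap(
    reads_path: str | os.PathLike,
    config: PipelineConfig,
    out: str | os.PathLike,
    log_path: str | os.PathLike | None = None,
) -> NeighborTable:
    """Run the full overlap-detection pipeline on a FASTA/FASTQ file.

    Writes the candidate TSV to ``out`` (with its names sidecar) and a
    machine-readable JSON run log with stage timings, alphabet size and
    flagged reads.
    """
    log: dict = {"config": asdict(config), "stages": {}}

    def stage(name: str):
        return _StageTimer(name, log)

    with stage("read_input"):
        reads = read_sequences(reads_path)
    if not reads:
        raise PipelineError("read_input: no sequences found in input")
    if len(reads) < 2:
        raise PipelineError("read_input: need at least 2 reads to find neighbors")
    log["n_reads"] = len(reads)

    with stage("count_kmers"):
        table = features.count_kmers(reads, k=config.k_mer_size)
    with stage("alphabet"):
        try:
            alphabet = features.filter_and_sample(
                table,
                min_count=config.min_count,
                fraction=config.sampling_fraction,
                seed=config.seed,
            )
        except features.EmptyAlphabetError as exc:
            raise PipelineError(f"alphabet: {exc}") from exc
    log["alphabet_size"] = len(alphabet)

    with stage("projection"):
        idf = features.idf_weights(table, alphabet)
        proj = dimred.srp_matrix(
            m=len(alphabet), d=config.dims, density=config.density, seed=config.seed
        )
        use_idf = config.scheme in ("idf", "tf_idf")
        matrix = dimred.fuse(proj, idf) if use_idf else proj
        # IDF is applied inside the fused projection; batches carry the
        # unweighted scheme
        batch_scheme = {"idf": "binary", "tf_idf": "tf"}.get(config.scheme, config.scheme)

    with stage("embed"):
        flagged: set[int] = set()

        def batches():
            for batch in features.iter_feature_batches(
                reads, alphabet, scheme=batch_scheme, batch_size=config.batch_size
            ):
                flagged.update(batch.flagged)
                yield batch

        emb = dimred.project_stream(batches(), matrix, read_names=[r[0] for r in reads])
    log["flagged_reads"] = sorted(reads[i][0] for i in flagged)

    with stage("knn"):
        if config.backend == "exact":
            table_nn = knn.exact_knn(emb, k=config.n_neighbors, metric=config.metric)
        else:
            try:
                table_nn = knn.ann_knn(
                    emb,
                    k=config.n_neighbors,
                    n_trees=config.n_trees,
                    seed=config.seed,
                    metric=config.metric,
                )
            except knn.AnnBackendUnavailable as exc:
                raise PipelineError(f"knn: {exc}") from exc

    with stage("write_candidates"):
        write_candidates(table_nn, out)

    if log_path is None:
        log_path = f"{os.fspath(out)}.log.json"
    with open(os.fspath(log_path), "w") as fh:
        json.dump(log, fh, indent=2)
    return table_nn


class _StageTimer:
    def __init__(self, name: str, log: dict):
        self.name = name
        self.log = log

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.log["stages"][self.name] = round(time.perf_counter() - self.t0, 3)
        return False


def run_evaluate(
    candidates_path: str | os.PathLike,
    reference_path: str | os.PathLike,
    out: str | os.PathLike,
    top_j: int | None = None,
    min_overlap: int = 1,
    curve_thresholds: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    max_unknown_frac: float = 0.01,
) -> evaluate.GraphMetrics:
    """Score a candidate table against a truth TSV or PAF reference.

    Writes a flat JSON metrics report to ``out`` and the low-connectivity
    curve to ``<out>.curve.tsv``. ``top_j`` truncates candidate lists to
    the best j neighbors per oriented read before scoring. Candidate read
    names missing from the reference universe are counted; above
    ``max_unknown_frac`` the evaluation fails.
    """
    nt = read_candidates(candidates_path)
    if len(nt) == 0:
        raise PipelineError("evaluate: candidate file contains no rows")
    if top_j is not None:
        nt = nt.truncated(top_j)

    reference_path = os.fspath(reference_path)
    with open(reference_path) as fh:
        first = fh.readline()
    if first.startswith("read_id\t"):
        truth = simulate.read_truth(reference_path)
        reference = simulate.truth_reference_graph(truth, min_overlap=min_overlap)
    else:
        reference = evaluate.reference_from_paf(reference_path, min_overlap=min_overlap)

    # remap candidate read indices onto the reference's name universe
    name_to_idx = {name: i for i, name in enumerate(reference.read_names)}
    if nt.read_names is None:
        raise PipelineError("evaluate: candidate table lacks read names")
    unknown = [n for n in nt.read_names if n and n not in name_to_idx]
    if len(unknown) > max_unknown_frac * max(1, len(reference.read_names)):
        raise PipelineError(
            f"evaluate: {len(unknown)} candidate read names unknown to the reference "
            f"(e.g. {unknown[0]!r})"
        )
    remap = {
        old: name_to_idx[name]
        for old, name in enumerate(nt.read_names)
        if name in name_to_idx
    }

    from .graph import OrientedRead

    queries: list[OrientedRead] = []
    lists: list[list[tuple[OrientedRead, float]]] = []
    for q, lst in zip(nt.queries, nt.neighbor_lists):
        if q.read_index not in remap:
            continue
        queries.append(OrientedRead(remap[q.read_index], q.orientation))
        lists.append(
            [
                (OrientedRead(remap[nb.read_index], nb.orientation), dist)
                for nb, dist in lst
                if nb.read_index in remap
            ]
        )
    nt = NeighborTable(
        k=nt.k, queries=queries, neighbor_lists=lists, read_names=reference.read_names
    )
    graph = build_overlap_graph(nt, n_reads=reference.n_reads)
    try:
        metrics = evaluate.score_graph(graph, reference)
    except evaluate.GraphScoringError as exc:
        raise PipelineError(f"evaluate: {exc}") from exc
    curve = evaluate.low_connectivity_curve(
        metrics, curve_thresholds, retained=reference.retained
    )
    report = metrics.to_dict()
    report["n_unknown_read_names"] = len(unknown)
    with open(os.fspath(out), "w") as fh:
        json.dump(report, fh, indent=2)
    with open(f"{os.fspath(out)}.curve.tsv", "w") as fh:
        fh.write("coc_threshold\tlow_connectivity_fraction\n")
        for t, frac in zip(curve_thresholds, curve):
            fh.write(f"{t}\t{frac:.6f}\n")
    return metrics


def run_simulate(
    out_fastq: str | os.PathLike,
    out_truth: str | os.PathLike,
    genome_length: int = 500_000,
    repeat_fraction: float = 0.2,
    repeat_unit_len: int = 2000,
    depth: float = 30.0,
    mean_len: int = 20_000,
    accuracy: float = 0.95,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[simulate.TruthRead]]:
    """Generate a synthetic dataset and write FASTQ + truth TSV."""
    genome = simulate.generate_genome(
        genome_length,
        repeat_fraction=repeat_fraction,
        repeat_unit_len=repeat_unit_len,
        seed=seed,
    )
    sub, ins, dele = simulate.error_rates_from_accuracy(accuracy)
    reads, truth = simulate.simulate_reads(
        genome,
        depth=depth,
        mean_len=mean_len,
        sub_rate=sub,
        ins_rate=ins,
        del_rate=dele,
        seed=seed + 1,
    )
    simulate.write_fastq(reads, out_fastq)
    simulate.write_truth(truth, out_truth)
    return reads, truth
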