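"""Shared fixtures: synthetic datasets at the study conditions.

The main dataset emulates a mid-size long-read experiment: a 500 kb
genome with 20% repeat content, 30x depth, 20 kb mean reads at 95%
accuracy (errors split half substitutions, a quarter each indel class).
Session-scoped so the expensive counting/featurization happens once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from overlapnn import dimred, evaluate, features, graph, knn, simulate


@dataclass
class Dataset:
    genome: simulate.SyntheticGenome
    reads: list[tuple[str, str]]
    truth: list[simulate.TruthRead]
    k: int
    table: features.KmerCountTable
    alphabet: features.KmerAlphabet
    idf: features.IdfWeights

    @property
    def read_names(self) -> list[str]:
        return [r[0] for r in self.reads]


def make_dataset(
    genome_length: int,
    repeat_fraction: float,
    repeat_unit_len: int,
    depth: float,
    mean_len: int,
    accuracy: float,
    seed: int,
    k: int = 13,
    min_count: int = 2,
    sampling_fraction: float = 0.15,
    repeat_families: int | None = None,
) -> Dataset:
    genome = simulate.generate_genome(
        genome_length, repeat_fraction, repeat_unit_len, seed=seed,
        repeat_families=repeat_families,
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
    table = features.count_kmers(reads, k, track_df=True)
    alphabet = features.filter_and_sample(
        table, min_count=min_count, fraction=sampling_fraction, seed=seed + 2
    )
    idf = features.idf_weights(table, alphabet)
    return Dataset(
        genome=genome, reads=reads, truth=truth, k=k,
        table=table, alphabet=alphabet, idf=idf,
    )


def embed(ds: Dataset, scheme: str = "idf", d: int = 1000, seed: int = 7,
          batch_size: int = 100_000) -> dimred.Embeddings:
    """Project a dataset's features the way the streamed pipeline does:
    IDF folded into the projection, batches carrying the unweighted
    scheme."""
    proj = dimred.srp_matrix(len(ds.alphabet), d, seed=seed)
    use_idf = scheme in ("idf", "tf_idf")
    matrix = dimred.fuse(proj, ds.idf) if use_idf else proj
    batch_scheme = {"idf": "binary", "tf_idf": "tf"}.get(scheme, scheme)
    batches = features.iter_feature_batches(
        ds.reads, ds.alphabet, scheme=batch_scheme, batch_size=batch_size
    )
    return dimred.project_stream(batches, matrix, read_names=ds.read_names)


def error_rate_of(ds: Dataset, emb: dimred.Embeddings, k: int = 6,
                  metric: str = "cosine") -> float:
    nt = knn.exact_knn(emb, k=k, metric=metric)
    og = graph.build_overlap_graph(nt, n_reads=len(ds.reads))
    ref = simulate.truth_reference_graph(ds.truth)
    return evaluate.score_graph(og, ref).error_rate


@pytest.fixture(scope="session")
def ds_main() -> Dataset:
    """500 kb / 20% repeats / 30x / 20 kb / 95% accuracy."""
    return make_dataset(500_000, 0.2, 2000, depth=30, mean_len=20_000,
                        accuracy=0.95, seed=0)


@pytest.fixture(scope="session")
def ds_main_embeddings(ds_main: Dataset) -> dimred.Embeddings:
    return embed(ds_main, scheme="idf", d=1000, seed=7)


@pytest.fixture(scope="session")
def ds_repeatrich() -> Dataset:
    """Repeat-rich dataset (40% repeats in 3 high-multiplicity families,
    ~13 copies each, like immunogene clusters) where weighting schemes
    separate: 300 kb / 20x / 12 kb / 92% accuracy."""
    return make_dataset(300_000, 0.4, 3000, depth=20, mean_len=12_000,
                        accuracy=0.92, seed=40, repeat_families=3)


@pytest.fixture(scope="session")
def ds_knn() -> Dataset:
    """Many short reads -> ~5,000 oriented vectors for ANN contracts:
    500 kb / 20x / 4 kb / 95% accuracy."""
    return make_dataset(500_000, 0.2, 2000, depth=20, mean_len=4_000,
                        accuracy=0.95, seed=60)


@pytest.fixture(scope="session")
def ds_knn_embeddings(ds_knn: Dataset) -> dimred.Embeddings:
    return embed(ds_knn, scheme="idf", d=512, seed=61)


@pytest.fixture(scope="session")
def tiny_dataset() -> Dataset:
    """Small, fast dataset for pipeline/CLI round trips:
    60 kb / 15x / 6 kb / 95% accuracy."""
    return make_dataset(60_000, 0.2, 1500, depth=15, mean_len=6_000,
                        accuracy=0.95, seed=80)
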