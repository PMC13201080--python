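"""Canonical k-mer counting, alphabet sampling, IDF weights and feature
rows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overlapnn import features
from overlapnn.diagnostics import cf_df_r2
from overlapnn.features import (
    EmptyAlphabetError,
    KmerAlphabet,
    canonical,
    count_kmers,
    featurize_batch,
    filter_and_sample,
    idf_weights,
    kmer_code,
    revcomp,
)

dna = st.text(alphabet="ACGT", min_size=3, max_size=25)


class TestCanonical:
    @pytest.mark.parametrize(
        "kmer, expected",
        [("ACG", "ACG"), ("CGT", "ACG"), ("AT", "AT"), ("TTT", "AAA")],
    )
    def test_examples(self, kmer, expected):
        assert canonical(kmer) == expected

    @settings(derandomize=True, max_examples=200)
    @given(dna)
    def test_idempotent_and_strand_symmetric(self, kmer):
        c = canonical(kmer)
        assert canonical(c) == c
        assert canonical(revcomp(kmer)) == c
        assert c <= revcomp(c)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            canonical("ANG")


class TestCountKmers:
    def test_hand_enumeration(self):
        table = count_kmers(["ACGTA"], k=3)
        # windows ACG, CGT (canonical ACG), GTA
        assert table.counts == {"ACG": 2, "GTA": 1}
        assert table.n_reads == 1

    def test_palindrome_counted_per_read(self):
        table = count_kmers(["ACGT", "ACGT"], k=4)
        assert table.counts == {"ACGT": 2}

    def test_masked_windows_skipped(self):
        table = count_kmers(["ANGT"], k=3)
        assert table.counts == {}
        assert table.n_reads == 1

    def test_empty_input(self):
        table = count_kmers([], k=5)
        assert len(table) == 0
        assert table.n_reads == 0

    def test_document_frequencies(self):
        table = count_kmers(["ACGACG", "ACGT"], k=3, track_df=True)
        # read 1 windows ACG, CGA, GAC, ACG; read 2 windows ACG, CGT -> ACG:
        # canonical ACG occurs 4 times across 2 reads
        assert table.counts["ACG"] == 4
        assert table.document_frequencies["ACG"] == 2

    def test_cf_upper_bounds_df(self, ds_main):
        assert (ds_main.table.cf >= ds_main.table.df).all()

    def test_cf_df_log_r2_on_reads(self, ds_main):
        r2, n = cf_df_r2(ds_main.table, min_count=2)
        assert n > 100_000
        assert r2 > 0.99


class TestFilterAndSample:
    def _table(self, counts: dict[str, int], n_reads=10, k=3):
        kmers = sorted(counts, key=kmer_code)
        return features.KmerCountTable(
            k=k,
            codes=np.array([kmer_code(m) for m in kmers], dtype=np.uint64),
            cf=np.array([counts[m] for m in kmers], dtype=np.int64),
            n_reads=n_reads,
        )

    def test_filter_only(self):
        table = self._table({"AAA": 1, "ACC": 5, "AGG": 9})
        alphabet = filter_and_sample(table, min_count=2, fraction=1.0, seed=0)
        assert alphabet.kmers == ["ACC", "AGG"]

    def test_identity(self):
        table = self._table({"AAA": 1, "ACC": 5, "AGG": 9})
        alphabet = filter_and_sample(table, min_count=1, fraction=1.0, seed=0)
        assert alphabet.kmers == ["AAA", "ACC", "AGG"]

    def test_sampled_size_is_floor_of_fraction(self, ds_main):
        survivors = int((ds_main.table.cf >= 2).sum())
        assert len(ds_main.alphabet) == int(0.15 * survivors)

    def test_deterministic(self, ds_main):
        again = filter_and_sample(ds_main.table, min_count=2, fraction=0.15, seed=2)
        assert np.array_equal(again.codes, ds_main.alphabet.codes)

    def test_empty_after_filter_raises(self):
        table = self._table({"AAA": 1})
        with pytest.raises(EmptyAlphabetError):
            filter_and_sample(table, min_count=5, fraction=1.0, seed=0)


class TestIdfWeights:
    def _one_column_table(self, cf, n_reads):
        return features.KmerCountTable(
            k=3,
            codes=np.array([kmer_code("ACG")], dtype=np.uint64),
            cf=np.array([cf], dtype=np.int64),
            n_reads=n_reads,
        )

    def test_zero_when_cf_equals_n_reads(self):
        table = self._one_column_table(100, 100)
        alphabet = KmerAlphabet(k=3, codes=table.codes.copy())
        assert idf_weights(table, alphabet).weights[0] == 0.0

    def test_natural_log_unit(self):
        table = self._one_column_table(37, 100)
        alphabet = KmerAlphabet(k=3, codes=table.codes.copy())
        w = idf_weights(table, alphabet).weights[0]
        assert w == pytest.approx(np.log(100 / 37))

    def test_strictly_decreasing_in_cf(self, ds_main):
        idf = ds_main.idf
        cf = ds_main.table.cf[np.searchsorted(ds_main.table.codes, ds_main.alphabet.codes)]
        order = np.argsort(cf, kind="stable")
        sorted_cf = cf[order]
        sorted_w = idf.weights[order]
        distinct = np.diff(sorted_cf) > 0
        assert (np.diff(sorted_w)[distinct] < 0).all()

    def test_missing_kmer_raises(self):
        table = self._one_column_table(5, 10)
        alphabet = KmerAlphabet(k=3, codes=np.array([kmer_code("AAA")], dtype=np.uint64))
        with pytest.raises(ValueError, match="absent"):
            idf_weights(table, alphabet)


def _alphabet_of(*kmers: str) -> KmerAlphabet:
    codes = np.array(sorted(kmer_code(m) for m in kmers), dtype=np.uint64)
    return KmerAlphabet(k=len(kmers[0]), codes=codes)


class TestFeaturizeBatch:
    def test_binary_orientation_rows(self):
        alphabet = _alphabet_of("ACG")
        batch = featurize_batch([("r0", "ACGACG")], alphabet, scheme="binary")
        rows = batch.rows.toarray()
        assert rows[0].tolist() == [1.0]  # + row: ACG occurs literally
        assert rows[1].tolist() == [0.0]  # - row: CGTCGT has no literal ACG
        assert batch.row_ids[0].orientation == "+"
        assert batch.row_ids[1].orientation == "-"

    def test_raw_tf_counts_occurrences(self):
        alphabet = _alphabet_of("ACG")
        batch = featurize_batch([("r0", "ACGACG")], alphabet, scheme="raw_tf")
        assert batch.rows.toarray()[0].tolist() == [2.0]

    def test_tf_normalizes_by_row_total(self):
        alphabet = _alphabet_of("ACG", "CGA")
        batch = featurize_batch([("r0", "ACGACG")], alphabet, scheme="tf")
        row = batch.rows.toarray()[0]
        # + row occurrences: ACG x2, CGA x1 -> 2/3, 1/3
        assert row == pytest.approx(
            np.array([2 / 3, 1 / 3])[np.argsort([kmer_code("ACG"), kmer_code("CGA")])]
        )

    def test_zero_row_flagged(self):
        alphabet = _alphabet_of("AAAAA")
        batch = featurize_batch([("short", "ACG"), ("nomatch", "CGCGCGCG")], alphabet)
        assert batch.flagged == {0, 1}
        assert batch.rows.nnz == 0

    def test_idf_scheme_scales_binary(self):
        alphabet = _alphabet_of("ACG")
        w = features.IdfWeights(weights=np.array([2.5]))
        batch = featurize_batch([("r0", "ACGACG")], alphabet, scheme="idf", idf=w)
        assert batch.rows.toarray()[0].tolist() == [2.5]

    def test_idf_scheme_requires_weights(self):
        alphabet = _alphabet_of("ACG")
        with pytest.raises(ValueError, match="requires IDF"):
            featurize_batch([("r0", "ACGACG")], alphabet, scheme="idf")

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=60), st.integers(0, 2**31 - 1))
    def test_minus_row_equals_plus_row_of_revcomp(self, seq, seed):
        rng = np.random.default_rng(seed)
        # alphabet: canonical forms of a few windows of the sequence
        starts = rng.integers(0, len(seq) - 5, size=4)
        kmers = {canonical(seq[s : s + 5]) for s in starts}
        alphabet = _alphabet_of(*kmers)
        fwd = featurize_batch([("a", seq)], alphabet, scheme="raw_tf")
        rev = featurize_batch([("a_rc", revcomp(seq))], alphabet, scheme="raw_tf")
        assert np.array_equal(fwd.rows.toarray()[1], rev.rows.toarray()[0])

    def test_batch_row_ids_interleaved(self, ds_main):
        batch = featurize_batch(ds_main.reads[:3], ds_main.alphabet)
        assert [(r.read_index, r.orientation) for r in batch.row_ids] == [
            (0, "+"), (0, "-"), (1, "+"), (1, "-"), (2, "+"), (2, "-"),
        ]


class TestKmerDumpImport:
    def test_merges_reverse_complements(self, tmp_path):
        dump = tmp_path / "dump.txt"
        dump.write_text("ACG 3\nCGT 2\nGTA 1\n")
        table = features.read_kmer_dump(dump, k=3, n_reads=4)
        assert table.counts == {"ACG": 5, "GTA": 1}
        assert table.n_reads == 4
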