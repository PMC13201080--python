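"""Reference graphs from PAF, metric computation, low-connectivity curve."""

import pytest

from overlapnn import evaluate
from overlapnn.evaluate import (
    GraphScoringError,
    PafParseError,
    low_connectivity_curve,
    reference_from_paf,
    score_graph,
)
from overlapnn.graph import FORWARD, REVERSE, OrientedRead, OverlapGraph, edge_key


def _paf_line(qname, qlen, qstart, qend, strand, tstart, tend, mapq, tags=""):
    nmatch = qend - qstart
    fields = [
        qname, str(qlen), str(qstart), str(qend), strand,
        "chr1", "1000000", str(tstart), str(tend),
        str(nmatch), str(qend - qstart), str(mapq),
    ]
    if tags:
        fields.append(tags)
    return "\t".join(fields) + "\n"


class TestReferenceFromPaf:
    def test_same_strand_overlap(self, tmp_path):
        paf = tmp_path / "aln.paf"
        paf.write_text(
            _paf_line("A", 10_000, 0, 10_000, "+", 0, 10_000, 60)
            + _paf_line("B", 10_000, 0, 10_000, "+", 5000, 15_000, 60)
        )
        ref = reference_from_paf(paf)
        expected = {
            edge_key(OrientedRead(0, FORWARD), OrientedRead(1, FORWARD)): 5000,
            edge_key(OrientedRead(0, REVERSE), OrientedRead(1, REVERSE)): 5000,
        }
        assert ref.edges == expected
        assert ref.retained == {0, 1}

    def test_opposite_strand_rule(self, tmp_path):
        paf = tmp_path / "aln.paf"
        paf.write_text(
            _paf_line("A", 10_000, 0, 10_000, "+", 0, 10_000, 60)
            + _paf_line("B", 10_000, 0, 10_000, "-", 5000, 15_000, 60)
        )
        ref = reference_from_paf(paf)
        assert set(ref.edges) == {
            edge_key(OrientedRead(0, FORWARD), OrientedRead(1, REVERSE)),
            edge_key(OrientedRead(0, REVERSE), OrientedRead(1, FORWARD)),
        }

    def test_short_read_filtered(self, tmp_path):
        paf = tmp_path / "aln.paf"
        paf.write_text(
            _paf_line("short", 4000, 0, 4000, "+", 0, 4000, 60)
            + _paf_line("B", 10_000, 0, 10_000, "+", 0, 10_000, 60)
        )
        ref = reference_from_paf(paf)
        assert 0 not in ref.retained and 1 in ref.retained
        assert ref.edges == {}

    def test_low_mapq_filtered(self, tmp_path):
        paf = tmp_path / "aln.paf"
        paf.write_text(_paf_line("A", 10_000, 0, 10_000, "+", 0, 10_000, 10))
        ref = reference_from_paf(paf)
        assert ref.retained == set()

    def test_low_aligned_fraction_filtered(self, tmp_path):
        paf = tmp_path / "aln.paf"
        paf.write_text(_paf_line("A", 10_000, 0, 4000, "+", 0, 4000, 60))
        ref = reference_from_paf(paf)
        assert ref.retained == set()

    def test_secondary_records_ignored(self, tmp_path):
        paf = tmp_path / "aln.paf"
        paf.write_text(
            _paf_line("A", 10_000, 0, 10_000, "+", 0, 10_000, 60, tags="tp:A:P")
            + _paf_line("A", 10_000, 0, 10_000, "+", 500_000, 510_000, 60, tags="tp:A:S")
        )
        ref = reference_from_paf(paf)
        assert ref.retained == {0}

    def test_best_primary_kept_by_mapq_then_length(self, tmp_path):
        paf = tmp_path / "aln.paf"
        paf.write_text(
            _paf_line("A", 10_000, 0, 6000, "+", 100, 6100, 40)
            + _paf_line("A", 10_000, 0, 10_000, "+", 200_000, 210_000, 60)
            + _paf_line("B", 10_000, 0, 10_000, "+", 205_000, 215_000, 60)
        )
        ref = reference_from_paf(paf)
        # A's MAPQ-60 alignment wins; it overlaps B by 5 kb
        assert ref.edges[edge_key(OrientedRead(0, FORWARD), OrientedRead(1, FORWARD))] == 5000

    def test_malformed_line_named(self, tmp_path):
        paf = tmp_path / "aln.paf"
        paf.write_text("only\tthree\tcolumns\n")
        with pytest.raises(PafParseError, match=":1"):
            reference_from_paf(paf)


def _ref(n_reads, edges, retained=None):
    return evaluate.ReferenceGraph(
        n_reads=n_reads,
        edges=edges,
        retained=set(range(n_reads)) if retained is None else retained,
        read_names=[f"r{i}" for i in range(n_reads)],
    )


def _graph(n_reads, keys, k=6):
    return OverlapGraph(
        n_reads=n_reads, k=k, edges={key: (1, 0.1) for key in keys}
    )


def _fkey(i, j):
    return edge_key(OrientedRead(i, FORWARD), OrientedRead(j, FORWARD))


class TestScoreGraph:
    def test_error_rate_arithmetic(self):
        ref_edges = {_fkey(i, i + 1): 1000 for i in range(8)}
        graph_keys = list(ref_edges) + [_fkey(0, 9), _fkey(2, 9)]
        metrics = score_graph(_graph(10, graph_keys), _ref(10, ref_edges))
        assert metrics.error_rate == pytest.approx(0.2)
        assert metrics.n_edges == 10
        assert metrics.n_correct_edges == 8

    def test_mean_overlap_counts_incorrect_as_zero(self):
        ref_edges = {_fkey(0, 1): 2000, _fkey(1, 2): 1000}
        graph_keys = list(ref_edges) + [_fkey(0, 3)]
        metrics = score_graph(_graph(4, graph_keys), _ref(4, ref_edges))
        assert metrics.mean_overlap_size == pytest.approx(1000.0)

    def test_connected_components_hand_counted(self):
        # 3 reads (6 vertices): triangle on (0+,1+,2+), pair (0-,1-); the
        # remaining vertex 2- is isolated -> 3 components
        tri = [_fkey(0, 1), _fkey(1, 2), _fkey(0, 2)]
        pair = [edge_key(OrientedRead(0, REVERSE), OrientedRead(1, REVERSE))]
        ref_edges = {key: 500 for key in tri + pair}
        metrics = score_graph(_graph(3, tri + pair), _ref(3, ref_edges))
        assert metrics.n_cc == 3
        assert metrics.n_singletons == 1

    def test_zero_edge_graph_rejected(self):
        with pytest.raises(GraphScoringError):
            score_graph(_graph(4, []), _ref(4, {}))

    def test_vertex_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            score_graph(_graph(4, [_fkey(0, 1)]), _ref(5, {}))

    def test_reference_identical_graph_is_perfect(self):
        ref_edges = {_fkey(i, i + 1): 700 for i in range(5)}
        metrics = score_graph(_graph(6, list(ref_edges)), _ref(6, ref_edges))
        assert metrics.error_rate == 0.0
        assert metrics.mean_overlap_size == pytest.approx(700.0)
        # 6 forward vertices form a path; 6 reverse vertices isolated
        assert metrics.n_singletons == 6
        assert metrics.n_cc == 1 + 6

    def test_error_rate_monotone_in_reference_permissiveness(self):
        graph_keys = [_fkey(0, 1), _fkey(1, 2), _fkey(2, 3), _fkey(0, 3)]
        small = {_fkey(0, 1): 100}
        grown = dict(small)
        rates = []
        for extra in [None, _fkey(1, 2), _fkey(2, 3)]:
            if extra is not None:
                grown[extra] = 100
            rates.append(score_graph(_graph(4, graph_keys), _ref(4, dict(grown))).error_rate)
        assert rates == sorted(rates, reverse=True)

    def test_filtered_reads_contribute_only_incorrect_edges(self):
        ref_edges = {_fkey(0, 1): 900}
        graph_keys = [_fkey(0, 1), _fkey(1, 3)]
        metrics = score_graph(
            _graph(4, graph_keys), _ref(4, ref_edges, retained={0, 1, 2})
        )
        assert metrics.n_correct_edges == 1
        assert metrics.n_vertices_retained == 6
        # n_cc over retained vertices only; n_cc_all adds read 3's two isolates
        assert metrics.n_cc_all == metrics.n_cc + 2


class TestLowConnectivityCurve:
    def _metrics(self, coc_values):
        coc = {OrientedRead(i, FORWARD): v for i, v in enumerate(coc_values)}
        return evaluate.GraphMetrics(
            error_rate=0.0, mean_overlap_size=0.0, coc=coc, n_singletons=0,
            n_cc=1, n_cc_all=1, n_edges=1, n_correct_edges=1,
            n_vertices=len(coc_values), n_vertices_retained=len(coc_values),
        )

    def test_all_connected(self):
        assert low_connectivity_curve(self._metrics([6, 6, 6]), [5]) == [0.0]

    def test_all_singletons(self):
        assert low_connectivity_curve(self._metrics([0, 0]), [1, 3]) == [1.0, 1.0]

    def test_counting(self):
        assert low_connectivity_curve(self._metrics([0, 1, 5, 9]), [5]) == [0.5]
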