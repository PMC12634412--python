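"""Compacted de Bruijn graph: construction oracles, BFS metrics, GFA round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srlens.dbg import (
    GraphMetrics,
    UnitigGraph,
    UnitigNode,
    build_unitig_graph,
    canonical_kmers_of,
    compute_graph_metrics,
    count_canonical_kmers,
    export_gfa,
    mark_reference_nodes,
    parse_gfa,
    unitig_graph_from_kmers,
)
from srlens.seq import revcomp

from oracles import dbg_oracle_kmers


def _dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _tile(seq, read_len=60, step=5):
    return [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]


def _bubble_reads(rng, flank=120):
    """Two haplotypes differing by one interior SNP, both flanks >= k."""
    hap1 = _dna(rng, 2 * flank + 1)
    mid = flank
    alt = "ACGT"[("ACGT".index(hap1[mid]) + 1) % 4]
    hap2 = hap1[:mid] + alt + hap1[mid + 1 :]
    return hap1, hap2, _tile(hap1) + _tile(hap2)


class TestConstruction:
    def test_single_read_one_node(self, rng):
        read = _dna(rng, 40)
        counts = count_canonical_kmers([read], 31)
        assert len(counts) == 10  # 40 - 31 + 1
        g = build_unitig_graph([read], k=31)
        assert len(g.nodes) == 1
        assert g.nodes[0].length == 40
        assert g.links == []
        assert g.nodes[0].sequence in (read, revcomp(read))

    def test_tiling_reads_compact_to_one_node(self, rng):
        hap = _dna(rng, 1000)
        g = build_unitig_graph(_tile(hap), k=31)
        assert len(g.nodes) == 1
        assert g.nodes[0].length == 1000

    def test_snp_bubble_four_nodes_four_edges(self, rng):
        hap1, hap2, reads = _bubble_reads(rng)
        g = build_unitig_graph(reads, k=31)
        assert len(g.nodes) == 4
        lengths = sorted(n.length for n in g.nodes)
        assert lengths[:2] == [61, 61]  # the two variant unitigs, 2k-1 each
        assert len(g.undirected_edges()) == 4

    def test_min_count_filters_singletons(self, rng):
        hap = _dna(rng, 300)
        reads = _tile(hap) * 2 + [_dna(rng, 40)]  # one spurious singleton read
        g = build_unitig_graph(reads, k=31, min_count=2)
        assert len(g.nodes) == 1

    def test_short_reads_skipped_and_empty_graph(self):
        g = build_unitig_graph(["ACGT"], k=31)
        assert g.nodes == [] and g.links == []

    def test_k_validation(self):
        with pytest.raises(ValueError):
            build_unitig_graph([], k=30)
        with pytest.raises(ValueError):
            build_unitig_graph([], k=9)

    def test_string_fallback_path_matches_packed(self, rng):
        """k > 31 takes a dict-based path; compare node sets at equivalent k."""
        hap = _dna(rng, 400)
        g33 = build_unitig_graph(_tile(hap, read_len=80), k=33)
        assert len(g33.nodes) == 1 and g33.nodes[0].length == 400

    def test_mean_count_reflects_multiplicity(self, rng):
        read = _dna(rng, 50)
        g = build_unitig_graph([read] * 7, k=31)
        assert g.nodes[0].mean_count == pytest.approx(7.0)


class TestKmerConservation:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_unitigs_conserve_kmer_set(self, seed):
        rng = np.random.default_rng(seed)
        reads = [_dna(rng, int(rng.integers(15, 80))) for _ in range(rng.integers(1, 20))]
        k = 15
        g = build_unitig_graph(reads, k=k)
        from_nodes = set()
        for n in g.nodes:
            kmers = canonical_kmers_of(n.sequence, k)
            assert from_nodes.isdisjoint(kmers)  # each k-mer in exactly one node
            from_nodes |= kmers
        assert from_nodes == dbg_oracle_kmers([r for r in reads if len(r) >= k], k)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_compaction_is_maximal(self, seed):
        """No node end may have a unique extension with a unique back-extension."""
        rng = np.random.default_rng(seed)
        reads = [_dna(rng, int(rng.integers(31, 120))) for _ in range(rng.integers(1, 12))]
        k = 15
        g = build_unitig_graph(reads, k=k)
        counts = count_canonical_kmers(reads, k)

        def canon(y):
            r = revcomp(y)
            return y if y <= r else r

        def succs(y):
            return [y[1:] + b for b in "ACGT" if canon(y[1:] + b) in counts]

        owner = {}
        for n in g.nodes:
            for km in canonical_kmers_of(n.sequence, k):
                owner[km] = n.node_id
        for n in g.nodes:
            if n.circular:
                continue
            for end_seq in (n.sequence[-k:], revcomp(n.sequence[:k])):
                nxt = succs(end_seq)
                if len(nxt) == 1:
                    back = succs(revcomp(nxt[0]))
                    # a unique extension with a unique back-extension may only
                    # stay unmerged when it folds back into the same node
                    # (hairpin/circular), never into a different node
                    if len(back) == 1:
                        assert owner[canon(nxt[0])] == n.node_id


class TestReferenceMarking:
    def test_single_node_flagged(self, rng):
        hap = _dna(rng, 500)
        g = build_unitig_graph(_tile(hap), k=31)
        mark_reference_nodes(g, hap)
        assert g.reference_nodes == {g.nodes[0].node_id}

    def test_bubble_window_with_major_allele_flags_three_of_four(self, rng):
        hap1, hap2, reads = _bubble_reads(rng)
        g = build_unitig_graph(reads, k=31)
        mark_reference_nodes(g, hap1)
        assert len(g.reference_nodes) == 3
        off = [n for n in g.nodes if n.node_id not in g.reference_nodes]
        assert len(off) == 1 and off[0].length == 61  # the minor-allele branch

    def test_unrelated_window_zero_flags(self, rng):
        g = build_unitig_graph(_tile(_dna(rng, 400)), k=31)
        mark_reference_nodes(g, _dna(rng, 200))
        assert g.reference_nodes == set()

    def test_window_shorter_than_k_errors(self, rng):
        g = build_unitig_graph(_tile(_dna(rng, 400)), k=31)
        with pytest.raises(ValueError):
            mark_reference_nodes(g, "ACGT")


def _chain_graph(names):
    """Linear chain of synthetic nodes for BFS checks."""
    nodes = [UnitigNode(n, "A" * 31, 1.0) for n in names]
    links = [(a, "+", b, "+") for a, b in zip(names, names[1:])]
    return UnitigGraph(k=31, nodes=nodes, links=links)


class TestGraphMetrics:
    def test_chain_surrounding_three(self):
        """R-D-E-F-G with R the reference: D,E,F within distance 3, G outside."""
        g = _chain_graph(["R", "D", "E", "F", "G"])
        g.reference_nodes = {"R"}
        m = compute_graph_metrics(g, "w")
        assert m.graph_size == 5
        assert m.n_reference_nodes == 1
        assert m.surrounding_nodes == 3

    def test_isolated_reference_node(self):
        g = _chain_graph(["R"])
        g.reference_nodes = {"R"}
        assert compute_graph_metrics(g).surrounding_nodes == 0

    def test_all_reference(self):
        g = _chain_graph(["A", "B", "C"])
        g.reference_nodes = {"A", "B", "C"}
        m = compute_graph_metrics(g)
        assert m.surrounding_nodes == 0
        assert m.n_reference_nodes == 3

    def test_surrounding_bounded_by_offref(self, rng):
        hap1, hap2, reads = _bubble_reads(rng)
        g = build_unitig_graph(reads, k=31)
        mark_reference_nodes(g, hap1)
        m = compute_graph_metrics(g, "w")
        assert m.surrounding_nodes <= m.graph_size - m.n_reference_nodes
        assert m.surrounding_nodes == 1  # minor branch sits on the reference path
        assert m.max_offref_coverage <= m.mean_ref_node_coverage


class TestGfa:
    def _roundtrip(self, g):
        g2 = parse_gfa(export_gfa(g))
        assert g2.k == g.k
        assert [(n.node_id, n.sequence) for n in g2.nodes] == [
            (n.node_id, n.sequence) for n in g.nodes
        ]
        assert set(g2.links) == set(g.links)
        assert g2.reference_nodes == g.reference_nodes
        return g2

    def test_single_node(self, rng):
        g = build_unitig_graph([_dna(rng, 60)], k=31)
        text = export_gfa(g)
        assert text.count("\nS\t") == 1 and "\nL\t" not in text
        self._roundtrip(g)

    def test_bubble_four_s_four_l(self, rng):
        _, _, reads = _bubble_reads(rng)
        g = build_unitig_graph(reads, k=31)
        mark_reference_nodes(g, reads[0])
        text = export_gfa(g)
        assert text.count("\nS\t") == 4
        assert text.count("\nL\t") == 4
        self._roundtrip(g)

    def test_empty_graph_header_only(self):
        g = build_unitig_graph([], k=31)
        assert export_gfa(g).startswith("H\t")
        assert len(export_gfa(g).strip().splitlines()) == 1
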