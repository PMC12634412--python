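"""Fisher enrichment against an exact hypergeometric oracle, BH, gene labels."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from srlens.enrich import (
    GeneAnnotation,
    assign_gene_groups,
    fisher_enrichment,
    gene_type_recovery,
)
from scipy import stats

from oracles import bh_oracle, fisher_oracle


def _gene(gid, contig="c", start=100, end=400, cogs=("J",), gtype="CDS"):
    return GeneAnnotation(gid, contig, start, end, "+", gtype, frozenset(cogs))


WIDX = pd.DataFrame(
    [
        ("c:1-1000", "c", 0, 1000),
        ("c:501-1500", "c", 500, 1500),
        ("c:1001-2000", "c", 1000, 2000),
    ],
    columns=["window_id", "contig_id", "start0", "end0"],
)


def _records(fully_flags):
    rows = []
    for wid, (fa, fb) in fully_flags.items():
        rows.append(
            {
                "window_id": wid,
                "fully_a": fa,
                "fully_b": fb,
                "merged_full": fa and fb,
            }
        )
    return pd.DataFrame(rows)


class TestAssignGeneGroups:
    def test_midpoint_assignment_earliest_window(self):
        records = _records({"c:1-1000": (True, True), "c:501-1500": (False, False)})
        # midpoint 250 lies only in the first window
        labels = assign_gene_groups([_gene("g1")], records, WIDX, mode="merged")
        assert labels["g1"] == "fully"
        # midpoint 750 lies in both; the earlier window wins
        labels = assign_gene_groups(
            [_gene("g2", start=600, end=900)], records, WIDX, mode="merged"
        )
        assert labels["g2"] == "fully"

    def test_merged_vs_per_assembly_modes(self):
        records = _records({"c:1-1000": (True, False)})
        gene = _gene("g1")
        assert assign_gene_groups([gene], records, WIDX, mode="merged")["g1"] == "not_fully"
        assert assign_gene_groups([gene], records, WIDX, mode="a")["g1"] == "fully"
        assert assign_gene_groups([gene], records, WIDX, mode="b")["g1"] == "not_fully"

    def test_outside_retained_set_unassigned(self):
        records = _records({"c:1-1000": (True, True)})
        labels = assign_gene_groups(
            [_gene("g1")], records, WIDX, mode="merged", retained=set()
        )
        assert labels["g1"] == "unassigned"

    def test_unknown_contig_errors(self):
        records = _records({"c:1-1000": (True, True)})
        with pytest.raises(ValueError, match="unknown contig"):
            assign_gene_groups([_gene("g1", contig="zzz")], records, WIDX, mode="merged")


class TestFisher:
    def test_spec_table(self):
        """a=2 b=8 c=8 d=2 -> two-sided exact p = 0.023."""
        assert stats.fisher_exact([[2, 8], [8, 2]])[1] == pytest.approx(0.023, abs=5e-4)
        assert fisher_oracle(2, 8, 8, 2) == pytest.approx(0.023, abs=5e-4)

    def test_balanced_table(self):
        odds, p = stats.fisher_exact([[5, 5], [5, 5]])
        assert odds == 1.0 and p == 1.0

    def test_scipy_matches_enumeration_oracle(self, rng):
        """100 random 2x2 tables with margins <= 30, |diff| < 1e-9."""
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)

    def test_enrichment_directions_and_counts(self):
        genes = (
            [_gene(f"x{i}", cogs=("X",)) for i in range(10)]
            + [_gene(f"j{i}", cogs=("J",)) for i in range(10)]
        )
        labels = {f"x{i}": "not_fully" for i in range(10)}
        labels.update({f"j{i}": "fully" for i in range(10)})
        results = {r.category: r for r in fisher_enrichment(labels, genes)}
        rx = results["X"]
        assert (rx.a, rx.b, rx.c, rx.d) == (0, 10, 10, 0)
        assert rx.direction == "enriched_in_not_fully"
        assert results["J"].direction == "enriched_in_fully"
        assert rx.a + rx.b + rx.c + rx.d == len(genes)

    def test_multi_category_genes_count_in_each(self):
        genes = [_gene("g1", cogs=("X", "V")), _gene("g2", cogs=("J",))]
        labels = {"g1": "not_fully", "g2": "fully"}
        cats = {r.category for r in fisher_enrichment(labels, genes)}
        assert cats == {"X", "V", "J"}

    def test_one_empty_group_errors(self):
        genes = [_gene("g1")]
        with pytest.raises(ValueError):
            fisher_enrichment({"g1": "fully"}, genes)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        """{0.01, 0.02, 0.04} over 3 categories -> {0.03, 0.03, 0.04}."""
        _, q, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        assert list(q) == pytest.approx([0.03, 0.03, 0.04])
        assert bh_oracle([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_statsmodels_matches_oracle_and_is_monotone(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 15)))
            _, q, _, _ = multipletests(p, method="fdr_bh")
            assert list(q) == pytest.approx(bh_oracle(list(p)), abs=1e-12)
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()


class TestGeneTypeRecovery:
    def test_fractions(self):
        genes = [_gene(f"t{i}", gtype="tRNA") for i in range(10)]
        labels = {f"t{i}": ("fully" if i < 4 else "not_fully") for i in range(10)}
        df = gene_type_recovery(genes, labels).set_index("gene_type")
        assert df.loc["tRNA", "fraction_fully"] == pytest.approx(0.4)
        assert np.isnan(df.loc["rRNA", "fraction_fully"])
        assert df.loc["rRNA", "n_fully"] == 0

    def test_all_fully(self):
        genes = [_gene("g1", gtype="rRNA")]
        df = gene_type_recovery(genes, {"g1": "fully"}).set_index("gene_type")
        assert df.loc["rRNA", "fraction_fully"] == 1.0
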