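"""Functional gene-category enrichment between fully and not-fully assembled windows.

Each gene is assigned to the window containing its midpoint (windows overlap,
so midpoint assignment counts each gene exactly once) and inherits that
window's label: "fully" when the window reached 100% recovery under the
chosen mode ("merged" = both designated assemblies; or a single assembly),
"not_fully" otherwise; genes on windows outside the retained reference set
are excluded.  One two-sided Fisher's exact test per COG category, with
Benjamini–Hochberg FDR across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_log = logging.getLogger(__name__)

#: standard single-letter COG functional category alphabet
COG_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

GENE_TYPES = ("CDS", "tRNA", "rRNA")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" | "-"
    gene_type: str  # CDS | tRNA | rRNA
    cog_categories: frozenset[str]

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        bad = set(self.cog_categories) - set(COG_ALPHABET)
        if bad:
            raise ValueError(f"{self.gene_id}: unknown COG letters {sorted(bad)}")


@dataclass
class EnrichmentResult:
    category: str
    a: int  # in category & fully assembled
    b: int  # not in category & fully
    c: int  # in category & not fully
    d: int  # not in category & not fully
    odds_ratio: float
    p_value: float
    q_value: float
    direction: str  # enriched_in_not_fully | enriched_in_fully | none


def read_annotations(path) -> list[GeneAnnotation]:
    """Annotation TSV: gene_id, contig_id, start, end, strand, gene_type,
    cog_categories (semicolon-joined, possibly empty)."""
    from .io import read_tsv

    df = read_tsv(path, dtype={"cog_categories": str})
    genes = []
    for row in df.itertuples(index=False):
        cats = row.cog_categories
        if isinstance(cats, float) and np.isnan(cats):
            cats = ""
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                contig_id=str(row.contig_id),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                gene_type=str(row.gene_type),
                cog_categories=frozenset(c for c in str(cats).split(";") if c),
            )
        )
    return genes


def read_annotations_gff3(path) -> list[GeneAnnotation]:
    """GFF3 reader mapping attributes ID, cog (semicolon-free) onto the
    annotation fields; feature types tRNA/rRNA map to gene_type."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"GFF3 line {lineno}: expected 9 columns")
            contig_id, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("CDS", "gene", "tRNA", "rRNA"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_type = ftype if ftype in ("tRNA", "rRNA") else "CDS"
            cats = frozenset(attr.get("cog", "").replace(",", "")) - {""}
            genes.append(
                GeneAnnotation(
                    gene_id=attr.get("ID", f"gene_{lineno}"),
                    contig_id=contig_id,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    gene_type=gene_type,
                    cog_categories=cats,
                )
            )
    return genes


def assign_gene_groups(
    genes: Sequence[GeneAnnotation],
    records: pd.DataFrame,
    window_index: pd.DataFrame,
    mode: str = "merged",
    retained: set[str] | None = None,
) -> dict[str, str]:
    """gene_id -> {"fully", "not_fully", "unassigned"}.

    ``mode`` is "merged" (fully means 100% recovery in both designated
    assemblies, via the ``merged_full`` column) or an assembly label (fully
    under that assembly alone, via ``fully_<label>``).
    """
    if mode == "merged":
        col = "merged_full"
    else:
        col = f"fully_{mode}"
    if col not in records.columns:
        raise KeyError(f"records lack column {col!r} for mode {mode!r}")
    fully_by_window = dict(zip(records["window_id"], records[col].astype(bool)))

    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    known_contigs = set(window_index["contig_id"])
    for row in window_index.itertuples(index=False):
        by_contig.setdefault(row.contig_id, []).append(
            (int(row.start0), int(row.end0), row.window_id)
        )
    for lst in by_contig.values():
        lst.sort()

    out: dict[str, str] = {}
    for gene in genes:
        if gene.contig_id not in known_contigs:
            raise ValueError(f"gene {gene.gene_id} on unknown contig {gene.contig_id!r}")
        mid0 = (gene.start + gene.end) // 2 - 1  # 0-based midpoint
        wid = None
        for start, end, w in by_contig[gene.contig_id]:
            if start <= mid0 < end:
                wid = w  # earliest window wins (list sorted by start)
                break
        if wid is None or (retained is not None and wid not in retained):
            out[gene.gene_id] = "unassigned"
            continue
        if wid not in fully_by_window:
            out[gene.gene_id] = "unassigned"
            continue
        out[gene.gene_id] = "fully" if fully_by_window[wid] else "not_fully"
    return out


def fisher_enrichment(
    labels: Mapping[str, str],
    genes: Sequence[GeneAnnotation],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Two-sided Fisher's exact test per observed COG category.

    Genes carrying several categories count once per category; q-values by
    Benjamini–Hochberg across all tested categories.
    """
    assigned = [g for g in genes if labels.get(g.gene_id) in ("fully", "not_fully")]
    n_fully = sum(1 for g in assigned if labels[g.gene_id] == "fully")
    n_not = len(assigned) - n_fully
    if n_fully == 0 or n_not == 0:
        raise ValueError("need at least one gene in each group")
    categories = sorted({c for g in assigned for c in g.cog_categories})
    results: list[EnrichmentResult] = []
    pvals = []
    for cat in categories:
        a = sum(1 for g in assigned if cat in g.cog_categories and labels[g.gene_id] == "fully")
        c = sum(1 for g in assigned if cat in g.cog_categories and labels[g.gene_id] == "not_fully")
        if a + c == 0:  # pragma: no cover - categories come from observed genes
            _log.info("skipping category %s with zero genes", cat)
            continue
        b = n_fully - a
        d = n_not - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if a * d == b * c:
            direction = "none"
        elif odds < 1:
            direction = "enriched_in_not_fully"
        else:
            direction = "enriched_in_fully"
        results.append(EnrichmentResult(cat, a, b, c, d, float(odds), float(p), np.nan, direction))
        pvals.append(p)
    if results:
        _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.q_value, r.category))
    return results


def gene_type_recovery(
    genes: Sequence[GeneAnnotation], labels: Mapping[str, str]
) -> pd.DataFrame:
    """Fraction of genes fully assembled, per gene type (CDS/tRNA/rRNA)."""
    rows = []
    for gtype in GENE_TYPES:
        members = [g for g in genes if g.gene_type == gtype]
        fully = sum(1 for g in members if labels.get(g.gene_id) == "fully")
        not_fully = sum(1 for g in members if labels.get(g.gene_id) == "not_fully")
        total = fully + not_fully
        rows.append(
            {
                "gene_type": gtype,
                "n_fully": fully,
                "n_not_fully": not_fully,
                "fraction_fully": (fully / total) if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
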