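"""Per-window read depth, the breadth-of-coverage retention filter, and SNP load.

The reference set for all downstream scoring is the subset of windows with at
least ``min_depth`` (default 1x) coverage over at least ``min_breadth``
(default 80%) of their length — windows below that simply never had enough
read information to assemble, so scoring them against SR assemblies would
conflate "hard to assemble" with "not sequenced".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DepthRecord, VariantRecord


@dataclass
class DepthTrack:
    window_id: str
    depths: np.ndarray  # int array, one entry per window position

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if (self.depths < 0).any():
            raise ValueError(f"{self.window_id}: negative depth")


@dataclass
class CoverageSummary:
    window_id: str
    mean_depth: float
    breadth: float
    pass_filter: bool
    snp_count: int
    coverage_class: str  # "low" | "high"


def window_depth(
    depth_records: Iterable[DepthRecord],
    window_index: pd.DataFrame,
    contig_lengths: dict[str, int] | None = None,
) -> list[DepthTrack]:
    """Project a per-base depth table onto windows.

    Record names may be window_ids (positions relative to the window) or
    contig_ids (positions relative to the contig; projected onto every window
    of that contig).  Positions absent from the table have depth 0.  A position
    beyond the window length — or beyond the contig length when
    ``contig_lengths`` is supplied — is a hard error naming the record.
    """
    widx = window_index.reset_index(drop=True)
    window_ids = list(widx["window_id"])
    lengths = (widx["end0"] - widx["start0"]).to_numpy()
    tracks = {wid: np.zeros(int(n), dtype=np.int64) for wid, n in zip(window_ids, lengths)}
    by_window = {wid: i for i, wid in enumerate(window_ids)}

    # contig dialect: group windows per contig for projection
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    contig_len: dict[str, int] = {}
    for _, row in widx.iterrows():
        by_contig.setdefault(row["contig_id"], []).append(
            (int(row["start0"]), int(row["end0"]), row["window_id"])
        )
        contig_len[row["contig_id"]] = max(
            contig_len.get(row["contig_id"], 0), int(row["end0"])
        )

    for rec in depth_records:
        if rec.name in by_window:
            track = tracks[rec.name]
            if rec.pos > len(track):
                raise ValueError(
                    f"depth record {rec.name}:{rec.pos} beyond window length {len(track)}"
                )
            track[rec.pos - 1] = rec.depth
        elif rec.name in by_contig:
            pos0 = rec.pos - 1
            if contig_lengths is not None and rec.pos > contig_lengths.get(
                rec.name, contig_len[rec.name]
            ):
                raise ValueError(
                    f"depth record {rec.name}:{rec.pos} beyond contig length"
                )
            if pos0 >= contig_len[rec.name]:
                # past the last window (trailing residue): no window signal
                continue
            for start, end, wid in by_contig[rec.name]:
                if start <= pos0 < end:
                    tracks[wid][pos0 - start] = rec.depth
        else:
            raise ValueError(f"depth record names unknown window/contig {rec.name!r}")
    return [DepthTrack(wid, tracks[wid]) for wid in window_ids]


def summarize_coverage(
    tracks: Sequence[DepthTrack],
    snp_counts: dict[str, int] | None = None,
    min_depth: int = 1,
    min_breadth: float = 0.8,
    cov_threshold: float = 10.0,
) -> list[CoverageSummary]:
    snp_counts = snp_counts or {}
    out = []
    for t in tracks:
        mean_depth = float(t.depths.mean()) if len(t.depths) else 0.0
        breadth = float((t.depths >= min_depth).mean()) if len(t.depths) else 0.0
        out.append(
            CoverageSummary(
                window_id=t.window_id,
                mean_depth=mean_depth,
                breadth=breadth,
                pass_filter=breadth >= min_breadth,
                snp_count=int(snp_counts.get(t.window_id, 0)),
                coverage_class="low" if mean_depth < cov_threshold else "high",
            )
        )
    return out


def filter_reference_set(
    summaries: Sequence[CoverageSummary], min_breadth: float = 0.8
) -> set[str]:
    """Windows retained as the reference set: breadth >= min_breadth."""
    return {s.window_id for s in summaries if s.breadth >= min_breadth}


def count_snps(
    variant_records: Iterable[VariantRecord],
    window_index: pd.DataFrame,
    min_qual: float = 0.0,
) -> dict[str, int]:
    """Count single-nucleotide substitutions per window.

    Variant coordinates are contig-level and 1-based.  Only records with a
    single-base REF and at least one single-base ALT count; a SNP falling in
    the overlap zone of two windows increments both (each window is scored
    independently).
    """
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for _, row in window_index.iterrows():
        by_contig.setdefault(row["contig_id"], []).append(
            (int(row["start0"]), int(row["end0"]), row["window_id"])
        )
    counts = {wid: 0 for wid in window_index["window_id"]}
    for rec in variant_records:
        if rec.qual is not None and rec.qual < min_qual:
            continue
        if len(rec.ref) != 1 or not any(len(a) == 1 for a in rec.alts):
            continue
        pos0 = rec.pos - 1
        for start, end, wid in by_contig.get(rec.chrom, ()):
            if start <= pos0 < end:
                counts[wid] += 1
    return counts


def snp_group_test(
    ca_counts: Sequence[int], nca_counts: Sequence[int]
) -> tuple[float, float, float]:
    """Two-sided Mann–Whitney U comparing SNP counts between window classes.

    Exact null distribution for small groups (< 20 per group), normal
    approximation with tie correction otherwise.  Returns
    (U statistic, p-value, median difference nca − ca).
    """
    if len(ca_counts) == 0 or len(nca_counts) == 0:
        raise ValueError("snp_group_test requires non-empty groups")
    method = "exact" if min(len(ca_counts), len(nca_counts)) < 20 else "asymptotic"
    res = stats.mannwhitneyu(ca_counts, nca_counts, alternative="two-sided", method=method)
    med_diff = float(np.median(nca_counts) - np.median(ca_counts))
    return float(res.statistic), float(res.pvalue), med_diff
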