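"""Percent recovery and cross-assembler consistency per reference window.

For each window and assembly, the best hit is the longest alignment above the
identity threshold; percent recovery is 100 x best-hit alignment length over
the window length.  Two designated assemblies are compared per window: equal
nonzero best-hit lengths make the window consistently assembled (CA), unequal
lengths not consistently assembled (NCA); windows with no hit in either
assembly form a third class, "unassembled", so that degenerate equality of
zeros does not inflate CA (a strict-equality mode is available).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, SeedIndex, seed_extend_align
from .windows import Contig, Window

DEFAULT_DIFF_EDGES = [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99, 100]

LENGTH_GROUPS = ("g0_499", "g500_999", "g1000")


def length_group(best_hit_length: int) -> str:
    if best_hit_length >= 1000:
        return "g1000"
    if best_hit_length >= 500:
        return "g500_999"
    return "g0_499"


def select_best_hit(
    hits: Sequence[AlignmentHit], min_identity: float = 99.0
) -> AlignmentHit | None:
    """Longest hit above the (strict) identity threshold.

    Ties broken by higher identity, then lexicographically smallest subject
    contig id, so reruns are bit-identical.
    """
    eligible = [h for h in hits if h.pct_identity > min_identity]
    if not eligible:
        return None
    return max(
        eligible,
        key=lambda h: (h.aln_length, h.pct_identity, _neg_str(h.subject_contig_id)),
    )


class _neg_str(str):
    """Inverts string comparison so max() prefers the smallest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def score_recovery(
    best: AlignmentHit | None, window_length: int, any_assembled_min: int = 100
) -> dict:
    """Per-assembly recovery fields for one window."""
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    best_len = best.aln_length if best is not None else 0
    pct = min(100.0, 100.0 * best_len / window_length)
    return {
        "best_hit_length": best_len,
        "percent_recovery": pct,
        "assembled_any": best_len >= any_assembled_min,
        "fully_assembled": pct == 100.0,
        "length_group": length_group(best_len),
        "subject_contig_id": best.subject_contig_id if best is not None else None,
    }


def classify_consistency(
    best_len_a: int, best_len_b: int, strict_equality: bool = False
) -> str:
    """CA/NCA/unassembled from the two designated assemblies' best-hit lengths."""
    if best_len_a == 0 and best_len_b == 0:
        return "CA" if strict_equality else "unassembled"
    return "CA" if best_len_a == best_len_b else "NCA"


def diff_histogram(
    diffs: Iterable[float], bin_edges: Sequence[float] = DEFAULT_DIFF_EDGES
) -> pd.DataFrame:
    """Counts of |recovery_a - recovery_b| per bin.

    Bins are half-open [lo, hi) with the last bin closed, so the dedicated
    [99, 100] bin captures windows found in only one assembler.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(np.fromiter(diffs, dtype=float), bins=edges)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
        }
    )


def hits_from_table(df: pd.DataFrame, assembly_label: str) -> dict[str, list[AlignmentHit]]:
    """AlignmentHits grouped by window from a parsed 12-column table."""
    out: dict[str, list[AlignmentHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.qseqid, []).append(
            AlignmentHit(
                window_id=row.qseqid,
                assembly_label=assembly_label,
                subject_contig_id=row.sseqid,
                aln_length=int(row.length),
                pct_identity=float(row.pident),
                mismatches=int(row.mismatch),
                gap_opens=int(row.gapopen),
                q_start=int(row.qstart),
                q_end=int(row.qend),
                s_start=int(row.sstart),
                s_end=int(row.send),
                score=float(row.bitscore),
            )
        )
    return out


def records_from_hits(
    windows: Sequence[Window],
    hits_by_label: Mapping[str, Mapping[str, Sequence[AlignmentHit]]],
    primary_pair: tuple[str, str] | None = None,
    min_identity: float = 99.0,
    any_assembled_min: int = 100,
    strict_equality: bool = False,
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """Recovery records from precomputed hits (bypasses the internal aligner)."""
    labels = list(hits_by_label)
    if primary_pair is None and len(labels) >= 2:
        primary_pair = (labels[0], labels[1])
    rows = []
    for w in windows:
        if restrict_to is not None and w.window_id not in restrict_to:
            continue
        row: dict = {"window_id": w.window_id, "contig_id": w.contig_id}
        fully_all = True
        for lab in labels:
            hits = hits_by_label[lab].get(w.window_id, [])
            fields = score_recovery(
                select_best_hit(hits, min_identity=min_identity),
                w.length,
                any_assembled_min=any_assembled_min,
            )
            row[f"best_len_{lab}"] = fields["best_hit_length"]
            row[f"recovery_{lab}"] = fields["percent_recovery"]
            row[f"assembled_{lab}"] = fields["assembled_any"]
            row[f"fully_{lab}"] = fields["fully_assembled"]
            row[f"length_group_{lab}"] = fields["length_group"]
            fully_all = fully_all and fields["fully_assembled"]
        if primary_pair is not None:
            a, b = primary_pair
            row["merged_full"] = bool(row[f"fully_{a}"] and row[f"fully_{b}"])
            row["consistency"] = classify_consistency(
                row[f"best_len_{a}"], row[f"best_len_{b}"], strict_equality
            )
            row["recovery_diff"] = abs(row[f"recovery_{a}"] - row[f"recovery_{b}"])
        else:
            row["merged_full"] = fully_all
        rows.append(row)
    return pd.DataFrame(rows)


def recover_windows(
    windows: Sequence[Window],
    assemblies: Mapping[str, Sequence[Contig]],
    primary_pair: tuple[str, str] | None = None,
    seed_k: int = 15,
    min_identity: float = 99.0,
    any_assembled_min: int = 100,
    strict_equality: bool = False,
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """Score every window against every assembly; one row per window.

    Columns per label: ``best_len_<label>``, ``recovery_<label>``,
    ``assembled_<label>``, ``fully_<label>``, ``length_group_<label>``; plus
    cross-assembly ``consistency``, ``merged_full``, ``recovery_diff`` for the
    designated ``primary_pair`` (defaults to the first two labels).
    """
    labels = list(assemblies)
    if len(labels) < 1:
        raise ValueError("at least one assembly required")
    if primary_pair is None and len(labels) >= 2:
        primary_pair = (labels[0], labels[1])
    if primary_pair is not None:
        for lab in primary_pair:
            if lab not in assemblies:
                raise KeyError(f"unknown assembly label {lab!r}")
    indexes = {lab: SeedIndex(list(ctgs), seed_k=seed_k) for lab, ctgs in assemblies.items()}
    rows = []
    for w in windows:
        if restrict_to is not None and w.window_id not in restrict_to:
            continue
        row: dict = {"window_id": w.window_id, "contig_id": w.contig_id}
        fully_all = True
        for lab in labels:
            hits = seed_extend_align(
                w, indexes[lab], assembly_label=lab, min_identity=min_identity
            )
            fields = score_recovery(
                select_best_hit(hits, min_identity=min_identity),
                w.length,
                any_assembled_min=any_assembled_min,
            )
            row[f"best_len_{lab}"] = fields["best_hit_length"]
            row[f"recovery_{lab}"] = fields["percent_recovery"]
            row[f"assembled_{lab}"] = fields["assembled_any"]
            row[f"fully_{lab}"] = fields["fully_assembled"]
            row[f"length_group_{lab}"] = fields["length_group"]
            fully_all = fully_all and fields["fully_assembled"]
        if primary_pair is not None:
            a, b = primary_pair
            row["merged_full"] = bool(row[f"fully_{a}"] and row[f"fully_{b}"])
            row["consistency"] = classify_consistency(
                row[f"best_len_{a}"], row[f"best_len_{b}"], strict_equality
            )
            row["recovery_diff"] = abs(row[f"recovery_{a}"] - row[f"recovery_{b}"])
        else:
            row["merged_full"] = fully_all
        rows.append(row)
    return pd.DataFrame(rows)
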