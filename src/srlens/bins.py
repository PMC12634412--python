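"""Genome-bin level aggregation of window recovery.

Windows are cross-classified into recovery length groups (not recovered
0-499 bp, partially recovered 500-999 bp, fully recovered >= 1 kb) by
coverage class (low: mean depth < ``cov_threshold``; high otherwise), and the
six cell fractions are reported per bin along with a rank by decreasing
fraction fully recovered.  Only windows with mean depth >= ``min_cov``
(default 1x) enter a bin's denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageSummary
from .recovery import LENGTH_GROUPS

CELLS = [(g, c) for g in LENGTH_GROUPS for c in ("low", "high")]


@dataclass
class BinSummary:
    bin_id: str
    n_windows: int
    fractions: dict = field(default_factory=dict)  # (length_group, cov_class) -> frac
    frac_fully: float = np.nan
    frac_not_recovered: float = np.nan
    rank: int = 0


def summarize_bins(
    assignments: Mapping[str, str],
    records: pd.DataFrame,
    label: str,
    coverage: Sequence[CoverageSummary],
    cov_threshold: float = 10.0,
    min_cov: float = 1.0,
) -> list[BinSummary]:
    """Per-bin 6-cell fractions for one assembly label.

    ``assignments`` maps contig_id -> bin_id (unbinned contigs absent);
    ``records`` is the recovery table (one row per window) and must carry
    ``length_group_<label>``.  Bins are ranked by ``frac_fully`` descending,
    ties broken by bin_id; a bin with zero qualifying windows is emitted with
    NaN fractions.
    """
    col = f"length_group_{label}"
    if col not in records.columns:
        raise KeyError(f"records lack column {col!r}")
    depth = {s.window_id: s.mean_depth for s in coverage}
    tallies: dict[str, dict[tuple[str, str], int]] = {
        b: {cell: 0 for cell in CELLS} for b in sorted(set(assignments.values()))
    }
    for row in records.itertuples(index=False):
        bin_id = assignments.get(row.contig_id)
        if bin_id is None:
            continue
        d = depth.get(row.window_id)
        if d is None or d < min_cov:
            continue
        cov_class = "low" if d < cov_threshold else "high"
        tallies[bin_id][(getattr(row, col), cov_class)] += 1
    out = []
    for bin_id, cells in tallies.items():
        n = sum(cells.values())
        if n == 0:
            out.append(BinSummary(bin_id=bin_id, n_windows=0))
            continue
        fracs = {cell: cnt / n for cell, cnt in cells.items()}
        out.append(
            BinSummary(
                bin_id=bin_id,
                n_windows=n,
                fractions=fracs,
                frac_fully=fracs[("g1000", "low")] + fracs[("g1000", "high")],
                frac_not_recovered=fracs[("g0_499", "low")] + fracs[("g0_499", "high")],
            )
        )
    out.sort(key=lambda s: (-(s.frac_fully if s.n_windows else -1.0), s.bin_id))
    for i, s in enumerate(out, start=1):
        s.rank = i
    return out


def bin_majority_counts(
    summaries: Sequence[BinSummary], threshold: float = 0.5
) -> tuple[int, int, int]:
    """(n bins mostly fully recovered, n bins mostly not recovered, n total).

    "Mostly" means the fraction is at least ``threshold``; the two categories
    are counted independently.  Bins without qualifying windows count only
    toward the total.
    """
    n_fully = sum(1 for s in summaries if s.n_windows and s.frac_fully >= threshold)
    n_not = sum(1 for s in summaries if s.n_windows and s.frac_not_recovered >= threshold)
    return n_fully, n_not, len(summaries)


def bin_summary_frame(summaries: Sequence[BinSummary]) -> pd.DataFrame:
    """Flat table of bin summaries, ordered by rank (stacked-bar layout)."""
    rows = []
    for s in sorted(summaries, key=lambda x: x.rank):
        row = {
            "bin_id": s.bin_id,
            "rank": s.rank,
            "n_windows": s.n_windows,
            "frac_fully": s.frac_fully,
            "frac_not_recovered": s.frac_not_recovered,
        }
        for g, c in CELLS:
            row[f"frac_{g}_{c}"] = s.fractions.get((g, c), np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
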