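"""Fixed-width sliding windows over reference contigs.

Long-read contigs are decomposed into windows of a fixed width ``W`` every
``step`` bases.  All downstream metrics (recovery, coverage, graph structure)
are computed per window, so only full-width windows are emitted: a trailing
residue shorter than ``W`` is discarded, which keeps every window directly
length-comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

_log = logging.getLogger(__name__)

_DNA = set("ACGTN")


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Window:
    """A [start, end) slice of a contig; coordinates are 0-based half-open.

    ``window_id`` uses 1-based inclusive coordinates for display
    (``{contig_id}:{start+1}-{end}``), matching common region notation.
    """

    window_id: str
    contig_id: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def window_id_for(contig_id: str, start: int, end: int) -> str:
    return f"{contig_id}:{start + 1}-{end}"


def n_windows(contig_length: int, width: int, step: int) -> int:
    """Closed-form window count for one contig."""
    if contig_length < width:
        return 0
    return (contig_length - width) // step + 1


def make_windows(
    contigs: Iterable[Contig], width: int = 1000, step: int = 500
) -> list[Window]:
    """Split contigs into full-width windows every ``step`` bases.

    Contigs with empty sequences or characters outside {A,C,G,T,N} are
    rejected with a logged warning; contigs shorter than ``width`` yield no
    windows (their count is logged).
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    if not 1 <= step <= width:
        raise ValueError(f"step must satisfy 1 <= step <= width, got {step}")
    out: list[Window] = []
    n_short = 0
    for contig in contigs:
        seq = contig.sequence.upper()
        if not seq or not set(seq) <= _DNA:
            _log.warning(
                "rejecting contig %r: empty or non-DNA characters", contig.contig_id
            )
            continue
        if len(seq) < width:
            n_short += 1
            continue
        for start in range(0, len(seq) - width + 1, step):
            end = start + width
            out.append(
                Window(
                    window_id=window_id_for(contig.contig_id, start, end),
                    contig_id=contig.contig_id,
                    start=start,
                    end=end,
                    sequence=seq[start:end],
                )
            )
    if n_short:
        _log.info("dropped %d contigs shorter than %d bp", n_short, width)
    return out
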