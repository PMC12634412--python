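"""Seed-and-extend local alignment of reference windows to assembly contigs.

Exact-match seeds (default 15-mers, both strands) are located through a hash
index of the assembly, clustered by diagonal, and each cluster region is
resolved by a full affine-gap Smith–Waterman over the spanned subject slice
(numba-compiled).  Scoring: match +1, mismatch −2, gap open −5 (first gapped
base), gap extend −2 (each further base).  Only hits whose percent identity
strictly exceeds ``min_identity`` (default 99.0) are reported, mirroring the
">99% identity" retention rule used when screening blastn hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seq import encode, revcomp
from .windows import Contig, Window

MATCH = 1
MISMATCH = -2
GAP_OPEN = 5  # cost of the first gapped base
GAP_EXTEND = 2  # cost of each additional gapped base

_DIAG_BAND = 16  # seeds within this diagonal spread are one cluster
_REGION_PAD = 60  # subject slack around a seed cluster


@dataclass(frozen=True)
class AlignmentHit:
    window_id: str
    assembly_label: str
    subject_contig_id: str
    aln_length: int  # alignment columns: matches + mismatches + gaps
    pct_identity: float
    mismatches: int
    gap_opens: int
    q_start: int  # 1-based, q_start <= q_end always
    q_end: int
    s_start: int  # 1-based; s_start > s_end signals a minus-strand subject
    s_end: int
    score: float


@njit(cache=False)
def _sw_region(q, s):  # pragma: no cover - exercised via wrapper
    """Affine-gap local alignment (Gotoh) with traceback.

    Returns (score, q0, q1, s0, s1, matches, mismatches, gap_opens, aln_len)
    with 0-based half-open coordinates, or score 0 if no positive alignment.
    """
    n = q.shape[0]
    m = s.shape[0]
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in query (left move)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in subject (up move)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop 1 diag 2 left(E) 3 up(F)
    e_ext = np.zeros((n + 1, m + 1), dtype=np.uint8)  # E came from E
    f_ext = np.zeros((n + 1, m + 1), dtype=np.uint8)  # F came from F
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - GAP_OPEN
            e_extend = E[i, j - 1] - GAP_EXTEND
            if e_extend > e_open:
                E[i, j] = e_extend
                e_ext[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - GAP_OPEN
            f_extend = F[i - 1, j] - GAP_EXTEND
            if f_extend > f_open:
                F[i, j] = f_extend
                f_ext[i, j] = 1
            else:
                F[i, j] = f_open
            sub = MATCH if qi == s[j - 1] else MISMATCH
            h = H[i - 1, j - 1] + sub
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return (0, 0, 0, 0, 0, 0, 0, 0, 0)
    i = bi
    j = bj
    matches = 0
    mism = 0
    gap_opens = 0
    aln_len = 0
    state = 0  # 0 in H, 2 in E, 3 in F
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mism += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            aln_len += 1
            if e_ext[i, j] == 0:
                gap_opens += 1
                state = 0
            j -= 1
        else:
            aln_len += 1
            if f_ext[i, j] == 0:
                gap_opens += 1
                state = 0
            i -= 1
    return (best, i, bi, j, bj, matches, mism, gap_opens, aln_len)


def smith_waterman(query: str, subject: str):
    """Local alignment of two sequences under the module scoring.

    Returns a dict with score, coordinates (0-based half-open), matches,
    mismatches, gap_opens and aln_length; score 0 means no alignment.
    """
    q = encode(query).astype(np.uint8)
    s = encode(subject).astype(np.uint8)
    # map ambiguous bases to distinct sentinels so N never matches anything
    q = np.where(q == 255, np.uint8(4), q)
    s = np.where(s == 255, np.uint8(5), s)
    score, q0, q1, s0, s1, matches, mism, gaps_open, aln_len = _sw_region(q, s)
    return {
        "score": int(score),
        "q0": int(q0),
        "q1": int(q1),
        "s0": int(s0),
        "s1": int(s1),
        "matches": int(matches),
        "mismatches": int(mism),
        "gap_opens": int(gaps_open),
        "aln_length": int(aln_len),
    }


class SeedIndex:
    """Hash index of exact k-mers over a set of assembly contigs."""

    def __init__(self, contigs: list[Contig], seed_k: int = 15):
        self.seed_k = seed_k
        self.contigs = list(contigs)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ci, contig in enumerate(self.contigs):
            seq = contig.sequence
            for pos in range(0, len(seq) - seed_k + 1):
                kmer = seq[pos : pos + seed_k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((ci, pos))

    def seeds(self, query: str) -> dict[int, list[tuple[int, int]]]:
        """contig index -> list of (query pos, subject pos) exact seed matches."""
        out: dict[int, list[tuple[int, int]]] = {}
        k = self.seed_k
        for qpos in range(0, len(query) - k + 1):
            hits = self.index.get(query[qpos : qpos + k])
            if hits:
                for ci, spos in hits:
                    out.setdefault(ci, []).append((qpos, spos))
        return out


def _cluster_seeds(seeds: list[tuple[int, int]], qlen: int) -> list[tuple[int, int]]:
    """Group seeds into (subject_lo, subject_hi) candidate regions."""
    diag_sorted = sorted(seeds, key=lambda t: (t[1] - t[0], t[1]))
    clusters: list[list[tuple[int, int]]] = []
    for qpos, spos in diag_sorted:
        d = spos - qpos
        placed = False
        for cl in clusters:
            d0 = cl[-1][1] - cl[-1][0]
            if abs(d - d0) <= _DIAG_BAND and abs(spos - cl[-1][1]) <= qlen + _REGION_PAD:
                cl.append((qpos, spos))
                placed = True
                break
        if not placed:
            clusters.append([(qpos, spos)])
    regions = []
    for cl in clusters:
        starts = [s - q for q, s in cl]
        lo = min(starts) - _REGION_PAD
        hi = max(starts) + qlen + _REGION_PAD
        regions.append((lo, hi))
    # merge overlapping regions
    regions.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in regions:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def seed_extend_align(
    window: Window,
    assembly_contigs: list[Contig] | SeedIndex,
    assembly_label: str = "assembly",
    seed_k: int = 15,
    min_identity: float = 99.0,
    min_aln_length: int | None = None,
) -> list[AlignmentHit]:
    """Align one window against assembly contigs on both strands.

    A prebuilt :class:`SeedIndex` may be passed instead of the contig list to
    amortize indexing across windows.  Hits below or at ``min_identity`` are
    dropped (strict ``>``).
    """
    if isinstance(assembly_contigs, SeedIndex):
        idx = assembly_contigs
    else:
        idx = SeedIndex(assembly_contigs, seed_k=seed_k)
    if window.length < idx.seed_k:
        raise ValueError(f"window {window.window_id} shorter than seed_k {idx.seed_k}")
    min_aln_length = idx.seed_k if min_aln_length is None else min_aln_length
    hits: list[AlignmentHit] = []
    seen: set[tuple[str, int, int, int, int]] = set()
    L = window.length
    for strand in ("+", "-"):
        qseq = window.sequence if strand == "+" else revcomp(window.sequence)
        per_contig = idx.seeds(qseq)
        for ci, seeds in per_contig.items():
            contig = idx.contigs[ci]
            for lo, hi in _cluster_seeds(seeds, L):
                lo = max(0, lo)
                hi = min(len(contig.sequence), hi)
                res = smith_waterman(qseq, contig.sequence[lo:hi])
                if res["score"] <= 0 or res["aln_length"] < min_aln_length:
                    continue
                identity = 100.0 * res["matches"] / res["aln_length"]
                if not identity > min_identity:
                    continue
                s0 = lo + res["s0"]
                s1 = lo + res["s1"]
                if strand == "+":
                    q_start, q_end = res["q0"] + 1, res["q1"]
                    s_start, s_end = s0 + 1, s1
                else:
                    # query coordinates back onto the forward window; subject
                    # coordinates reversed to signal the minus strand
                    q_start, q_end = L - res["q1"] + 1, L - res["q0"]
                    s_start, s_end = s1, s0 + 1
                key = (contig.contig_id, q_start, q_end, s_start, s_end)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    AlignmentHit(
                        window_id=window.window_id,
                        assembly_label=assembly_label,
                        subject_contig_id=contig.contig_id,
                        aln_length=res["aln_length"],
                        pct_identity=identity,
                        mismatches=res["mismatches"],
                        gap_opens=res["gap_opens"],
                        q_start=q_start,
                        q_end=q_end,
                        s_start=s_start,
                        s_end=s_end,
                        score=float(res["score"]),
                    )
                )
    return hits
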