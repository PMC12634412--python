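"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: alignment goes through
Biopython's PairwiseAligner, Fisher p-values through exact Fraction
arithmetic over the hypergeometric distribution, window counts through naive
start-position enumeration, and small de Bruijn graphs through brute-force
k-mer set construction.
"""

from __future__ import annotations

import math
from fractions import Fraction

from Bio import Align

SW_SCORING = dict(match_score=1, mismatch_score=-2, open_gap_score=-5, extend_gap_score=-2)


def sw_oracle(query: str, subject: str) -> dict:
    """Best local alignment of two sequences via Biopython (same scoring as
    the library: a gap of length L costs 5 + 2(L-1))."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    for key, val in SW_SCORING.items():
        setattr(aligner, key, val)
    alignments = aligner.align(query, subject)
    best = alignments[0]
    counts = best.counts()
    aln_length = counts.identities + counts.mismatches + counts.gaps
    return {
        "score": best.score,
        "matches": counts.identities,
        "mismatches": counts.mismatches,
        "gaps": counts.gaps,
        "aln_length": aln_length,
        "identity": 100.0 * counts.identities / aln_length if aln_length else 0.0,
    }


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's (with the conventional
    tiny relative tolerance for floating-tie agreement).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
    observed = probs[a]
    cutoff = observed + observed * Fraction(1, 10**7)
    return float(sum(p for p in probs.values() if p <= cutoff))


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg q-values: q_i = min_{j>=i} p_(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


def window_count_oracle(length: int, width: int, step: int) -> int:
    """Naive enumeration of valid window start positions."""
    return sum(1 for start in range(0, max(length, 1), step) if start + width <= length)


def dbg_oracle_kmers(seqs: list[str], k: int) -> set[str]:
    """Canonical k-mer set by brute force."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            rc = kmer.translate(comp)[::-1]
            out.add(min(kmer, rc))
    return out
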