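"""Compacted de Bruijn graphs of the reads underlying a reference window.

K-mers are counted in canonical form (lexicographic minimum of a k-mer and
its reverse complement); maximal non-branching paths of the bidirected k-mer
graph are compacted into unitig nodes, the display unit of assembly-graph
viewers.  Nodes sharing at least one canonical k-mer with the reference
window are flagged as reference nodes; the count of non-reference nodes
within graph distance ``max_dist`` (default 3) of any reference node — the
"surrounding nodes" — serves as a proxy for local population diversity, and
total node count ("graph size") for overall diversity.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import networkx as nx

from .seq import decode_kmer, encode, revcomp
from .windows import Window

Link = tuple[str, str, str, str]  # (node_a, sign_a, node_b, sign_b)


@dataclass
class UnitigNode:
    node_id: str
    sequence: str
    mean_count: float
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class UnitigGraph:
    k: int
    nodes: list[UnitigNode]
    links: list[Link]
    reference_nodes: set[str] = field(default_factory=set)

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def undirected_edges(self) -> set[tuple[str, str]]:
        """Orientation-free node pairs (self-loops dropped)."""
        out = set()
        for a, _, b, _ in self.links:
            if a != b:
                out.add((a, b) if a <= b else (b, a))
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n.node_id,
                sequence=n.sequence,
                mean_count=n.mean_count,
                reference=n.node_id in self.reference_nodes,
            )
        g.add_edges_from(self.undirected_edges())
        return g


@dataclass
class GraphMetrics:
    window_id: str
    graph_size: int
    n_reference_nodes: int
    surrounding_nodes: int
    mean_ref_node_coverage: float
    max_offref_coverage: float


# ------------------------------------------------------------ k-mer counting

def count_canonical_kmers(
    reads: Iterable[str], k: int, min_count: int = 1
) -> dict[str, int]:
    """Canonical k-mer counts over a read set; reads shorter than k and
    k-mers containing non-ACGT characters are skipped."""
    _check_k(k)
    if k <= 31:
        return _count_kmers_packed(reads, k, min_count)
    counts: dict[str, int] = {}
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            kmer = read[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            canon = kmer if kmer <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1
    if min_count > 1:
        counts = {s: c for s, c in counts.items() if c >= min_count}
    return counts


def _count_kmers_packed(reads, k, min_count, chunk_bases: int = 8_000_000):
    """Vectorized 2-bit-packed counting (k <= 31 fits an int64)."""
    sep = np.array([255], dtype=np.uint8)
    partial: list[tuple[np.ndarray, np.ndarray]] = []
    buf: list[np.ndarray] = []
    size = 0

    def flush():
        nonlocal buf, size
        if not buf:
            return
        arr = np.concatenate(buf)
        buf = []
        size = 0
        n = len(arr) - k + 1
        if n <= 0:
            return
        fwd = np.zeros(n, dtype=np.int64)
        rc = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for i in range(k):
            c = arr[i : i + n].astype(np.int64)
            valid &= c <= 3
            fwd = (fwd << 2) | (c & 3)
            rc |= ((~c) & 3) << (2 * i)
        canon = np.minimum(fwd, rc)[valid]
        kk, cc = np.unique(canon, return_counts=True)
        partial.append((kk, cc))

    for read in reads:
        read = read.upper()
        if len(read) < k:
            continue
        buf.append(encode(read))
        buf.append(sep)
        size += len(read) + 1
        if size >= chunk_bases:
            flush()
    flush()
    if not partial:
        return {}
    all_k = np.concatenate([p[0] for p in partial])
    all_c = np.concatenate([p[1] for p in partial])
    order = np.argsort(all_k, kind="stable")
    all_k = all_k[order]
    all_c = all_c[order]
    uk, start = np.unique(all_k, return_index=True)
    sums = np.add.reduceat(all_c, start)
    keep = sums >= min_count
    return {decode_kmer(int(v), k): int(c) for v, c in zip(uk[keep], sums[keep])}


def canonical_kmers_of(seq: str, k: int) -> set[str]:
    """Canonical k-mer set of a single sequence."""
    out = set()
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


# ------------------------------------------------------------ graph building

def _check_k(k: int) -> None:
    if k % 2 == 0 or not 11 <= k <= 63:
        raise ValueError(f"k must be odd and in [11, 63], got {k}")


def build_unitig_graph(
    reads: Iterable[str], k: int = 31, min_count: int = 1
) -> UnitigGraph:
    """Build the compacted canonical de Bruijn graph of a read set.

    K-mers with count below ``min_count`` are discarded before compaction.
    An empty surviving k-mer set yields an empty graph.
    """
    counts = count_canonical_kmers(reads, k, min_count)
    return unitig_graph_from_kmers(counts, k)


def unitig_graph_from_kmers(counts: dict[str, int], k: int) -> UnitigGraph:
    _check_k(k)

    def canon(y: str) -> str:
        r = revcomp(y)
        return y if y <= r else r

    def succs(y: str) -> list[str]:
        stem = y[1:]
        return [stem + b for b in "ACGT" if canon(stem + b) in counts]

    def in_deg(y: str) -> int:
        return len(succs(revcomp(y)))

    visited: set[str] = set()
    raw: list[tuple[str, list[str], bool]] = []  # (sequence, oriented path, circular)
    for start in sorted(counts):
        if start in visited:
            continue
        visited.add(start)
        path = [start]
        circular = False
        cur = start
        while True:  # extend right
            nxt_list = succs(cur)
            if len(nxt_list) != 1:
                break
            nxt = nxt_list[0]
            if in_deg(nxt) != 1:
                break
            if canon(nxt) in visited:
                circular = nxt == path[0]
                break
            path.append(nxt)
            visited.add(canon(nxt))
            cur = nxt
        if not circular:  # extend left by walking right from the twin
            cur = revcomp(start)
            left: list[str] = []
            while True:
                nxt_list = succs(cur)
                if len(nxt_list) != 1:
                    break
                nxt = nxt_list[0]
                if in_deg(nxt) != 1 or canon(nxt) in visited:
                    break
                left.append(nxt)
                visited.add(canon(nxt))
                cur = nxt
            path = [revcomp(y) for y in reversed(left)] + path
        seq = path[0] + "".join(y[-1] for y in path[1:])
        rc_seq = revcomp(seq)
        if rc_seq < seq:
            seq = rc_seq
            path = [revcomp(y) for y in reversed(path)]
        raw.append((seq, path, circular))

    raw.sort(key=lambda t: t[0])
    nodes: list[UnitigNode] = []
    start_lookup: dict[str, tuple[str, str]] = {}
    endpoint_out: dict[tuple[str, str], str] = {}
    paths: dict[str, list[str]] = {}
    for i, (seq, path, circular) in enumerate(raw):
        nid = f"u{i}"
        mean_count = float(np.mean([counts[canon(y)] for y in path]))
        nodes.append(UnitigNode(nid, seq, mean_count, circular))
        paths[nid] = path
        start_lookup[path[0]] = (nid, "+")
        start_lookup[revcomp(path[-1])] = (nid, "-")
        endpoint_out[(nid, "+")] = path[-1]
        endpoint_out[(nid, "-")] = revcomp(path[0])

    flip = {"+": "-", "-": "+"}
    links: set[Link] = set()
    for nid, _ in paths.items():
        for sign in "+-":
            u = endpoint_out[(nid, sign)]
            for nxt in succs(u):
                if nxt not in start_lookup:
                    raise RuntimeError("compaction invariant violated: successor is internal")
                nid2, sign2 = start_lookup[nxt]
                cand = (nid, sign, nid2, sign2)
                alt = (nid2, flip[sign2], nid, flip[sign])
                links.add(min(cand, alt))
    return UnitigGraph(k=k, nodes=nodes, links=sorted(links))


def pop_simple_bubbles(
    graph: UnitigGraph,
    max_ratio: float = 0.5,
    min_flank_length: int = 150,
) -> UnitigGraph:
    """Remove the minor branch of isolated simple bubbles and recompact.

    A simple bubble is a pair of branch nodes connecting the same two flank
    ends (the signature a single substitution leaves: two branches of length
    2k-1).  The lower-coverage branch is dropped when its mean k-mer count is
    at most ``max_ratio`` of the major branch's and both flanks are at least
    ``min_flank_length`` long — dense variant regions have short inter-variant
    flanks and are left untouched, mimicking how real assemblers resolve
    isolated variants but fragment on tangled ones.
    """
    incident: dict[str, list[Link]] = {n.node_id: [] for n in graph.nodes}
    for link in graph.links:
        a, _, b, _ = link
        incident[a].append(link)
        if b != a:
            incident[b].append(link)

    def signature(nid: str) -> frozenset | None:
        links = incident[nid]
        if len(links) != 2:
            return None
        sig = set()
        for a, sa, b, sb in links:
            if a == nid and b == nid:
                return None
            flip = {"+": "-", "-": "+"}
            reps = [(a, sa, b, sb), (b, flip[sb], a, flip[sa])]
            reps = [
                tuple("*" if x == nid else x for x in rep) for rep in reps
            ]
            sig.add(min(reps))
        return frozenset(sig)

    node_by_id = {n.node_id: n for n in graph.nodes}
    length_of = {n.node_id: n.length for n in graph.nodes}
    candidates: dict[frozenset, list[str]] = {}
    max_branch_len = 2 * graph.k + 2
    for n in graph.nodes:
        if n.length > max_branch_len:
            continue
        sig = signature(n.node_id)
        if sig is None:
            continue
        partners = {x for rep in sig for x in rep if x not in ("*", "+", "-")}
        if any(length_of[p] < min_flank_length for p in partners):
            continue
        candidates.setdefault(sig, []).append(n.node_id)

    dropped: set[str] = set()
    for sig, nids in candidates.items():
        if len(nids) != 2:
            continue
        n1, n2 = (node_by_id[i] for i in nids)
        minor, major = sorted(
            (n1, n2), key=lambda n: (n.mean_count, _neg_lex(n.sequence))
        )
        if major.mean_count > 0 and minor.mean_count / major.mean_count <= max_ratio:
            dropped.add(minor.node_id)

    if not dropped:
        return graph
    surviving = [n.sequence for n in graph.nodes if n.node_id not in dropped]
    return build_unitig_graph(surviving, k=graph.k, min_count=1)


class _neg_lex(str):
    """Inverts ordering so sorted() breaks count ties toward dropping the
    lexicographically larger sequence deterministically."""

    def __lt__(self, other):
        return str.__gt__(self, other)


# -------------------------------------------------------- reference marking

def mark_reference_nodes(graph: UnitigGraph, window: Window | str) -> UnitigGraph:
    """Flag nodes sharing >= 1 canonical k-mer with the window sequence."""
    seq = window.sequence if isinstance(window, Window) else window
    if len(seq) < graph.k:
        raise ValueError(f"window shorter than k={graph.k}")
    ref_set = canonical_kmers_of(seq, graph.k)
    flagged = set()
    for node in graph.nodes:
        if canonical_kmers_of(node.sequence, graph.k) & ref_set:
            flagged.add(node.node_id)
    graph.reference_nodes = flagged
    return graph


def compute_graph_metrics(
    graph: UnitigGraph, window_id: str = "", max_dist: int = 3
) -> GraphMetrics:
    """Graph size and surrounding-node count by multi-source BFS.

    Distance is the minimum number of edges on the undirected compacted-node
    graph from any reference node; surrounding nodes are non-reference nodes
    at distance 1..max_dist.
    """
    adj: dict[str, set[str]] = {n.node_id: set() for n in graph.nodes}
    for a, b in graph.undirected_edges():
        adj[a].add(b)
        adj[b].add(a)
    dist = {nid: 0 for nid in graph.reference_nodes}
    queue = deque(graph.reference_nodes)
    while queue:
        cur = queue.popleft()
        if dist[cur] >= max_dist:
            continue
        for nb in adj[cur]:
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                queue.append(nb)
    surrounding = sum(
        1 for nid, d in dist.items() if 1 <= d <= max_dist and nid not in graph.reference_nodes
    )
    ref_covs = [n.mean_count for n in graph.nodes if n.node_id in graph.reference_nodes]
    off_covs = [n.mean_count for n in graph.nodes if n.node_id not in graph.reference_nodes]
    return GraphMetrics(
        window_id=window_id,
        graph_size=len(graph.nodes),
        n_reference_nodes=len(graph.reference_nodes),
        surrounding_nodes=surrounding,
        mean_ref_node_coverage=float(np.mean(ref_covs)) if ref_covs else float("nan"),
        max_offref_coverage=float(max(off_covs)) if off_covs else float("nan"),
    )


# ------------------------------------------------------------------ GFA 1.0

def export_gfa(graph: UnitigGraph) -> str:
    """GFA 1.0 text: S-lines with mean-count (dp) and reference (rf) tags,
    L-lines with (k-1)M overlaps, k recorded on the header."""
    lines = [f"H\tVN:Z:1.0\tkl:i:{graph.k}"]
    for n in graph.nodes:
        rf = 1 if n.node_id in graph.reference_nodes else 0
        lines.append(
            f"S\t{n.node_id}\t{n.sequence}\tdp:f:{n.mean_count:g}\trf:i:{rf}"
        )
    ov = f"{graph.k - 1}M"
    for a, sa, b, sb in graph.links:
        lines.append(f"L\t{a}\t{sa}\t{b}\t{sb}\t{ov}")
    return "\n".join(lines) + "\n"


def parse_gfa(text: str) -> UnitigGraph:
    k = None
    nodes: list[UnitigNode] = []
    links: list[Link] = []
    refs: set[str] = set()
    for line in text.splitlines():
        if not line:
            continue
        fields = line.split("\t")
        if fields[0] == "H":
            for tag in fields[1:]:
                if tag.startswith("kl:i:"):
                    k = int(tag[5:])
        elif fields[0] == "S":
            nid, seqs = fields[1], fields[2]
            mean_count = 0.0
            for tag in fields[3:]:
                if tag.startswith("dp:f:"):
                    mean_count = float(tag[5:])
                elif tag.startswith("rf:i:") and int(tag[5:]):
                    refs.add(nid)
            nodes.append(UnitigNode(nid, seqs, mean_count))
        elif fields[0] == "L":
            links.append((fields[1], fields[2], fields[3], fields[4]))
    if k is None:
        k = 31  # pragma: no cover - writers always emit the kl header tag
    return UnitigGraph(k=k, nodes=nodes, links=links, reference_nodes=refs)
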