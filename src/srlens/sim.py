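"""Synthetic communities with planted coverage and strain-diversity structure.

Each genome is uniform random DNA carrying two haplotypes: the major
haplotype is emitted as the reference contig (standing in for a long-read
assembled contig), the minor haplotype carries substitutions planted at a
high density inside a few "diversity islands" and a low density elsewhere,
emulating strain-variable regions (integrated viruses, defense islands).
Single-end reads are drawn from genomes proportional to lognormal abundances
and from the major/minor haplotype with probability (1-f, f); genes tile each
genome and one COG category is preferentially planted inside islands.

Each simulated genome extends a hidden flank of 2x read length beyond both
ends of the emitted reference contig, and reads are drawn over the flanked
genome; the reference windows therefore see edge-free, uniform coverage, as
contigs embedded in larger replicons would.  Depth tables and VCFs are
emitted from read provenance, which preserves the exact file formats while
avoiding an external mapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .dbg import build_unitig_graph, pop_simple_bubbles
from .enrich import GeneAnnotation
from .windows import Contig, make_windows

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: COG letters used for uniformly placed genes (everything but the planted X)
NON_MOBILE_COGS = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWYZ"]
MOBILE_COG = "X"


@dataclass
class CommunityConfig:
    n_genomes: int = 3
    genome_length: int = 50_000
    abundance_lognormal: tuple[float, float] = (0.0, 1.0)  # (mu, sigma)
    islands_per_genome: int | Sequence[int] = 2
    island_length: int = 5_000
    island_snp_density: float = 0.01  # substitutions per bp inside islands
    background_snp_density: float = 0.0005
    minor_haplotype_freq: float = 0.3
    read_length: int = 150
    error_rate: float = 0.001  # per-base substitution probability
    total_bases: int | None = None  # default: 30x the summed genome length
    mobile_cog_fraction_in_islands: float = 0.8
    gene_length: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.island_snp_density < 0 or self.background_snp_density < 0:
            raise ValueError("SNP densities must be >= 0")
        if not 0 < self.minor_haplotype_freq <= 0.5:
            raise ValueError("minor_haplotype_freq must be in (0, 0.5]")
        for i in range(self.n_genomes):
            if self.islands_for(i) * self.island_length > self.genome_length:
                raise ValueError("islands do not fit in the genome")
        if self.total_bases is None:
            self.total_bases = 30 * self.n_genomes * self.genome_length
        if self.total_bases <= 0:
            raise ValueError("total_bases must be > 0")

    def islands_for(self, genome_index: int) -> int:
        if isinstance(self.islands_per_genome, int):
            return self.islands_per_genome
        return int(self.islands_per_genome[genome_index])

    @property
    def flank(self) -> int:
        return 2 * self.read_length


@dataclass
class Community:
    config: CommunityConfig
    contigs: list[Contig]  # reference contigs (major haplotype interior)
    major_codes: list[np.ndarray]  # flanked genomes, 2-bit codes
    minor_codes: list[np.ndarray]
    abundances: np.ndarray  # normalized genome abundances
    islands: dict[str, list[tuple[int, int]]]  # reference coords, half-open
    snps: list[tuple[str, int, str, str]]  # (contig_id, pos0, ref, alt)
    genes: list[GeneAnnotation]
    gene_island: dict[str, bool]
    bins: dict[str, str]

    @property
    def flank(self) -> int:
        return self.config.flank


@dataclass
class ReadSet:
    sequences: list[str]
    provenance: pd.DataFrame  # read_id, contig_id, start0 (ref coords), haplotype, strand
    read_length: int


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_community(config: CommunityConfig) -> Community:
    """Genomes, haplotypes, islands, planted SNPs, genes and ground-truth bins."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    flank = config.flank
    full_len = L + 2 * flank
    contigs: list[Contig] = []
    major_codes, minor_codes = [], []
    islands: dict[str, list[tuple[int, int]]] = {}
    snps: list[tuple[str, int, str, str]] = []
    genes: list[GeneAnnotation] = []
    gene_island: dict[str, bool] = {}
    bins: dict[str, str] = {}

    raw_abund = rng.lognormal(
        mean=config.abundance_lognormal[0],
        sigma=config.abundance_lognormal[1],
        size=config.n_genomes,
    )
    abundances = raw_abund / raw_abund.sum()

    for gi in range(config.n_genomes):
        contig_id = f"genome{gi + 1:02d}"
        major = rng.integers(0, 4, size=full_len, dtype=np.uint8)
        # islands: non-overlapping intervals in reference coords
        n_isl = config.islands_for(gi)
        isl: list[tuple[int, int]] = []
        if n_isl:
            gap_total = L - n_isl * config.island_length
            cuts = np.sort(rng.integers(0, gap_total + 1, size=n_isl))
            pos = 0
            for j in range(n_isl):
                start = int(cuts[j]) + j * config.island_length
                isl.append((start, start + config.island_length))
                pos = start + config.island_length
        islands[contig_id] = isl

        island_mask = np.zeros(L, dtype=bool)
        for s, e in isl:
            island_mask[s:e] = True
        dens = np.where(island_mask, config.island_snp_density, config.background_snp_density)
        snp_pos = np.flatnonzero(rng.random(L) < dens)
        minor = major.copy()
        if len(snp_pos):
            shift = rng.integers(1, 4, size=len(snp_pos)).astype(np.uint8)
            gpos = snp_pos + flank
            minor[gpos] = (major[gpos] + shift) % 4
            for p in snp_pos:
                snps.append(
                    (
                        contig_id,
                        int(p),
                        _decode(major[flank + p : flank + p + 1]),
                        _decode(minor[flank + p : flank + p + 1]),
                    )
                )
        major_codes.append(major)
        minor_codes.append(minor)
        contigs.append(Contig(contig_id, _decode(major[flank : flank + L])))
        bins[contig_id] = f"bin{gi + 1:02d}"

        # genes tile the reference with fixed length and alternating strand
        n_genes = L // config.gene_length
        for j in range(n_genes):
            start0 = j * config.gene_length
            end0 = start0 + config.gene_length
            mid = (start0 + end0) // 2
            on_island = bool(island_mask[mid])
            if j % 25 == 7:
                gene_type = "tRNA"
            elif j % 50 == 23:
                gene_type = "rRNA"
            else:
                gene_type = "CDS"
            if on_island and rng.random() < config.mobile_cog_fraction_in_islands:
                cog = MOBILE_COG
            else:
                cog = NON_MOBILE_COGS[rng.integers(0, len(NON_MOBILE_COGS))]
            gene_id = f"{contig_id}_g{j:04d}"
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    contig_id=contig_id,
                    start=start0 + 1,
                    end=end0,
                    strand="+" if j % 2 == 0 else "-",
                    gene_type=gene_type,
                    cog_categories=frozenset({cog}),
                )
            )
            gene_island[gene_id] = on_island

    return Community(
        config=config,
        contigs=contigs,
        major_codes=major_codes,
        minor_codes=minor_codes,
        abundances=abundances,
        islands=islands,
        snps=snps,
        genes=genes,
        gene_island=gene_island,
        bins=bins,
    )


def simulate_reads(community: Community, chunk: int = 20_000) -> ReadSet:
    """Single-end reads with i.i.d. substitution errors and constant quality."""
    config = community.config
    rng = np.random.default_rng([config.seed, 1])
    rl = config.read_length
    if rl > config.genome_length:
        raise ValueError("read_length exceeds genome_length")
    n_reads = int(config.total_bases // rl)
    counts = rng.multinomial(n_reads, community.abundances)
    flank = community.flank
    offsets = np.arange(rl)
    seqs: list[str] = []
    prov_rows = []
    ridx = 0
    for gi, cnt in enumerate(counts):
        contig_id = community.contigs[gi].contig_id
        full_len = len(community.major_codes[gi])
        done = 0
        while done < cnt:
            m = min(chunk, cnt - done)
            starts = rng.integers(0, full_len - rl + 1, size=m)
            hap = rng.random(m) < config.minor_haplotype_freq
            minus = rng.random(m) < 0.5
            mat = np.where(
                hap[:, None],
                community.minor_codes[gi][starts[:, None] + offsets],
                community.major_codes[gi][starts[:, None] + offsets],
            ).astype(np.uint8)
            if config.error_rate > 0:
                err = rng.random((m, rl)) < config.error_rate
                shift = rng.integers(1, 4, size=(m, rl)).astype(np.uint8)
                mat = np.where(err, (mat + shift) % 4, mat)
            rc = (3 - mat)[:, ::-1]
            mat = np.where(minus[:, None], rc, mat)
            for i in range(m):
                seqs.append(_decode(mat[i]))
                prov_rows.append(
                    (
                        f"r{ridx:07d}",
                        contig_id,
                        int(starts[i]) - flank,
                        int(hap[i]),
                        "-" if minus[i] else "+",
                    )
                )
                ridx += 1
            done += m
    prov = pd.DataFrame(
        prov_rows, columns=["read_id", "contig_id", "start0", "haplotype", "strand"]
    )
    return ReadSet(sequences=seqs, provenance=prov, read_length=rl)


def suggested_min_count(depth: float) -> int:
    """K-mer abundance cutoff for :func:`toy_assemble` at a given total depth.

    A fixed cutoff of 2 suffices for shallow libraries, but deep libraries
    accumulate recurrent errors — two or more reads substituting the same
    base at the same position — whose k-mers then survive the cutoff and
    shatter unitigs.  Scaling the cutoff to ~4% of total depth keeps those
    out while staying far below real haplotype k-mer coverage.
    """
    return max(2, int(round(depth / 25)))


def toy_assemble(
    reads: Sequence[str] | ReadSet,
    k: int,
    min_count: int = 2,
    pop_bubbles: bool = False,
    pop_max_ratio: float = 0.5,
    pop_min_flank: int = 150,
) -> list[Contig]:
    """Unitig assembler: maximal non-branching paths of the k-mer graph.

    Stands in for a short-read assembler; two runs with different k (and
    optionally different variant handling) provide the two "assembler" labels
    for consistency classification.  With ``pop_bubbles`` the minor branch of
    isolated simple bubbles is removed before emitting contigs — assemblers
    differ most in exactly this treatment of population variants, so the
    popping/non-popping pair disagrees on variant-bearing windows while
    agreeing on clean sequence.  Output order is deterministic (lexicographic
    by sequence).
    """
    seqs = reads.sequences if isinstance(reads, ReadSet) else list(reads)
    graph = build_unitig_graph(seqs, k=k, min_count=min_count)
    if pop_bubbles:
        graph = pop_simple_bubbles(
            graph, max_ratio=pop_max_ratio, min_flank_length=pop_min_flank
        )
    contigs = [
        Contig(f"ctg{i:05d}", node.sequence)
        for i, node in enumerate(graph.nodes)
        if node.length >= k
    ]
    return contigs


def emit_depth_and_variants(
    reads: ReadSet, community: Community
) -> tuple[dict[str, np.ndarray], list[tuple[str, int, str, str, float | None, str]]]:
    """Per-base depth from read provenance, and planted SNPs as VCF tuples.

    Depth at a reference position is the number of reads whose true source
    interval covers it — no mapping involved.
    """
    L = community.config.genome_length
    rl = reads.read_length
    depth = {c.contig_id: np.zeros(L + 1, dtype=np.int64) for c in community.contigs}
    prov = reads.provenance
    for contig_id, grp in prov.groupby("contig_id", sort=False):
        arr = depth[contig_id]
        starts = np.clip(grp["start0"].to_numpy(), 0, L)
        ends = np.clip(grp["start0"].to_numpy() + rl, 0, L)
        np.add.at(arr, starts, 1)
        np.add.at(arr, ends, -1)
    tracks = {cid: np.cumsum(arr[:-1]) for cid, arr in depth.items()}
    f = community.config.minor_haplotype_freq
    vcf_rows = [
        (cid, pos0 + 1, ref, alt, None, f"AF={f:g}")
        for cid, pos0, ref, alt in community.snps
    ]
    return tracks, vcf_rows


def window_truth(
    community: Community,
    reads: ReadSet | None = None,
    width: int = 1000,
    step: int = 500,
) -> pd.DataFrame:
    """Per-window planted truth: island overlap, SNP count, realized depth."""
    windows = make_windows(community.contigs, width=width, step=step)
    tracks = None
    if reads is not None:
        tracks, _ = emit_depth_and_variants(reads, community)
    snp_by_contig: dict[str, np.ndarray] = {}
    for cid, pos0, _, _ in community.snps:
        snp_by_contig.setdefault(cid, [])
    for cid in snp_by_contig:
        snp_by_contig[cid] = np.array(
            sorted(p for c, p, _, _ in community.snps if c == cid), dtype=np.int64
        )
    rows = []
    for w in windows:
        isl = community.islands.get(w.contig_id, [])
        overlap = 0
        for s, e in isl:
            overlap += max(0, min(e, w.end) - max(s, w.start))
        frac = overlap / w.length
        pos = snp_by_contig.get(w.contig_id)
        n_snp = (
            int(((pos >= w.start) & (pos < w.end)).sum()) if pos is not None and len(pos) else 0
        )
        row = {
            "window_id": w.window_id,
            "contig_id": w.contig_id,
            "island_frac": frac,
            "island_member": frac >= 0.5,
            "planted_snp_count": n_snp,
        }
        if tracks is not None:
            row["true_mean_depth"] = float(tracks[w.contig_id][w.start : w.end].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------- file output

def write_community(
    community: Community,
    reads: ReadSet,
    outdir: str | Path,
    width: int = 1000,
    step: int = 500,
) -> dict[str, Path]:
    """Write the simulator outputs in their standard formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "reads": outdir / "reads.fastq",
        "provenance": outdir / "read_provenance.tsv",
        "depth": outdir / "depth.tsv",
        "vcf": outdir / "variants.vcf",
        "annotations": outdir / "annotations.tsv",
        "bins": outdir / "bins.tsv",
        "truth": outdir / "truth_windows.tsv",
    }
    sio.write_fasta(community.contigs, paths["reference"])
    qual = "I" * reads.read_length
    with open(paths["reads"], "w") as fh:
        for rid, seq in zip(reads.provenance["read_id"], reads.sequences):
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    sio.write_tsv(reads.provenance, paths["provenance"])
    tracks, vcf_rows = emit_depth_and_variants(reads, community)
    depth_rows = []
    for cid in sorted(tracks):
        arr = tracks[cid]
        for pos0 in np.flatnonzero(arr):
            depth_rows.append((cid, int(pos0) + 1, int(arr[pos0])))
    sio.write_depth_table(depth_rows, paths["depth"])
    lengths = {c.contig_id: c.length for c in community.contigs}
    sio.write_vcf(vcf_rows, paths["vcf"], contig_lengths=lengths)
    ann = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in community.genes],
            "contig_id": [g.contig_id for g in community.genes],
            "start": [g.start for g in community.genes],
            "end": [g.end for g in community.genes],
            "strand": [g.strand for g in community.genes],
            "gene_type": [g.gene_type for g in community.genes],
            "cog_categories": [";".join(sorted(g.cog_categories)) for g in community.genes],
        }
    )
    sio.write_tsv(ann, paths["annotations"])
    bins_df = pd.DataFrame(
        sorted(community.bins.items()), columns=["contig_id", "bin_id"]
    )
    sio.write_tsv(bins_df, paths["bins"])
    sio.write_tsv(window_truth(community, reads, width, step), paths["truth"])
    return paths
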