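"""End-to-end orchestration: windowing -> coverage filter -> recovery ->
consistency -> graph metrics -> enrichment -> bin report.

Every stage writes its TSV under the output directory and logs record
counts; reruns with identical configuration and inputs are byte-identical.
``run_simulated_pipeline`` first generates a synthetic community (reference,
reads, depth, variants, annotations, bins, toy assemblies) and then runs the
same stages on those files, so the full pipeline closes with no external
tools.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .bins import bin_majority_counts, bin_summary_frame, summarize_bins
from .coverage import (
    count_snps,
    filter_reference_set,
    summarize_coverage,
    window_depth,
)
from .dbg import build_unitig_graph, compute_graph_metrics, export_gfa, mark_reference_nodes
from .enrich import assign_gene_groups, fisher_enrichment, gene_type_recovery, read_annotations
from .recovery import diff_histogram, hits_from_table, records_from_hits, recover_windows
from .sim import CommunityConfig, simulate_community, simulate_reads, toy_assemble, write_community
from .windows import make_windows

_log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path
    reference_fasta: Path
    assembly_fastas: dict[str, Path]  # label -> FASTA
    depth_tsv: Path | None = None
    vcf: Path | None = None
    reads_fastq: Path | None = None
    provenance_tsv: Path | None = None  # read_id, contig_id, start0 (for graph stage)
    annotations_tsv: Path | None = None
    bins_tsv: Path | None = None
    hits_tsv: dict[str, Path] | None = None  # precomputed 12-column alignments

    width: int = 1000
    step: int = 500
    min_breadth: float = 0.8
    min_depth: int = 1
    min_qual: float = 0.0
    min_identity: float = 99.0
    any_assembled_min: int = 100
    seed_k: int = 15
    k: int = 31
    min_count: int = 1
    max_dist: int = 3
    cov_threshold: float = 10.0
    min_cov: float = 1.0
    enrichment_mode: str = "merged"
    primary_pair: tuple[str, str] | None = None
    bin_label: str | None = None  # assembly label for bin summaries
    graph_window_ids: Sequence[str] | None = None  # None = all retained windows
    write_gfa: bool = False

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        self.reference_fasta = Path(self.reference_fasta)
        self.assembly_fastas = {k: Path(v) for k, v in self.assembly_fastas.items()}
        if not 0 <= self.min_breadth <= 1:
            raise ValueError("min_breadth must be in [0, 1]")
        if self.primary_pair is None:
            labs = list(self.assembly_fastas) or list(self.hits_tsv or {})
            if len(labs) >= 2:
                self.primary_pair = (labs[0], labs[1])

    @classmethod
    def from_file(cls, path: str | Path, **overrides):
        """Load from a simple ``key = value`` text file; unknown keys rejected."""
        known = {f.name for f in dc_fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            values[key] = val
        values.update(overrides)
        return cls(**values)  # type: ignore[arg-type]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    windows: list
    coverage: list
    retained: set[str]
    records: pd.DataFrame
    graph_metrics: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    gene_types: pd.DataFrame | None
    bin_summaries: pd.DataFrame | None
    bin_counts: tuple[int, int, int] | None
    outputs: dict[str, Path]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.monotonic()
            try:
                result = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            _log.info("stage %s done in %.1fs", name, time.monotonic() - t0)
            return result
        return wrapper
    return deco


#: linear prerequisites of each optional terminal stage
_STAGE_PREREQS = {
    "windows": (),
    "filter": ("windows",),
    "recover": ("windows", "filter"),
    "graph": ("windows", "filter"),
    "enrich": ("windows", "filter", "recover"),
    "bins": ("windows", "filter", "recover"),
}


def run_pipeline(config: PipelineConfig, stages: set[str] | None = None) -> PipelineResult:
    """Execute the pipeline; ``stages`` limits which terminal stages run
    (prerequisites are always computed)."""
    if stages is not None:
        unknown = stages - set(_STAGE_PREREQS)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        wanted = set(stages)
        for s in stages:
            wanted.update(_STAGE_PREREQS[s])
    else:
        wanted = set(_STAGE_PREREQS)
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    windows = _stage_windows(config, outputs)
    coverage, retained = _stage_filter(config, windows, outputs)
    records = (
        _stage_recover(config, windows, retained, outputs)
        if "recover" in wanted
        else pd.DataFrame()
    )
    gm = _stage_graph(config, windows, retained, outputs) if "graph" in wanted else None
    enr, gtr = (
        _stage_enrich(config, records, windows, retained, outputs)
        if "enrich" in wanted
        else (None, None)
    )
    bs, bc = (
        _stage_bins(config, records, coverage, outputs)
        if "bins" in wanted
        else (None, None)
    )
    return PipelineResult(
        windows=windows,
        coverage=coverage,
        retained=retained,
        records=records,
        graph_metrics=gm,
        enrichment=enr,
        gene_types=gtr,
        bin_summaries=bs,
        bin_counts=bc,
        outputs=outputs,
    )


@_stage("windows")
def _stage_windows(config, outputs):
    contigs = sio.read_fasta(_require(config.reference_fasta, "windows"))
    windows = make_windows(contigs, width=config.width, step=config.step)
    sio.write_fasta(
        [type(contigs[0])(w.window_id, w.sequence) for w in windows] if windows else [],
        config.outdir / "windows.fasta",
    )
    sio.write_window_index(windows, config.outdir / "windows.tsv")
    outputs["windows"] = config.outdir / "windows.tsv"
    _log.info("windows: %d windows from %d contigs", len(windows), len(contigs))
    return windows


@_stage("filter")
def _stage_filter(config, windows, outputs):
    widx = sio.read_window_index(config.outdir / "windows.tsv")
    tracks = window_depth(
        sio.parse_depth_table(_require(config.depth_tsv, "filter")), widx
    )
    snp_counts = None
    if config.vcf is not None:
        snp_counts = count_snps(sio.parse_vcf(config.vcf), widx, min_qual=config.min_qual)
    coverage = summarize_coverage(
        tracks,
        snp_counts=snp_counts,
        min_depth=config.min_depth,
        min_breadth=config.min_breadth,
        cov_threshold=config.cov_threshold,
    )
    retained = filter_reference_set(coverage, min_breadth=config.min_breadth)
    df = pd.DataFrame(
        {
            "window_id": [s.window_id for s in coverage],
            "mean_depth": [s.mean_depth for s in coverage],
            "breadth": [s.breadth for s in coverage],
            "pass_filter": [s.pass_filter for s in coverage],
            "snp_count": [s.snp_count for s in coverage],
            "coverage_class": [s.coverage_class for s in coverage],
        }
    )
    sio.write_tsv(df, config.outdir / "coverage.tsv")
    outputs["coverage"] = config.outdir / "coverage.tsv"
    _log.info("filter: %d/%d windows retained", len(retained), len(coverage))
    return coverage, retained


@_stage("recover")
def _stage_recover(config, windows, retained, outputs):
    if config.hits_tsv:
        hits_by_label = {
            label: hits_from_table(sio.parse_alignment_table(path), label)
            for label, path in config.hits_tsv.items()
        }
        records = records_from_hits(
            windows,
            hits_by_label,
            primary_pair=config.primary_pair,
            min_identity=config.min_identity,
            any_assembled_min=config.any_assembled_min,
            restrict_to=retained,
        )
    else:
        assemblies = {
            label: sio.read_fasta(path) for label, path in config.assembly_fastas.items()
        }
        records = recover_windows(
            windows,
            assemblies,
            primary_pair=config.primary_pair,
            seed_k=config.seed_k,
            min_identity=config.min_identity,
            any_assembled_min=config.any_assembled_min,
            restrict_to=retained,
        )
    sio.write_tsv(records, config.outdir / "recovery.tsv")
    outputs["recovery"] = config.outdir / "recovery.tsv"
    if config.primary_pair is not None and len(records):
        hist = diff_histogram(records["recovery_diff"])
        sio.write_tsv(hist, config.outdir / "diff_hist.tsv")
        outputs["diff_hist"] = config.outdir / "diff_hist.tsv"
    _log.info("recover: %d windows scored", len(records))
    return records


@_stage("graph")
def _stage_graph(config, windows, retained, outputs):
    if config.reads_fastq is None or config.provenance_tsv is None:
        _log.info("graph: skipped (no reads/provenance)")
        return None
    reads = sio.read_fastq_sequences(config.reads_fastq)
    prov = sio.read_tsv(config.provenance_tsv)
    rl = len(reads[0]) if reads else 0
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    order = np.arange(len(prov))
    for cid, grp in prov.groupby("contig_id", sort=False):
        by_contig[cid] = (grp["start0"].to_numpy(), order[grp.index.to_numpy()])
    wanted = set(config.graph_window_ids) if config.graph_window_ids is not None else None
    rows = []
    for w in windows:
        if w.window_id not in retained:
            continue
        if wanted is not None and w.window_id not in wanted:
            continue
        starts, idxs = by_contig.get(w.contig_id, (np.array([]), np.array([], dtype=int)))
        mask = (starts + rl > w.start) & (starts < w.end)
        sub = [reads[i] for i in idxs[mask]]
        graph = build_unitig_graph(sub, k=config.k, min_count=config.min_count)
        mark_reference_nodes(graph, w)
        m = compute_graph_metrics(graph, window_id=w.window_id, max_dist=config.max_dist)
        rows.append(
            {
                "window_id": m.window_id,
                "graph_size": m.graph_size,
                "n_reference_nodes": m.n_reference_nodes,
                "surrounding_nodes": m.surrounding_nodes,
                "mean_ref_node_coverage": m.mean_ref_node_coverage,
                "max_offref_coverage": m.max_offref_coverage,
            }
        )
        if config.write_gfa:
            gfa_dir = config.outdir / "gfa"
            gfa_dir.mkdir(exist_ok=True)
            safe = w.window_id.replace(":", "_")
            (gfa_dir / f"{safe}.gfa").write_text(export_gfa(graph))
    df = pd.DataFrame(rows)
    sio.write_tsv(df, config.outdir / "graph_metrics.tsv")
    outputs["graph_metrics"] = config.outdir / "graph_metrics.tsv"
    _log.info("graph: %d windows profiled", len(df))
    return df


@_stage("enrich")
def _stage_enrich(config, records, windows, retained, outputs):
    if config.annotations_tsv is None:
        _log.info("enrich: skipped (no annotations)")
        return None, None
    genes = read_annotations(config.annotations_tsv)
    widx = sio.read_window_index(config.outdir / "windows.tsv")
    labels = assign_gene_groups(
        genes, records, widx, mode=config.enrichment_mode, retained=retained
    )
    counts = pd.Series([labels[g.gene_id] for g in genes]).value_counts()
    if counts.get("fully", 0) == 0 or counts.get("not_fully", 0) == 0:
        # degenerate labeling (e.g. everything fully assembled): nothing to test
        _log.info("enrich: one label group is empty, emitting empty table")
        results = []
    else:
        results = fisher_enrichment(labels, genes)
    df = pd.DataFrame(
        {
            "category": [r.category for r in results],
            "a_fully": [r.a for r in results],
            "b_fully_other": [r.b for r in results],
            "c_notfully": [r.c for r in results],
            "d_notfully_other": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "direction": [r.direction for r in results],
        }
    )
    sio.write_tsv(df, config.outdir / "enrichment.tsv")
    outputs["enrichment"] = config.outdir / "enrichment.tsv"
    gtr = gene_type_recovery(genes, labels)
    sio.write_tsv(gtr, config.outdir / "gene_type_recovery.tsv")
    outputs["gene_type_recovery"] = config.outdir / "gene_type_recovery.tsv"
    _log.info("enrich: %d categories tested", len(df))
    return df, gtr


@_stage("bins")
def _stage_bins(config, records, coverage, outputs):
    if config.bins_tsv is None:
        _log.info("bins: skipped (no bin assignments)")
        return None, None
    assignments = sio.read_bins_table(config.bins_tsv)
    label = config.bin_label
    if label is None:
        label = (
            config.primary_pair[0]
            if config.primary_pair is not None
            else next(iter(config.assembly_fastas))
        )
    summaries = summarize_bins(
        assignments,
        records,
        label,
        coverage,
        cov_threshold=config.cov_threshold,
        min_cov=config.min_cov,
    )
    df = bin_summary_frame(summaries)
    sio.write_tsv(df, config.outdir / "bin_summary.tsv")
    outputs["bin_summary"] = config.outdir / "bin_summary.tsv"
    counts = bin_majority_counts(summaries)
    _log.info(
        "bins: %d bins, %d mostly fully recovered, %d mostly not recovered",
        counts[2], counts[0], counts[1],
    )
    return df, counts


def _require(path, stage):
    if path is None:
        raise StageError(stage, "required input missing")
    path = Path(path)
    if not path.exists():
        raise StageError(stage, f"input file not found: {path}")
    return path


# ------------------------------------------------------- simulated pipeline

def run_simulated_pipeline(
    community_config: CommunityConfig,
    outdir: str | Path,
    assembler_ks: tuple[int, int] = (21, 31),
    toy_min_count: int = 2,
    **pipeline_overrides,
) -> PipelineResult:
    """Simulate a community, toy-assemble it twice, run all stages.

    The two "assemblers" differ in k and in variant handling: the first
    fragments at every bubble, the second pops isolated simple bubbles the
    way aggressive assemblers resolve low-frequency variants — so the pair
    disagrees (NCA) where population variation sits and agrees (CA) on clean
    sequence.
    """
    outdir = Path(outdir)
    simdir = outdir / "sim"
    community = simulate_community(community_config)
    reads = simulate_reads(community)
    paths = write_community(
        community,
        reads,
        simdir,
        width=pipeline_overrides.get("width", 1000),
        step=pipeline_overrides.get("step", 500),
    )
    assembly_fastas = {}
    for kk, pop in zip(assembler_ks, (False, True)):
        label = f"toyasm_k{kk}"
        contigs = toy_assemble(reads, k=kk, min_count=toy_min_count, pop_bubbles=pop)
        path = simdir / f"{label}.fasta"
        sio.write_fasta(contigs, path)
        assembly_fastas[label] = path
    config = PipelineConfig(
        outdir=outdir,
        reference_fasta=paths["reference"],
        assembly_fastas=assembly_fastas,
        depth_tsv=paths["depth"],
        vcf=paths["vcf"],
        reads_fastq=paths["reads"],
        provenance_tsv=paths["provenance"],
        annotations_tsv=paths["annotations"],
        bins_tsv=paths["bins"],
        **pipeline_overrides,
    )
    return run_pipeline(config)
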