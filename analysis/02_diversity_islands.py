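"""Diversity-island study: strain variation as a driver of assembly failure.

Simulates a deep (200x) three-genome community in which each genome carries
two 6 kb "diversity islands" — regions where a 30%-frequency minor haplotype
diverges at 0.01 substitutions/bp — runs the full pipeline (recovery,
consistency, de Bruijn graph metrics, gene enrichment), and contrasts island
windows with clean windows at equal coverage.

Writes:
  results/diversity_window_table.tsv   per-window recovery + graph metrics + truth
  results/diversity_summary.tsv        island vs clean group statistics
  results/diff_hist.tsv                recovery-difference histogram between assemblers
  results/enrichment.tsv               per-COG-category Fisher/FDR results
  results/gene_type_recovery.tsv       CDS/tRNA/rRNA full-assembly fractions
Raw pipeline outputs land under scratch/analysis/diverse/.
"""

import shutil
import sys
from pathlib import Path

import pandas as pd
from scipy.stats import mannwhitneyu

from srlens.io import write_tsv
from srlens.pipeline import run_simulated_pipeline
from srlens.sim import (
    CommunityConfig,
    simulate_community,
    simulate_reads,
    suggested_min_count,
    window_truth,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis" / "diverse"
RESULTS = ROOT / "results"

SEED = 2


def main() -> None:
    cfg = CommunityConfig(
        n_genomes=3,
        genome_length=30_000,
        abundance_lognormal=(0.0, 0.0),
        islands_per_genome=2,
        island_length=6_000,
        island_snp_density=0.01,
        background_snp_density=0.0005,
        minor_haplotype_freq=0.3,
        error_rate=0.001,
        total_bases=200 * 90_000,
        seed=SEED,
    )
    result = run_simulated_pipeline(
        cfg, SCRATCH, toy_min_count=suggested_min_count(200)
    )
    community = simulate_community(cfg)
    reads = simulate_reads(community)
    truth = window_truth(community, reads)

    m = (
        result.records.merge(result.graph_metrics, on="window_id")
        .merge(truth.drop(columns=["contig_id"]), on="window_id")
    )
    RESULTS.mkdir(exist_ok=True)
    write_tsv(m, RESULTS / "diversity_window_table.tsv")

    island = m[m["island_frac"] == 1.0]
    clean = m[m["island_frac"] == 0.0]
    rows = []
    for metric in ("recovery_toyasm_k21", "recovery_toyasm_k31", "graph_size", "surrounding_nodes"):
        p = mannwhitneyu(island[metric], clean[metric]).pvalue
        rows.append(
            {
                "metric": metric,
                "island_mean": island[metric].mean(),
                "clean_mean": clean[metric].mean(),
                "island_median": island[metric].median(),
                "clean_median": clean[metric].median(),
                "mannwhitney_p": p,
                "n_island": len(island),
                "n_clean": len(clean),
            }
        )
    summary = pd.DataFrame(rows)
    write_tsv(summary, RESULTS / "diversity_summary.tsv")
    for name in ("diff_hist.tsv", "enrichment.tsv", "gene_type_recovery.tsv"):
        shutil.copy(SCRATCH / name, RESULTS / name)

    print(summary.to_string(index=False))
    cons = result.records["consistency"].value_counts()
    print(f"\nconsistency classes: {cons.to_dict()}")
    enr = result.enrichment.set_index("category")
    print(
        f"planted mobile-element category X: q = {enr.loc['X', 'q_value']:.2e} "
        f"({enr.loc['X', 'direction']})"
    )
    print(
        "\nIsland windows recover far worse than clean windows at identical 200x "
        "coverage, and their read graphs are larger and more interconnected — "
        "high within-population diversity, not lack of data, is what defeats the "
        "assemblers there; the genes planted in those islands (category X) come "
        "out strongly enriched among not-fully-assembled genes."
    )


if __name__ == "__main__":
    sys.exit(main())
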