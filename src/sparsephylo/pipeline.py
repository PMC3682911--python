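"""End-to-end orchestration: assemble -> search -> support -> diagnostics
-> audit, with deterministic per-stage seeding and checkpoint artifacts.

The master seed fans out to per-stage seeds through numpy SeedSequence
spawn keys in a fixed stage order (documented in STAGES), so any stage can
be re-run in isolation and reproduce its artifacts byte-identically.
"""
from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import assembly, diagnostics, formats, phylo, support, taxonomy
from .assembly import Supermatrix
from .formats import PartitionDef, read_fasta, read_taxonomy, write_newick
from .phylo import GTRGammaModel, LikelihoodEngine, PartitionedModel, PatternData
from .trees import Tree

#: stage order used for seed fan-out (index = spawn key)
STAGES = ("simulate", "assemble", "search", "support", "diagnose", "audit")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything the published protocol exposes as a knob."""

    output_dir: Path
    gene_fastas: dict[str, Path] = field(default_factory=dict)
    taxonomy_path: Optional[Path] = None
    min_total_bp: int = 250              # species below this total are dropped
    n_starts: int = 11                   # parsimony starting trees
    support_replicates: int = 1000       # RELL replicates
    strong_support: float = 85.0         # "strong support" convention
    summary_threshold: float = 85.0      # support summary uses strictly-greater
    gamma_categories: int = 4
    codon_partitions: bool = False       # split coding genes by codon position
    coding_genes: tuple[str, ...] = ()
    master_seed: int = 0

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        if self.n_starts < 1:
            raise PipelineError("need at least one search start")

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(self.master_seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


def build_partition_scheme(gene_parts: Sequence[PartitionDef],
                           coding_genes: Sequence[str]) -> list[PartitionDef]:
    """Default partitioning: by gene, with coding genes further split by
    codon position; rRNA (non-coding) genes stay unsplit."""
    out: list[PartitionDef] = []
    for p in gene_parts:
        if p.name in coding_genes:
            for pos in (1, 2, 3):
                out.append(PartitionDef(f"{p.name}_pos{pos}", p.start, p.end,
                                        codon_position=pos))
        else:
            out.append(p)
    return out


@dataclass
class RunResult:
    matrix: Supermatrix
    stats: assembly.MatrixStats
    tree: Tree
    lnl: float
    support_records: list
    regression: Optional[diagnostics.RegressionResult]
    support_summary: Optional[diagnostics.SupportSummary]
    audit_reports: list
    audit_summary: dict
    artifacts: dict[str, Path]


def assemble_matrix(cfg: RunConfig) -> Supermatrix:
    pools = {}
    for gene, path in cfg.gene_fastas.items():
        recs = read_fasta(path, gene)
        pools[gene] = assembly.select_longest_per_species(recs)
    m = assembly.concatenate(pools, gene_order=list(cfg.gene_fastas))
    m = assembly.filter_min_total(m, cfg.min_total_bp)
    m = assembly.deduplicate_identical(m)
    return m


def run_pipeline(cfg: RunConfig, matrix: Optional[Supermatrix] = None,
                 log=print) -> RunResult:
    """Run the full analysis.  `matrix` short-circuits assembly (used when
    the supermatrix was simulated in-process); otherwise the per-gene FASTA
    pools in the config are assembled first."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.time()

    def stage(name):
        log(f"[{time.time() - t0:7.1f}s] stage: {name}")

    try:
        stage("assemble")
        if matrix is None:
            if not cfg.gene_fastas:
                raise PipelineError(
                    "stage 'assemble' failed: no input matrix and no gene "
                    "FASTAs configured")
            matrix = assemble_matrix(cfg)
        stats = assembly.matrix_statistics(matrix)
        parts = build_partition_scheme(matrix.partitions, cfg.coding_genes) \
            if cfg.codon_partitions else matrix.partitions
        formats.write_nexus_matrix(matrix, matrix.partitions, out / "supermatrix.nex")
        formats.write_partition_file(parts, out / "partitions.txt")
        (out / "matrix_stats.txt").write_text(stats.report() + "\n")
        for line in matrix.removal_log:
            log("  " + line)
        artifacts["matrix"] = out / "supermatrix.nex"
        artifacts["partitions"] = out / "partitions.txt"
        artifacts["stats"] = out / "matrix_stats.txt"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'assemble' failed: {exc}") from exc

    try:
        stage("search")
        scheme = [PartitionDef(p.name, p.start, p.end, p.codon_position)
                  for p in parts]
        pm = PartitionedModel([
            (p, GTRGammaModel(n_categories=cfg.gamma_categories)) for p in scheme])
        sub = Supermatrix(list(matrix.taxa), matrix.data, scheme, [])
        data = PatternData.from_matrix(sub)
        tree, lnl = phylo.ml_search(data, pm, n_starts=cfg.n_starts,
                                    seed=cfg.stage_seed("search"))
        write_newick(tree, out / "best_tree.nwk")
        artifacts["best_tree"] = out / "best_tree.nwk"
        log(f"  best lnL = {lnl:.2f} over {cfg.n_starts} starts")
    except Exception as exc:
        raise PipelineError(f"stage 'search' failed: {exc}") from exc

    try:
        stage("support")
        tree, records = support.annotate_support(
            tree, data, pm, B=cfg.support_replicates,
            seed=cfg.stage_seed("support"))
        write_newick(tree, out / "best_tree_shl.nwk")
        support.write_support_table(records, out / "branch_support.tsv")
        artifacts["annotated_tree"] = out / "best_tree_shl.nwk"
        artifacts["support_table"] = out / "branch_support.tsv"
    except Exception as exc:
        raise PipelineError(f"stage 'support' failed: {exc}") from exc

    regression = summary = None
    try:
        stage("diagnose")
        try:
            regression = diagnostics.completeness_regression(tree, matrix)
        except diagnostics.DiagnosticsError as exc:
            log(f"  completeness regression skipped: {exc}")
        summary = diagnostics.support_summary(tree, cfg.summary_threshold)
        lines = [f"internal_edges\t{summary.n_internal_edges}",
                 f"percent_above_{cfg.summary_threshold:g}\t{summary.fraction_above:.1f}"]
        if regression is not None:
            lines += [f"completeness_r\t{regression.r:.4f}",
                      f"completeness_p\t{regression.p_value:.4f}",
                      f"slope\t{regression.slope:.6f}"]
        (out / "diagnostics.tsv").write_text("\n".join(lines) + "\n")
        artifacts["diagnostics"] = out / "diagnostics.tsv"
    except Exception as exc:
        raise PipelineError(f"stage 'diagnose' failed: {exc}") from exc

    reports, audit_summary = [], {}
    try:
        stage("audit")
        if cfg.taxonomy_path is not None:
            table = read_taxonomy(cfg.taxonomy_path)
            reports, audit_summary = taxonomy.audit_classification(
                tree, table, threshold=cfg.strong_support)
            taxonomy.write_audit_table(reports, out / "taxonomy_audit.tsv")
            (out / "audit_summary.json").write_text(
                json.dumps(audit_summary, indent=2, default=str) + "\n")
            artifacts["audit"] = out / "taxonomy_audit.tsv"
    except Exception as exc:
        raise PipelineError(f"stage 'audit' failed: {exc}") from exc

    stage("done")
    return RunResult(matrix, stats, tree, lnl, records, regression, summary,
                     reports, audit_summary, artifacts)
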