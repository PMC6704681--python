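"""End-to-end orchestration: screen -> similarity -> network -> modules -> report.

Runs the full analysis for one or more similarity measures over the same
input screen (a file or a synthetic configuration), writes every
intermediate artifact into the output directory, and collects a run report
with per-measure similarity summaries, network statistics, module
statistics and cross-measure comparisons (pairwise Clustering Error and
shared-gene counts).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assessment, community, network, sga_data, similarity, synthetic_data

__all__ = ["PipelineConfig", "MeasureRecord", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Exactly one of ``input_path`` (a tab-separated query x array matrix) or
    ``synthetic`` (a generator configuration) must be set.
    """

    out_dir: str
    input_path: str | None = None
    synthetic: synthetic_data.SyntheticConfig | None = None
    transformation: str = "one_square"
    measures: tuple = ("maryland_bridge", "ochiai", "braun_blanquet_max", "pearson")
    k_edges: int = 20000
    min_size: int = 5
    max_size: int = 50
    annotations_path: str | None = None
    reference_path: str | None = None
    unmeasured: str = "empty"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_path and synthetic")
        if not self.measures:
            raise ValueError("at least one similarity measure is required")
        for m in self.measures:
            if m not in similarity.MEASURES:
                raise ValueError(f"unknown similarity measure: {m!r}")
        if self.transformation not in ("one_square", "two_squares"):
            raise ValueError(f"unknown transformation: {self.transformation!r}")
        if self.k_edges < 1:
            raise ValueError("k_edges must be >= 1")


@dataclass
class MeasureRecord:
    """Everything the pipeline measured for one similarity measure."""

    measure: str
    summary: similarity.SimilaritySummary
    network_counts: dict
    n_modules: int
    genes_in_modules: int
    pct_of_giant: float
    solution: community.ClusteringSolution = field(repr=False)
    bhi: float | None = None
    enrichment: assessment.EnrichmentResult | None = None
    type1: int | None = None
    type2: int | None = None
    consistent_modules: int | None = None


@dataclass
class RunReport:
    measures: dict
    ce: pd.DataFrame
    shared_genes: pd.DataFrame
    universe: list


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


class _StageError(RuntimeError):
    pass


def _stage(name: str, measure: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise _StageError(f"stage {name!r} failed for measure {measure!r}: {exc}") from exc


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> RunReport:
    """Execute the pipeline and write artifacts under ``cfg.out_dir``.

    With ``resume=True`` previously written per-measure similarity matrices
    are loaded instead of recomputed, so a report can be rebuilt from the
    intermediates alone.  Deterministic: the same configuration (including
    any synthetic seed) produces byte-identical reports.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list = []

    if cfg.synthetic is not None:
        screen = synthetic_data.simulate_screen(cfg.synthetic)
        matrix = screen.matrix
        sga_data.write_interaction_matrix(matrix, out / "matrix.tsv")
        community.write_clustering(screen.truth_solution(), out / "truth_modules.tsv")
        assessment.write_annotations(screen.annotations, out / "annotations.tsv")
        annotations = screen.annotations
        log_lines.append(f"simulated screen: {len(matrix.query_ids)} query x {len(matrix.array_ids)} array genes")
    else:
        matrix = sga_data.read_interaction_matrix(cfg.input_path, unmeasured=cfg.unmeasured)
        annotations = None
        log_lines.append(f"read {cfg.input_path}: {len(matrix.query_ids)} query x {len(matrix.array_ids)} array genes")
    if cfg.annotations_path is not None:
        annotations = assessment.read_annotations(cfg.annotations_path)

    reference = None
    if cfg.reference_path is not None:
        reference = community.read_clustering(cfg.reference_path)

    universe = sga_data.gene_universe(matrix)
    supermatrix = sga_data.build_one_square(matrix)
    log_lines.append(f"gene universe: {len(universe)} genes")

    records: dict = {}
    for measure in cfg.measures:
        mdir = out / measure
        mdir.mkdir(exist_ok=True)
        sim_path = mdir / "similarity.tsv"
        if resume and sim_path.exists():
            sim = similarity.read_similarity_matrix(sim_path)
        else:
            if cfg.transformation == "one_square":
                sim = _stage("similarity", measure, similarity.similarity_one_square, supermatrix, measure)
            else:
                sim = _stage("similarity", measure, similarity.similarity_two_squares, matrix, measure)
            similarity.write_similarity_matrix(sim, sim_path)
        summary = _stage("summarize", measure, similarity.summarize, sim)
        net = _stage("network", measure, network.build_top_k_network, sim, cfg.k_edges)
        giant = _stage("giant_component", measure, network.giant_component, net)
        network.write_edge_list(giant, mdir / "edges.tsv")
        counts = network.network_summary(net, giant)
        solution = _stage(
            "modules", measure, community.girvan_newman_clustering, giant, cfg.min_size, cfg.max_size
        )
        community.write_clustering(solution, mdir / "clustering.tsv")
        genes_in_modules = len(solution.genes())
        record = MeasureRecord(
            measure=measure,
            summary=summary,
            network_counts=counts,
            n_modules=solution.n_modules,
            genes_in_modules=genes_in_modules,
            pct_of_giant=100.0 * genes_in_modules / counts["nodes_giant"],
            solution=solution,
        )
        if annotations is not None:
            try:
                record.bhi = assessment.bhi_solution(solution, annotations)
            except ValueError:
                record.bhi = None
            if solution.modules:
                record.enrichment = assessment.uncharacterized_enrichment(
                    solution, annotations, universe
                )
                types = [assessment.module_type(m, annotations) for m in solution.modules]
                record.type1 = types.count(1)
                record.type2 = types.count(2)
        if reference is not None and annotations is not None:
            record.consistent_modules = sum(
                assessment.module_consistency(m, reference, annotations) for m in solution.modules
            )
        records[measure] = record
        log_lines.append(
            f"{measure}: nodes={counts['nodes']} giant={counts['nodes_giant']} "
            f"modules={solution.n_modules} genes_in_modules={genes_in_modules}"
        )

    names = list(cfg.measures)
    ce = pd.DataFrame(0.0, index=names, columns=names)
    shared = pd.DataFrame(0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        sol_a, sol_b = records[a].solution, records[b].solution
        if sol_a.modules and sol_b.modules:
            val = assessment.clustering_error(sol_a, sol_b)
            ce.loc[a, b] = ce.loc[b, a] = val
            shared.loc[a, b] = shared.loc[b, a] = len(sol_a.genes() & sol_b.genes())
    for a in names:
        shared.loc[a, a] = len(records[a].solution.genes())

    report = RunReport(records, ce, shared, universe)
    _write_report(report, cfg, out)
    (out / "run.log").write_text("".join(line + "\n" for line in log_lines))
    _write_config(cfg, out / "config_resolved.txt")
    return report


def _write_report(report: RunReport, cfg: PipelineConfig, out: Path) -> None:
    rows = []
    for measure, rec in report.measures.items():
        row = {
            "measure": measure,
            "sim_mean": rec.summary.mean,
            "sim_variance": rec.summary.variance,
            "sim_median": rec.summary.median,
            "sim_min": rec.summary.minimum,
            "sim_max": rec.summary.maximum,
            "threshold_weight": rec.network_counts["threshold_weight"],
            "nodes": rec.network_counts["nodes"],
            "nodes_giant": rec.network_counts["nodes_giant"],
            "edges": rec.network_counts["edges"],
            "edges_giant": rec.network_counts["edges_giant"],
            "n_modules": rec.n_modules,
            "genes_in_modules": rec.genes_in_modules,
            "pct_of_giant": rec.pct_of_giant,
            "bhi": rec.bhi,
            "pct_uncharacterized": (
                100.0 * rec.enrichment.proportion if rec.enrichment else None
            ),
            "enrichment_direction": rec.enrichment.direction if rec.enrichment else None,
            "enrichment_p": rec.enrichment.p if rec.enrichment else None,
            "modules_with_uncharacterized": (
                rec.enrichment.n_modules_with_uncharacterized if rec.enrichment else None
            ),
            "type1_modules": rec.type1,
            "type2_modules": rec.type2,
            "consistent_modules": rec.consistent_modules,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    formatted = table.map(lambda x: "" if x is None or (isinstance(x, float) and np.isnan(x)) else _fmt(x))
    formatted.to_csv(out / "report.tsv", sep="\t", index=False)
    rounded = table.copy()
    for col in rounded.columns:
        if rounded[col].dtype.kind == "f":
            rounded[col] = rounded[col].round(2)
    rounded.to_csv(out / "report_rounded.tsv", sep="\t", index=False)
    report.ce.round(6).to_csv(out / "ce_matrix.tsv", sep="\t")
    report.shared_genes.to_csv(out / "shared_genes.tsv", sep="\t")


def _write_config(cfg: PipelineConfig, path: Path) -> None:
    lines = []
    for key, value in vars(cfg).items():
        if key == "synthetic" and value is not None:
            for skey, sval in vars(value).items():
                lines.append(f"synthetic.{skey}={sval}")
        else:
            lines.append(f"{key}={value}")
    path.write_text("".join(line + "\n" for line in lines))
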