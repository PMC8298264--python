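"""End-to-end orchestration: differential expression -> networks -> sets.

A single YAML config names the inputs, thresholds and seed; the pipeline
writes per-stage TSV/GraphML outputs plus a machine-readable JSON summary.
All randomness (Louvain node order) flows from the config seed.  A stage
failure aborts the run naming the stage; an output file interrupted mid-write
is left behind with a ``.partial`` suffix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import bpnet, diffexpr, io_tables, ipsets
from .io_tables import KO, WT

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    expression: str
    conditions: str
    annotations: str
    out_dir: str
    ip_annotations: str | None = None
    alpha: float = 0.05
    lfc_cut: float = 2.0
    increase_threshold: float = 1000.0
    reduced_threshold: float = 1.0
    equal_variance: bool = True
    weighted_centrality: bool = True
    require_up: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("alpha", "lfc_cut", "increase_threshold",
                     "reduced_threshold"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate_files(self) -> None:
        paths = [self.expression, self.conditions, self.annotations]
        if self.ip_annotations:
            paths.append(self.ip_annotations)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    writer(tmp)
    tmp.replace(path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute differential expression -> networks -> set analysis.

    Returns the run summary (also written to ``summary.json``): counts at
    each stage and the manifest of output files.
    """
    cfg.validate_files()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {"seed": cfg.seed}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
        return _Ctx()

    with _stage("diffexpr"):
        condition_of = io_tables.read_condition_map(cfg.conditions)
        matrix = io_tables.read_expression(cfg.expression, condition_of)
        de = diffexpr.differential_expression(
            matrix, alpha=cfg.alpha, lfc_cut=cfg.lfc_cut,
            equal_variance=cfg.equal_variance,
        )
        de_path = out / "de.tsv"
        _atomic_write(de_path, lambda p: io_tables.write_report(de, p))
        manifest["de"] = str(de_path)
        summary["genes_tested"] = int(len(de))
        summary["genes_significant"] = int(de["significant"].sum())
        summary["genes_selected"] = int(de["selected"].sum())

    with _stage("bpnet"):
        ann = io_tables.read_annotations(cfg.annotations)
        means = diffexpr.condition_means(matrix)
        nets = {}
        for cond, col in ((WT, "mean_wt"), (KO, "mean_ko")):
            net = bpnet.build_network(means[col].to_dict(), ann,
                                      condition=cond)
            nets[cond] = net
            path = out / f"{cond.lower()}.graphml"
            _atomic_write(path, lambda p, n=net: io_tables.write_graphml(
                n, p))
            manifest[f"net_{cond.lower()}"] = str(path)
        cent = {
            cond: bpnet.eigenvector_centrality(
                nets[cond], weighted=cfg.weighted_centrality)
            for cond in (WT, KO)
        }
        gene_nodes = nets[WT].gene_nodes | nets[KO].gene_nodes
        report = bpnet.centrality_rate_of_change(cent[WT], cent[KO],
                                                 nodes=gene_nodes)
        complements = bpnet.classify_functional_complements(
            report, de, increase_threshold=cfg.increase_threshold,
            require_up=cfg.require_up,
        )
        reduced = bpnet.classify_reduced_importance(
            cent[KO], threshold_pct=cfg.reduced_threshold,
            gene_nodes=nets[KO].gene_nodes,
        )
        report = bpnet.apply_classifications(report, complements, reduced)
        cent_path = out / "centrality.tsv"
        _atomic_write(cent_path,
                      lambda p: io_tables.write_report(report, p))
        manifest["centrality"] = str(cent_path)
        comp_path = out / "complements.tsv"
        comp_report = report[report["gene_id"].isin(complements)]
        _atomic_write(comp_path,
                      lambda p: io_tables.write_report(comp_report, p))
        manifest["complements"] = str(comp_path)
        partition = bpnet.louvain_communities(nets[KO], seed=cfg.seed)
        summary.update({
            "net_wt_genes": len(nets[WT].gene_nodes),
            "net_wt_bps": len(nets[WT].bp_nodes),
            "net_wt_edges": nets[WT].n_edges,
            "net_ko_genes": len(nets[KO].gene_nodes),
            "net_ko_bps": len(nets[KO].bp_nodes),
            "net_ko_edges": nets[KO].n_edges,
            "complements": sorted(complements),
            "n_complements": len(complements),
            "reduced_importance": sorted(reduced),
            "n_reduced": len(reduced),
            "ko_modularity": partition.modularity,
            "ko_communities": partition.n_communities,
        })

    if cfg.ip_annotations:
        with _stage("ipsets"):
            ip_ann = io_tables.read_ip_annotations(cfg.ip_annotations)
            selected = set(de.loc[de["selected"], "gene_id"])
            de_ann = ann.restrict_genes(selected)
            coverage = ipsets.akirin2_only_bps(de_ann, ip_ann)
            cov_path = out / "coverage.tsv"
            _atomic_write(cov_path,
                          lambda p: io_tables.write_report(coverage, p))
            manifest["coverage"] = str(cov_path)
            only = coverage.loc[coverage["akirin2_only"], "bp_id"].tolist()
            summary["n_bps_annotated"] = int(len(coverage))
            summary["n_bps_akirin2_only"] = int(len(only))
            summary["akirin2_only_bps"] = only
            if only:
                part = ipsets.membership_partition(de_ann, only)
                part_path = out / "partition.tsv"
                _atomic_write(
                    part_path,
                    lambda p: io_tables.write_report(
                        ipsets.partition_report(part), p),
                )
                manifest["partition"] = str(part_path)
                summary["partition_total_genes"] = part.total
                summary["partition_in_all"] = part.in_all

    summary["outputs"] = manifest
    _atomic_write(
        out / "summary.json",
        lambda p: Path(p).write_text(
            json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        ),
    )
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
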