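"""End-to-end orchestration: simulate -> filter -> stages -> enrich -> network.

A run is configured by a :class:`PipelineConfig` (YAML/JSON on disk) and
produces a run directory containing the generated inputs, the interactor
calls and filter ledger, the DE table, Venn and crosstab JSON, the clustered
heatmap matrix, per-stage enrichment tables and term networks, and a
machine-readable ``summary.json`` that echoes every count (all figures and
tables derive from it).  Runs are deterministic under a fixed seed; the
config hash and seed are embedded in the summary for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import tables_io
from .enrichment_network import (build_term_network, enrich_terms,
                                 results_to_frame, shared_terms, top_terms)
from .interactor_filter import FilterConfig, calls_to_frame, run_cascade
from .stage_expression import (DEConfig, compute_rpkm, de_test, heatmap_matrix,
                               intersect_tf, stage_crosstab, venn_partition)
from .synthetic_data import SimulationParams, simulate_all
from .tables_io import STAGES

logger = logging.getLogger(__name__)

__all__ = ["EnrichConfig", "PipelineConfig", "validate_config", "run_pipeline",
           "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class EnrichConfig:
    alpha: float = 0.01
    use_fdr: bool = False
    kappa_threshold: float = 0.4
    top_m: int = 20

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("enrichment.alpha must be in (0, 1)")
        if not -1 <= self.kappa_threshold <= 1:
            raise ConfigError("enrichment.kappa_threshold must be in [-1, 1]")
        if self.top_m < 1:
            raise ConfigError("enrichment.top_m must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "results/run"
    seed: int = 0
    sim: SimulationParams = field(default_factory=SimulationParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    de: DEConfig = field(default_factory=DEConfig)
    enrichment: EnrichConfig = field(default_factory=EnrichConfig)
    log_level: str = "INFO"

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_SECTION_TYPES = {"sim": SimulationParams, "filter": FilterConfig,
                  "de": DEConfig, "enrichment": EnrichConfig}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid '{section}' config: {exc}") from exc


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> PipelineConfig:
    """Parse, default and range-check a YAML/JSON pipeline config.

    Unknown keys are rejected with the offending name; omitted sections get
    their documented defaults.
    """
    if data is None:
        if path is None:
            raise ConfigError("need a path or a data dict")
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_known = {"outdir", "seed", "log_level", *_SECTION_TYPES}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        sub = data.get(name, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"'{name}' must be a mapping")
        if name == "sim" and "seed" not in sub:
            sub = {**sub, "seed": int(data.get("seed", 0))}
        sections[name] = _build_section(cls, sub, name)
    return PipelineConfig(outdir=str(data.get("outdir", "results/run")),
                          seed=int(data.get("seed", 0)),
                          log_level=str(data.get("log_level", "INFO")),
                          **sections)


def _write_inputs(outdir: Path, sim: dict) -> None:
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    for stage, tables in sim["quant"].items():
        for i, t in enumerate(tables, start=1):
            tables_io.write_quant_table(t, inputs / f"quant_{stage}_rep{i}.tsv")
    tables_io.write_crapome(sim["crapome"], inputs / "crapome.tsv")
    tables_io.write_expression_matrix(sim["transcriptome"], inputs / "counts.tsv")
    tables_io.write_gmt(sim["annotations"], inputs / "genesets.gmt")
    tables_io.write_tf_list(sim["tf_list"], inputs / "tf_list.txt")


def _read_inputs(outdir: Path, n_replicates: int) -> dict:
    inputs = outdir / "inputs"
    quant = {stage: [tables_io.read_quant_table(
        inputs / f"quant_{stage}_rep{i}.tsv")
        for i in range(1, n_replicates + 1)] for stage in STAGES}
    return {
        "quant": quant,
        "crapome": tables_io.read_crapome(inputs / "crapome.tsv"),
        "transcriptome": tables_io.read_expression_matrix(inputs / "counts.tsv"),
        "annotations": tables_io.read_gmt(inputs / "genesets.gmt"),
        "tf_list": tables_io.read_tf_list(inputs / "tf_list.txt"),
    }


def _truth_eval(calls, truth) -> dict:
    """Precision/recall of pooled final calls against ground-truth labels."""
    final_genes = {c.gene_symbol for c in calls if c.final_pass}
    true_genes = truth.genes_with_label("true_interactor")
    tp = len(final_genes & true_genes)
    fp = len(final_genes - true_genes)
    fn = len(true_genes - final_genes)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the whole analysis; returns the run directory."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ipmsflow")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())
    summary: dict = {"config_hash": config.hash(), "seed": config.seed}
    stage_name = "simulate"
    try:
        logger.info("run start: config hash %s seed %d", config.hash(), config.seed)
        sim = simulate_all(config.sim)
        _write_inputs(outdir, sim)
        stage_name = "read"
        data = _read_inputs(outdir, config.sim.n_replicates)

        stage_name = "filter"
        matrix = data["transcriptome"]
        expressed = {s: matrix.expressed_genes(s) for s in STAGES}
        calls, ledger = run_cascade(data["quant"], data["crapome"],
                                    expressed, config.filter)
        calls_to_frame(calls).to_csv(outdir / "interactor_calls.tsv",
                                     sep="\t", index=False)
        ledger.to_json(outdir / "filter_ledger.json")
        summary["ledger"] = json.loads(ledger.to_json())
        summary["truth_eval"] = _truth_eval(calls, sim["truth"])

        stage_name = "stages"
        de = de_test(matrix, config.de)
        de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        interactomes = {s: {c.gene_symbol for c in calls
                            if c.stage == s and c.final_pass} for s in STAGES}
        venn = venn_partition(interactomes["OPC"], interactomes["OL"])
        (outdir / "venn.json").write_text(json.dumps(venn.to_dict(), indent=2))
        summary["venn"] = {k: v for k, v in venn.to_dict().items()
                           if k.startswith("n_")}
        specific = {"OPC": set(venn.a_specific), "OL": set(venn.b_specific)}
        crosstab = stage_crosstab(specific, de)
        ct_dict = {s: ct.to_dict() for s, ct in crosstab.items()}
        (outdir / "crosstab.json").write_text(json.dumps(ct_dict, indent=2))
        summary["crosstab"] = ct_dict

        de_class = dict(zip(de["gene_id"], de["de_class"]))
        heat_genes = sorted(
            [g for g in specific["OPC"] if de_class.get(g) == "OPC_up"]
            + [g for g in specific["OL"] if de_class.get(g) == "OL_up"])
        rpkm = compute_rpkm(matrix)
        if heat_genes:
            mat, row_order, col_order, display = heatmap_matrix(rpkm, heat_genes)
            mat.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
            display.to_csv(outdir / "heatmap_display.tsv", sep="\t")
            (outdir / "heatmap_order.json").write_text(json.dumps(
                {"rows": [heat_genes[i] for i in row_order],
                 "columns": [str(mat.columns[i]) for i in range(len(mat.columns))]},
                indent=2))
        summary["n_heatmap_genes"] = len(heat_genes)

        tf = intersect_tf(interactomes, data["tf_list"])
        tf_out = {s: sorted(v) for s, v in tf["per_stage"].items()}
        (outdir / "tf_intersection.json").write_text(json.dumps(tf_out, indent=2))
        summary["tf_counts"] = {s: len(v) for s, v in tf_out.items()}

        stage_name = "enrich"
        enr_results = {}
        for s in STAGES:
            query = interactomes[s] & expressed[s]
            if not query:
                logger.warning("stage %s: empty interactome, skipping enrichment", s)
                continue
            results = enrich_terms(query, data["annotations"], expressed[s],
                                   alpha=config.enrichment.alpha,
                                   use_fdr=config.enrichment.use_fdr)
            enr_results[s] = results
            results_to_frame(results).to_csv(
                outdir / f"enrichment_{s}.tsv", sep="\t", index=False)
            top = top_terms(results, min(config.enrichment.top_m, len(results)))
            results_to_frame(top).to_csv(
                outdir / f"top_terms_{s}.tsv", sep="\t", index=False)
            network = build_term_network(
                results, data["annotations"], query,
                kappa_threshold=config.enrichment.kappa_threshold)
            tables_io.write_network(network, outdir / f"term_network_{s}.graphml")
            summary.setdefault("enrichment", {})[s] = {
                "n_tested": len(results),
                "n_enriched": sum(r.enriched for r in results),
                "n_network_terms": sum(
                    1 for _, d in network.nodes(data=True) if d["kind"] == "term"),
                "n_kappa_edges": sum(
                    1 for *_e, d in network.edges(data=True) if d["kind"] == "kappa"),
            }
        if len(enr_results) == 2:
            m = config.enrichment.top_m
            shared = shared_terms(enr_results["OPC"], enr_results["OL"],
                                  min(m, min(len(r) for r in enr_results.values())))
            summary["n_shared_top_terms"] = len(shared)

        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        sort_keys=True) + "\n")
        logger.info("run complete in %.1f s", time.monotonic() - t0)
        return outdir
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage_name}: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage_name, exc)
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
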