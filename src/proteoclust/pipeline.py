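"""End-to-end orchestration: simulate -> cluster -> analyze.

The pipeline reads a single YAML config (every threshold of the underlying
modules is overridable there), runs the fixed stage order prefilter ->
align -> graph -> Louvain -> census, and renders the report files: cluster
text file, edge list, census summary JSON, length/census/representation/
multiplicity report TSVs, and the anomaly findings TSV.  Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import anomaly, stats
from .align import EdgeCriteria, ScoringParams, build_homology_graph, write_edge_tsv
from .cluster import Clustering, classify_clusters, louvain
from .model import (ProteomeSet, read_cluster_file, read_fasta, read_metadata,
                    write_cluster_file)
from .prefilter import FilterParams
from .simulate import SimulationConfig, generate_pan_proteome, write_simulation

log = logging.getLogger("proteoclust")


@dataclass
class PipelineConfig:
    fasta: str = "sim.faa"
    metadata: str = "sim.meta.tsv"
    outdir: str = "out"
    seed: int = 0
    filter_params: FilterParams = field(default_factory=FilterParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    criteria: EdgeCriteria = field(default_factory=EdgeCriteria)
    louvain_min_gain: float = 1e-9
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # analysis thresholds
    truncation_low: float = 0.9
    truncation_high: float = 1.1
    fragment_max_gap_bp: int = 300
    fragment_sum_tol: float = 0.10
    missing_min_representation: float = 0.9
    representation_q: float = 0.9
    label_patterns: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("fasta", "metadata", "outdir", "seed", "louvain_min_gain",
                    "truncation_low", "truncation_high", "fragment_max_gap_bp",
                    "fragment_sum_tol", "missing_min_representation",
                    "representation_q", "label_patterns"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "filter" in raw:
            cfg.filter_params = FilterParams(**raw["filter"])
        if "scoring" in raw:
            cfg.scoring = ScoringParams(**raw["scoring"])
        if "criteria" in raw:
            cfg.criteria = EdgeCriteria(**raw["criteria"])
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            for tup_key in ("family_length_range", "identity_range"):
                if tup_key in sim:
                    sim[tup_key] = tuple(sim[tup_key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic pan-proteome and write FASTA/metadata/truth."""
    sim = config.simulation
    sim.rng_seed = config.seed
    sim.validate()
    proteome, truth = generate_pan_proteome(sim)
    paths = write_simulation(proteome, truth, config.outdir)
    log.info("simulate: %d organisms, %d records", proteome.n_organisms,
             proteome.n_records)
    return paths


def load_proteome(config: PipelineConfig) -> ProteomeSet:
    entries = read_fasta(config.fasta)
    if not entries:
        raise ValueError("no sequences")
    return read_metadata(config.metadata, entries)


def run_cluster(config: PipelineConfig) -> tuple[ProteomeSet, Clustering, dict]:
    """Prefilter -> align -> graph -> Louvain -> census; write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = load_proteome(config)
    log.info("input: %d sequences from %d organisms", proteome.n_records,
             proteome.n_organisms)
    graph, accepted = build_homology_graph(proteome, config.filter_params,
                                           config.scoring, config.criteria)
    log.info("graph: %d vertices, %d accepted edges", graph.n_vertices,
             graph.n_edges)
    clustering = louvain(graph, seed=config.seed, min_gain=config.louvain_min_gain,
                         proteome=proteome)
    census = clustering.census or classify_clusters(clustering, proteome)
    log.info("clusters: %d total (Q=%.4f)", clustering.n_clusters,
             clustering.modularity)
    write_cluster_file(clustering.assignment, proteome, outdir / "clusters.tsv")
    write_edge_tsv(accepted, outdir / "edges.tsv")
    summary = {
        "n_sequences": proteome.n_records,
        "n_organisms": proteome.n_organisms,
        "n_edges": graph.n_edges,
        "modularity": clustering.modularity,
        "total_clusters": census.total,
        "singletons": census.singleton,
        "single_organism_multi": census.single_organism_multi,
        "multi_organism": census.multi_organism,
    }
    with open(outdir / "census.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return proteome, clustering, summary


def run_analyze(config: PipelineConfig) -> dict:
    """Descriptive stats and anomaly findings from an existing cluster file."""
    outdir = Path(config.outdir)
    cluster_path = outdir / "clusters.tsv"
    if not cluster_path.exists():
        raise FileNotFoundError(f"cluster file {cluster_path} not found; run cluster first")
    proteome = load_proteome(config)
    assignment = read_cluster_file(cluster_path)
    if set(assignment) != set(proteome.records):
        raise ValueError("cluster file does not cover the proteome")

    clusters: dict[int, list[str]] = {}
    for sid, cid in assignment.items():
        clusters.setdefault(cid, []).append(sid)

    with open(outdir / "length_stats.tsv", "w") as fh:
        fh.write("cluster_id\tn_sequences\tmin\tmean\tmax\tstd_dev\n")
        for cid in sorted(clusters):
            row = stats.length_stats(clusters[cid], proteome).row()
            fh.write("\t".join(str(x) for x in (cid, *row)) + "\n")

    with open(outdir / "label_census.tsv", "w") as fh:
        fh.write("cluster_id\tannotation\tcount\tpercent\n")
        for cid in sorted(clusters):
            census = stats.label_census(clusters[cid], proteome)
            for lab, count, pct in census.entries:
                fh.write(f"{cid}\t{lab}\t{count}\t{pct:.2f}\n")

    profile = stats.representation_profile(assignment, proteome,
                                           config.representation_q)

    findings: list[anomaly.AnomalyFinding] = []
    for cid in sorted(clusters):
        mem = clusters[cid]
        if len(mem) >= 3:
            findings.extend(anomaly.detect_truncated(
                mem, proteome, config.truncation_low, config.truncation_high))
            findings.extend(anomaly.detect_missing_members(
                mem, proteome, config.missing_min_representation))
    findings.extend(anomaly.detect_fragment_pairs(
        proteome, assignment, config.fragment_max_gap_bp, config.fragment_sum_tol))
    if config.label_patterns:
        label_map = anomaly.infer_label_map(config.label_patterns, assignment, proteome)
        findings.extend(anomaly.detect_mislabeled(assignment, proteome, label_map))
    anomaly.write_findings_tsv(findings, outdir / "findings.tsv")
    log.info("analyze: %d findings, representation profile(q=%.2f)=%.3f",
             len(findings), config.representation_q, profile)

    report = {
        "n_clusters": len(clusters),
        "representation_q": config.representation_q,
        "representation_profile": profile,
        "n_findings": len(findings),
        "findings_by_kind": {
            k: sum(1 for f in findings if f.kind == k) for k in anomaly.KINDS
        },
    }
    with open(outdir / "analysis.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_all(config: PipelineConfig) -> dict:
    paths = run_simulate(config)
    config.fasta = str(paths["fasta"])
    config.metadata = str(paths["metadata"])
    _, _, summary = run_cluster(config)
    report = run_analyze(config)
    return {"census": summary, "analysis": report}
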