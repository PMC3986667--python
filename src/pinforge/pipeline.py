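"""Config-driven orchestration of the full construction-and-analysis arc.

fixture -> interolog sub-networks -> iterative integration -> confidence
scores -> topology -> signaling sub-network and evolutionary origins ->
neighbor-majority function assignment.  Every stage writes a plain TSV
artifact and the run ends with a checksum manifest, so identical config
and seed reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import homology, integration, signaling, synthetic, topology
from . import function_assignment as fa
from .errors import ConfigError, UsageError
from .io_formats import (
    read_annotations,
    read_blast_tab,
    read_interactions,
    read_obo,
    write_network,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    input_dir: Path | None = None          # existing fixture dir; None = generate
    n_families: int = 50
    evalue_max: float = 1e-5
    score_bin_width: int = 5
    high_score_cutoff: int = 30
    hub_degree_cutoff: int = 33
    signaling_go_id: str = signaling.SIGNALING_GO_ID
    assignment_threshold: float = 0.25
    force: bool = False
    organisms: list[tuple[str, str, float]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw: dict[str, Any] = yaml.safe_load(handle) or {}
        raw["out_dir"] = Path(raw.get("out_dir", "pinforge_out"))
        if raw.get("input_dir"):
            raw["input_dir"] = Path(raw["input_dir"])
        raw["organisms"] = [tuple(o) for o in raw.get("organisms", [])]
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the run manifest."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise UsageError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 0: fixture ------------------------------------------------
    if config.input_dir is None:
        universe_config = synthetic.UniverseConfig(
            seed=config.seed, n_families=config.n_families
        )
        universe = synthetic.generate_universe(universe_config)
        fixture_dir = out / "fixture"
        synthetic.write_fixture(universe, fixture_dir)
        logger.info("fixture: %d families, %d organisms",
                    config.n_families, len(universe.organisms))
    else:
        fixture_dir = Path(config.input_dir)
        if not fixture_dir.exists():
            raise ConfigError(f"input directory {fixture_dir} does not exist")

    organisms = _read_organisms(fixture_dir / "organisms.tsv")
    if len(organisms) < 2:
        raise ConfigError("pipeline needs at least 2 organisms")
    stage_map = {name: stage for name, stage, _ in organisms}
    order = [name for name, _, _ in organisms]

    dag = read_obo(fixture_dir / "go.obo")
    annotations = read_annotations(fixture_dir / "annotations.tsv", dag)
    pathways = signaling.read_pathways(fixture_dir / "pathways.tsv")

    # --- stage 1: interolog sub-networks ---------------------------------
    subnets: list[homology.SubNetwork] = []
    summaries = []
    for name in order:
        records = read_interactions(
            fixture_dir / "interactions" / f"{name}.mitab.txt",
            organism=name,
        )
        hits = read_blast_tab(fixture_dir / "blastx" / f"{name}.tsv")
        best = homology.best_hits(hits, config.evalue_max)
        unigene_map = homology.map_unigenes(best)
        sub = homology.build_subnetwork(records, unigene_map, name, stage_map[name])
        subnets.append(sub)
        summaries.append(
            homology.subnetwork_summary(sub, n_input_interactions=len(records))
        )
        logger.info("subnet %s: %d proteins, %d interactions",
                    name, len(sub.nodes), len(sub.edges))
    _write_tsv(
        out / "subnetworks.tsv",
        ["organism", "n_unigenes", "n_proteins", "n_interactions",
         "interaction_fraction"],
        [[s["organism"], s["n_unigenes"], s["n_proteins"], s["n_interactions"],
          round(s.get("interaction_fraction", 0.0), 4)] for s in summaries],
    )

    # --- stage 2: integration & scoring ----------------------------------
    hit_tables = {}
    for q in order:
        for t in order:
            if q != t:
                path = fixture_dir / "blastp" / f"{q}__{t}.tsv"
                if path.exists():
                    hit_tables[(q, t)] = read_blast_tab(path)
    network = integration.integrate_all(subnets, hit_tables, config.evalue_max)
    write_network(network, out / "network.tsv")
    _write_tsv(
        out / "turn_log.tsv",
        ["turn", "query_organism", "nodes", "edges"],
        [[e.turn, e.query_organism, e.n_nodes, e.n_edges]
         for e in network.turn_log],
    )
    histogram = integration.score_distribution(network, config.score_bin_width)
    _write_tsv(
        out / "score_distribution.tsv",
        ["low", "high", "count", "percent"],
        [[b["low"], b["high"], b["count"], round(b["percent"], 4)]
         for b in histogram],
    )
    high = integration.filter_by_score(network, config.high_score_cutoff)
    write_network(high, out / "high_score_network.tsv")

    # --- stage 3: topology ------------------------------------------------
    graph = network.graph()
    topo_rows = []
    for sub in subnets:
        g = sub.graph()
        if g.number_of_nodes():
            report = topology.topology_report(g, lwcc_only=True)
            topo_rows.append([sub.organism, *_topo_row(report)])
    full_report = topology.topology_report(graph, lwcc_only=True)
    topo_rows.append(["integrated", *_topo_row(full_report)])
    _write_tsv(
        out / "topology.tsv",
        ["network", "nodes", "edges", "diameter", "average_path_length",
         "clustering_coefficient", "average_degree", "index_aggregation"],
        topo_rows,
    )
    hub_list = topology.hubs(graph, config.hub_degree_cutoff)
    _write_tsv(out / "hubs.tsv", ["protein", "degree"],
               [[h, graph.degree(h)] for h in hub_list])

    # --- stage 4: signaling & evolution ----------------------------------
    sig = signaling.extract_go_subnetwork(
        graph, annotations, config.signaling_go_id, dag, expand_neighbors=True
    )
    origins = signaling.analyze_origins(network, stage_map)
    _write_tsv(
        out / "signaling_subnetwork.tsv",
        ["protein_a", "protein_b", "evo_group", "complete_origin"],
        [[a, b,
          origins.evo_groups.get(tuple(sorted((a, b))), ""),
          origins.complete_origins.get(tuple(sorted((a, b))), "")]
         for a, b in sorted(sig.graph.edges)],
    )
    profile_rows = []
    for pathway, members in sorted(pathways.items()):
        profile = signaling.pathway_origin_profile(
            graph, members, origins.complete_origins
        )
        for stage, fraction in profile.items():
            profile_rows.append([pathway, stage, round(fraction, 4)])
    _write_tsv(out / "pathway_origins.tsv",
               ["pathway", "stage", "proportion"], profile_rows)

    # --- stage 5: function assignment ------------------------------------
    result = fa.assign_functions(
        graph, annotations, threshold=config.assignment_threshold
    )
    _write_tsv(
        out / "assigned_functions.tsv",
        ["protein", "go_id", "go_depth", "support"],
        [[p, t, fa.go_depth(dag, t), round(result.provenance[p][t], 4)]
         for p in sorted(result.assigned) for t in sorted(result.assigned[p])],
    )
    depth_dist = fa.depth_distribution(result, dag)
    _write_tsv(out / "assignment_depths.tsv", ["depth", "count"],
               [[d, c] for d, c in depth_dist.items()])

    n_unclassified = sum(
        1 for v in graph.nodes if not annotations.get(v)
    )
    manifest = {
        "seed": config.seed,
        "organisms": order,
        "stages": {
            "subnetworks": summaries,
            "integration": {
                "n_nodes": len(network.nodes),
                "n_edges": len(network.edges),
                "turns": [[e.turn, e.query_organism, e.n_nodes, e.n_edges]
                          for e in network.turn_log],
            },
            "topology": dict(zip(
                ["nodes", "edges", "diameter", "average_path_length",
                 "clustering_coefficient", "average_degree",
                 "index_aggregation"], _topo_row(full_report))),
            "signaling": {
                "n_seeds": len(sig.seeds),
                "n_isolated_seeds": len(sig.isolated_seeds),
                "n_interactions": sig.n_interactions,
            },
            "assignment": {
                "n_assigned": len(result.assigned),
                "n_unclassified": n_unclassified,
                "coverage": (len(result.assigned) / n_unclassified
                             if n_unclassified else None),
                "rounds": result.rounds,
            },
        },
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.tsv"))
        },
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def report(manifest: dict) -> str:
    """Human-readable summary of a completed run."""
    lines = ["pinforge run summary", "===================="]
    stages = manifest.get("stages", {})
    if "integration" in stages:
        lines.append("integration growth (turn, query, nodes, edges):")
        for row in stages["integration"]["turns"]:
            lines.append("  turn %d  %-8s nodes=%d edges=%d" % tuple(row))
    if "topology" in stages:
        topo = stages["topology"]
        lines.append("LWCC topology:")
        for key, value in topo.items():
            lines.append(f"  {key}: {value}")
    if "signaling" in stages:
        sig = stages["signaling"]
        lines.append(
            "signaling: %d seed proteins (%d isolated), %d interactions"
            % (sig["n_seeds"], sig["n_isolated_seeds"], sig["n_interactions"])
        )
    if "assignment" in stages:
        a = stages["assignment"]
        cov = f"{100 * a['coverage']:.0f}%" if a["coverage"] is not None else "n/a"
        lines.append(
            "function assignment: %d of %d unclassified proteins (%s) in %d rounds"
            % (a["n_assigned"], a["n_unclassified"], cov, a["rounds"])
        )
    if not stages:
        lines.append("(manifest incomplete — partial report)")
    return "\n".join(lines)


def _topo_row(r: topology.TopologyReport) -> list:
    return [r.n_nodes, r.n_edges, r.diameter, round(r.average_path_length, 4),
            round(r.clustering_coefficient, 4), round(r.average_degree, 4),
            round(r.index_aggregation, 4)]


def _read_organisms(path: Path) -> list[tuple[str, str, float]]:
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("organism\t"):
                continue
            name, stage, order, retention = line.split("\t")[:4]
            rows.append((int(order), name, stage, float(retention)))
    rows.sort()
    return [(name, stage, retention) for _, name, stage, retention in rows]


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()
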