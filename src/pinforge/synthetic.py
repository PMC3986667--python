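"""Synthetic multi-organism universe with known ground truth.

The generator emulates the data situation of a transcriptome-only target
organism surrounded by six annotated model organisms: ortholog families
shared across organisms with stage-dependent retention, family-level
interactions partially conserved per organism, unigene (transcript)
homology hits with BLAST-like E-values, cross-organism protein homology
tables, a small rooted GO DAG, partial per-protein annotation, one
planted pathway and planted per-protein function labels.  Every piece of
downstream machinery (best-hit selection, interolog filtering, iterative
integration, GO sub-network extraction, origin classification, function
assignment) can therefore be validated against planted truth without any
external download.

True homology hits sample E-values log-uniformly in [1e-50, 1e-6] and
decoys in [1e-4, 1], cleanly separated around the 1e-5 acceptance
threshold, so best-hit selection recovers exactly the planted ortholog
pairs.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .io_formats import BLAST_COLUMNS, HomologyHit

# Six organisms mirroring the classic model-organism panel: two
# bilaterian invertebrates, three vertebrates, one primitive unicellular.
# The listed order is the integration order (closest relative first);
# retention probabilities echo the very different sub-network sizes such
# panels produce.
DEFAULT_ORGANISMS: tuple[tuple[str, str, float], ...] = (
    ("Dmel", "B", 0.80),
    ("Cele", "B", 0.55),
    ("Hsap", "V", 0.70),
    ("Rnor", "V", 0.45),
    ("Mmus", "V", 0.50),
    ("Scer", "P", 0.60),
)

TRUE_EVALUE_RANGE = (1e-50, 1e-6)
DECOY_EVALUE_RANGE = (1e-4, 1.0)


@dataclass(frozen=True)
class UniverseConfig:
    seed: int = 0
    n_families: int = 50
    organisms: tuple[tuple[str, str, float], ...] = DEFAULT_ORGANISMS
    edge_density: float = 0.08
    interaction_conservation: float = 0.7
    unigene_coverage: float = 0.9
    multi_unigene_prob: float = 0.15
    annotation_coverage: float = 0.7
    n_go_terms: int = 40
    go_max_depth: int = 6
    decoy_prob: float = 0.5
    pathway_size: int = 8

    def validate(self) -> None:
        if self.n_families < 0:
            raise ConfigError("n_families must be >= 0")
        if not self.organisms:
            raise ConfigError("at least one organism is required")
        for name, stage, retention in self.organisms:
            if stage not in ("P", "B", "V"):
                raise ConfigError(f"{name}: stage must be P, B or V")
            if not 0.0 <= retention <= 1.0:
                raise ConfigError(f"{name}: retention_prob outside [0, 1]")
        for attr in (
            "edge_density", "interaction_conservation", "unigene_coverage",
            "multi_unigene_prob", "annotation_coverage", "decoy_prob",
        ):
            value = getattr(self, attr)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{attr} outside [0, 1]")
        if self.n_go_terms < 2:
            raise ConfigError("n_go_terms must be >= 2 (root + signaling)")
        if self.go_max_depth < 1:
            raise ConfigError("go_max_depth must be >= 1")


@dataclass
class SyntheticUniverse:
    config: UniverseConfig
    organisms: tuple[tuple[str, str, float], ...]
    families: list[str]
    proteins: dict[tuple[str, str], str]          # (organism, family) -> protein id
    presence: dict[str, set[str]]                 # organism -> families present
    family_edges: set[tuple[str, str]]            # family-level interactions
    interactions: dict[str, list[tuple[str, str]]]  # organism -> protein pairs
    unigene_to_family: dict[str, str]
    blastx: dict[str, list[tuple]]                # organism -> outfmt6 rows
    blastp: dict[tuple[str, str], list[tuple]]    # (query org, target org) -> rows
    planted_unigene_best: dict[str, dict[str, str]]  # org -> unigene -> protein
    planted_cross_best: dict[tuple[str, str], dict[str, str]]
    go_terms: dict[str, tuple[str, str, tuple[str, ...]]]  # id -> (name, ns, parents)
    go_root: str
    annotations: dict[str, set[str]]              # protein -> GO terms
    pathway_families: set[str]
    planted_functions: dict[str, str]             # protein -> true GO term
    family_functions: dict[str, str]              # family -> true GO term

    def blastx_hits(self, organism: str) -> list[HomologyHit]:
        return _rows_to_hits(self.blastx.get(organism, []))

    def blastp_hits(self, query_org: str, target_org: str) -> list[HomologyHit]:
        return _rows_to_hits(self.blastp.get((query_org, target_org), []))

    def stage_map(self) -> dict[str, str]:
        return {name: stage for name, stage, _ in self.organisms}

    def pathway_proteins(self) -> set[str]:
        return {
            self.proteins[(org, fam)]
            for org, _, _ in self.organisms
            for fam in self.pathway_families
            if (org, fam) in self.proteins
        }


def _rows_to_hits(rows: Sequence[tuple]) -> list[HomologyHit]:
    hits = []
    rank_counter: dict[str, int] = {}
    for row in rows:
        query = row[0]
        rank = rank_counter.get(query, 0)
        rank_counter[query] = rank + 1
        hits.append(
            HomologyHit(
                query=query, subject=row[1],
                evalue=float(row[10]), bitscore=float(row[11]), rank=rank,
            )
        )
    return hits


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    value = 10.0 ** rng.uniform(math.log10(low), math.log10(high))
    return float(f"{value:.3e}")  # freeze at written precision for round trips


def _hit_row(
    rng: np.random.Generator, query: str, subject: str, true_hit: bool
) -> tuple:
    if true_hit:
        evalue = _log_uniform(rng, *TRUE_EVALUE_RANGE)
        bitscore = round(float(rng.uniform(100.0, 400.0)), 1)
        pident = round(float(rng.uniform(60.0, 100.0)), 2)
    else:
        evalue = _log_uniform(rng, *DECOY_EVALUE_RANGE)
        bitscore = round(float(rng.uniform(20.0, 40.0)), 1)
        pident = round(float(rng.uniform(20.0, 40.0)), 2)
    length = int(rng.integers(80, 500))
    return (
        query, subject, pident, length, int(rng.integers(0, 30)),
        int(rng.integers(0, 5)), 1, length, 1, length, evalue, bitscore,
    )


def generate_universe(config: UniverseConfig) -> SyntheticUniverse:
    """Sample a complete universe; deterministic for a given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    org_names = [name for name, _, _ in config.organisms]

    families = [f"F{i:04d}" for i in range(1, config.n_families + 1)]

    presence: dict[str, set[str]] = {}
    proteins: dict[tuple[str, str], str] = {}
    for name, _, retention in config.organisms:
        kept = {f for f in families if rng.random() < retention}
        presence[name] = kept
        for fam in sorted(kept):
            proteins[(name, fam)] = f"{name}_{fam}"

    family_edges: set[tuple[str, str]] = set()
    for i, fa in enumerate(families):
        for fb in families[i + 1:]:
            if rng.random() < config.edge_density:
                family_edges.add((fa, fb))

    interactions: dict[str, list[tuple[str, str]]] = {}
    for name in org_names:
        realized = []
        for fa, fb in sorted(family_edges):
            if fa in presence[name] and fb in presence[name]:
                if rng.random() < config.interaction_conservation:
                    realized.append((proteins[(name, fa)], proteins[(name, fb)]))
        interactions[name] = realized

    # unigenes: the target organism's transcripts, one or two per covered family
    unigene_to_family: dict[str, str] = {}
    family_unigenes: dict[str, list[str]] = {}
    counter = 1000
    for fam in families:
        if rng.random() < config.unigene_coverage:
            k = 2 if rng.random() < config.multi_unigene_prob else 1
            ids = []
            for _ in range(k):
                uid = f"Unigene{counter}_A0A"
                counter += 1
                unigene_to_family[uid] = fam
                ids.append(uid)
            family_unigenes[fam] = ids

    # BLASTX-style unigene -> protein hits, one table per organism
    blastx: dict[str, list[tuple]] = {}
    planted_unigene_best: dict[str, dict[str, str]] = {}
    for name in org_names:
        rows: list[tuple] = []
        truth: dict[str, str] = {}
        org_proteins = sorted(proteins[(name, f)] for f in presence[name])
        for fam in families:
            for uid in family_unigenes.get(fam, []):
                per_query: list[tuple] = []
                subject = None
                if fam in presence[name]:
                    subject = proteins[(name, fam)]
                    per_query.append(_hit_row(rng, uid, subject, True))
                    truth[uid] = subject
                decoy_pool = [p for p in org_proteins if p != subject]
                if decoy_pool and rng.random() < config.decoy_prob:
                    decoy = decoy_pool[int(rng.integers(len(decoy_pool)))]
                    per_query.append(_hit_row(rng, uid, decoy, False))
                per_query.sort(key=lambda r: r[10])  # BLAST sorts by significance
                rows.extend(per_query)
        blastx[name] = rows
        planted_unigene_best[name] = truth

    # BLASTP-style cross-organism protein hits, one table per ordered pair
    blastp: dict[tuple[str, str], list[tuple]] = {}
    planted_cross_best: dict[tuple[str, str], dict[str, str]] = {}
    for q_name in org_names:
        for t_name in org_names:
            if q_name == t_name:
                continue
            rows = []
            truth = {}
            t_proteins = sorted(proteins[(t_name, f)] for f in presence[t_name])
            for fam in sorted(presence[q_name]):
                query = proteins[(q_name, fam)]
                per_query = []
                subject = None
                if fam in presence[t_name]:
                    subject = proteins[(t_name, fam)]
                    per_query.append(_hit_row(rng, query, subject, True))
                    truth[query] = subject
                decoy_pool = [p for p in t_proteins if p != subject]
                if decoy_pool and rng.random() < config.decoy_prob:
                    decoy = decoy_pool[int(rng.integers(len(decoy_pool)))]
                    per_query.append(_hit_row(rng, query, decoy, False))
                per_query.sort(key=lambda r: r[10])
                rows.extend(per_query)
            blastp[(q_name, t_name)] = rows
            planted_cross_best[(q_name, t_name)] = truth

    # toy GO DAG: rooted, acyclic by construction (parents precede children)
    go_root = "GO:0000001"
    signaling = "GO:0023052"
    go_terms: dict[str, tuple[str, str, tuple[str, ...]]] = {
        go_root: ("biological_process", "biological_process", ()),
        signaling: ("signaling", "biological_process", (go_root,)),
    }
    depths = {go_root: 1, signaling: 2}
    term_ids = [go_root, signaling]
    for i in range(config.n_go_terms - 2):
        tid = f"GO:1{i:06d}"
        eligible = [t for t in term_ids if depths[t] < config.go_max_depth]
        if not eligible:
            eligible = [go_root]
        n_parents = 2 if (len(eligible) > 1 and rng.random() < 0.25) else 1
        idx = rng.choice(len(eligible), size=n_parents, replace=False)
        parents = tuple(sorted(eligible[int(j)] for j in idx))
        go_terms[tid] = (f"process {i}", "biological_process", parents)
        depths[tid] = 1 + min(depths[p] for p in parents)
        term_ids.append(tid)

    # planted pathway: a connected ball of families in the family graph
    pathway_families = _plant_pathway(families, family_edges, config.pathway_size)

    # planted functions: one leaf-ish term per family; pathway families
    # additionally carry the signaling term so GO extraction finds them
    assignable = [t for t in term_ids if t not in (go_root, signaling)]
    family_functions: dict[str, str] = {}
    for fam in families:
        if assignable:
            family_functions[fam] = assignable[int(rng.integers(len(assignable)))]

    annotations: dict[str, set[str]] = {}
    planted_functions: dict[str, str] = {}
    for name in org_names:
        for fam in sorted(presence[name]):
            protein = proteins[(name, fam)]
            term = family_functions.get(fam)
            if term is not None:
                planted_functions[protein] = term
            if rng.random() < config.annotation_coverage and term is not None:
                terms = {term}
                if fam in pathway_families:
                    terms.add(signaling)
                annotations[protein] = terms

    return SyntheticUniverse(
        config=config,
        organisms=config.organisms,
        families=families,
        proteins=proteins,
        presence=presence,
        family_edges=family_edges,
        interactions=interactions,
        unigene_to_family=unigene_to_family,
        blastx=blastx,
        blastp=blastp,
        planted_unigene_best=planted_unigene_best,
        planted_cross_best=planted_cross_best,
        go_terms=go_terms,
        go_root=go_root,
        annotations=annotations,
        pathway_families=pathway_families,
        planted_functions=planted_functions,
        family_functions=family_functions,
    )


def _plant_pathway(
    families: list[str], family_edges: set[tuple[str, str]], size: int
) -> set[str]:
    if not families or size <= 0:
        return set()
    adjacency: dict[str, set[str]] = {f: set() for f in families}
    for a, b in family_edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    start = max(families, key=lambda f: (len(adjacency[f]), f))
    members = {start}
    frontier = sorted(adjacency[start])
    while frontier and len(members) < size:
        nxt = frontier.pop(0)
        if nxt in members:
            continue
        members.add(nxt)
        frontier.extend(sorted(adjacency[nxt] - members))
    return members


def build_subnetworks(
    universe: SyntheticUniverse, evalue_max: float = 1e-5
):
    """In-memory convenience: interolog sub-networks for every organism.

    Equivalent to writing the fixture and running the file-based stages,
    but skips the disk round trip.  Returns (subnetworks in integration
    order, cross-organism hit tables keyed by (query, target) organism).
    """
    from .homology import best_hits, build_subnetwork, map_unigenes
    from .io_formats import InteractionRecord

    subnets = []
    for name, stage, _ in universe.organisms:
        best = best_hits(universe.blastx_hits(name), evalue_max)
        unigene_map = map_unigenes(best)
        records = [
            InteractionRecord(a, b, name)
            for a, b in universe.interactions.get(name, [])
        ]
        subnets.append(build_subnetwork(records, unigene_map, name, stage))
    hit_tables = {
        (q, t): universe.blastp_hits(q, t)
        for q, _, _ in universe.organisms
        for t, _, _ in universe.organisms
        if q != t
    }
    return subnets, hit_tables


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(universe: SyntheticUniverse, directory: str | Path) -> dict:
    """Write the universe as on-disk files; return a manifest with checksums.

    Layout: ``interactions/<org>.mitab.txt`` (MITAB-lite pairs),
    ``blastx/<org>.tsv`` and ``blastp/<query>__<target>.tsv`` (outfmt 6),
    ``go.obo``, ``annotations.tsv``, ``organisms.tsv``, ``pathways.tsv``
    and ``manifest.yaml``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    inter_dir = directory / "interactions"
    inter_dir.mkdir(exist_ok=True)
    for name, _, _ in universe.organisms:
        path = inter_dir / f"{name}.mitab.txt"
        with open(path, "w") as handle:
            for a, b in universe.interactions.get(name, []):
                handle.write(f"uniprotkb:{a}-uniprotkb:{b}\n")
        files[f"interactions/{name}"] = path

    blastx_dir = directory / "blastx"
    blastx_dir.mkdir(exist_ok=True)
    for name, _, _ in universe.organisms:
        path = blastx_dir / f"{name}.tsv"
        _write_blast_rows(universe.blastx.get(name, []), path)
        files[f"blastx/{name}"] = path

    blastp_dir = directory / "blastp"
    blastp_dir.mkdir(exist_ok=True)
    for q_name, _, _ in universe.organisms:
        for t_name, _, _ in universe.organisms:
            if q_name == t_name:
                continue
            path = blastp_dir / f"{q_name}__{t_name}.tsv"
            _write_blast_rows(universe.blastp.get((q_name, t_name), []), path)
            files[f"blastp/{q_name}__{t_name}"] = path

    obo_path = directory / "go.obo"
    _write_obo(universe, obo_path)
    files["go"] = obo_path

    ann_path = directory / "annotations.tsv"
    with open(ann_path, "w") as handle:
        handle.write("protein\tgo_id\n")
        for protein in sorted(universe.annotations):
            for term in sorted(universe.annotations[protein]):
                handle.write(f"{protein}\t{term}\n")
    files["annotations"] = ann_path

    org_path = directory / "organisms.tsv"
    with open(org_path, "w") as handle:
        handle.write("organism\tstage\torder\tretention_prob\n")
        for order, (name, stage, retention) in enumerate(universe.organisms, 1):
            handle.write(f"{name}\t{stage}\t{order}\t{retention}\n")
    files["organisms"] = org_path

    path_path = directory / "pathways.tsv"
    with open(path_path, "w") as handle:
        handle.write("pathway\tprotein\n")
        for protein in sorted(universe.pathway_proteins()):
            handle.write(f"planted\t{protein}\n")
    files["pathways"] = path_path

    truth_path = directory / "planted_functions.tsv"
    with open(truth_path, "w") as handle:
        handle.write("protein\tgo_id\n")
        for protein in sorted(universe.planted_functions):
            handle.write(f"{protein}\t{universe.planted_functions[protein]}\n")
    files["planted_functions"] = truth_path

    manifest = {
        "seed": universe.config.seed,
        "n_families": universe.config.n_families,
        "files": {
            key: {
                "path": str(path.relative_to(directory)),
                "sha256": _sha256(path),
            }
            for key, path in sorted(files.items())
        },
    }
    with open(directory / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return manifest


def _write_blast_rows(rows: Sequence[tuple], path: Path) -> None:
    with open(path, "w") as handle:
        for row in rows:
            fields = list(row)
            fields[10] = f"{fields[10]:.3e}"
            handle.write("\t".join(str(v) for v in fields) + "\n")


def _write_obo(universe: SyntheticUniverse, path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in sorted(universe.go_terms):
            name, namespace, parents = universe.go_terms[tid]
            handle.write(f"\n[Term]\nid: {tid}\nname: {name}\n")
            handle.write(f"namespace: {namespace}\n")
            for parent in parents:
                pname = universe.go_terms[parent][0]
                handle.write(f"is_a: {parent} ! {pname}\n")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()
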