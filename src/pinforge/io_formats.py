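"""Readers and writers for every external format the pipeline touches.

Interaction lists arrive as a MITAB-lite dialect: two protein identifiers
per line, either tab-separated or joined as ``uniprotkb:A-uniprotkb:B``
(the form PINA exports).  Homology hits arrive as BLAST tabular output
(outfmt 6).  The GO ontology arrives as an OBO file restricted to ``is_a``
relations.  All networks are persisted as plain TSV so the artifacts stay
diff-able.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_MITAB_PAIR = re.compile(r"^uniprotkb:(?P<a>.+?)-uniprotkb:(?P<b>.+)$")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of an interaction pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionRecord:
    """One undirected protein-protein interaction from a source organism."""

    protein_a: str
    protein_b: str
    source_organism: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.protein_a, self.protein_b)

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass(frozen=True)
class HomologyHit:
    """A ranked alignment hit; ``rank`` is the per-query file-order index."""

    query: str
    subject: str
    evalue: float
    bitscore: float
    rank: int


def read_interactions(
    path: str | Path,
    dialect: str = "mitab_lite",
    organism: str = "",
) -> list[InteractionRecord]:
    """Read an interaction list, collapsing duplicate unordered pairs.

    ``mitab_lite`` accepts both ``uniprotkb:A-uniprotkb:B`` lines and
    two-column tab-separated lines; ``tsv`` accepts only the latter.
    ``uniprotkb:`` prefixes are stripped.  Self-interactions are retained.
    The number of collapsed duplicates is logged.
    """
    if dialect not in ("mitab_lite", "tsv"):
        raise FormatError(f"unknown interaction dialect: {dialect!r}")
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    n_self = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                fields = line.split("\t")
                a, b = fields[0], fields[1]
            elif dialect == "mitab_lite":
                match = _MITAB_PAIR.match(line)
                if match is None:
                    raise FormatError(
                        f"{path}:{lineno}: cannot parse interaction line {line!r}"
                    )
                a, b = match.group("a"), match.group("b")
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            a = a.removeprefix("uniprotkb:").strip()
            b = b.removeprefix("uniprotkb:").strip()
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty protein identifier")
            pair = canonical_pair(a, b)
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            if a == b:
                n_self += 1
            records.append(InteractionRecord(a, b, organism))
    if n_dup:
        logger.info("%s: collapsed %d duplicate unordered pairs", path, n_dup)
    if n_self:
        logger.info("%s: retained %d self-interactions", path, n_self)
    return records


def normalize_protein_names(
    records: Iterable[InteractionRecord],
    id_to_name: Mapping[str, str],
) -> tuple[list[InteractionRecord], int]:
    """Replace protein IDs by protein names wherever a name is known.

    Interaction files mix accessions and gene symbols for the same protein
    (e.g. ``A1Z8V7`` vs ``Vha36-2``); downstream merging needs one
    canonical label per protein, so any identifier with a known name is
    rewritten to that name.  Identifiers absent from the map are kept.
    Returns the rewritten records and the number of distinct identifiers
    replaced.
    """
    replaced: set[str] = set()

    def fix(ident: str) -> str:
        name = id_to_name.get(ident)
        if name is not None and name != ident:
            replaced.add(ident)
            return name
        return ident

    out = [
        InteractionRecord(fix(r.protein_a), fix(r.protein_b), r.source_organism)
        for r in records
    ]
    return out, len(replaced)


def read_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Read BLAST tabular (outfmt 6) hits, preserving file order.

    Ranks are assigned per query in order of appearance, which is how
    "first aligned sequence" rules are later applied.  Duplicate
    (query, subject) lines are kept; deduplication is not this layer's job.
    """
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#",
            dtype={"qseqid": str, "sseqid": str}, float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return []
    for col in ("evalue", "bitscore"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            bad = frame.index[coerced.isna()][0] + 1
            raise FormatError(f"{path}: non-numeric {col} on data line {bad}")
        frame[col] = coerced
    ranks = frame.groupby("qseqid", sort=False).cumcount()
    return [
        HomologyHit(
            query=row.qseqid,
            subject=row.sseqid,
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
            rank=int(rank),
        )
        for row, rank in zip(frame.itertuples(index=False), ranks)
    ]


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str
    namespace: str
    parents: tuple[str, ...]


@dataclass
class GoDag:
    """A GO ontology restricted to ``is_a`` edges.

    ``depth`` follows the shortest ``is_a`` path from the namespace root,
    with the root itself at depth 1.
    """

    terms: dict[str, GoTerm]
    roots: dict[str, str] = field(default_factory=dict)  # namespace -> root id
    _depths: dict[str, int] = field(default_factory=dict, repr=False)
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    raise FormatError(
                        f"term {term.id} has unknown parent {parent}"
                    )
                graph.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            raise FormatError("is_a relations contain a cycle")
        if not self.roots:
            for term in self.terms.values():
                if not term.parents:
                    self.roots[term.namespace] = term.id
        # every non-root term must reach its namespace root
        for term in self.terms.values():
            if term.parents:
                if not self.ancestors(term.id) & set(self.roots.values()):
                    raise FormatError(f"term {term.id} cannot reach a root")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def parents(self, term_id: str) -> tuple[str, ...]:
        return self.terms[term_id].parents

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All is_a ancestors of ``term_id`` (the term itself excluded)."""
        cached = self._ancestors.get(term_id)
        if cached is not None:
            return cached
        result: set[str] = set()
        stack = list(self.terms[term_id].parents)
        while stack:
            current = stack.pop()
            if current not in result:
                result.add(current)
                stack.extend(self.terms[current].parents)
        frozen = frozenset(result)
        self._ancestors[term_id] = frozen
        return frozen

    def depth(self, term_id: str) -> int:
        """Shortest-path depth from the namespace root (root = 1)."""
        cached = self._depths.get(term_id)
        if cached is not None:
            return cached
        term = self.terms[term_id]
        if not term.parents:
            depth = 1
        else:
            depth = 1 + min(self.depth(p) for p in term.parents)
        self._depths[term_id] = depth
        return depth


def read_obo(path: str | Path) -> GoDag:
    """Parse an OBO ontology into a :class:`GoDag`.

    Only ``is_a`` edges are kept; obsolete terms are skipped (obonet's
    default).  Cyclic input is rejected.
    """
    graph = obonet.read_obo(path)
    terms: dict[str, GoTerm] = {}
    for node, data in graph.nodes(data=True):
        parents = tuple(
            sorted(
                target
                for _, target, key in graph.out_edges(node, keys=True)
                if key == "is_a"
            )
        )
        terms[node] = GoTerm(
            id=node,
            name=data.get("name", node),
            namespace=data.get("namespace", "biological_process"),
            parents=parents,
        )
    return GoDag(terms=terms)


AnnotationTable = dict[str, set[str]]


def read_annotations(path: str | Path, dag: GoDag | None = None) -> AnnotationTable:
    """Read a two-column (protein, GO id) TSV into a protein -> terms map."""
    table: AnnotationTable = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("protein\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            protein, term = fields
            if dag is not None and term not in dag:
                raise FormatError(f"{path}:{lineno}: unknown GO term {term}")
            table.setdefault(protein, set()).add(term)
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("protein\tgo_id\n")
        for protein in sorted(table):
            for term in sorted(table[protein]):
                handle.write(f"{protein}\t{term}\n")


def _sidecar_paths(path: str | Path) -> tuple[Path, Path, Path]:
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".tsv" else path
    return path, Path(f"{base}.nodes.tsv"), Path(f"{base}.turns.tsv")


def write_network(network, path: str | Path) -> list[Path]:
    """Write an integrated network as TSV: edges, node ledgers, turn log.

    Three files are produced: ``<path>`` with one row per edge (pair,
    source organisms, per-turn edge scores, total score), a ``.nodes.tsv``
    sidecar with per-node ledgers, and a ``.turns.tsv`` sidecar with the
    integration log.  The round trip through :func:`read_network` is
    lossless.
    """
    edge_path, node_path, turn_path = _sidecar_paths(path)
    n = network.n_turns
    with open(edge_path, "w") as handle:
        cols = ["protein_a", "protein_b", "sources"]
        cols += [f"r{i}" for i in range(1, n + 1)] + ["score"]
        handle.write("\t".join(cols) + "\n")
        for pair in sorted(network.edges):
            ledger = network.edges[pair]
            row = [pair[0], pair[1], ";".join(sorted(ledger.sources))]
            row += [str(v) for v in ledger.per_turn]
            row.append(str(network.score(pair)))
            handle.write("\t".join(row) + "\n")
    with open(node_path, "w") as handle:
        cols = ["protein", "sources", "unigenes"]
        cols += [f"a{i}" for i in range(1, n + 1)]
        handle.write("\t".join(cols) + "\n")
        for name in sorted(network.nodes):
            ledger = network.nodes[name]
            row = [
                name,
                ";".join(sorted(ledger.sources)),
                ";".join(sorted(ledger.unigenes)),
            ]
            row += [str(v) for v in ledger.per_turn]
            handle.write("\t".join(row) + "\n")
    with open(turn_path, "w") as handle:
        handle.write("turn\tquery_organism\tnodes\tedges\n")
        for entry in network.turn_log:
            handle.write(
                f"{entry.turn}\t{entry.query_organism}\t"
                f"{entry.n_nodes}\t{entry.n_edges}\n"
            )
    return [edge_path, node_path, turn_path]


def read_network(path: str | Path):
    """Read back a network written by :func:`write_network`."""
    from .integration import EdgeLedger, IntegratedNetwork, NodeLedger, TurnRecord

    edge_path, node_path, turn_path = _sidecar_paths(path)
    edge_frame = pd.read_csv(edge_path, sep="\t", dtype=str)
    node_frame = pd.read_csv(node_path, sep="\t", dtype=str)
    score_cols = [c for c in edge_frame.columns if re.fullmatch(r"r\d+", c)]
    n_turns = len(score_cols)
    expected = ["protein_a", "protein_b", "sources"] + score_cols + ["score"]
    if list(edge_frame.columns) != expected:
        raise FormatError(f"{edge_path}: unexpected edge schema")
    network = IntegratedNetwork(n_turns=n_turns)
    for row in node_frame.itertuples(index=False):
        per_turn = [int(getattr(row, f"a{i}")) for i in range(1, n_turns + 1)]
        sources = set(row.sources.split(";")) if isinstance(row.sources, str) and row.sources else set()
        unigenes = set(row.unigenes.split(";")) if isinstance(row.unigenes, str) and row.unigenes else set()
        network.nodes[row.protein] = NodeLedger(
            name=row.protein, sources=sources, unigenes=unigenes, per_turn=per_turn
        )
    for row in edge_frame.itertuples(index=False):
        pair = canonical_pair(row.protein_a, row.protein_b)
        if pair[0] not in network.nodes or pair[1] not in network.nodes:
            raise FormatError(f"{edge_path}: edge endpoint missing from node table")
        per_turn = [int(getattr(row, f"r{i}")) for i in range(1, n_turns + 1)]
        sources = set(row.sources.split(";")) if isinstance(row.sources, str) and row.sources else set()
        network.edges[pair] = EdgeLedger(pair=pair, sources=sources, per_turn=per_turn)
    if turn_path.exists():
        turn_frame = pd.read_csv(turn_path, sep="\t", dtype=str)
        for row in turn_frame.itertuples(index=False):
            network.turn_log.append(
                TurnRecord(
                    turn=int(row.turn),
                    query_organism=row.query_organism,
                    n_nodes=int(row.nodes),
                    n_edges=int(row.edges),
                )
            )
    return network
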