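# Methods

## The problem

For most non-model organisms — here, the motivating case is an aquatic
crustacean known only through a de novo transcriptome — no experimental
protein–protein interaction (PPI) data exist. The standard workaround is
the *interolog* transfer: an interaction observed between two proteins
in a model organism is inferred in the target organism when both
proteins have homologous transcripts there. `pinforge` implements this
construction end to end: per-model-organism sub-networks, iterative
integration into one network with a per-interaction confidence score,
and the downstream analyses that such a network supports (topology,
GO-defined sub-network extraction, evolutionary-origin classification,
neighbor-majority function assignment).

## Interolog sub-networks

For each model organism the inputs are (i) its PPI list (PINA-style
identifier pairs) and (ii) a BLASTX-style tabular hit file of target
transcripts ("unigenes") against the organism's proteome. A unigene's
homolog is the *first* hit in file order with E-value strictly below
1e-5 — the classic "first aligned sequence" rule, which favors BLAST's
own significance ordering rather than re-sorting. Ties on file rank
(possible when hit tables are concatenated) break by lower E-value,
higher bitscore, then lexicographic subject, so selection is
deterministic for any input ordering.

An interaction enters the organism's sub-network iff *both* partner
proteins are hit by at least one unigene. Nodes are the endpoints of
kept edges; proteins with unigene support but no surviving interaction
are dropped, since the construction counts proteins *in interactions*.
The unigene↔protein relation is many-to-many and is carried along as a
per-protein unigene set.

Mixed identifier usage (the same protein as accession in one pair and
gene symbol in another) is resolved before filtering: any identifier
with a known name is rewritten to the name, names are case-preserved,
and duplicate unordered pairs are collapsed with a logged count.
Self-interactions are retained.

## Iterative integration and the confidence score

Sub-networks are merged one per turn, closest relative first. With M
sub-networks there are N = M − 1 turns; the accumulating network is the
*target*, the incoming sub-network the *query*. Query proteins map onto
target proteins by the same first-passing-hit rule applied to
cross-organism (BLASTP-style) hit tables, restricted to proteins
actually present in the two networks; at turn k the query's tables
against every already-integrated organism are concatenated in
integration order, so the closest relative wins rank ties. Mappings may
be many-to-one (two query proteins can collapse into one target
protein); collapses are logged, never forbidden.

Each turn writes one entry into every node's and edge's ledger:

* **Edge score R_i** — a query edge is translated through the mapping
  (unmapped endpoints keep their query names and enter as new nodes).
  If the translated edge already existed before the turn it is *matched*
  and scores 3; otherwise it is added with score 1. Every pre-existing
  target edge not matched this turn scores 2. Before an edge exists its
  entries are 0. One uniform rule covers the both-mapped, one-mapped and
  unmapped cases, and deliberately allows an edge matched in an early
  turn to be matched again by a later organism.
* **Node score A_i / B_i** — a target protein that absorbs one or more
  query homologs scores 2 if any absorbed protein shares a unigene with
  it (same target-organism transcript: strong evidence the two are the
  same protein), 1 if the unigene sets are disjoint, and 0 in turns
  where it absorbs nothing. Absorbed proteins' unigenes and source
  organisms are unioned into the surviving node.

The confidence score of an interaction is

    S = Σ_{i=1..N} (A_i + R_i + B_i)

summed over *all* N turns. With the canonical six-organism panel
(N = 5), the per-turn maximum is 2 + 3 + 2 = 7 and the score maximum is
35, attained exactly when an edge is matched in every turn and both
endpoints undergo same-unigene merges every turn. The minimum for an
edge added in the final turn with unmerged endpoints is 1; an edge
present from turn 1 can never score below 2N. Self-loops (possible
after a many-to-one collapse) contribute the same node ledger twice,
consistent with the two-node shape of the formula.

The first sub-network is scored in turn 1 like any target: its
unmatched edges receive R = 2, its never-merged nodes 0. This
turn-1 convention is forced by the same consistency argument as the
all-turns accrual — without it the stated maximum of 35 is unattainable.

Downstream conveniences: a binned score histogram (default bin width 5,
bins [1–5], [6–10], …; percentages sum to 100), a score filter (edges
with S ≥ cutoff, default 30, nodes restricted to kept edges) and a hub
query (degree strictly greater than a cutoff, default 33).

## Topology

Seven features are reported per network, usually on the largest
(weakly) connected component: node count, edge count, diameter (max BFS
hop distance over connected pairs), average path length (mean over
connected unordered pairs — well-defined on fragmented graphs too),
mean clustering coefficient, average degree (self-loops counted twice)
and index aggregation (|LWCC| / |V|). The clustering coefficient is
C_v = 2 e_v / (k_v (k_v − 1)) with e_v the edge count among v's
neighbors; self-loops are excluded from neighborhoods, and nodes with
fewer than two neighbors contribute C_v = 0 to the mean by default (an
exclusive mode exists, as conventions differ). Because the networks are
undirected, strongly and weakly connected components coincide; only the
weak notion is implemented.

## Signaling sub-network and evolutionary origins

Protein annotations are ancestor-closed over the GO DAG's is_a edges
(true-path rule), so a protein annotated with any descendant of
"signaling" (GO:0023052) counts as a signaling protein; a
direct-match-only mode is available. The extracted sub-network is the
seed proteins plus edges among them (seeds without such an edge are
counted as isolated); optional neighbor expansion adds every neighbor
of a seed and all seed-incident edges.

Source organisms are classified into three stages — primitive (P) <
bilaterian (B) < vertebrate (V). A protein or edge originates at the
*earliest* stage among the organisms it occurs in (taken from the
integration ledgers' source sets); a complete interaction (protein,
protein, edge) originates at the *latest* of its three component
origins. Per pathway (membership is an input table, not a database
lookup), the origin profile is the proportion of member–member edges
per complete-origin stage, summing to 1 when the pathway has any edge.

## Function assignment

Unclassified proteins (no GO biological-process annotation) inherit
terms from their network neighbors: a term is assigned when it is
carried by strictly more than 25% of the protein's *annotated*
neighbors, and a protein whose annotated neighbor is unique inherits
all of that neighbor's terms. Rounds are synchronous — every assignment
in a round is computed from the previous round's classified state, so
iteration order cannot matter — and repeat until a round assigns
nothing; newly classified proteins participate fully in later rounds.
No cap is placed on the number of assigned terms (the >25% rule
replaces a fixed top-k rule precisely because annotated proteins often
carry many terms). The threshold denominator is the annotated-neighbor
count by default; an all-neighbors mode exists because the counting
base is a genuine ambiguity of the procedure. GO depth of an assigned
term is the shortest is_a path from the namespace root (root = 1), and
the depth distribution counts (protein, term) assignment pairs.

## Synthetic universe

The generator emulates the data situation above with known ground
truth: ortholog families shared across a six-organism panel (two
bilaterian invertebrates, three vertebrates, one primitive unicellular;
integration order fixed, stages B,B,V,V,V,P), per-organism presence by
stage-specific retention probabilities (0.45–0.80, echoing how unevenly
real panels cover a target proteome), family-level interactions at
density 0.08 realized per organism with conservation 0.7, 90% unigene
coverage with 15% two-unigene families, a rooted random GO DAG (40
terms, depth ≤ 6, acyclic by construction since parents precede
children) containing a planted "signaling" term, 70% annotation
coverage, one planted connected pathway and one planted function label
per family. True homology hits sample E-values log-uniformly in
[1e-50, 1e-6] and decoys in [1e-4, 1], cleanly separated around the
1e-5 cutoff, so best-hit selection recovers the planted ortholog map
exactly — deliberate: it lets every downstream stage be checked against
planted truth rather than against another heuristic.

What the generator does *not* emulate: sequence-level alignment (hits
are sampled, not computed), realistic scale-free degree distributions,
annotation noise, paralogy (one protein per family per organism) and
borderline E-values. Passing tests therefore demonstrate the
correctness of the rules and bookkeeping, not robustness to ambiguous
homology calls on real data.

Default problem sizes — universes of 50–60 families and six organisms,
random graphs of ≤ 15–30 nodes for the metric cross-checks — were
chosen so planted structure is non-trivial (dozens of edges per
organism, multi-round assignment cascades) while the whole suite
re-runs in seconds.

## Numerical and degenerate-input choices

* E-value thresholds are strict (<), matching the quoted rule; decoys
  at exactly the cutoff are rejected.
* E-values are written at three significant digits and parsed with
  round-trip float precision, so fixtures round-trip byte-exactly.
* All tie-breaks (hit selection, component ordering, hub ordering) are
  made deterministic and documented above; consistent relabeling of
  identifiers yields isomorphic results.
* Empty networks: topology and degree functions refuse them; the score
  histogram of an edgeless network is empty; an empty universe writes
  valid empty files.
* Seeds flow through `numpy.random.default_rng` only; identical
  config + seed reproduces identical bytes, checksummed in manifests.

## Known limitations

* Origin classification trusts the homology renaming: a wrong merge
  propagates into presence sets and origins.
* The confidence score is ordinal, not probabilistic — no calibration
  against experimentally validated interactions is attempted.
* Many-to-one merges can create self-loops whose biological meaning is
  doubtful; they are kept, flagged by their pair shape, and excluded
  from clustering neighborhoods.
* The real-data scale of the motivating study (thousands of proteins,
  tens of thousands of interactions) requires external transcriptome
  and interaction downloads; this package reproduces the *method* and
  validates it on synthetic universes.
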