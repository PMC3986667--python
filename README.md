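# pinforge

Homology-based construction and analysis of protein–protein interaction
networks (PINs) for organisms that have a transcriptome but no
experimental interactome — the situation of most non-model species,
such as aquaculture crustaceans.

The package is aimed at computational biologists who have (a) a set of
assembled transcripts ("unigenes") for a target organism, (b) PPI lists
for a panel of model organisms, and (c) BLAST tabular hit files linking
the two. From these it builds per-organism *interolog* sub-networks
(interactions whose both partners have a homologous unigene), merges
them iteratively — closest relative first — into one integrated PIN,
scores every interaction's cross-species support, and runs the standard
downstream analyses: network topology, GO-defined (signaling)
sub-network extraction, evolutionary-origin classification, and
neighbor-majority function assignment for unannotated proteins.

## The model

During integration, the accumulating network is the *target* and each
incoming sub-network the *query*; query proteins map onto target
proteins by a first-passing-BLASTP-hit rule (E < 1e-5). Each of the
N integration turns appends one component to every interaction's score:

* edge matching R_i ∈ {1, 2, 3} — 3 if the (homology-translated) query
  edge matches an existing target edge, 2 for a target edge not matched
  this turn, 1 for an edge newly added from the query (0 before the
  edge exists);
* point matching A_i, B_i ∈ {0, 1, 2} per endpoint — 2 when the protein
  absorbs a query homolog that shares a unigene with it, 1 when the
  unigene sets are disjoint, 0 when nothing is absorbed.

The confidence score of an interaction pair is

    S = Σ_{i=1..N} (A_i + R_i + B_i),

so with the canonical six-organism panel (N = 5) the maximum is
5 × (2 + 3 + 2) = 35, and high S marks interactions conserved across
many organisms. A synthetic multi-organism universe with planted
ortholog families, decoy homology hits, a toy GO DAG and planted
function labels makes the whole pipeline testable offline.

## Worked example

```python
from pinforge.synthetic import UniverseConfig, generate_universe, build_subnetworks
from pinforge.integration import integrate_all, score_distribution

universe = generate_universe(UniverseConfig(seed=1))   # 50 families, 6 organisms
subnets, hit_tables = build_subnetworks(universe)
network = integrate_all(subnets, hit_tables)

for entry in network.turn_log:
    print(entry.turn, entry.query_organism, entry.n_nodes, entry.n_edges)
scores = network.scores()
print("max S", max(scores.values()), "min S", min(scores.values()))
```

prints

```
1 Cele 34 49
2 Hsap 39 61
3 Rnor 42 66
4 Mmus 42 66
5 Scer 43 69
max S 32 min S 5
```

Reading: the Drosophila-like sub-network seeds the target; each turn
merges the next organism and the node/edge counts grow monotonically to
43 proteins and 69 interactions. The best-supported interaction scores
32 of a possible 35 (present and matched in nearly every organism with
same-unigene merges); the weakest scores 5. `score_distribution(network)`
bins these scores ([1–5], [6–10], …) with percentages summing to 100 —
here the mode is the [16–20] bin at 39.1% of interactions.

The same arc runs from the shell, writing every artifact (sub-network
summaries, scored network, turn log, score histogram, topology table,
signaling sub-network, pathway origin profiles, assigned functions) as
TSV plus a checksum manifest:

```
pinforge run-all --seed 1 --out out/
```

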