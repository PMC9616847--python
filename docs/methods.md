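# Methods

## Scope and model

The package operates downstream of differential-expression analysis: it
consumes a finished DEG table, an evidence-scored undirected PPI edge list,
and a flat gene→GO annotation table with background counts. It does not
compute fold changes from counts, query STRING, or walk the GO DAG — term
membership tables are treated as flat, the way STRING and BiNGO exports
present them. Gene identifiers are opaque case-sensitive strings.

The up- and down-regulated directions are screened as independent branches
that share the network and annotations and meet only in the final
shared/specific process comparison.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `lfc_min` | 2 | minimum \|log2FC\| for a regulation call (inclusive) |
| `fdr_max` | 0.05 | FDR bound for a call (strict) |
| `admission_p` | 0.05 | hypergeometric p for a GO term to enter gene scoring |
| `round1_cutoff` | 80 | average GO percentile a gene must reach (inclusive) |
| `round2_mark` | 50 | composite topology percentile to survive (inclusive) |
| `enrichment_cutoff` | 0.05 | significance bound for over-representation |
| MCODE `node_score_cutoff` | 0.2 | weight tolerance for greedy expansion |
| MCODE `kcore` | 2 | minimum core a complex must contain |
| MCODE `fluff` / `fluff_density` | on / 0.1 | attach boundary neighbors above this closed-neighborhood density |
| MCODE `haircut` | off | drop degree-1 members after expansion |

These defaults are the reference screening settings the pipeline was built
around; every one is exposed through `RunConfig` and the CLI.

## Numerical and algorithmic choices

**Percentile rank.** percentile(g) = 100 · #(score ≤ score(g)) / N — the
inclusive empirical CDF, so tied scores share one value and the maximum is
always 100. This is the simplest definition under which an "80% and above"
band is guaranteed to contain the top-scoring genes. The same definition is
used in round 1 (GO scores) and round 2 (each centrality), which keeps the
two screening scales commensurate. Consequence worth knowing: when many
values tie (e.g. isolated nodes in a sparse induced subnetwork, where five of
the six centralities are 0 for everyone), the whole tie group ranks at the
top, and the round-2 mark can pass all nodes. Metric values are rounded to
9 decimals before ranking so that symmetry-equivalent nodes tie exactly
instead of being split by floating-point noise.

**Namespace averaging.** A gene's average percentile runs over the
namespaces in which it is annotated to at least one admitted term;
compartment-specific genes are not penalized with zeros for namespaces they
do not occupy. Genes absent from all namespaces are excluded from the round-1
table entirely.

**Round-2 direction.** Survivors are those at or **above** the mark
(selecting central genes); `below=True` gives the complementary reading.

**Centralities.** Shortest paths are unweighted (edge confidence scores are
kept but not used for topology). Betweenness and stress count each unordered
pair once and are unnormalized; closeness and radiality are computed within
each connected component (radiality uses the component diameter); eigenvector
centrality is the principal eigenvector of each component's adjacency matrix
(dense symmetric eigendecomposition), sign-fixed positive and normalized to
unit Euclidean norm per component. Singleton components get 0 for all
path-based metrics and 1 for the eigenvector entry (the unit-norm
convention). "Stress" is computed from per-source BFS path counts
(σ_sv · σ_vt summed over pairs with d(s,v)+d(v,t)=d(s,t)).

**MCODE-style detection.** Vertex weight is k × density of the highest
k-core of the closed neighborhood. Expansion admits an unassigned neighbor
when its weight strictly exceeds seed_weight × (1 − node_score_cutoff), and
proceeds transitively. A consequence of weighting by the neighborhood's
*densest core* is that nodes bridging two dense complexes can weigh as much
as interior nodes, so complexes connected by a bridge between equally dense
cliques merge into one cluster at the default cutoff. Complexes without a
2-core are discarded and their nodes stay available to later seeds. Core
members are assigned exclusively (clusters are node-disjoint); fluffed
boundary nodes are reported in a separate flagged set and may be attached to
several clusters. Cluster n, E, density and score are computed over the core
members only: at the default fluff density of 0.1 almost any boundary
neighbor qualifies (a degree-1 neighbor has closed-neighborhood density 1),
so folding fluff into the score would measure the sparse periphery rather
than the complex. Haircut is off by default (a triangle complex, 3 nodes and
3 edges, is then reported intact). All ties — seed order, member listing,
equal scores — break lexicographically on node id, so output is
deterministic.

**Hypergeometric test.** P(X ≥ o) is computed with exact big-integer
combinatorics (one tail sum of products of binomial coefficients, one
division), giving full double precision; the floating-point `scipy`
survival function serves as an independent cross-check in the tests. The
reference population is the annotation background, not the network node set.
Benjamini–Hochberg adjustment is available but off by default (raw
p ≤ cutoff is the reference rule).

**Percentages.** Reporting helpers round half-up to 2 decimals, matching
how retention percentages are conventionally printed from integer counts.

**qPCR.** RQ = 2^−ΔΔCt (Livak). Replicates are averaged on the Ct scale —
equivalent to a geometric mean on the quantity scale — and the replicate SDs
of the two ΔCt terms combine in quadrature into a fold-change interval
[2^−(ΔΔCt+SD), 2^−(ΔΔCt−SD)].

## What the synthetic generator emulates — and what it does not

`SyntheticSpec` defaults describe a 500-gene study: 15% up- and 18%
down-regulated genes (slightly more down than up), regulated
|log2FC| = 2 + |N(0.9, 0.6)| (mean ≈ 2.9, so calls are sharp at the
threshold while magnitudes stay realistic), significant FDR ~ U(0, 0.05).
Null genes split 80/20 between sub-threshold fold changes and large fold
changes with non-significant FDR, so both rejection routes occur. The
network is an Erdős–Rényi background (p_out = 0.02) with planted near-clique
modules (default two modules, sizes 10 and 6, p_in = 0.9) drawn from the
up-regulated genes — dense complexes among prioritized genes, which is what
the downstream stages assume. Annotations are 30 random terms per namespace
(sizes 5–60) plus planted terms drawn preferentially from the up-regulated
set (default a 40-gene BP term at 50% up-genes and a 30-gene MF term at
40%). All randomness flows from the single spec seed; identical specs yield
byte-identical artifacts.

By construction the threshold screen recovers the planted regulated sets
exactly, which is used as a closed-loop test. What the generator does *not*
emulate: correlated annotation structure (GO DAG ancestry), degree
heterogeneity and scale-free topology of real PPI networks, evidence-score
structure on edges, or FDR/log2FC dependence. Passing tests therefore
demonstrate algorithmic correctness and recovery under idealized planted
structure, not performance on real interactomes.

## Problem sizes used in the test suite

Unit and property tests run on graphs of ≤ 12 nodes (with exhaustive
all-pairs oracles on ≤ 8 nodes), 100–500-gene synthetic bundles, a 50-seed
module-recovery experiment at 200 genes, and a 1000-permutation type-I-error
calibration at a 2000-gene population (term 300, query 500 — a configuration
chosen from the exact null distribution so the discrete test's attainable
p-values are dense near the 0.05 cutoff; at coarser configurations the
realized size of any exact discrete test sits well below nominal, which is a
property of the distribution, not of the implementation).

## Known limitations

- Flat annotation semantics: no true-path propagation; parent/child terms
  are scored independently.
- The GO "fold enrichment" score is unbounded for tiny background counts; it
  is always paired with the hypergeometric admission filter.
- The bridged-complex merging behavior described above is inherent to
  core-density vertex weighting; lowering `node_score_cutoff` separates
  complexes whose interiors are denser than their bridges.
- With heavily tied composite scores the round-2 screen can be
  non-discriminating (see percentile note); on real, denser subnetworks ties
  are rare.
- Edge confidence scores are carried through I/O but only used as a
  filtering threshold (`score_min`), never as path weights.
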