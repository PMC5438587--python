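# Methods

## Data model

A `BipartiteNetwork` holds two disjoint guilds — A, the passive species
(plants, matrix rows) and B, the active species (pollinators or seed
dispersers, columns) — plus inter-guild edges with optional positive
weights. Intra-guild edges, self-loops, duplicate labels and duplicate
edges are rejected at construction. All structural analyses run on the
binarized network: any positive weight counts as a link, matching the
convention that the adjacency element `a_mj` is 1 when an interaction
exists.

Species with no interactions (all-zero rows or columns in an input
matrix) are retained as degree-0 nodes and logged. They sit in shell 0,
have infinite k-radius, zero k-degree and zero k-risk, never belong to
the giant component, and never take part in the MusRank iteration.

## Shell decomposition

The k-core is computed by the standard Batagelj–Zaveršnik degree
pruning (via `networkx.core_number`) on the whole bipartite graph, both
guilds together. We use the standard, possibly disconnected, core: the
pruning rule itself does not enforce connectivity, and within each
connected component the usual decomposition applies. A brute-force
oracle (delete degree-<k nodes to fixpoint, for each k) guards this
choice in the test suite over hundreds of random networks.

The **innermost shell of a guild** is taken at the *per-guild* maximum
shell index, not the global maximum. Wherever both coincide (as in the
worked fixture) this makes no difference; where one guild is absent
from the global top core, the per-guild rule keeps the target set of
k-radius non-empty whenever the guild has any node.

## k-magnitudes

- `k_radius`: mean hop-count shortest-path distance to the opposite
  guild's innermost shell. Distances are computed by one BFS per
  innermost-shell member, so a full table costs O(|N| · |E|). A target
  unreachable from the node (outside its component) contributes an
  infinite distance and makes the mean infinite.
- `k_degree`: sum of `1 / k_radius(j)` over binary neighbours *j*. A
  neighbour with infinite k-radius contributes 0 — the natural
  `1/∞ → 0` limit, which keeps sums finite on fragmented networks.
- `k_risk(m) = Σ (shell(m) − shell(j)) + ε·shell(m)` over neighbours
  *j* in strictly lower shells. ε defaults to 0.01, two orders of
  magnitude below the integer shell-difference sum, so it orders
  species *between* shells without ever reordering species whose
  integer parts differ (property-tested for ε ∈ (0, 0.1]).

All magnitudes are label-permutation equivariant and deterministic.

## Rankings

`rank_by` produces a descending order plus explicit tie groups (scores
equal within 1e-12). Ties are *not* broken at ranking time; the
extinction module shuffles within tie groups. Members of a tie group
are listed in label order purely for reproducibility of exports.

- **degree**: binary degree on the whole graph.
- **eigenvector**: principal eigenvector of the full bipartite
  adjacency (no one-mode projection), power iteration to 1e-10 relative
  tolerance, normalized to maximum entry 1. Bipartite spectra are
  symmetric (±λ pairs), which stalls plain power iteration; iterating
  `A + I` shifts the spectrum without changing the eigenvector. A dense
  eigensolver serves as the independent oracle in the tests.
- **MusRank** (active species only): the nonlinear map
  `I ← M·V`, `V ← 1/(Mᵀ·(1/I))` from all-ones, both vectors
  renormalized to mean 1 per step, stopping when the max relative
  change < 1e-10 (default; `tol`/`max_iter` exposed). Importances are
  floored at 1e-300 because the map divides by them. On strongly nested
  networks part of the importance vector collapses toward the floor —
  a known property of this fixed point; the collapsed species form one
  tie group and are shuffled during extinctions. Degree-0 animals and
  plants are excluded from the iteration with score 0 (a degree-0
  plant's vulnerability update would divide by zero).

## Extinction procedures

Both procedures are static: one ranking computed on the intact network,
no rewiring, no re-ranking.

**Giant component.** The GC baseline is the largest connected component
of the intact network, so networks with pre-isolated species start at
fraction 1. During a removal sequence only components carrying at least
one interaction count: a stranded single species is not a functioning
component, so a fully disconnected network has GC size 0. Ties between
equal largest components resolve toward the component containing the
lexicographically smallest label (determinism on degenerate inputs).

**Procedure 1 (mixed).** Species of either guild are removed one per
step in rank order. Only primary removals are counted; species isolated
by a removal stay in the graph (they shrink the GC but do not advance
the removal counter). The run stops at the first step with
GC fraction ≤ 0.5 (threshold configurable in (0, 1)), and the score is
`removed / all species × 100` — the denominator is every species in the
network, isolated ones included.

**Procedure 2 (primary_animals).** Only animals are removed, in rank
order; a both-guild ranking is filtered to animals preserving relative
order and tie structure, so all five indexes share one interface. A
plant is secondarily extinct when removals bring its degree to zero;
plants isolated in the intact network never lose a partner and are
never counted as extinct, which makes the final surviving fraction
equal the initially-isolated share. Both the surviving-plant fraction
and the GC fraction are recorded at every step; each curve gets the
anchor (0, 1) prepended and is summarised by its trapezoidal AUC over
the removed-animal fraction in [0, 1]. The quadrature is a convention
fixed here so AUCs are comparable across indexes.

**Tie shuffling and seeds.** Each (index, repetition) pair draws an
independent RNG stream via `numpy` `SeedSequence` from
`(base seed, index id, repetition number)`, so any single repetition is
reproducible in isolation and results are independent of evaluation
order. Within each tie group the order is a uniform shuffle. With 100
repetitions the mean stays within three standard errors of the exact
mean over all tie permutations, verified against exhaustive enumeration
on small networks.

## Synthetic generator

`generate_bipartite(n_plants, n_animals, connectance, nestedness_bias,
seed)` draws exactly `round(connectance · n_plants · n_animals)` edges
(minimum 1) without replacement. Cell (i, j) is sampled with
probability proportional to
`(1 − bias) + bias · r_i · s_j`, where `r` and `s` are linearly
decreasing rank propensities, so bias 0 gives uniform random bipartite
graphs and bias 1 a nested core–periphery structure with generalists at
low ranks. Exact edge counts (rather than independent Bernoulli cells)
keep connectance 1 exactly complete and the edge count reproducible.
The generator emulates nestedness and connectance only — not degree
distributions fitted to field data, phenology, sampling effort or
forbidden links — so tests passing on synthetic networks demonstrate
algorithmic correctness, not ecological realism.

## Problem sizes and numerical choices

The test suite's batch comparisons use networks of around 110 species
(55 + 55, connectance 0.06, bias 1.0, 20 seeds, 25 repetitions per
index) — large enough for a clear core–periphery structure while
keeping the whole suite in a few seconds. The directional comparison of
k-risk against plain degree on those networks is logged, not asserted:
a definitive comparison belongs to real field collections, which this
package reads (web-of-life CSV dialect) but does not ship.

Floating-point comparisons in the worked-example tests use an absolute
tolerance of 1e-12; scores within 1e-12 of each other count as tied in
rankings; eigenvector and MusRank iterate to 1e-10 relative tolerance.

## Known limitations

- Weighted generalisations (s-cores, weight-modulated distances) are
  out of scope; weights are carried through I/O but analysis is binary.
- MusRank's partial collapse means its ranking below the leading
  species can degenerate to tie groups on strongly nested networks.
- The removal-percentage denominator (all species) and the AUC anchor
  convention are package conventions; comparisons across tools should
  check these match.
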