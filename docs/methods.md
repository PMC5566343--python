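# Methods

## Model

A PPI network is an undirected simple graph G = (V, E) over opaque,
case-sensitive protein identifiers. A *partial dense vertex cover* is a
collection of disjoint subsets C₁, …, C_k of V in which every induced
subgraph G(Cᵢ) meets three floors — degree density
α = min-within-degree/(|Cᵢ|−1) ≥ λ, edge density
δ = |E(G(Cᵢ))|/C(|Cᵢ|,2) ≥ γ, diameter R ≤ p — is locally maximal, and whose
residual graph contains no further subset meeting the floors. The
feasibility region is governed by 0 < λ ≤ γ ≤ 1 and the positive integer p.
R is implemented as the maximum pairwise shortest-path length of the induced
subgraph (infinite when it is disconnected, which counts as a violated
constraint); that is the operational formula even though such a quantity is
sometimes loosely called an eccentricity bound. Singletons take α = δ = 0
and R = 0, so positive floors exclude them from ever being covers: they are
the residual players.

Detection is framed as a sequential non-cooperative game whose players are
the vertices. A player's strategies are to propose a coalition, accept or
reject a joining request, or leave a coalition; the preference relation
orders outcomes so that players prefer membership in a minimum partial dense
vertex cover over staying alone over arbitrary groupings. A Nash equilibrium
— a partition in which no player gains from unilateral deviation —
corresponds to a minimum partial dense vertex cover.

## The engine

`nash_pdc` plays one deterministic run:

1. **Rule of order.** All players are ranked once, on the full graph, by
   √(d_v · t(v)) descending, where t(v) is local transitivity (fraction of
   neighbor pairs of v that are adjacent; 0 when d_v < 2, where no triple is
   centered on v). Ties break by degree descending, then node id ascending.
   Ranking before the loop (rather than re-ranking each residual game) makes
   the rule a fixed protocol of the game.
2. **Proposal.** The best-ranked active player proposes its closed p-th
   order neighborhood, computed inside the residual game: BFS paths may not
   route through players that already quit.
3. **Best response (prune, then grow).** The narrative notion "accept iff it
   is your best response" is operationalized greedily: while any floor is
   violated and more than `min_size` members remain, the non-proposer member
   with the smallest within-coalition degree leaves (ties: higher id first);
   removing the weakest-connected member is the step that most directly
   raises both α and δ, the quantities the preference relation orders. The
   proposer is never pruned — the coalition is defined around its
   neighborhood. If the floors cannot be met the proposal fails. A surviving
   coalition then absorbs, one vertex at a time, the adjacent active vertex
   with the most links into it whose entry keeps every floor satisfied
   (ties: lower id first), which enforces local maximality.
4. **Residual game.** A stable coalition's members quit. A failed proposer
   is marked exhausted — it never proposes again but remains joinable; one
   proposal per player makes termination immediate and keeps the run
   deterministic. Leftover players form the residual.

Feasibility checks run cheapest-first (size, α, δ, then a bounded BFS
diameter check), so the expensive diameter test only fires on candidates
that are already dense; the work per proposal stays proportional to the
p-ball, consistent with an overall O(N(log N + d_max^p)) worst case.

`verify_cover_set` re-checks an arbitrary cover property by property and,
optionally, certifies residual exhaustiveness by enumerating every residual
subset of size ≥ `min_size` (practical up to ~15 residual vertices). It is
implemented independently of the engine's incremental bookkeeping and serves
as the test oracle: on 200 random graphs of ≤ 12 nodes the engine's output
passes exhaustive verification of all properties.

## Parameters

| symbol | meaning | default | rationale |
|---|---|---|---|
| λ | degree-density floor | 0.6 | the worked two-block example's setting; every member must touch ≥ 60% of its coalition |
| γ | edge-density floor (λ ≤ γ) | 0.65 | same source; near-clique complexes |
| p | diameter bound and proposal radius | 2 | small-world assumption: complex members interact directly or via one shared partner |
| min_size | minimum coalition cardinality | 3 | excludes bare edges from being called complexes while keeping small true complexes |
| seed | recorded for randomized variants | 0 | the default engine is deterministic and never consumes it |

Sparse, low-density complexes can be sought simply by lowering λ and γ by
orders of magnitude (e.g. λ = 0.001, γ = 0.0008); nothing in the engine
assumes dense defaults.

## Synthetic benchmarks

`generate_gn` draws planted 4-partition (Girvan–Newman) graphs: 128 vertices
in 4 modules of 32, every intra-module pair linked with probability
p_in = z(1−μ)/31 and inter-module pair with p_out = zμ/96, so each vertex
has expected total degree z (default 16, the canonical GN instantiation; the
module sizes 128/4/32 are the standard benchmark) and an expected fraction μ
of its edges leaves its module. `generate_er` draws G(n, p) null graphs.
`rewire` redirects each edge endpoint independently to a uniformly random
vertex with probability ρ, discarding collisions and self-loops so the graph
stays simple. All three are seeded and bit-reproducible; sub-seeds for sweep
instances derive from one master seed via `numpy.random.SeedSequence`.

What the generators emulate — and what they do not: planted-partition graphs
have Poisson-like degrees, equal-sized non-overlapping modules, and
independent edges. Real PPI networks are heavy-tailed, their complexes
overlap and vary in size by an order of magnitude, and interaction sampling
is biased. Passing the synthetic battery therefore shows correctness of the
game dynamics and robustness to independent noise, not performance on real
interactomes.

## Evaluation metrics

NMI follows the entropy form
−2 Σᵢⱼ n_ij log(n_ij·n/(nᵢ·nⱼ)) / (Σᵢ nᵢ log(nᵢ/n) + Σⱼ nⱼ log(nⱼ/n)),
equal to 1 exactly for identical partitions (the 0/0 case of two one-class
partitions is defined as 1). When a game outcome is scored against a planted
partition, residual singletons enter as singleton classes, because the game
semantics make every protein either a complex member or a singleton cluster.
This convention charges the detector for every uncovered vertex; it is the
strictest reasonable reading.

Complex-level agreement uses the Jaccard matching score D = √(S·T) and the
contingency statistics Sn, PPV, Acc = √(Sn·PPV) on the table
t_ji = |R_j ∩ P_i|. Predicted complexes exclude residual singletons by
default (an `include_singletons` flag reverses this): reported predicted
complex counts in this literature are far below proteome size, so singletons
are evidently not counted as predictions. Zero-overlap predicted columns
contribute to neither aggregate; an all-zero table raises rather than
returning a defined PPV.

Connectivity density of a module is Σ_{v∈M} (within-module degree of v)
divided by the total edge count of the network — twice the internal edge
count over |E|, so the whole graph scores 2. The module-replacement (shift)
experiment swaps ⌈fraction·|M|⌉ uniformly chosen members for equally many
uniformly chosen outside vertices adjacent to at least one remaining member;
for genuinely dense modules the shifted density falls below the original on
average, which the 300-replicate experiment on planted modules reproduces.

## Numerical and degenerate-input choices

* All tie-breaks (pruning victim, growth candidate, rule of order) are fixed
  and id-based, so identical input and configuration give byte-identical
  output, including coalition order.
* Density comparisons use exact rational thresholds in floating point
  (`m ≥ γ·k(k−1)/2`); no epsilon is applied, matching the definition's sharp
  inequalities.
* Disconnected candidates (infinite diameter) are handled by the same prune
  loop; the diameter floor simply reads as violated.
* Edge-list readers drop self-loops (logged) and collapse duplicates;
  complex readers collapse duplicate members; writers order members
  lexicographically so outputs diff cleanly.

## Problem sizes used in the shipped experiments

The test suite and the reproduction script run the mixing sweep at 20 seeded
instances per μ ∈ {0.1, …, 0.7}, the rewiring sweep at 20 instances per
ρ ∈ {0, 0.05, 0.1, 0.25, 0.4} (base μ = 0.1), the null model at 10–20
ER(128, 16/127) instances, exhaustive engine-vs-definition verification at
200 random graphs of ≤ 12 vertices, and the shift experiment at 300
replacements per planted module. These sizes give standard errors on the
reported means of well under 0.01 NMI.

## Known limitations

* **Exact planted-module recovery and the default floors.** A planted
  32-vertex GN module at expected degree 16 has edge density
  δ ≈ 0.516(1−μ) ≤ 0.52, below the default γ = 0.65 for every μ, and its
  diameter exceeds p = 2 with non-negligible probability even at μ = 0.1.
  Under the default floors the equilibrium therefore consists of dense
  near-clique cores inside modules plus residual singletons — mean NMI
  ≈ 0.64 at μ = 0.1, decaying monotonically with μ and ρ — rather than the
  exact planted partition, and no setting of (λ, γ, p) consistent with the
  definition makes the mean NMI over repeated instances exactly 1.0. The
  reproduction script reports what the method actually computes.
* The detector returns one equilibrium partition; no claim of uniqueness is
  made, and overlapping complexes are out of scope (a protein quits the game
  on joining a coalition).
* Weighted or directed interaction data are not supported; identifier
  mapping across databases is the caller's concern.
* On null (Erdős–Rényi) graphs matched to benchmark density, triangles and
  other ≥ min_size near-cliques occur by chance and are, by the definition
  itself, feasible locally-maximal covers; the engine reports them. Callers
  wanting to suppress chance-level structure should raise `min_size` (size 5
  near-cliques at γ = 0.65 are vanishingly rare in such null graphs).
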