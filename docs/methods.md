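# Methods

## Model and assumptions

The aligner treats both interactomes as simple undirected graphs: parallel
edges are collapsed and self-loops dropped at parse time, since a
self-interaction carries no information for edge conservation between two
nodes. The source network must be no larger than the target
(n₁ ≤ n₂); every source node is mapped, injectively, to a target node.
The sole search objective is the conserved-edge count |f(E₁)|; sequence
information enters only through the initialization, not the objective.
This mirrors the division of labour in objective-function-based aligners:
topology drives the search, homology seeds it.

## Similarity blending

S = α·B̂ + (1−α)·T̂, where B̂ is the max-normalized sequence-score matrix
and T̂ the max-normalized neighbor-sum term A₁B̂A₂ᵀ. The blend is computed
on normalized terms because raw bit-scores (order 10²–10³) and neighbor
sums (scaling with degree products) differ by orders of magnitude; without
normalization α would not act as an interpretable weight. Source material
for this design left the scaling open; max-normalization is this package's
choice, and it is what makes the α = 1 ⇒ "sequence only" limit exact. The
topology term is computed from the normalized B so that its own
normalization is scale-free. Degenerate cases: an all-zero B yields an
all-zero S (no division by zero), and rows of isolated source nodes are
zero in T̂ by construction.

Default α = 0.4, the recommended weight for aligners that blend sequence
against topological similarity this way.

## Search parameters

| parameter | default | meaning |
|---|---|---|
| pop_size | 40 | bats in the swarm |
| max_iters | 1000 | iteration cap T |
| patience | 10 | stop after N stagnant iterations |
| f_min, f_max | 0, 1 | frequency band; binarization threshold is the midpoint 0.5·(f_max−f_min) |
| theta | 0.9 | loudness decay per acceptance |
| gamma | 0.9 | pulse-rate growth rate |
| loudness0 | 1.0 | initial loudness (early improving moves accepted almost surely) |
| rate0 | 0.5 | pulse-rate ceiling; local search triggers with probability 1−r |

θ, γ, A₀ and r₀ are not fixed by the method's source description; the
defaults are the canonical bat-algorithm settings. The pulse-rate growth
law as printed there is self-referential (rᵢᵗ on both sides); the
canonical form rᵢᵗ = rᵢ⁰(1−exp(−γt)) is used, and the initial rate is its
t = 0 value, 0, so local search is always considered until a first
acceptance. The acceptance comparison is strict: equal-objective
candidates are rejected, which is what makes the best-objective trace
non-decreasing and the patience criterion well-defined.

Two further points the equations leave open, resolved as follows:

* **Velocity refresh.** The per-iteration velocity rule can only turn
  flying dimensions off, never on; the single stated velocity-from-position
  rule (freeze endpoints of conserved edges) is therefore re-applied
  whenever a bat accepts a new position. The velocity computed during an
  iteration stays on the bat even when the candidate is rejected. The
  alternative (discarding it on rejection) was implemented and measured
  during development and is behaviourally indistinguishable on the
  workloads tested.
* **Greedy seeding.** All bats share one greedy pass (ties between equal
  maximal scores broken uniformly at random from the seeded stream); only
  the random completion of similarity-less sources differs per bat. With a
  dense similarity matrix the population therefore starts identical and
  diversifies through its stochastic dynamics.

## Search behaviour and known limitations

The dynamics make the swarm a *monotone constructive* hill-climber: both
endpoints of every conserved edge are frozen at each acceptance, frozen
dimensions never unfreeze between acceptances, and acceptance requires
strict improvement — so along any accepted trajectory the conserved-edge
set only grows and the search explores only monotone extensions of the
greedy seed's conserved structure. When the seed locks structure
inconsistent with the global optimum, that optimum is unreachable no
matter the budget. Consequently the swarm is strong when the similarity
matrix is informative (a noiseless indicator similarity yields the exact
mapping already at initialization) and weak as pure combinatorial
optimizer under uninformative guidance: on random 7-node instances with
uniform dense similarity it reaches the exhaustive-permutation optimum in
a minority of cases, typically stalling one conserved edge short, because
the last step would require breaking locked structure. This is a property
of the update equations, not of their implementation, and is the regime
real use avoids by seeding from homology.

## Synthetic instances

`generate_pair` derives the target network from the source by a random
injective relabeling (plus `n_extra` target-only nodes, attached by one
degree-preferential edge each), rewires `⌊rewire_p·|E₁|⌋` copied edges to
uniformly random non-edges, and builds a similarity matrix with 1 at true
pairs (minus a `sim_dropout` fraction zeroed) over uniform(0, sim_noise)
background. Replacement edges never reuse the image of a source edge, so
conserved(true_map) = |E₁| − n_rewired holds exactly — convenient for
verifying searches against construction bookkeeping. The generator
emulates what alignment benchmarks provide (related network pairs with
ground truth) in minimal form; it does not reproduce the degree evolution,
modular structure or annotation realism of grown benchmark families or of
real interactomes, so passing tests demonstrate correctness of the
machinery and behaviour under controlled noise, not performance on real
PPI data. The annotation helper gives each true pair a shared set of 3 GO
terms with per-term dropout 0.2 per side, enough to exercise GOC
end-to-end with a predictable expected overlap.

Generator defaults (edge probability ≈ 0.1 at n = 50, rewiring 0.1–0.2,
similarity noise 0.2–0.3) are chosen to mimic sparse PPI-like densities
(mean degree 3–8, matching the published benchmark tables) with noise
levels at which the true mapping remains identifiable.

## Metrics

GOC is reported both as the literal sum over aligned pairs of Jaccard
indices of GO term-ID sets — the primary value, faithful to its usual
printed definition — and as the mean over pairs with a non-empty term
union, which is comparable across instance sizes. Pairs with both term
sets empty contribute nothing to either. Term sets are compared as raw ID
sets; ontology-ancestor expansion and semantic-similarity measures (Wang,
and the AFS score built on it) are out of scope because they require the
GO DAG. Undefined metrics (zero denominators: EC on an edgeless source,
ICS on an edgeless induced region, S³ when both are empty) are reported as
None/null, never silently as 0.

## Numerical and determinism notes

All randomness in a run flows from one `numpy` Generator seeded by the
user; identical seeds give bit-identical alignments, traces and synthetic
instances. Greedy ties are broken by a uniform draw from that stream
rather than by index order, avoiding systematic bias toward low-index
nodes. Edge sets are stored canonically ((min, max), sorted), so no
iteration order depends on hashing. Conserved-edge counting packs target
edges into sorted integer keys and uses binary search, keeping the
objective evaluation O(|E₁| log |E₂|) per candidate.

## Problem sizes

The test suite and the acceptance script run on instances of 7–50 nodes
(oracle comparisons up to n = 30, swarm runs at n = 50, exhaustive
optimality checks at n = 7 where all 5040 permutations can be enumerated);
these sizes exercise every code path while keeping full runs fast. The
dense matrix representation is adequate to a few thousand nodes, matching
the published benchmark scale.
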