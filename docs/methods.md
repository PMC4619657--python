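# Methods

## The binding model

Proteins are particles carrying one *binding slot* per annotated domain
occurrence (a domain listed twice gives two independent slots). A pair of
slots may bond only if an interaction rule licenses the (protein, domain) /
(protein, domain) combination, and every rule is anchored on an observed PPI
edge: a known DDI between the partners' domains where one exists, otherwise
a fresh fictitious domain pair added to the two proteins — but only when
they share a functional annotation term, the evidence that the physical
interaction is plausible despite missing domain data. Each rescued edge
receives its own private fictitious pair, so rescue can never license
binding on an edge the PPI network does not contain. Edges with neither DDI
support nor a shared term are dropped, and a protein stays in the model only
if it retains at least one rule and has abundance data.

Copy numbers enter as `round(√abundance)` instances (half-up, minimum 1 for
any detected protein). The square root compresses the 4–5 orders of
magnitude of cellular copy numbers into a particle count a lattice
simulation can carry while preserving the abundance ranking; the refinement
squares predicted complex counts on output to return to the original scale.

## Spatial stochastic simulation

Space is a `grid_side × grid_side` lattice of sub-volumes (SVs), sized by
default to hold ≈ 50 instances per SV. Dynamics follow the
Gillespie-multiparticle operator split:

* every `diffusion_interval` (default 1 time unit) each free instance and
  each bound group picks uniformly among *stay* and its four lattice
  neighbours; off-grid moves are resampled among valid neighbours
  (reflecting boundary; a periodic option exists). Bound groups move as
  rigid units, which keeps all members of a complex in one SV — the simplest
  scheme consistent with reactions being SV-local.
* between moves, an exact SSA runs independently in every occupied SV:
  association fires at `k_on` per co-located complementary pair of *free*
  slots, creating a bond and merging the two groups; dissociation fires at
  `k_off` per bond, splitting the group if its bond graph disconnects
  (fragments stay in place and may rebind, reflecting the higher re-binding
  probability of co-located molecules).

Slot exclusivity — a slot holds at most one bond — is the mechanism that
converts abundance differences into competition: when two proteins bind the
same slot type, the more abundant competitor occupies more of the available
sites. Conservation of instances, slot exclusivity, co-location of bound
groups and rule licensing are asserted invariants (`check_invariants`).

Kinetic constants are not dictated by the input data; the defaults are
`k_on = 1`, `k_off = 0.1` (arbitrary time units), a binding-favoured regime
in which complexes accumulate. `t_end = 200` diffusion intervals, two
independent runs with random initial placements, sampled at `t_end/2` and
`t_end` — four collection points in total. All randomness flows from a
single seed through per-run `SeedSequence` spawns, so identical
(model, config, seed) triples reproduce identical complex lists. `k_off = 0`
is accepted as the absorbing limit (useful for assembly tests).

## Refinement and quantification

Connected bound groups of ≥ 2 instances (simulated complexes, SCs) from all
collection points are pooled. The frequency matrix counts, per unordered
protein pair, the SCs containing both; the affinity
`entry(a,b) / max(occurrence(a), occurrence(b))` normalizes away the overall
prevalence of promiscuous proteins. Average-linkage agglomeration on
distance 1 − affinity, cut at 1 − τ (τ = 0.5), yields the refined complexes
(RCs); the max-normalized affinity plus average linkage is one concrete
choice among reasonable matrix-refinement schemes and is isolated behind
`cluster_matrix` so it can be swapped.

Each SC is assigned to the RC with maximal overlap score ω, provided
ω ≥ 0.25 (ties: larger RC, then smaller id) — the same 0.25 convention used
for benchmark matching. An RC's simulated abundance is its assignment
count, tallied per run and per (run, time point); the reported abundance is
the square of the pooled count. The coefficient of variation is the sample
standard deviation over per-run counts divided by their mean. The LG/SM
filters (defaults: abundance < 2, size boundary 10) act on simulated
abundances before squaring. Free-subunit quantification subtracts each
protein's per-snapshot bound multiplicity from its instance count.

## Benchmarking

The overlap score ω(A,B) = |A∩B|²/(|A||B|) drives all qualitative metrics.
Recall counts reference complexes hit at ω > 0.25; MMR is the weight of an
exact maximum one-to-one matching (Hungarian assignment) divided by the
number of references; geometric accuracy is √(Sn·PPV) over the
intersection-count matrix; the composite score is their sum. A prediction
whose best ω is ≤ 0.25 is a new complex (the boundary counts as new).
Reference sets can be de-duplicated (size ≥ 3, greedy ω ≥ 0.8 redundancy
scan in descending size order, making the result order-independent). The
subunit-average baseline (mean raw abundance of members) is provided for
quantitative comparisons only.

## Drug perturbation

The bound domain types of a drug are inferred from its target list by a
one-sided hypergeometric enrichment of each domain's presence among targets
versus the model proteome, Benjamini–Hochberg-corrected at α = 0.05, with a
majority-rule fallback (> 50% of targets) when nothing passes. The drug
becomes a species with one slot per bound domain type and `round(√abundance)`
instances; it binds the matching slot of any protein that carries the domain
and is a target or a PPI partner of one, with the same default kinetics as
protein–protein bonds (the drug's kinetics are configurable). Because of
slot exclusivity, drug occupancy occludes the protein–protein bonds through
those domains.

Control and treated complexomes are matched greedily by descending ω above
0.25, one-to-one. Matched pairs are tested with a Welch t-test on the four
per-(run, time point) abundance counts; p < α flags a quantitative change,
unmatched RCs are qualitative changes, and pairs with fewer than two
replicates per arm are marked untestable.

## Synthetic fixtures

The generator plants `n_planted` (default 10) disjoint complexes of 3–8
members, wired as a random spanning tree plus extra edges (probability 0.3),
each edge carrying a private domain pair that enters the DDI table with
probability `ddi_coverage` (default 0.34, the typical fraction of PPI edges
with known DDI support in real corpora). Co-members share a complex-specific
annotation term — subunits of a real complex act in the same process — so
uncovered planted edges are always eligible for fictitious rescue, while
noise edges share a term only at `shared_function_rate` (default 0.75,
chosen so rescue lifts effective coverage to the ≈ 0.85 seen in curated
networks). 100 decoy proteins carry abundances, background domains and
annotations but almost no interactions, exercising the builder's retention
rules; spurious edges make up `noise_ppi_rate` (default 5%) of the PPI list.
Abundances are log-normal(μ = 4, σ = 1), clamped to ≥ 1 — copy numbers
spanning ~10–10⁵ like a real proteome. Everything is deterministic under
the seed.

The drug fixture rewires one planted complex (the victim) so all its
internal bonds run through a single bridging domain carried by every victim
member and nothing else — the enrichable signal — and sets the drug's
targets to the victim's members. Default drug abundance 250 000 (500
instances) saturates the victim's ~100 bridging slots.

What the fixtures do *not* emulate: scale-free topology, shared domains
across unrelated complexes, overlapping complexes (an option exists),
stoichiometry beyond one slot per edge, or measurement noise in abundances.
Passing tests therefore demonstrate the pipeline's mechanics and its
statistical behaviour under controlled conditions, not performance on real
interactomes.

## Numerical and design notes

* SSA channel selection recomputes per-rule channel counts from free-slot
  pools each event (O(#active rules)); slot pools use swap-pop indexed lists
  for O(1) removal and uniform sampling.
* Determinism: proteins are placed in sorted-id order; SVs are swept in
  sorted order; group and bond ids are monotone counters; clustering input
  is lexicographically ordered, so every stage is reproducible bit-for-bit.
* Degenerate inputs: a 1×1 lattice is the well-mixed limit; zero-instance
  species are placed nowhere but change no random draws (a zero-abundance
  drug reproduces the control trajectory exactly under the same seed);
  empty reference sets make recall/MMR undefined (reported as missing), and
  a t-test over constant identical replicates returns p = 1.
* The Welch (unequal-variance) t-test is used over the pooled-variance
  variant for robustness; replicates are the per-(run, time point) counts.

## Known limitations

* **Saturation decouples counts from copy numbers.** In the default
  binding-favoured regime (`k_off/k_on = 0.1`) per-slot occupancy in
  populated SVs approaches 1, and instances of one complex chain into long
  connected groups (a member can simultaneously bind partners from two
  different copies). The number of observed groups then scales with the
  dissociation rate rather than with subunit abundance, so *changes* in one
  complex's abundance move its predicted count only weakly. A fragmentation
  regime (`k_off ≈ k_on`) restores abundance sensitivity but lowers
  run-to-run reproducibility of the counts at small fixture scale. At
  proteome scale the two effects relax; at fixture scale they trade off,
  and the defaults favour assembly and reproducibility.
* Diffusion is uniform across proteins and groups (no size-dependent
  mobility); space is 2D; there are no compartments or membranes.
* The frequency-matrix refinement is a heuristic consensus step; τ, the
  association threshold and the LG/SM thresholds are tunable and their
  defaults were fixed once for the fixture scale.
* Drug binding is reversible with protein-like kinetics; irreversible
  inhibitors would need a much smaller `k_off` for the drug rules
  (configurable per run, not per rule).
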