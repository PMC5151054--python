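# Methods

`constrainet` builds *constraint network models* of weighted, directed,
dense interareal connectomes: ensembles of networks that satisfy a chosen
set of empirical features but are otherwise maximally random.  Scoring
which *unconstrained* features these ensembles nevertheless reproduce
separates genuine, independently organized network hallmarks from
structural byproducts ("spandrels") of the constrained ones.

## Features and the constraint error

For a weights matrix `W = {w_ij}` (row = source), the constrained features
are:

* **node strength** — out: `s_i = Σ_j w_ij`; in: `s_j = Σ_i w_ij`;
  constrained as two vectors because a directed network's hub structure is
  not captured by either direction alone;
* **node wiring cost** — `Σ_j d_ij b_ij` per direction, with `d_ij` the
  pathway length and `b_ij` its bandwidth (capacity);
* **module weight** — `l_uv = Σ_{i∈u} Σ_{j∈v} w_ij` for modules `u, v` of a
  partition; `l_uu` is the intra-module weight.  Nodes that belong to no
  module (`UNASSIGNED`) contribute to no module entry but are still
  constrained through their strengths.

Every feature has a *binary* variant in which weights (and bandwidths) are
replaced by adjacencies `a_ij = 1{w_ij > 0}`.

Achieved values `c` are compared with targets `c̃` through the normalized
error

    e_i = mean_j |c_ij − c̃_ij| / mean_j |c̃_ij|,
    E   = ((1/k) Σ_i e_i^q)^(1/q),

a generalized mean over the `k` constraint types with `q = 2` by default
(mean squared error; `q = 1` and `q → ∞` are supported and do not move the
global minimum).  Normalizing the per-type mean absolute error by the mean
absolute target makes `e_i` scale-free; each `(feature, variant,
partition)` entry counts as one type.  A network scored against its own
features satisfies `E = 0` for every `q`.

### Model presets

* `wiring_cost` — out/in node wiring cost;
* `wiring_cost_strength` — wiring cost + node strength;
* `intra_module_only` — intra-module weight without strengths;
* `basic_hallmark` — intra-module weight + node strength (the modules-and-
  hubs model);
* `benchmark` — intra- and inter-module weight at two resolutions + node
  strength (upper bound for hierarchy reproduction).

Each preset carries both weighted and binary variants for the
hard-constraint sampler and weighted-only variants
(`binary_variants=False`) for the soft-constraint sampler and the
"weighted-only" hard sampler.

## Hard-constraint sampler (simulated annealing)

Each sample starts from the reference network, randomizes it with a long
sequence of unconditional mirrored slot exchanges (preserving bilateral
weight relationships), and then minimizes `E` by Metropolis annealing:
a move exchanges the contents of two off-diagonal slots — *including empty
slots*, so binary topology can change — together with their bilaterally
mirrored slots.  Moves that lower `E` are always accepted; others with
probability `exp(−ΔE/T)`; `T` shrinks geometrically per stage.  The
empirical weight multiset is conserved bit-exactly by construction, and a
bandwidth travels with its weight while a distance stays with the node
pair.

Numerical design:

* constraint vectors are updated incrementally (a move touches ≤ 4 slots),
  with a full recomputation at each stage boundary to bound floating-point
  drift; the wrapper additionally verifies the final `E` against a fully
  independent evaluation through the feature functions;
* when the drawn slot pair and its mirrored pair partially collide (only
  possible through midline, self-mirrored nodes), the proposal is
  discarded rather than applied asymmetrically — so every applied move is
  an involution and the chain is reversible;
* the full-scale schedule (`full_schedule`) is T0 = 1, cooling
  factor 0.999 per 10⁴ iterations, 10⁹ iterations, tolerance E < 0.005.
  The desk-scale `test_schedule` keeps T0 and the tolerance but shortens
  stages to `4 n²` iterations with cooling 0.995 and a 1.2 × 10⁴-stage
  budget — on 30–60-node references this converges in a few seconds per
  sample.  A sample that ends above tolerance is returned flagged
  (`success=False`) with its best error, for the caller to retry;
* the inner loop is a numba kernel; all randomness flows through one seed
  per sample.

Wiring-cost constraints are the hardest to satisfy at desk scale: matching
per-node sums of products of continuous distances and bandwidths to 0.5%
on a ~30-node network nearly pins the original configuration, and the
scaled schedules typically plateau at E ≈ 0.007 instead of 0.005.  Such
samples are flagged but remain usable models (wiring costs matched to
about 1%); the basic-hallmark and module presets reach E < 0.005 reliably.

## Soft-constraint sampler (maximum entropy / ERGM)

The maximum-entropy distribution over integer-weighted networks with
expected node strengths and module weights factorizes per connection into
geometric laws `P_ij(w) = (1 − p_ij) p_ij^w` with `p_ij = x_i y_j z_uv`.
The auxiliary variables solve

    Σ_j p_ij/(1−p_ij) = s̃_i^out,   Σ_i p_ij/(1−p_ij) = s̃_j^in,
    Σ_{i∈u,j∈v} p_ij/(1−p_ij) = l̃_uv,

which we treat in log-variables with damped Newton iteration (analytic
Jacobian, backtracking line search that keeps every `p_ij < 1`),
warm-started by a few exact coordinate sweeps; coordinate sweeps also
serve as a fallback when a Newton step stalls.  Slots touching an
unassigned node carry no module multiplier (`z = 1`); zero-strength nodes
and zero-target module blocks are fixed at `p = 0`; inconsistent targets
(out/in sums differing, module weights exceeding the total) are rejected
before solving.

Real weights are mapped to integers by a precision factor (default
`10⁴ / median positive weight`, configurable) before fitting and divided
back after sampling.  Constraints hold exactly for the ensemble
expectation — per-sample errors are O(1) while the error of the
N-network ensemble mean decays like N^(−1/2).  Binary features and
individual connection weights are not constrained, and wiring costs are
not representable in this first-order family.

## Cost-minimized lattice

The lattice model assigns the reference's positive weights, sorted
descending, one-to-one to the off-diagonal slots with the smallest
distances (all slots with a defined distance are candidates, not only
observed pathways).  Distances are first perturbed by uniform noise of
half-width `noise_frac ×` median existing-connection distance (default
1%) to break near-ties robustly.  By the rearrangement inequality the
zero-noise assignment minimizes `Σ d_ij w_ij` over all placements onto the
chosen slots.  Assignment is global rather than per-hemisphere-orbit:
with noisy mirror weights a mirrored assignment is ill-defined, and the
global assignment preserves the weight multiset bit-exactly.

## Module hierarchies

Partitions are scored with the directed weighted modularity

    Q = (1/v) Σ_ij [w_ij − γ s_i^out s_j^in / v] δ(m_i, m_j),

(`v` = total weight; higher resolution γ → smaller modules; unassigned
nodes are scored as singletons).  The optimizer is a randomized greedy
multi-level (Louvain-style) local-mover whose final pass guarantees a
local maximum under single-node moves on the original network.  Per γ on
the grid (default 0.5 to 2.5 in steps of 0.05) a consensus partition is
built from many restarts by iteratively thresholding the co-assignment
matrix at its analytic permutation-null expectation and re-clustering
until all restarts agree.  Runs of identical consensus partitions spanning
γ intervals ≥ 0.2 are reported as *stable ranges*.

Partition similarity is `NMI = 2 I /(S₁ + S₂)` with entropies in bits
(the arithmetic-mean normalization; scale-invariant, so the base is
cosmetic), `UNASSIGNED` counting as its own category, and two zero-entropy
partitions defined as identical (NMI 1).  Model hierarchies are scored by
`hierarchy_accuracy`: for each reference level (a partition with a
designated γ) take the model's stable partition nearest in γ and report
the NMI, or 0 when the model has no stable partition.

## Rich clubs

For a club node set `R`, `D(R) = Σ_{i≠j∈R} w_ij(model) / Σ_{i≠j∈R}
w̃_ij(reference)`, both orientations counted, diagonal excluded.  `D` is
linear in the model weights, so the ensemble-mean density equals the mean
of per-sample densities.  A network lacks the club when `D < 1`
(boundary `D = 1` counts as possessing it).  Club membership is an input;
no detection is performed.

## Synthetic reference generator

The generator emulates the statistical structure of dense interareal
reconstructions and provides ground truth for every test:

* bilateral hemispheres (default 28 areas each) with an exact mirror
  pairing; mirrored weights carry relative log-normal noise
  (`mirror_noise`, default 0.1 — rank-based bilateral symmetry stays near
  1, as in real reconstructions);
* a planted two-level hierarchy: 7 high-resolution modules nested in 4
  low-resolution modules (surjection `nesting`), both bilateral;
* unassigned hub areas (default 4 per hemisphere) that connect into every
  module ("high connection diversity") with moderately strong weights and
  densely interconnect with strong weights — the planted rich club.  Hub
  weight factors are the one deliberately asymmetric knob: hub→module
  weights get the boost `h`, hub↔hub weights `h²`; making hub→module
  weights as strong as hub↔hub ones swamps the module signal and no
  generator regime then recovers the planted partitions;
* log-normal weights (σ = 0.75 on the natural-log scale) multiplied by
  module/hub factors (low-module boost `b`, high-module `b²`, default
  `b = h = 6`), spanning ~4 orders of magnitude overall;
* connection probabilities proportional to the same factors, rescaled (with
  a 0.98 cap) to a target density of 0.6;
* 3-D spatial embedding with module members co-located and hemispheres
  mirrored through the midline plane; distances are Euclidean and defined
  for absent connections (as the lattice model requires);
* bandwidths equal to weights (`proportional`, for data without
  cross-section estimates) or drawn independently (`independent`).

Defaults were chosen once so that the planted high-resolution partition is
recovered from the resolution sweep with NMI ≥ 0.9 and hubs sit near the
top of the strength ranking; they are frozen as the package's study
conditions.  What the generator does **not** emulate: anatomical geometry
of real tracts, distance-dependent connection probabilities, reciprocity
structure, or the exact empirical weight distributions — so passing tests
demonstrate correctness of the machinery and the qualitative constraint
logic, not quantitative agreement with any real connectome.

## The spandrel experiment

`run_spandrel_experiment` generates, for each preset × sampler, an
ensemble of models of a synthetic reference; re-detects each model's
module hierarchy by the full sweep; scores per-level NMI against the
reference's planted partitions (γ per level taken from the reference's own
stable ranges); and summarizes planted-club densities.  The headline
qualitative result — the basic-hallmark (modules + hubs) model reproduces
the unconstrained low-resolution partition and the hub-club density better
than the wiring-cost + strength model — holds on desk-scale references
(32 nodes, 6 samples/preset) in 10/10 generator seeds.

## Problem sizes and numerical conventions

Tests and the acceptance script use the default 56-node reference for
sampling accuracy and max-ent checks, 32-node references for
experiment-level checks, and ≤ 8-node toys wherever an exhaustive oracle
(all 4140 partitions of 8 nodes; all 720 weight permutations of 6 slots)
is the comparison.  Ensemble sizes are 10 samples for hard-constraint
accuracy and {10, 100, 1000} for soft-constraint convergence.  Ties in
the lattice are broken by the distance noise; ties in the local mover by
first-best with a 10⁻¹² improvement margin; the consensus threshold is the
analytic permutation-null expectation rather than a tuned constant.

## Known limitations

* Uniformity of hard-constraint sampling is plausible (ergodic, reversible
  moves) but not formally guaranteed; no parallel tempering is provided.
* Soft-constraint sampling can misrepresent multimodal target
  distributions; it supports only first-order (strength/module-weight)
  constraints.
* Wiring-cost-constrained annealing plateaus slightly above the 0.005
  tolerance at desk scale (see above).
* The modularity variant (γ inside the bracket, Leicht–Newman directed
  null) and the NMI normalization (arithmetic) are stated conventions;
  both have alternatives in the literature that would change absolute
  values but not the qualitative orderings tested here.
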