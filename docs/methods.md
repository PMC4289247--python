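# Methods

## Model

Genes of N species form a multi-layer network: within a layer, edges record
co-association (here: co-expression); between layers, edges record
orthology. A module assignment gives every gene a label σ ∈ {1..q} and is
scored by

H(σ) = − [ Σ_layers Σ_ij Λ_ij δ(σ_i,σ_j) + κ Σ_{(i,j)∈O} w_ij δ(σ_i,σ_j) + κ_t Σ_{(i,j,k)∈T} δ(σ_i,σ_j,σ_k) ]

with Λ_ij = A_ij − λ k_i k_j / 2m per layer (degrees and m of that layer),
O the set of cross-species ortholog pairs and T the optional 1-1-1 triplets
for N ≥ 3. Lower H is better. The intra-layer sums are the summands of
Newman modularity over ordered pairs *including* i = j, which makes two
identities exact: the all-one-module labeling scores 0 at λ = 1, and two
disjoint triangles labeled separately score Q = 0.5 when normalized by 2m.

**Layer scale.** By default the layer terms are left on their raw scale
(no division by 2m). On that scale one co-labeled edge contributes ≈ 2 and
one co-labeled one-to-one ortholog pair contributes κ, so κ of order 1–3
balances the two edge types and, crucially, both terms order at the same
temperature during annealing. Dividing each layer by its 2m (available as
`CostParams(normalize_layers=True)`) rescales intra-layer couplings by
~1/2m: the orthology term then freezes ortholog pairs thousands of times
hotter than the modularity term can act, and single-spin dynamics lock into
fragmented conserved modules. We verified this directly: on the default
planted scenario the normalized cost at κ = 1 leaves the conserved modules
shattered into ortholog-pair clumps while the raw scale recovers the planted
optimum in every run. The normalized option is kept for sensitivity
analysis; κ must be retuned when using it.

**Ortholog weights.** w_ij = (1/a + 1/b)/2, where a is the number of
orthologs of i in j's species and b vice versa. One-to-one pairs keep
weight 1; a complete a×b clique contributes total weight ≈ (a+b)/2 rather
than a·b, which is what lets clique-straddled conserved structures stay
resolved (see the clique study below). Alternatives 1/(a·b), 1/√(a·b) and
uniform weights are selectable (`scheme=` in `compute_ortholog_weights`,
`weight_scheme` in the run config).

**Resolution.** λ multiplies the null term; λ = 1 is the conventional
default. Large modules produced by the resolution limit of any global
modularity-like objective can be broken up by re-running the tool on the
module's subnetwork; no recursive scheme is built in.

## Optimization

Heat-bath simulated annealing: labels start uniform-random; at each
temperature, 20 full sweeps resample one gene at a time from the Gibbs
distribution of its local cost over all q labels (computed incrementally
from the gene's incident edges, ortholog links, triplets and per-label
degree sums; the incremental energies are held to agree with full cost
recomputation to 1e−9 in the tests). The initial temperature is the
smallest value on a doubling grid whose measured flip rate exceeds 1 − 1/q
(i.e. the system is fully melted); cooling multiplies T by 0.9; the run
stops when fewer than 1% of genes flip in a sweep (or after
`max_temperatures` = 200, flagged non-converged). The reported labeling is
the best-cost configuration seen anywhere in the run. The sweep kernel is
numba-compiled; a run is bit-reproducible from its seed, and ensembles use
seeds seed+0..R−1 so parallel and serial execution agree exactly.

Three deterministic label-set moves run after each temperature's sweeps,
because single-spin dynamics cannot relabel a whole module at once:

* **coalescence** — merge two labels whenever that strictly lowers H
  (exact gain from between-label edge counts, degree sums and orthology
  weights). This is the move that aligns a conserved module's two layer
  halves onto one label (cost gain κ·Σw, modularity-neutral) and heals
  fragments.
* **group reassignment** — move all genes of one (layer, label) group to a
  better label, steepest-descent, each move verified against the exact cost.
* **decollision** — groups in different layers that share a label with zero
  (κ-weighted) orthology between them are cost-neutrally separated onto
  fresh labels. Such collisions are invisible to H but fake cross-layer
  co-appearance in the consensus; at κ = 0 every cross-layer co-label is
  separated, which restores exact independence of the layers.

All three are exact-descent (or neutral) moves on the same cost function,
not heuristics toward any external target; at high temperature the
subsequent sweeps re-randomize their effect.

Because ties in H are possible (e.g. before/after a neutral decollision),
the best-configuration tracker prefers the later, structurally cleaned
configuration at equal cost.

**q.** q only caps the number of modules; labels coalesce as the system
cools, and the final module count is invariant over q ∈ {10, 50, 250} on
planted instances (tested). Default q = 250 in the CLI config; the bundled
scenarios use smaller q matched to their size.

## Consensus

The co-appearance matrix holds, for each gene pair, the fraction of R runs
in which it was co-labeled (R = 32 by default in the CLI; the desk-scale
scenarios use R = 8–16). Modules are connected components of the graph
thresholded at co-appearance ≥ 0.95; components smaller than `min_size` = 5
stay unassigned. Components (rather than cliques) realize the transitivity
of "assigned to the same module" and are deterministic; the threshold uses
≥, which differs from strict > only on exact grid points k/R. A module is
tagged *conserved* if it has ≥ 3 genes from each of ≥ 2 species and at
least one internal ortholog pair, otherwise *specific* to its majority
species. Module sizes are fitted by discrete maximum likelihood to
p(s) ∝ s^α (Hurwitz-zeta normalization, xmin = smallest module size,
α reported negative); the fit warns when only two distinct sizes exist and
refuses < 10 modules or zero spread.

## Co-expression layers

Expression is optionally log2(x+1)-transformed, z-scored per gene, and
correlated (Pearson; ≥ 3 conditions required, zero-variance or incomplete
genes dropped). Each gene nominates its top d partners by |r|; the network
is the union of nominations with the correlation's sign on each edge, so
mean degree ∈ [d, 2d] and the edge set grows monotonically with d.
d is chosen as the smallest value whose network is a single connected
component over all usable genes ("giant" read strictly; a coverage-fraction
variant is exposed). If no d ≤ d_max connects the network, d_max is used
with a warning — the default scenario caps d_max at 10 to keep layers
sparse, accepting a handful of isolated genes. Ties at the d-th rank break
by (|r| descending, gene index ascending) for bit-reproducibility. Signed
mode scores the positive and negative subnetworks separately (Q⁺ − Q⁻),
each with its own degrees and m.

## Synthetic data

The generators plant known structure so every stage is testable offline:

* **Networks** — per species, genes split evenly into modules; edges
  Bernoulli(p_in) within and Bernoulli(p_out) between modules. Conserved
  modules (the first `n_conserved`) are matched across species by
  within-module position; each matched pair becomes an ortholog with
  probability f (default 0.9 — real ortholog calls do not cover every
  conserved gene). Optional complete bipartite ortholog cliques and
  uniformly random "noise" orthologs (pairs whose co-expression is not
  conserved, the bulk of a real ortholog table) can be added.
* **Expression** — each cross-species module group draws a latent profile
  over conditions (conserved counterparts share it); gene profiles are
  √ρ·latent + √(1−ρ)·noise, giving expected within-module Pearson ρ
  (verified to ±0.05 at 30 conditions). Default study: 2 species × 200
  genes, 4 modules each, 2 conserved, ρ = 0.7, 30 conditions.
* **Benchmarks** — module-specific GO terms shared across conserved
  counterparts plus ubiquitous terms (idf 0) and random rare terms;
  metagenes sampled from matched ortholog pairs; regulators targeting one
  planted module each; ncRNAs copying module mean profiles plus noise.

What the generator does **not** emulate: heavy-tailed degree and module-size
distributions, overlapping modules, condition-dependent (dynamic)
co-expression, correlated noise between genes, and ortholog tables with
realistic paralog family structure. Passing tests therefore demonstrate
correctness of the machinery and qualitative behavior of the method, not
performance on genome-scale data.

## Evaluation choices

* **GO similarity** — gene×term incidence, term j weighted by
  idf_j = ln(n/n_j) (natural log; terms on all genes vanish), genes compared
  by cosine. The GO similarity network's weighted modularity
  (ordered-pair null, W_ii = 0) benchmarks a module assignment; the κ scan
  recommends argmax of that modularity when GO input is available, else the
  knee of the recovery/modularity tradeoff (argmax of the sum of both
  min-max-scaled curves).
* **Ortholog enrichment** — observed cross-module ortholog pairs vs
  expected O·(n_a/N_a)·(n_b/N_b); the hypergeometric tail draws n_a·n_b
  candidate pairs from N_a·N_b total with O successes. The urn is a
  documented convention (pairs are not strictly exchangeable).
* **Clustering overlap** — gene pairs co-assigned by both clusterings over
  pairs co-assigned by at least one (category "neither" excluded as it
  dwarfs the rest); defined 1 when neither side co-assigns any pair.
* **Regulator coherence** — mean shared-regulator count over within-module
  pairs / over between-module pairs; permutation null shuffles the
  gene-to-module assignment preserving sizes; add-one p-value.
* **ncRNA mapping** — pooled null from 10 condition-shuffles of every ncRNA
  profile; neighbor threshold = smallest correlation with empirical FDR
  (null tail / observed tail) < 5%; per-module upper-tail hypergeometric on
  the neighbors, mapped where p < 0.01 (multiple mappings allowed). Class
  enrichment draws each module's mapped ncRNAs from the pool of all mapped
  ncRNAs. No multiple-testing correction where raw thresholds are the
  convention; a Benjamini–Hochberg helper is deliberately not applied by
  default.
* GO terms are used as given (no ancestor propagation); gene identifiers
  match exactly and case-sensitively.

## Study sizes

The bundled scenarios are desk-scale by design: ground-state validation on
50 random instances with M ≤ 10 and q ≤ 3 (exhaustive enumeration up to
label permutation); end-to-end recovery at M = 400, q = 50, R = 16; the
clique study at M = 32 with an 8×8 clique and κ = 8 (on the raw layer
scale, uniform weights make the clique's κ·32 between-structure pull exceed
the 2×56 modularity cost of merging, while normalized weights reduce the
pull to κ·4 — the two regimes bracket the collapse threshold); the κ scan
at 2 × 60 genes, q = 20, R = 8, 3 seeds, grid {0, 0.5, 1, 3, 10}. The full
suite runs in about a minute plus kernel compilation.

## Known limitations

* Simulated annealing is a heuristic; convergence to the global optimum is
  only verified exhaustively on tiny instances. The label-set moves remove
  the dominant metastabilities we observed (fragmentation, misalignment,
  collisions) but cannot split a mixed label within one layer — the sweeps
  must do that while the system is still warm.
* One global κ couples all species pairs; per-pair coupling constants are
  not implemented.
* The signed cost is available but on planted data we saw no advantage over
  unsigned scoring, and its energy landscape is rougher.
* Module extraction at 0.95 is stringent: genes whose assignment varies
  across runs are dropped rather than forced, so coverage < 100% is normal
  on hard data.
* The ncRNA FDR threshold is global (pooled over ncRNAs), not per-ncRNA.
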