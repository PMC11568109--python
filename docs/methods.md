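# Methods

This note documents the models and procedures implemented in `gracoal`,
the parameter choices that matter, and what the synthetic benchmarks do
and do not demonstrate.

## Graphlets, orbits and graphlet adjacency

A graphlet is a small connected non-isomorphic induced subgraph; the nine
graphlets on 2–4 nodes (G0–G8) and the 15 automorphism orbits of their
node positions follow the standard numbering (G0 edge, G1 3-path, G2
triangle, G3 4-path, G4 3-star, G5 4-cycle, G6 paw, G7 diamond, G8 K4).
For a network H = (V, E), `count_graphlets` enumerates **every** connected
induced subgraph on 2–4 nodes exactly once, growing subsets node-by-node
from each anchor with an exclusive-neighbourhood rule (each subset is
produced at exactly one anchor and extension order). Classification uses
(size, edge count, maximum induced degree), which separates G0–G8 without
a general isomorphism routine; the orbit of a node within a graphlet is
determined by its induced degree. The enumeration is exact by
construction and is cross-checked in the test suite against an
independent oracle that enumerates all subsets with `itertools` and
classifies by `networkx` isomorphism.

The graphlet adjacency matrix is

    A_Gi(u, v) = c_uv(Gi) / theta_Gi   (u != v),   A_Gi(u, u) = 0,

where c_uv(Gi) counts occurrences of Gi touching u and v simultaneously
and theta_Gi = |V(Gi)| − 1, so each row sums to the touch count t_u(Gi).
A_G0 is the ordinary adjacency matrix. The symmetric normalization used
for spectral embedding is D^{−1/2} A_Gi D^{−1/2} with D = diag(t_u); the
negative exponent is the standard choice that rescales rather than
amplifies. Nodes with t_u = 0 yield zero rows and are excluded from
embeddings (and can therefore never be enriched downstream).

Complexity is output-sensitive: roughly proportional to the number of
connected 4-subsets (≈ n·d³ at mean degree d). At the scales used here
(n = 500, mean degree 4) a full count takes well under a second.

## Disk embeddings

**Graphlet Spectral embedding** is Laplacian eigenmaps on the normalized
graphlet adjacency: coordinates are the eigenvectors of L = I − Ã_Gi for
the `dim` smallest nonzero eigenvalues, computed by dense symmetric
eigendecomposition on the largest connected component of the
graphlet-adjacency graph (components are ordered by size, then smallest
member label). Because A_Gi's rows sum to t_u, the vector sqrt(t_u) is an
exact null vector of L on each component, so exactly one eigenvalue per
component is zero and "smallest nonzero" means eigenvalues 2..dim+1 in
sorted order. Signs are fixed by making the first entry of magnitude
> 1e−12 positive, which makes the embedding a pure function of the
network.

**Angular step.** Raw angles are measured against the positive y-axis
(the pole), compass style: angle = atan2(x, y) mod 2π. Nodes are ranked
by (raw angle, label) — the label breaks ties deterministically — and the
node of rank k among N embedded nodes receives the final angle 2πk/N:
equidistant placement on the disk periphery preserving the raw circular
order. A node at the exact origin is assigned raw angle 0 and logged.

**Radial step.** GraCoal ranks nodes by t_u(Gi) (descending, label
tie-break) and sets rad_u = ln(r_u): the most frequent toucher of the
graphlet sits at the centre, and because a disk's circumference grows
with radius the many low-count nodes get proportionally more room. The
classical coalescent baseline instead ranks by degree and sets
rad_u = β·ln(r_u) + (1−β)·ln(N) with β = 1/(λ−1) from a power-law fit of
the degree distribution. Graphlet-count distributions need not follow a
power law, which is why the GraCoal radius omits the exponent weighting.

**Power-law fit.** The continuous maximum-likelihood estimator
λ̂ = 1 + n / Σ ln(d_i/d_min) with d_min = 1 by default (an optional
`d_min` restricts the fit to the tail d ≥ d_min). λ̂ is clamped below at
1.5, so β ≤ 2; the clamp only fires when the degrees carry no tail
information. When a clamped fit pushes β above 1, the rank-1 end of the
radius formula goes negative; `coalescent_embed` floors radii at zero in
that out-of-model regime (logged). For λ ∈ (2, 3), the regime the radius
formula assumes, radii are always in [0, ln N].

**GraSpring** is a Fruchterman–Reingold layout whose attraction along
each graphlet-adjacency edge is multiplied by the normalized weight
Ã_Gi(u, v), with uniform repulsion k²/d (k = 1/√n), displacement capped
by a temperature that cools linearly from 0.1 over a fixed 50 iterations,
and the spectral embedding as initialization — no randomness anywhere, so
repeated runs are byte-identical, and zero iterations return the
initialization unchanged. The loop is implemented directly (≈20 lines of
numpy) rather than through a layout library so that the zero-iteration
identity and exact determinism hold.

## SAFE enrichment

Given a 2D embedding (disk embeddings are converted via x = r·sin θ,
y = r·cos θ):

1. every network edge is weighted by the Euclidean distance between its
   endpoints in the embedding (coincident endpoints get 1e−12 so
   shortest paths stay defined), and exact all-pairs weighted
   shortest-path distances (WSPD) are computed with Dijkstra;
2. the neighbourhood of u is {u} ∪ {v : WSPD(u,v) < α}, strict
   inequality. α is tuned by bisection over the sorted distinct finite
   distances to the smallest value whose mean neighbourhood size reaches
   the target (default 50); because mean size is a step function of α the
   search is exact — no smaller α reaches the target;
3. enrichment of term T in neighbourhood N(u) is the upper-tail
   hypergeometric probability of drawing at least the observed number of
   T-genes when |N(u) ∩ annotated| genes are drawn from the annotated
   population. Only annotated nodes count — in the population, the
   sample, and the enriched-gene denominator. Benjamini–Hochberg
   correction is applied across terms within each neighbourhood;
   significance is adjusted p < 0.05. A term is *enriched* if significant
   in ≥ 1 neighbourhood; an annotated gene is *enriched* if ≥ 1 term is
   significant in the gene's own neighbourhood;
4. terms enriched in < 10 neighbourhoods (default) are discarded; the
   rest are clustered by average-linkage agglomerative clustering on
   1 − Jaccard of their enriched-neighbourhood sets, cutting the
   dendrogram at 75% of its maximum merge height (default). Each domain
   is labelled with the five most frequent words of its term names after
   stop-word removal (a built-in list of English function words plus
   annotation boilerplate such as "process", "regulation", "positive",
   "negative"; overridable), ties alphabetical.

Genes dropped from an embedding (zero graphlet count or outside the
embedded component) can never be enriched but remain in the denominator
of the comparison report, so an embedding that discards many nodes pays
for it. Per-run enriched-gene sets can be unioned across graphlet
adjacencies; domain uniqueness across runs is summarized by the maximum
Jaccard overlap of term sets against all other runs (Max JI = 0 marks a
completely unique domain), and a domain's paralog ratio is the fraction
of its enriched genes appearing in at least one paralog pair.

## Model fitting

A model family fits a network if the network's wiring cannot be
distinguished from the family's internal variability. For each family,
15 seeded instances are generated with node count equal and edge count
within ±5% of the real network's; the graphlet correlation matrix (GCM)
of each network — Spearman rank correlations between the 11 non-redundant
2–4-node orbit-count columns (orbits 0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11),
with one artificial node touching every orbit once appended to avoid
all-zero columns (a column still constant after that is treated as
uncorrelated) — is compared by the graphlet correlation distance (GCD),
the Euclidean norm of the upper-triangle difference. The 15 real-vs-model
GCDs are tested against the 105 model-vs-model GCDs by a two-sided
Mann–Whitney U (normal approximation, tie correction); the family fits
iff p > 0.05.

Families: ER (uniform G(n, m)); SF-BA (preferential attachment,
m = round(E/n)); SF-GD (gene duplication: from a connected 2-node seed,
duplicate a uniform node, keep each parent edge with probability p_keep,
link child to parent with probability p_parent, default 1); GEO (random
geometric on the unit square, radius bisected to the edge target on the
realized point set); GEO-GD (geometric duplication: each new point is a
Gaussian perturbation, σ = 0.05, of a uniform existing point, then
radius-connected); STICKY (exactly E edges drawn with probability
proportional to the product of the endpoints' stickiness indices
θ_i = d_i/√Σd — drawn by Gumbel top-k so the edge target always holds
exactly, a conditional variant of the classical independent-Bernoulli
stickiness model). SF-GD's p_keep is tuned per instance by bisection,
using per-(child, neighbour) pre-drawn uniforms that make the edge count
an exactly monotone step function of p_keep for a fixed seed. Further
families can be registered in `MODEL_FAMILIES`.

**Known limitation.** The MWU compares 15 distances that all share the
one real network against 105 pairwise distances. When the "real" network
is itself an instance of the family, those 15 values are mutually
correlated through that instance's own atypicality, the MWU independence
assumption fails, and the p-value distribution is U-shaped rather than
uniform: the self-acceptance rate in the Monte-Carlo recovery experiment
is well below 1 − 0.05 (measured ≈ 55–80% at n = 500, 1000 edges, rather
than ≥ 95%). Discrimination in the other direction is unaffected —
mismatched families separate completely (p ≈ 4e−10). This is a property
of the fitting procedure itself, inherited by design; consumers should
read "fits" as "not distinguishable by this test", not as a calibrated
5%-level decision.

## Paralogs and triangles

Paralog candidates come from 12-column tabular alignment output
(query, subject, % identity, ..., E-value, bit score); a pair is kept if
identity ≥ 85%, E ≤ 0.001 and bit score ≥ 50, dropping self-hits and
deduplicating unordered pairs. The triangle co-occurrence test compares
c_uv(G2) — the number of triangles containing both genes, equal to the
number of shared neighbours of an adjacent pair — between the paralog
pairs present in the network and all remaining node pairs (a seeded
uniform subsample of 1e5 pairs when the background is larger), by a
one-sided MWU (paralogs > background). The all-pairs background is a
choice: it makes the null "a random pair of genes", dominated by
non-adjacent zero-count pairs, which matches the intuition that
duplication specifically creates shared neighbourhoods.

## Synthetic benchmarks

* `planted_module_fixture`: stochastic-block network, one annotation term
  per module. Defaults used by the recovery benchmark: 4 modules × 30
  nodes, p_in = 0.3, p_out = 0.01 — modular, sparse between modules,
  comfortably connected within. If the graph is disconnected the largest
  component is kept and the truth updated.
* `duplication_fixture`: SF-GD growth recording every (child, parent)
  duplication as a planted paralog pair (n − 2 pairs). The benchmark uses
  300 nodes, p_keep = 0.5, p_parent = 1.
* `scale_free_fixture`: preferential attachment with a λ = 3 tail.

All generators are pure functions of (parameters, seed). The fixtures
emulate modularity, duplication-induced triangles and scale-freeness, but
not other features of real molecular networks: no overlapping or
hierarchical annotation structure, no annotation noise, no degree-
dependent annotation bias, and much smaller sizes. Passing the recovery
benchmarks therefore shows the machinery is correct and sensitive under
its own assumptions, not that the biological conclusions transfer to any
particular real network.

## Problem sizes and determinism

The shipped experiments use: 50 random graphs of ≤ 12 nodes for the
counting oracle; 120-node module benchmarks for SAFE; n = 500 networks
with 1000 edges (mean degree 4, genetic-interaction-like sparsity), 15
instances per family and 20 repeats for model-fit recovery; 300-node
duplication networks for the paralog test; 1e4 samples for the exponent
fit. Every stochastic step takes an explicit integer seed and every
ranking breaks ties by node label, so all outputs — embeddings,
enrichment tables, reports — are byte-reproducible.
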