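# gracoal

Graphlet-based hyperbolic (disk) network embedding with SAFE functional
enrichment, graphlet-correlation model fitting and paralog-triangle
analysis — for systems biologists studying how function is organized in
genetic interaction and other scale-free molecular networks.

## What it does

Scale-free biological networks embed poorly with force-directed layouts:
hubs collapse into a "hairball". Coalescent-style embeddings avoid this by
mapping a network onto a disk whose circumference grows with radius —
angle encodes community, radius encodes topological importance. This
package implements the **graphlet coalescent (GraCoal) embedding**, which
generalizes that idea from plain edges to graphlets (the nine connected
induced subgraphs on 2–4 nodes, G0–G8). For a chosen graphlet Gi:

1. the network is embedded in 2D by spectral decomposition of the
   symmetrically normalized **graphlet adjacency**
   `A_Gi(u,v) = c_uv(Gi)/θ_Gi`, where `c_uv(Gi)` counts the occurrences of
   Gi touching nodes u and v simultaneously and `θ_Gi` is the graphlet
   size minus one (G0 gives back the ordinary adjacency matrix);
2. nodes are ranked by angle from the y-axis pole and placed
   equidistantly on the disk periphery;
3. node u gets radius `rad_u = ln(r_u)`, where `r_u` ranks nodes by how
   often they touch Gi.

On top of any such embedding the package runs the **SAFE** pipeline
(Spatial Analysis of Functional Enrichment): edges are weighted by
embedding distance, local neighbourhoods are cut at a shortest-path
threshold α tuned to a mean size of 50, each neighbourhood × annotation
is tested by an upper-tail hypergeometric test over annotated genes with
Benjamini–Hochberg correction per neighbourhood, and enriched terms are
clustered into functional domains by Jaccard overlap of their
neighbourhood sets. More enriched genes/terms ⇒ the embedding captures
more of the network's functional organization.

Two companion analyses probe *why* triangle-based embeddings work well in
duplication-rich genomes: a **model-fitting** test that compares a network
against random-graph families (including scale-free gene duplication,
SF-GD) via the graphlet correlation distance and a Mann–Whitney U test,
and a **paralog-triangle** test asking whether paralogous gene pairs
(alignment identity ≥ 85%, E ≤ 0.001, bit score ≥ 50) co-occur on more
triangles than other gene pairs.

Everything runs on synthetic or user-supplied networks: edge lists (TSV),
GMT annotations, BLAST outfmt-6 tables. All computations are exact or
seeded, and every output is byte-reproducible.

## Worked example

```python
from gracoal import (planted_module_fixture, gracoal_embed, run_safe,
                     enrichment_summary, build_domains)

fx = planted_module_fixture(n_modules=4, module_size=30,
                            p_in=0.3, p_out=0.01, seed=1)
emb = gracoal_embed(fx.network, graphlet_index=0)
res, nbhd = run_safe(fx.network, emb, fx.annotations, target_mean_size=50)
print(enrichment_summary(res, fx.annotations.restricted_to(fx.network.nodes)))
```

Output (see `examples/safe_enrichment.py` for the full script):

```
alpha = 5.901, mean neighbourhood size = 50.0
enriched genes: 120 / 120 (100.0%)
enriched terms: ['module_0', 'module_1', 'module_2', 'module_3']
```

The fixture plants four 30-gene modules with one annotation term each;
GraCoal on graphlet G0 separates the modules into four angular sectors
(`examples/embed_disk.py` prints the sectors), and SAFE recovers all four
planted terms and flags every annotated gene as enriched — the embedding
captured the planted functional organization completely.

Other example scripts, one per capability:

* `examples/graphlet_counts.py` — exact graphlet/orbit/pair counts on a toy.
* `examples/embed_disk.py` — the disk geometry of a modular network.
* `examples/safe_enrichment.py` — the enrichment pipeline above, plus domains.
* `examples/compare_embeddings.py` — GraCoal vs Graphlet Spectral vs
  GraSpring, per-graphlet and union rows.
* `examples/model_fitting.py` — which random-graph family fits a
  duplication-grown network (SF-GD fits, ER and preferential attachment
  are rejected at p ≈ 4e-10).
* `examples/paralog_triangles.py` — planted duplicate pairs touch a median
  of 10 triangles vs 0 for background pairs (one-sided MWU p ≈ 0).

A thin CLI wraps the same functions:

```sh
gracoal simulate --kind modules --seed 1 --nodes 120 --out fx/
gracoal embed --network fx/network.tsv --graphlet 0 --method gracoal --out emb.tsv
gracoal safe --network fx/network.tsv --embedding emb.tsv --gmt fx/annotations.gmt --out safe/
gracoal fit --network fx/network.tsv --family SF-GD --family ER --seed 7 --out fit.tsv
```

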