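# gecluster

Protein complex prediction from condition-specific protein–protein
interaction (PPI) networks, with GO-slim annotation weighting and
cross-condition complex-evolution analysis.

## The problem

Protein complexes appear as dense clusters in PPI networks, but a *static*
PPI network — the union of all interactions ever observed for an organism —
mixes proteins that are never expressed at the same time. Purely
topological clusterers therefore chase edges that cannot co-occur.
`gecluster` addresses this in three steps:

1. **Dynamic network.** Given a time-course expression matrix, a gene is
   *active* at a time point when its value reaches its own temporal mean:
   `val(g, t) ≥ Mean(g)` (inclusive, so flat constitutive profiles stay in).
   The dynamic network is the static network restricted to proteins active
   over a chosen time-point selection (`any` or `all` semantics), with
   isolated survivors dropped.
2. **Combined network.** Every protein pair sharing GO-slim terms gets an
   edge weighted by the number of shared terms `w(u,v) = |T(u) ∩ T(v)|`;
   original PPI edges are always kept (weight possibly 0) and annotation
   edges that were not PPI edges are counted as *added* edges.
3. **Seed-expansion clustering (GECluster).** Nodes are visited in
   non-increasing combined-degree order; each unassigned seed grows a
   cluster by admitting, one at a time, the combined-network neighbor that
   (a) has *strong functional similarity* — FS-Weight ≥ `fs_min` — with
   **every** current member, and (b) does not decrease the cluster density
   `2m / (n(n−1))`. FS-Weight between proteins *i*, *j* with closed
   neighborhoods `N_i`, `N_j` on the dynamic network is

   ```
   FS(i,j) =  2|N_i ∩ N_j| / (|N_i − N_j| + 2|N_i ∩ N_j| + λ_ij)
            · 2|N_i ∩ N_j| / (|N_j − N_i| + 2|N_i ∩ N_j| + λ_ji)

   λ_ij = max(0, N_avg − |N_i|),   N_avg = 2|E| / |V|
   ```

Predicted complexes are scored against a reference set with the matching
score `M_Score(A,B) = |V_A ∩ V_B|² / (|V_A|·|V_B|)`; pairs with
`M_Score ≥ M_thres` (default 0.2) match, giving complex-level
`Recall = N_mc/N_c`, `Precision = N_mp/N_p` and their harmonic mean F1.
The same matcher relates complexes *across* conditions (which complexes
persist from one ethanol stage of a fermentation to the next), and a
core/attachment census tracks how complex composition shifts.

The clusterer is exposed as a scikit-learn-style estimator
(`GECluster(fs_min=0.25, min_size=3).fit(combined, dynamic)` with
`complexes_`, `labels_`, `stats_` attributes); everything else is plain
functions over `networkx` graphs and `pandas` frames. A synthetic
benchmark generator plants ground-truth complexes with coherent expression
and annotations, so the whole pipeline is testable offline.

## Worked example

Generate a small benchmark (8 planted complexes, 80 background proteins,
10% edge/annotation noise) and run the full pipeline:

```sh
gecluster simulate --config sim.yaml --out-dir fixtures --seed 42
gecluster run-all --config run.yaml
```

with `run.yaml` pointing at the generated `edges.tsv`, `expression.tsv`,
`annotations.tsv` and `complexes.tsv` (see `gecluster run-all --help`).
The run prints, among other counts:

```
"dynamic":        105 nodes, 174 edges   (all generated proteins expressed somewhere)
"combined_edges": 266, "added_edge_count": 92
"n_complexes":    9
"evaluation":     {"recall": 0.875, "precision": 0.889, "f1": 0.882, "m_thres": 0.2}
```

Read: annotation sharing added 92 edges to the 174 PPI edges; seed
expansion emitted 9 complexes of which 8 matched a planted complex at
`M_Score ≥ 0.2`, recovering 7 of the 8 planted ones — F1 0.88 under 10%
noise. In the noiseless limit (`p_in: 1.0, p_out: 0.0, fidelity: 1.0`)
the recovery is exact (F1 = 1).

Other subcommands: `build-dynamic`, `build-combined`, `cluster` (with
`--fs-min-sweep START:STOP:STEP` for threshold curves), `evaluate`,
`stats`, `evolve`, `composition`.

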