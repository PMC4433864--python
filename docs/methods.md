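# Methods

## Model and procedure

The package predicts protein complexes in four stages, each a pure
function of its inputs (the only randomness in the package is the
synthetic generator's seed).

**Activity and the dynamic network.** For a gene *g* with expression
values over the time points of a series, `Mean(g)` is the arithmetic mean
over all time points and *g* is active at *t* iff `val(g,t) ≥ Mean(g)`.
The comparison is inclusive by design: a constant profile equals its own
mean everywhere, and excluding every flat housekeeping gene would be
biologically perverse. Replicates within a time point are collapsed
before the rule is applied (mean by default; `first` available). A
dynamic network for a time-point selection keeps a protein iff its gene is
active at **any** selected time point (`mode="any"`, the default) or at
**all** of them (`mode="all"`); both are exposed because the aggregation
rule over a multi-time-point condition is a genuine modelling choice, not
a derivable fact. Proteins absent from the expression file are treated as
never expressed; retained proteins left without any surviving edge are
dropped and counted in the provenance report.

**Combined network.** Annotation is taken as an opaque protein → GO-slim
term map; all three aspects (BP/MF/CC) contribute indiscriminately, and no
ontology traversal is performed (the input is assumed already slimmed).
Pair weights are term-set intersection sizes, accumulated per term so that
a pair sharing *k* terms yields one edge of weight *k*, never parallel
edges. PPI edges whose endpoints share no term are **kept at weight 0**:
the combined network is a weighted dynamic network plus added edges, never
a pruned one. Weight-0 edges participate in adjacency, candidacy and the
density's edge count *m*; they contribute 0 to weight-based candidate
ordering.

**FS-Weight.** Computed on the *dynamic* network's topology (not the
combined one), because its small-degree penalty is calibrated by the
average degree `N_avg = 2|E|/|V|` of the interaction network. Closed
neighborhoods are used (`N_i` includes *i* itself), which makes adjacent
proteins share at least the pair `{i, j}`. Both λ terms are clamped at 0,
the score is symmetric and lies in [0, 1], and non-adjacent pairs are
legal inputs — the clusterer scores every candidate against every current
member, most of which it is not adjacent to.

**Seed expansion.** Seeds are visited in non-increasing combined-network
degree (all edges, including annotation-added ones), ties broken
lexicographically. Expansion proceeds in rounds: candidates are the
combined-network neighbors of current members (minus assigned nodes unless
`overlap=True`), ranked by descending total edge weight to the members,
then descending FS-Weight to the seed, then lexicographically; the first
candidate passing both admission tests joins and the candidate list is
rebuilt, so a candidate rejected early may be admitted later once the
membership has changed. Admission requires strong similarity
(`FS ≥ fs_min`) with *every* member **and** a non-decreasing density,
where "decrease" means `new < old − 1e−12`. Expansion stops at the first
round with no admissible candidate.

A structural consequence worth stating: the first admission creates a
seed–neighbor pair of density 1 (candidates are always neighbors of a
member), and since 2m/(n(n−1)) may never decrease from 1, **every emitted
cluster is a clique of the combined network**. This is exactly where the
annotation edges earn their keep — a genuine complex whose interaction
record is incomplete still reaches clique density once shared GO-slim
terms fill in the unobserved pairs, while the FS test (measured on the
interaction topology) rejects spurious cliques formed by annotation alone.

Clusters below `min_size` (default 3, the usual benchmark filter) are
produced internally and discarded; their members are *not* marked
assigned and may join later clusters, but each node seeds at most one
expansion. With `overlap=False` (default) emitted clusters are pairwise
disjoint; with `overlap=True` assigned nodes may be re-admitted as
members, never as seeds.

**Evaluation.** `M_Score(A,B) = |V_A ∩ V_B|²/(|V_A|·|V_B|)`; a pair
matches at `M_Score ≥ M_thres`. `N_mc`/`N_mp` count distinct matched
reference/predicted complexes, not pairs. Recall, Precision and F1 follow;
empty denominators yield 0 with a warning rather than an error. When
benchmarking against a condition-specific network, the reference set is
first curated: each reference complex is intersected with the network's
nodes and dropped below `min_size`. Network statistics: the clustering
coefficient is the mean local clustering coefficient with degree-<2 nodes
contributing 0; the characteristic path length is the mean shortest-path
length over connected pairs; the diameter is the **maximum** shortest-path
length (the familiar reading — a published table reporting diameter 12
beside characteristic path length 4.2 is only consistent with the max).
Disconnected inputs are handled per component, with a component count
reported.

**Evolution.** Cross-condition complex relationships reuse the same
matcher and the same 0.2 threshold — no separate threshold is defined for
persistence, and reusing the evaluation machinery is the only internally
consistent choice. Core/attachment status is caller-supplied (an external
classification of subunits); no attempt is made to infer it from topology,
and no statistical test is attached to the census — raw counts only.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `fs_min` | 0.25 | strong-similarity threshold on FS-Weight (inclusive); complex-level F1 peaks near here on the training condition, and a sweep helper (`cluster --fs-min-sweep`) regenerates the curve |
| `min_size` | 3 | minimum emitted cluster size, matching the reference-set filter |
| `M_thres` | 0.2 | match threshold on M_Score, the conventional value in complex-level benchmarking |
| `mode` | `any` | activity aggregation over a time-point selection |
| `replicate_policy` | `mean` | replicate collapsing on read |
| `overlap` | off | whether assigned nodes may re-join later clusters |

## Synthetic benchmark

The generator plants `n_complexes` complexes (sizes uniform on
`size_range`) as `p_in`-dense subgraphs; all other pairs get edges with
probability `p_out` (`0 ≤ p_out < p_in ≤ 1`). Members share one private
GO-slim term carried with probability `fidelity`; each of the
`n_background` proteins carries one of `n_decoy_terms` decoy terms.
Expression is a two-level step function (`high=10`, `low=2`): a member's
gene sits at `high` during its complex's scheduled stages and `low`
otherwise, so the ≥-mean activity rule holds *exactly* during active
stages — a controlled mean relation is what the activity rule needs, and
realistic noise is an optional overlay (`noise_sigma`, which weakens the
guarantee). A `background_offstage_frac` fraction of background genes is
expressed only at the last stage, making early-stage dynamic filtering
genuinely informative; the rest get incoherent uniform expression.
Schedules (`active_stages`) let complexes appear and disappear across
stages to exercise the evolution analysis. Core/attachment rosters split
each complex's sorted members roughly in half. Defaults (20 complexes,
sizes 3–10, `p_in=0.9`, `p_out=0.01`, `fidelity=0.9`, 200 background, 3
stages, 1 replicate) are the package's standard study conditions.

What the generator does **not** emulate: scale-free degree structure of
real interactomes, correlated annotation between complexes, biological
replicate variance structure, or identifier formats of any real database.
Passing tests therefore demonstrate correctness of the algorithms under a
controlled planted model, not performance on real proteome-scale data.

## Numerical choices

- Density comparisons use an absolute tolerance of 1e−12; "does not
  decrease" means `new ≥ old − 1e−12`. FS-Weight carries no tolerance of
  its own (pure rational arithmetic in floats).
- The singleton cluster has no defined density; the first admission is
  gated by the FS test only.
- All orderings (seeds, candidates, file output) have total deterministic
  tie-breaks, so identical inputs produce byte-identical outputs.
- Degenerate inputs: an empty network clusters to an empty complex set
  (not an error); empty evaluation denominators give 0 with a warning;
  empty expression files, malformed lines, duplicate genes, negative
  values and blank cells are rejected on read (no imputation — the
  activity rule needs a value at every time point).

## Known limitations

- FS-Weight context construction is O(|V| + |E|) but the clusterer's
  all-members similarity check is quadratic in cluster size with caching;
  comfortable at the few-thousand-node scale of condition-specific
  networks, not tuned for full interactomes.
- The clique consequence of the density rule means very sparsely
  annotated regions of the network can only yield complexes that are
  cliques of PPI edges alone; recall there falls back to what topology
  supports.
- Gene and protein identifiers are assumed to live in one namespace; no
  mapping is attempted.
- Term weighting is a raw shared-term count: frequent shallow GO-slim
  terms count as much as specific ones (no information-content weighting,
  no term ancestry).
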