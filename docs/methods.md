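# Methods

`celltopics` clusters single-cell multi-omics count data by topic modeling on
a gene–cell multigraph. This note records the model, the numerical choices,
and what the synthetic benchmarks do and do not establish.

## The network view of a count matrix

A count matrix is read as a weighted bipartite multigraph: genes and cells
are nodes, and a count of `w` transcripts of gene `g` in cell `c` contributes
an edge of multiplicity `w` between them. With two omics layers (e.g. mRNA
and lncRNA counts over the same cells) the graph is tripartite: both gene
families attach to the shared cell nodes and there are never gene–gene or
cell–cell edges. By default edge weights are the raw integer counts of the
(optionally HVG-selected) genes; `round` and `floor` modes are available for
normalized matrices, since multigraph multiplicities must be integers.

Pre-processing follows the standard single-cell recipe: per-cell library-size
normalization to a fixed target sum, and highly-variable-gene selection by
binned normalized dispersion (variance/mean z-scored within equal-frequency
mean bins; genes above `min_disp` are kept, default 0.5, settable per layer
because the two RNA families differ in intrinsic variability).

## The model: typed degree-corrected SBM

Inference fits a degree-corrected stochastic block model whose blocks are
constrained to be homogeneous in node type: blocks of cells are **clusters**,
blocks of genes are **topics** (one topic family per layer). The fit
minimizes a description length `Σ = S + L` in nats.

`S` is the *exact* log-count of degree-corrected multigraphs with the
observed degrees and block edge counts:

```
S = Σ_r ln e_r!  −  Σ_{r<s} ln e_rs!  −  Σ_v ln k_v!  +  Σ_{i<j} ln A_ij!
```

where `e_rs` is the edge multiplicity between blocks r and s, `e_r = Σ_s
e_rs`, `k_v` a node degree, and `A_ij` an entry of the count matrix. We use
the exact factorial form rather than its Stirling approximation
(`−E − Σ_v ln k_v! − ½ Σ_rs e_rs ln(e_rs/(e_r e_s))`): the two agree for the
edge counts typical of real data, but the exact form is non-negative by
construction (it is the log of a count) and has no small-count artifacts —
a fully determined graph costs exactly 0 nats.

`L` encodes the model itself, with uniform (maximum-ignorance) priors:

* partition, per node type `t`: `ln N_t + ln C(N_t−1, B_t−1) + ln N_t! − Σ_r
  ln n_r!` (choose the block count, the block sizes as a composition, and the
  assignment);
* block edge matrix, per layer `l`: `ln C(B_cell·B_l + E_l − 1, E_l)`
  (distribute the layer's `E_l` edges over the allowed cell-block ×
  gene-block pairs);
* degrees, per block: `ln C(n_r + e_r − 1, e_r)` (distribute the block's
  stubs over its nodes).

These constants are documented here and in the code; their correctness is
enforced operationally, by tests that compare incrementally maintained `Σ`
against full recomputation (to 1e-9 after 1000 moves) and by exhaustive
enumeration of all typed partitions on graphs small enough to enumerate.

## Minimization

Moves are proposed with the neighbor-guided kernel: to move node `v`, sample
one of its incident edges, read the neighbor's block `t`, and propose target
block `s` (among the existing blocks of `v`'s own type plus one fresh empty
block, `B` candidates in total) with probability

```
Pr(r→s | t) = (e_ts + ε) / (e_t + ε B),        ε = 1 by default.
```

`e_t` is block `t`'s degree *restricted to edges toward `v`'s type*, which
makes the kernel sum to one over the candidates; for a cell move this equals
the full block degree, and it is why a multipartite move conditions on a
single layer at a time — the normalization of the other layer never enters.
When block `t` has no edges toward `v`'s type the kernel degenerates to the
uniform `1/B`. Proposals are accepted by Metropolis–Hastings on `ΔΣ` with
the forward/reverse proposal ratio. (Some descriptions of this sampler
present the kernel itself as the acceptance probability; used that way it
cannot minimize `Σ`, so it is implemented here — as in the framework it
derives from — as the proposal distribution.)

Single-node moves alone cannot cross the barrier between two well-formed
blocks that ought to be one, so greedy descent alternates node sweeps with
**agglomerative merge passes**: all same-type block pairs are scanned (a
connectivity-guided subset above 10,000 pairs) and the best merge is applied
while it lowers `Σ`. A fit runs, per initialization: greedy descent to a
local minimum, `explore_sweeps` (default 60; 500 on graphs of ≤16 nodes)
finite-temperature sweeps at `beta` (default 1) tracking the best state
visited, then a final greedy polish. `n_init` independent restarts (default
7, the cost/quality elbow in the study this package models) are run from
random typed partitions; the restart with minimal final `Σ` wins.

Convergence: a phase stops when no sweep improves `Σ` by more than `tol`
(1e-6 nats) for `patience` (10) consecutive sweeps, with a hard cap of 1000
sweeps. Seeding: restart `i` uses seed `(seed + i) mod 2^31`; fits are
bit-reproducible for a fixed master seed.

The hierarchy is agglomerative: the winning partition's block multigraph
(blocks as nodes, `e_rs` as multiplicities) is itself fitted, recursively,
until one block per type remains; each level is therefore an exact coarsening
of the level below. The hierarchy is built only for the winning restart. If
a recursion step achieves no coarsening, the trivial one-block-per-type top
level is appended and recursion stops. Level 0 is the flat description-length
optimum; unlike a full nested-prior fit it does not necessarily contain
hundreds of micro-clusters at the bottom.

## Topics, clusters and probability tables

For any level, with `k_g` the degree of gene `g` and `e_T` the total
multiplicity incident to topic `T`:

* `P(g | T) = k_g / e_T` for `g ∈ T`, zero elsewhere (hard membership);
* `P(T | c) = e(c, T) / k_c^(layer)`, the fraction of cell `c`'s edges in
  that layer that run into `T`'s genes. Rows sum to one per layer; cells
  with zero degree in a layer get a zero row and are flagged, not
  renormalized.

A published description of the second ratio inverts numerator and
denominator; as printed it would not normalize, so the normalizing direction
is implemented.

## Topic-to-cluster assignment

Raw `P(T|c)` is dominated by large generic topics, so it is centered:
`Pc(T|c) = P(T|c) − mean_c' P(T|c')`. Cluster-level values are means over
member cells, and cluster `K` receives every topic with `Pc(T|K) > μ_K +
n·σ_K`, where `μ_K`, `σ_K` are the mean and **population** (divide-by-N)
standard deviation of `Pc(·|K)` across topics (population vs sample is not
specified in the source; divide-by-N is the simpler convention and the
worked examples fix it). The multiplier `n` starts at 3 and decreases in
exact decimal steps of 0.05 (computed as integers over 100, so the grid
never drifts) until (i) every cluster has at least one topic and (ii) no two
clusters have identical topic sets — subsets allowed. Lowering `n` only
loosens thresholds, so topic sets grow monotonically and the first feasible
grid value is optimal. If the conditions still fail at `n = 0` (e.g. two
clusters with identical centered profiles) the operation raises an error
naming the offending clusters rather than guessing an assignment. In
tripartite fits the two layers' topics are pooled column-wise and `μ`, `σ`
are computed across the pooled topics. The same operation applies to any
cell partition, not only fitted clusters.

## Evaluation: NMI, NMI*, AMI

NMI is mutual information normalized by the arithmetic mean of the label
entropies (the normalization is not pinned down by the source; geometric,
min and max are exposed as options). NMI grows with cluster count even for
meaningless partitions, so scores are reported relative to **NMI***: the
mean NMI of `n_shuffles` (default 100) random permutations of the predicted
labels — a null that preserves the number and sizes of clusters. NMI := 0
when either partition has a single cluster, which keeps NMI* finite.
NMI/NMI* ≈ 1 flags a clustering no better than chance. AMI (expected mutual
information under the permutation model, computed exactly from the
hypergeometric law of each contingency cell) compares two clusterings when
neither is ground truth; it is cross-checked against scikit-learn to 1e-9
but implemented independently.

Because NMI* shrinks faster than NMI as partitions coarsen, NMI/NMI* of
fits with very different cluster counts are not comparable; benchmark
comparisons in the test suite therefore score each fit at its hierarchy
level whose cluster count is closest to the planted number of groups.

## Enrichment

Topics are tested against GMT gene-set collections by upper-tail
hypergeometric probabilities, with the universe taken as the analyzed
feature list of the relevant layer (the original analysis does not state its
universe; the feature list is the defensible default since only those genes
could have entered a topic). Before testing, each collection is pruned of
sets larger than 15% of the collection's distinct genes — a fast
approximation of Jaccard-redundancy pruning that removes the huge unspecific
sets which otherwise dominate the test. p-values are BH-adjusted within each
topic's family of tests. Each topic is then labeled with its most enriched
set under a global greedy rule in q order: a set may label only the topic
where it is most significant, other topics fall back to their next-best set;
ties break by larger overlap, then set name, then topic name, making the
summary deterministic. Topics with nothing under the FDR threshold (default
0.05) are labeled `unannotated`.

## Synthetic data

The generator emulates a four-population breast-cancer PDX design — two
subtypes, each with a drug-sensitive and a drug-resistant population —
profiled in two layers over the same cells. Genes are partitioned into
topics (contiguous blocks, Dirichlet(1) within-topic profiles); each
population mixes topics according to an affinity row; counts are multinomial
at a per-cell depth drawn uniformly from `depth_range`. Layer 2 is
overdispersed by per-cell, per-gene gamma multipliers with mean 1 and
variance `dispersion` (default layer dispersions 0.0 and 0.4), which
reproduces the empirically higher coefficient of variation of lncRNAs.

Defaults (the "stated world"): 4 × 50 cells, 200 + 150 genes, 4 topics per
layer, depths 800–1200. Layer-1 affinities separate the subtypes strongly
(6 vs 0.3) and the resistance axis weakly (1.2 vs 0.3–0.5); layer-2
affinities separate resistance strongly within the luminal-like subtype
(6 vs 0.3) and weakly in the basal-like one. With these defaults a
tripartite fit recovers the subtype split at the coarsest informative level
and the four populations near the 4-cluster level with NMI/NMI* far above 1.

`complementary_spec()` is a scaled-down preset (4 × 30 cells, 60 + 60 genes,
depths 400–600, dispersions 0.15/0.25) whose two population axes are fully
crossed over the layers: layer 1 carries only the subtype axis, layer 2 only
the resistance axis. Neither layer alone can resolve the four populations;
the tripartite fit can, which is the cleanest operationalization of
"complementary information" and what the multi-omics benchmark uses.

What a green synthetic benchmark does **not** establish: the generator has
no ambient RNA, doublets, batch effects, or realistic gene-gene correlation
beyond topic structure, and its multinomial/gamma-multinomial noise is
tamer than real droplet data. Recovery on it validates the inference
machinery, not performance on any real dataset.

`planted_partition_layer` provides the classical Poisson planted-partition
benchmark (aligned cell/gene blocks at `rate_in`, default 5.0, vs background
`rate_out`, default 0.5 — a 10× signal) used for the recovery tests.

## Scaling choices in the test suite

The heavy benchmarks run with `n_init = 2` (instead of the default 7) and,
for the complementarity benchmark, with 120 cells and 60 genes per layer, so
the whole suite fits a single-CPU budget; the planted signals are strong
enough that extra restarts do not change the outcome. The thresholds
themselves (NMI ≥ 0.9 in ≥ 90% of seeds; tripartite median NMI/NMI* ≥ each
single layer's median over 20 seeds) are asserted unchanged.

## Known limitations

* Level-0 granularity follows the flat description-length optimum, not a
  nested-prior fit; very fine micro-cluster levels seen in nested fits are
  not reproduced.
* The MCMC is asymptotically correct but the fit is a point estimate (best
  of `n_init` restarts); no posterior uncertainty over partitions is
  reported.
* Hard cluster/topic membership only; no overlapping or mixed-membership
  blocks.
* `graph-tool`-style nested-model constants differ from ours by
  partition-independent offsets; absolute `Σ` values are not comparable
  across implementations, only differences within one fit.
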