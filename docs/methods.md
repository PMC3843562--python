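# Methods

## Network model

A regulatory network is a simple directed graph over typed vertices
(TF, miRNA, non-TF gene). The allowed regulator→target pairs are
TF→{TF, non-TF, miRNA} and miRNA→{TF, non-TF}: TFs act
transcriptionally on any gene including miRNA genes, miRNAs act
post-transcriptionally on protein-coding transcripts, and miRNA→miRNA
regulation does not exist in this model. Self-loops (autoregulation)
are excluded because the centrality definitions below do not address
them; duplicate edges are rejected at load time. A gene annotated both
housekeeping and tissue-specific is rejected rather than silently
resolved, and miRNAs are never housekeeping.

Gene classes are *tissue-relative*: when classifying the nodes of a
tissue network, a gene specific to a different tissue counts as
trivial there. TS annotations may name several tissues for any node
type (the data model does not force single-tissue specificity;
classification only asks whether the current tissue is named).

**Tissue extraction.** The network of a tissue is the induced subgraph
over nodes whose expression profile names that tissue. Expression is
binary presence — no abundance thresholding. Nodes isolated after
induction are retained: they are expressed genes with no surviving
regulation, and removing them would bias the composition of random
background sets drawn from the tissue network.

## Centralities

* **In-/out-degree**: edge counts per direction.
* **Betweenness**: directed shortest-path betweenness with endpoint
  exclusion, normalized by (n−1)(n−2) so values lie in [0, 1]; vertex
  pairs with no connecting path contribute nothing. The unnormalized
  pair-sum is also exposed. Computed with networkx's Brandes
  implementation and cross-checked in the test suite against an
  independent per-pair BFS path-counting oracle.
* **Cluster coefficient**: the neighborhood of v is the union of its
  in- and out-neighbors; CC(v) is the fraction of unordered neighbor
  pairs joined by an edge in either direction, 0 when v has fewer
  than two neighbors. The undirected reading is deliberate: the
  mixed-direction neighborhoods around miRNAs (miRNA→target together
  with TF→miRNA) only close into triangles when direction is ignored,
  and that triangle structure is exactly the miRNA–TF co-regulation
  signal the cluster coefficient is meant to capture. Downstream
  conclusions are rank-based (resampling on means), so they are
  unchanged by any monotone rescaling of either convention.
* **Characteristic path length**: mean directed shortest-path length
  over reachable ordered pairs only; infinite distances are dropped
  because tissue networks are far from strongly connected. A network
  with no reachable pair reports NaN, not 0.

## Target Compact Rate

For a miRNA set with N_mir ≥ 2 members, mean out-degree ⟨K_out⟩ and
mean target number ⟨N_targ⟩ = (distinct targets of the union)/N_mir:

    TCR = (⟨N_targ⟩/⟨K_out⟩ − 1/N_mir) / (1 − 1/N_mir)

⟨N_targ⟩ is the union count divided by N_mir — not the mean of
per-miRNA target counts — because only that reading produces the two
boundary identities exactly: disjoint target sets give
⟨N_targ⟩ = ⟨K_out⟩ and TCR = 1, while identical target sets of any
size give ⟨N_targ⟩/⟨K_out⟩ = 1/N_mir and TCR = 0. Members with
out-degree 0 are rejected (the ratio is undefined for them); the
pipeline therefore excludes miRNAs that lose all targets under tissue
induction from that tissue's TCR set and records the exclusion in the
run manifest.

## Resampling test for topological bias

Given a centrality table, a small set and a disjoint background, the
observed statistic is the small set's mean. The null consists of 2000
(configurable) means of uniform without-replacement samples of the
small set's size drawn from the background, independently across
resamples. Both one-sided P-values use the add-one estimator
(r+1)/(R+1) with ties counted ≥ (resp. ≤), so P ≥ 1/(R+1) and a finite
resample never reports P = 0. A one-sided P < α (default 0.10)
declares the direction HIGHER or LOWER.

Two estimator conventions worth stating:

* An *exhaustive* mode enumerates every background subset instead of
  resampling and applies the same add-one convention with the number
  of enumerated sets as denominator. Because add-one smoothing depends
  on that denominator, exhaustive and Monte-Carlo P-values are
  compared in the tests on the de-smoothed tail proportions
  (#{null ≥ observed}/R), which is the quantity both estimate.
* Sampling the null from the background alone (rather than the pooled
  small set + background) is the procedure implemented; it is
  calibrated only when the background is much larger than the small
  set. When the two are comparable in size, the finite-population
  factor (N−k)/(N−1) under-disperses the null and inflates the
  declared-significance rate — with k = 8 against N = 24 the
  either-direction rate at α = 0.10 roughly doubles. The analyses this
  package is designed for have small focal classes against large
  trivial backgrounds, where the effect is negligible; users pairing
  similarly sized sets should read the P-values as approximate.

No multiple-testing correction is applied across the tissue × class ×
parameter grid; cells are reported individually with both one-sided
P-values, and the significance matrix marks only the significant
direction.

Fisher exact tests (neighbor enrichment, class association) are
two-sided by default, with sidedness exposed as an option; a
degenerate margin (all or no nodes in the class) reports P = 1 with
the odds ratio flagged undefined. The enrichment default level is
0.05, the resampling level 0.10.

## Synthetic-network generator

The generator emulates the study conditions the statistics are meant
to detect, not any particular organism's genome:

* **Sizes and classes** (defaults): 80 TFs, 400 non-TF genes, 60
  miRNAs over seven tissues (brain, heart, kidney, liver, ovary,
  spleen, testis); 20% of genes TS, 20% HK (none for miRNAs), disease
  labels Bernoulli(0.3) independent of the other classes — matching
  the observed absence of disease/TS association.
* **Expression**: HK genes in all tissues, TS genes in exactly their
  one tissue, trivial genes in a uniform random nonempty tissue
  subset.
* **Degrees**: out-degrees are drawn per regulator from a
  mean-parameterized count distribution, by default a negative
  binomial with dispersion 2 (variance μ + μ²/2) to mimic the
  heavy-tailed degree skew of regulatory networks; Poisson and
  constant alternatives are exposed. TS TFs get their mean raised by
  `ts_tf_degree_boost` (default +3). TF targets are sampled uniformly
  from all other nodes, which also gives miRNAs nonzero in-degree and
  enables the miRNA–TF triangle structure discussed above. miRNA
  out-degrees have a floor of 1.
* **Planted TCR contrast**: each TS miRNA owns a private pool of
  non-TF genes; each target slot is private with probability equal to
  `ts_mirna_target_disjointness`, otherwise drawn from the single
  shared pool that all trivial miRNAs use. Disjointness 1 forces
  TCR = 1 exactly. Trivial miRNAs sample min(k, pool size) targets
  from the shared pool; with the constant degree distribution at mean
  equal to the pool size every trivial miRNA regulates the full pool
  and the trivial TCR is exactly 0. The per-slot uniforms and target
  permutations are drawn identically for every disjointness value
  (common random numbers), making the realized TCR nondecreasing in
  the knob for a fixed seed — a deterministic property the tests
  exploit.
* **Reproducibility**: all randomness flows from one seed through
  spawned child streams per component; regeneration is
  byte-identical.

What the generator does **not** emulate: correlated expression across
tissues, degree–class correlations beyond the planted ones, the
empirical sizes of curated gene lists, or the bow-tie/hierarchical
global structure of real transcriptional networks. Passing tests
therefore demonstrate that the statistics recover effects of the
planted kind at realistic sizes — not that any particular biological
claim holds in real data.

## Pipeline and reporting

Per tissue: extract the network, classify nodes, compute centralities,
run the resampling comparison for each configured (small, background,
parameter) cell — TS vs trivial, HK vs trivial, TS vs HK, disease vs
non-disease, for TFs and miRNAs — plus TCR and connected-TF means for
the miRNA classes, neighbor enrichments, class associations and global
statistics. Each cell's resampling seed derives deterministically from
the run seed and the cell index and is recorded in the manifest, so
any single cell is independently re-derivable. A failure in one tissue
is logged and isolated; other tissues proceed. Output TSVs are sorted
and written with fixed float formatting, so identical config + seed
reproduces identical bytes.

## Problem sizes in the test suite

Oracle-equivalence tests run on networks of ≤ 12 nodes (100 random
instances) and 200 random miRNA/target configurations; calibration
uses 200 generator replicates at ~286 nodes with 2000 resamples per
cell; planted-effect recovery uses 50 replicates at 440 TFs. These
sizes keep the full suite in the low minutes on one CPU while leaving
the statistical checks well-powered.
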