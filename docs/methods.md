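# Methods

This note documents the statistical procedures `dgnet` implements, the
choices made where a convention had to be fixed, and what the synthetic
data generator does and does not emulate.

## Network model

The interactome is a simple undirected, unweighted graph over gene
identifiers.  Identifiers are opaque strings upper-cased at ingest; no
alias resolution is attempted, since symbol mapping belongs upstream of
any network analysis.  Self-loops are dropped and duplicate edges
collapsed at read time, with counts reported, so that Σk_i = 2|E| holds
for every graph the package constructs.  Distances are hop counts
(0 for self).  Unreachable node pairs are *excluded from* — not counted
as infinite in — every average over distances, and each statistic
reports how many pairs were excluded; on the connected synthetic
fixtures the exclusion count is zero.

## Topology statistics

For a gene set S mapped onto network G:

* degree k(g): number of interaction partners;
* characteristic shortest-path distance: mean hops from g to every
  other reachable node of G (distances between two members of S are
  included — the quantity describes g against the whole network);
* global centrality: mean hops from g to the other reachable members of
  S, with paths free to traverse non-members;
* hub fraction: share of S with k ≥ cutoff.

The hub cutoff is the degree at which the distribution's upper tail
"straightens out".  That visual criterion is operationalized as a
tail-fraction rule: the smallest degree d whose upper-tail node share
first drops to ≤ 0.21 (default chosen to reproduce the conventional
~20% hub share in interactome studies; on the default fixture the rule
yields a 0.1997 hub share).  A manual cutoff override is always
available and is the recommended mode for replication work, since any
automatic rule on a discrete distribution is a convention.  Hubs are
*non-strict* (k ≥ cutoff), so the cutoff degree itself counts as a hub.
The rule requires ≥ 3 distinct degree values and refuses degenerate
(regular) graphs.

Bulk shortest-path computation goes through `scipy.sparse.csgraph`
(breadth-first search in compiled code, chunked at 512 sources), which
keeps whole-interactome summaries at 10⁴ nodes in seconds.

### Resampling significance

The empirical p-value of a set statistic draws `n_reps` node sets of
the same size uniformly *without replacement from all network nodes* —
not from any annotation-matched background — recomputes the statistic,
and counts draws **strictly** more extreme in the stated direction.
Strictness makes p = 0 attainable and means ties never count as
evidence against the observation; with matched G(n, m) nulls it also
makes the average-degree metric degenerate (every null has the same
mean degree), which the null-model report flags rather than hides.
Default `n_reps` = 1000, following the resolution at which empirical
p-values of ~0.001 are meaningful.  Drawing the observed set itself
uniformly yields empirical p-values that are uniform on [0, 1] (mean
0.499 over 200 experiments on the default fixture) — the calibration
the test suite enforces.

Between-set rank comparisons use the Wilcoxon rank-sum test: exact null
distribution when the combined sample is ≤ 20 without ties, otherwise
the tie-corrected normal approximation; the method used is recorded in
the result.

## Steiner subnetwork extraction

The disease subnetwork spans the mapped disease genes (terminals) with
the classic metric-closure heuristic, a 2-approximation of the optimal
Steiner tree per connected component: (1) complete graph on terminals
weighted by pairwise hop distance; (2) Kruskal MST with ties broken by
lexicographic edge label; (3) each closure edge expanded to the
lexicographically smallest shortest path; (4) union of paths; (5)
iterative pruning of non-terminal leaves.  Components containing a
single terminal contribute it to `terminals_unreachable` rather than a
singleton subnetwork.  Measured against a brute-force optimum on 200
random graphs (≤ 12 nodes, ≤ 6 terminals) the heuristic's worst
observed ratio is 1.33.

Edge induction is ON by default: the final subnetwork is the induced
subgraph of the interactome on the tree's node set.  A bare tree is
nearly cycle-free by construction and would make downstream clustering
and community analysis vacuous; the induced subnetwork restores the
interaction density around the tree (on the default fixture: 251 nodes,
523 edges from a 250-edge tree).  `include_induced_edges=False` returns
the tree itself.

All tie-breaks being lexicographic makes extraction bit-reproducible
across runs and platforms — a deliberate trade: the reported subnetwork
is *one canonical member* of the family of equally good solutions, not
a unique optimum.

### Null model

Non-randomness is tested against Erdős–Rényi G(n, m) graphs matched on
node and edge counts, sampled uniformly (edges drawn without
replacement from all node pairs).  Metrics: average degree (degenerate,
see above), average shortest-path distance over reachable pairs
(reported two-sided via both tail counts, p = min(1, 2·min(tails)/reps)),
and average clustering coefficient (upper tail).  A degree-preserving
switching null is deliberately out of scope; G(n, m) answers the
question "is this structure explained by size and density alone".

## k-clique percolation

Cliques are of fixed size k (a larger complete subgraph contributes all
its k-subsets); two k-cliques are adjacent iff they share exactly k−1
nodes; communities are node unions of connected components of that
relation, sorted by size then smallest member.  Enumeration walks the
maximal cliques and expands k-subsets, with union-find over shared
(k−1)-subsets; it refuses (with guidance) beyond a configurable budget
of 10⁶ k-cliques rather than running unbounded on pathological inputs.
The implementation is checked for exact agreement against a naive
k-subset enumeration oracle and against networkx's percolation
routine.  When counting "nodes forming communities" the union of
community members is used; overlapping membership is not
double-counted.

The membership fraction of a gene set divides by the set's members
*present in the analyzed network* (typically the extracted subnetwork),
so sets that barely map in are not silently diluted.

## Pathway enrichment and crosstalk

Enrichment: one-sided Fisher exact test of the 2×2 table (overlap,
pathway-only, disease-only, neither) against a background defaulting to
the union of all pathway genes and all interactome nodes (a canonical
proprietary background not being available, the most inclusive
observable universe is used).  The filter is score > 2 **and**
overlap > 5, where score = −log₁₀ p; the score threshold of 2 is
equivalent to p < 0.01.

Crosstalk for each unordered pair of filtered pathways builds the table
(n, N−n, r, R−r): n = shared genes, N = *sum* of the two pathway sizes
(shared genes counted twice, following the "total nodes of the two
tested pathways" convention; a union-based N is available behind a
flag), and r, R = across-all-pairs averages of n and N.  Self-pairs are
excluded from the averages.  Because Fisher's test needs integer
counts, r and R are rounded half-up for the test; the unrounded values
are retained in the output.  The identical construction applies to
links, where a pathway's link set is every interactome edge with both
endpoints inside the pathway (no requirement that the edge be annotated
to the pathway — a PPI-based reading).  BH-FDR is applied separately to
the node and link p-vectors; a pair is significant when
min(p_nodes, p_links) < 0.01 on the raw p-values, with the adjusted
q-values reported alongside.  At least 3 pathways are required, since r
and R are meaningless for a single pair.

## GWAS prioritization

Inputs are two tables of one smallest association p-value per gene,
p ∈ (0, 1].  Joint-significant genes have p < α (default 0.05) in both
studies; genes missing from either study are excluded everywhere,
including from the randomization universe.  "Not less than" in the
randomization is implemented as ≥.  The randomization draws `n_sets`
(default 1000) uniform subsets of the subnetwork's size from the shared
universe and reports the fraction with joint count ≥ observed, repeated
`n_repeats` (default 10) times under derived seeds.  Candidates are
joint-significant subnetwork genes outside the seed list; each gets an
ego subnetwork of its seed / joint-significant neighbors.  The
pathway-guided route extracts a Steiner subnetwork over a pathway's
genes and ranks non-seed nodes by their degree inside it (descending,
lexicographic tie-break) — the high-degree connector is the positional
candidate.

Gene-level smallest p-values are biased toward long genes (more
markers, more chances at a small minimum).  No correction is applied —
the statistic is consumed as published — but every prioritization
result carries a caveat field, and the generator can induce
length-correlated p-values so users can measure the bias's impact.

## Synthetic data generator

The generator is the package's test bed and demonstration input.  What
it emulates, per artifact:

* **Interactome** — growth by preferential attachment from a seed
  clique of m nodes (m = `attachment_edges`, default 3), each new node
  attaching to m distinct degree-weighted targets; after each
  attachment a triangle is closed among the new node's neighbors with
  probability `triangle_closure_prob` (default 0.25).  Defaults give
  ~10⁴ nodes, mean degree ≈ 7, a heavy right tail (max degree > 70×
  the median), clustering ≈ 0.12, connected by construction.  Chosen
  over configuration-model alternatives because the pipeline needs
  *tunable clustering* with guaranteed connectivity.
* **Gene sets** — degree^exponent-weighted samples.  The shipped
  contrasts: cancer-like (300 genes, exponent 2.0, clique planting),
  essential-like (1000, 1.5), disease-like (160, 0.7), neuro-like
  (300, 0.3), nde-like (500, −0.5).  Sizes follow the conventional
  scale of curated disease/essential/control lists; exponents were
  fixed once to separate the sets' mean degrees in the canonical order
  with margin at the default sizes.  Clique planting grows half the set
  inside 2-hop neighborhoods of chosen members, giving the internal
  clustering real cancer-gene modules show.
* **Pathways** — breadth-first balls around random centers (internal
  links guaranteed), 12 pathways of 30–60 genes; three pairs carry
  planted Jaccard overlaps (0.4, 0.35, 0.3) and all other pairs are
  disjoint by construction; six pathways draw 25% of their members from
  the disease set so enrichment exists to find.
* **GWAS** — null genes p ~ Uniform(0, 1], signal genes
  p ~ Beta(a, 1) with a = 0.1, so P(p < t) = tᵃ (≈ 0.74 at t = 0.05);
  two studies are independent given their distinct derived seeds.  In
  the pipeline the signal set is the extracted subnetwork's node set.

Every artifact is a pure function of the configuration, including its
master seed; sub-seeds derive from fixed `SeedSequence` spawn keys (one
stream id per artifact), so adding a generator call never perturbs
earlier draws.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: literature/ascertainment bias
(well-studied genes have inflated degree), false interactions and
missing edges, the exact degree sequence of any real interactome,
linkage disequilibrium between nearby genes' GWAS p-values, gene-length
artifacts (unless explicitly induced), and overlapping pathway
hierarchies deeper than pairwise Jaccard.  Conclusions about method
*calibration* (uniform p under the null, exact oracle agreement)
transfer to real data; conclusions about *power* are specific to the
planted effect sizes.

## Problem sizes and numerical conventions

The default analysis scale — 10⁴-node interactome, 1000-draw resampling
and null-model tests, 1000-set × 10-repeat GWAS randomization, k = 3…7
— was chosen so the full pipeline completes in well under a minute on a
single CPU while every empirical p retains 10⁻³ resolution; all of it
scales up by configuration.  Other conventions: empirical p-values use
strict comparisons; Fisher tables arising from averages are rounded
half-up; JSON reports are written with sorted keys and GraphML with
sorted node/edge insertion so reruns are byte-identical; the clique
budget guards enumeration; errors name the offending input (file, line,
stage) rather than failing deep in a library.

## Known limitations

Identifier normalization is purely syntactic (upper-casing); the
Steiner result is one canonical optimum among ties; only Erdős–Rényi
nulls are provided for subnetwork non-randomness; crosstalk inherits
the arbitrariness of the pair-average contingency construction (the
test is a screening heuristic, not a calibrated model); and the
enrichment background matters — with a different background the same
overlap can change significance class.
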