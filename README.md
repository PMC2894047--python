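# dgnet — disease-gene network and pathway analysis

`dgnet` characterizes how a set of disease candidate genes sits inside a
protein–protein interaction network (an *interactome*), and uses that
structure — together with pathway annotations and gene-level GWAS
p-values — to nominate new candidate genes.  It implements the classic
systems-genetics workflow used for complex disorders such as
schizophrenia, where many genes of small effect are expected to organize
into networks and pathways rather than act alone.

## What it computes

**Topology statistics with resampling nulls.** For a gene set mapped onto
the interactome: per-gene degree *k*; the *characteristic shortest-path
distance* (mean hop count from a gene to every other reachable node);
*global centrality* (mean hop count to the other set members, paths free
to traverse non-members); and the hub fraction at a degree cutoff taken
from the upper tail of the degree distribution.  Significance of a
set-level statistic is an empirical p-value: draw N random gene sets of
the same size uniformly from the network, and report
p = #{draws strictly more extreme} / N.  Between-set comparisons use the
Wilcoxon rank-sum test.

**Disease subnetwork extraction.** An approximate Steiner minimal tree
spans the disease genes: build the metric closure over the terminals
(pairwise hop distances), take its minimum spanning tree, expand closure
edges back into shortest paths, prune non-terminal leaves, and (by
default) restore all interactome edges among the retained nodes.  All
tie-breaks are lexicographic, so the result is bit-reproducible.
Non-randomness of the extracted subnetwork is tested against Erdős–Rényi
G(n, m) graphs matched on node and edge counts (average degree, average
shortest-path distance, average clustering coefficient).

**k-clique percolation communities.** A community is the union of
k-cliques connected through k-cliques sharing exactly k−1 nodes.  The
fraction of a gene set inside communities, tracked over k = 3…7,
measures whether the set occupies the densely interlocked core of the
subnetwork or its periphery.

**Pathway enrichment and crosstalk.** Enrichment of the disease set in
each pathway is a one-sided Fisher exact test; a pathway passes when its
score −log₁₀ p exceeds 2 and it contains more than 5 disease genes.  For
every pair of enriched pathways, crosstalk asks whether they share more
genes (or more interactome edges) than the average pair, via a Fisher
test on the 2×2 table (n, N−n, r, R−r), with Benjamini–Hochberg FDR per
statistic and a smaller-p rule at 0.01.

**GWAS-based prioritization.** Genes of the subnetwork with association
p < 0.05 in *both* of two independent GWAS are "joint-significant";
those outside the original disease list become novel candidates, each
with an ego subnetwork of its seed/significant neighbors.  Whether the
subnetwork carries more joint signal than chance is tested by drawing
1,000 equal-sized gene sets from the universe of genes shared by both
studies, repeated 10 times.

**Synthetic data.** A seeded generator produces scale-free interactomes
(preferential attachment with tunable triangle closure), gene sets with
controllable degree bias and clustering, overlap-controlled pathway
collections, and GWAS tables that are Uniform(0, 1) under the null with
a Beta(a, 1) planted signal — so the whole pipeline is testable without
any downloads.

## Worked example

```python
from dgnet import RunConfig, run_pipeline, default_config

cfg = RunConfig(outdir="demo", master_seed=1, synthetic=default_config(1))
report = run_pipeline(cfg)

topo = report["stages"]["topology"]["sets"]
for name in ("cancer-like", "essential-like", "disease-like", "neuro-like", "nde-like"):
    s = topo[name]
    print(f"{name:15s} mean degree {s['average_degree']:6.2f}  empirical p {s['degree_empirical_p']:.3f}")
```

prints

```
cancer-like     mean degree  49.05  empirical p 0.000
essential-like  mean degree  22.31  empirical p 0.000
disease-like    mean degree  14.18  empirical p 0.000
neuro-like      mean degree  10.56  empirical p 0.000
nde-like        mean degree   4.84  empirical p 1.000
```

The five synthetic sets reproduce the canonical ordering: hub-rich
cancer-like genes are the most connected, the disease set sits in the
middle, and the neutral set is so peripheral that *every* random draw
beats it (p = 1).  Continuing with the same report:

```
subnetwork: 251 nodes / 523 edges; clustering empirical p = 0.0
joint-significant genes: 135, novel candidates: 56,
randomization p per repeat: [0.0, 0.0, ..., 0.0]
```

The extracted disease subnetwork clusters far more than any of 1,000
matched random graphs (empirical p = 0), and carries far more joint GWAS
signal than any of 1,000 random gene sets in each of 10 repeats.

Every stage also writes TSV/GraphML artifacts plus `report.json` under
the output directory; reruns with the same seed are byte-identical.

The same workflow is available from the shell:

```sh
dgnet simulate --seed 1 --outdir fixture/
dgnet subnet --network fixture/interactome.edges.tsv \
             --terminals fixture/disease-like.genes.txt --outdir subnet/
dgnet pipeline --config run.json
```

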