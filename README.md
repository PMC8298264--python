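# regulomeshift

Network analysis of how a transcription cofactor's knockdown reshapes a
cell's regulome. Given expression profiles of wildtype (WT) and knockdown
(KO) cells plus gene → biological-process (GO:BP) annotations, the package
builds one weighted bipartite gene → process network per condition,
measures each gene's importance by eigenvector centrality, and classifies
genes by how their importance shifts after the knockdown. It was built for
systems-biology analyses of cofactors that act through interacting
proteins — where the interesting genes are the ones that *take over*
network importance when the cofactor is removed ("functional complements")
— but the stages are general.

## The method

For each condition, every annotated gene becomes a source node connected
to the processes it participates in; the edge weight is the gene's
representation in that condition (by default log2(1 + mean expression)
across replicates). Node importance is the eigenvector centrality of the
symmetrized weighted adjacency, computed by shifted power iteration and
rescaled so the top node scores exactly 1; "relative importance" is that
score as a percentage. For each gene present in both networks the rate of
change

    R = 100 · (c_KO − c_WT) / c_WT   [%]

drives two calls:

- **functional complements** — genes with R > 1000 % (or newly present in
  the KO network) that are also up-regulated (log2FC > 0);
- **reduced importance** — genes whose KO relative importance drops below
  1 %.

Around this core the package provides the supporting statistics of such a
study: per-gene Student's t tests with strict |log2FC| > 2 selection at
raw P < 0.05, qPCR ΔΔCt fold changes (fold = 2^−ΔΔCt), SWATH proteomics
Total-Area-Sums normalization with a ≥3-peptides-per-protein filter,
peptide-array empty-spot normalization with per-peptide t tests and
one-way ANOVA, single-site (Wiseman) ITC isotherm simulation and
nonlinear-least-squares fitting of (Ka, ΔH, n), interacting-protein
BP-coverage set analysis, Louvain clustering, and a seeded synthetic-data
generator that produces every input with recorded ground truth.

## Worked example

```sh
python examples/02_network_complements.py
```

```
network sizes: WT 200 genes / 20 BPs, KO 200 / 20
planted complements: ['G0000', 'G0001', 'G0002', 'G0003', 'G0004', 'G0005']
called complements:  ['G0000', 'G0001', 'G0002', 'G0003', 'G0004', 'G0005']
genes below 1% relative importance in KO: 0
KO Louvain clusters: 8 (modularity 0.386)

gene_id     c_wt     c_ko  rate_of_change
  G0000 0.009276 0.156613     1588.431715
  G0001 0.010827 0.178653     1550.127216
  G0002 0.011099 0.169730     1429.274954
  G0003 0.010954 0.174864     1496.407812
  G0004 0.009966 0.161867     1524.195727
  G0005 0.010463 0.180014     1620.529878
```

The simulation plants six genes that are nearly silent in WT, switch on
after the knockdown and are broadly annotated; all six gain more than
1000 % network importance and are recovered exactly, with no false calls
among the 194 other genes. The remaining examples cover differential
expression (`01`), interacting-protein coverage and gene-membership
partitions (`03`), peptide arrays (`04`), ITC fitting (`05`) and the
file-driven pipeline (`06`).

A thin command line mirrors the stages:

```sh
regulomeshift simulate --seed 3 --out-dir sim/
regulomeshift de --expr sim/expr.tsv --conditions sim/cond.yaml --out de.tsv
regulomeshift network --expr sim/expr.tsv --conditions sim/cond.yaml \
    --ann sim/ann.tsv --de de.tsv --out-prefix run
regulomeshift run --config run.yaml      # full pipeline from YAML
```

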