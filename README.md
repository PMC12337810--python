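# methylscape

Tumor classification by genome-wide DNA methylation is built on a small set
of recurring operations: quality-control of array samples, selection of the
most variable CpGs, low-dimensional embedding and (consensus) clustering of
the resulting "landscape", counting differentially methylated probes (DMPs)
between every pair of diagnosis groups, summarising those counts as a
relatedness network, reading promoter methylation as gene activity, and
decomposing bulk profiles into cell-type fractions. `methylscape`
implements this full stack as a tested Python library for epigenomics
analysts, together with a synthetic EPIC-like cohort generator that plants
known group structure, known differential probes, and known cell-type
mixtures — so every stage can be validated against ground truth without any
external download.

## The statistics at the core

**Moderated differential methylation.** For each CpG probe *g*, with
two-group pooled variance s²_g on d = n₁ + n₂ − 2 degrees of freedom, the
variance is shrunk toward a prior s₀² estimated from all probes:

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
    t̃_g = (x̄₂ − x̄₁) / (s̃_g · √(1/n₁ + 1/n₂)),   t̃_g ~ t(d₀ + d)

The prior (d₀, s₀²) is fitted by the method of moments on log variances
(digamma/trigamma closed forms; d₀ → 0 recovers the ordinary pooled t).
A probe is a DMP when its Benjamini–Hochberg adjusted p < 0.01 **and**
|Δβ| > 0.3 — on the beta scale the effect threshold reads as a
30-percentage-point methylation difference. All G·(G−1)/2 group pairs are
evaluated (253 pairs for 23 groups).

**Relatedness network.** Nodes are diagnosis groups; a pair with DMP count
c gets an edge binned into {0}, [1, 999], [1000, 4999], [5000, 9999] or
[10000, 14999]; fewer DMPs = stronger similarity. Pairs with c ≥ 15,000 get
no edge, and any group left isolated is annotated with its closest possible
connection and the exact count.

**Landscape.** Top-k CpGs by across-sample standard deviation (default
k = 10,000) feed t-SNE, hierarchical clustering (1 − Pearson, average
linkage), and consensus clustering (B resampled 80% subsamples, cut at k
groups; the consensus matrix records co-clustering frequencies). A
Mann–Whitney comparison of within-reference versus reference-vs-other
consensus values quantifies which entities are epigenetically
indistinguishable from a reference group.

**Promoter activity and deconvolution.** Gene activity = 1 − mean beta over
the gene's transcription-start-site (TSS) probes; hypermethylated TSS DMPs
mark genes inhibited, hypomethylated activated, tested for gene-set
over-representation with the hypergeometric distribution. Cell-type
fractions solve min‖S·f − a‖² subject to f ≥ 0, Σf = 1 per sample.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/03_landscape.py` builds the default synthetic study cohort
(23 diagnosis groups, 430 samples, 20,000 probes, with the hepatic and
pancreatic mucinous-cystic-neoplasm groups planted as identical siblings)
and prints:

```
t-SNE 5-NN label purity over 430 samples: 0.981
dendrogram cut at k=23 produced 23 clusters
groups with consensus indistinguishable from within-MCN-P: ['MCN-L']
```

Purity 0.981 means 98% of samples sit among neighbours of their own entity
in the embedding (the planted identical siblings account for most of the
deficit), and the consensus-degree test singles out exactly the planted
sibling as statistically indistinguishable. `python
examples/04_differential_methylation.py` shows the moderated test on a
planted contrast:

```
empirical-Bayes prior: d0 = 1.86 pseudo-observations, s0^2 = 1.43e-05
DMPs called: 300 of 300 planted (recall 1.000); false calls: 0
```

A thin CLI wraps the same stages end to end:

```sh
methylscape run-all --out runs/demo --seed 1
```

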