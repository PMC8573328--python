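# invgsea

A two-contrast transcriptome analysis pipeline for studying degeneration and
its genetic rescue, built around four stages:

1. **Differential expression** — per-gene two-group tests on a counts matrix,
   with differential calls at raw *P* < 0.01 and |log₂ fold change| > 0.2.
2. **Gene-set enrichment** — the weighted running-sum (Kolmogorov–Smirnov
   style) enrichment statistic with phenotype- or gene-set-permutation
   p-values, NES, and Benjamini–Hochberg FDR over a GMT collection.
3. **Inverted enrichment** — a cross-contrast procedure that asks whether the
   genes defining one condition (e.g. neuronal degeneration in wild-type
   animals) are systematically *reverse*-regulated in a second contrast
   (e.g. knockout vs. wild type): direction-aware scoring of the first
   contrast's differential gene set against the second contrast's ranked
   list, plus exact direction-flip counts.
4. **Core-module detection** — STRING-style interaction networks thresholded
   at combined score > 0.4 and mined with a from-scratch MCODE
   implementation (degree cutoff 2, node score cutoff 0.2, haircut, K-core 2,
   max depth 100).

A synthetic-data generator with full ground truth (negative-binomial counts,
planted differential genes whose direction is partially inverted between
contrasts, planted dense subgraphs) makes every stage testable offline.

## The statistics

For a ranked gene list *L* of *N* genes with ranking metric *r_j* and a gene
set *S* with *N_h* members in *L*, the running score after position *i* is

    P_hit(S, i) = Σ_{j ≤ i, g_j ∈ S} |r_j|^w / Σ_{g_j ∈ S} |r_j|^w
    P_miss(S, i) = Σ_{j ≤ i, g_j ∉ S} 1 / (N − N_h)

and the enrichment score ES is the value of P_hit − P_miss at the position
where |P_hit − P_miss| is maximal (so |ES| = max_i |P_hit − P_miss|, signed
by the side of the list where the set concentrates). At *w* = 0 the
magnitude reduces to the classical two-sample KS statistic between hit and
miss ranks; the default is *w* = 1.

Significance comes from permutations (phenotype label shuffles with
re-ranking, or same-size random gene sets). With observed ES and permuted
ES\* of matching sign,

    p = (1 + #{|ES*| ≥ |ES|}) / (1 + #{same-sign permutations})
    NES = ES / mean |ES*|  (same-sign permutations)

For the inverted-enrichment stage, each contrast-A up-gene keeps its
contrast-B metric and each contrast-A down-gene contributes the negated
metric before the ES is computed, so concordant regulation gives NES > 0 and
inverted regulation NES < 0.

MCODE weights each vertex by the highest k-core level of its closed
neighborhood times that core's density, grows complexes greedily from
high-weight seeds, and scores a module as induced density × node count.

## Worked example

Simulate a two-contrast study in which 80% of the contrast-A differential
genes are reverse-regulated in contrast B, then run the full pipeline:

```python
from invgsea import SimDesign
from invgsea.pipeline import cmd_simulate, cmd_run_all, PipelineConfig, ContrastDef

cmd_simulate(SimDesign(inversion_fraction=0.8, seed=13), "demo", n_sets=25)
cfg = PipelineConfig(
    contrast_A=ContrastDef("demo/counts_A.tsv", "demo/groups.tsv", "A_trt", "A_ctrl"),
    contrast_B=ContrastDef("demo/counts_B.tsv", "demo/groups.tsv", "B_trt", "B_ctrl"),
    gene_sets="demo/gene_sets.gmt", network="demo/network.tsv",
    out_dir="demo/out", seed=13, n_permutations=500)
manifest = cmd_run_all(cfg)
```

The manifest reports, per stage:

```
dge_A       n_genes 2000   n_up 85   n_down 85
dge_B       n_genes 2000   n_up 92   n_down 76
enrichment  n_sets_tested 25
inversion   nes -1.87   p_value 0.0081   n_inverted 97
modules     n_modules 1
```

Contrast A calls 170 differential genes (planted: 200 at |log₂FC| = 1).
The inverted-enrichment NES of −1.87 with p ≈ 0.008 says those genes sit
significantly toward the *opposite* end of contrast B's ranked list — the
planted 80% inversion is detected — and 97 genes flip their call outright.
`demo/out/modules.tsv` lists the detected interaction module (9 nodes, 34
edges, score 8.5), recovering the planted dense subgraph. The same analyses
are available from the shell via the `invgsea` console script
(`invgsea simulate`, `dge`, `rank`, `enrich`, `invert`, `modules`,
`run-all`); permutation commands require `--seed`.

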