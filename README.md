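# reginfluence

Quantitative modelling of how a transcription factor binding site's
**position relative to the transcription start site (TSS)** determines its
contribution to gene expression.

Genome-wide ChIP experiments show that regulatory proteins bind thousands
of sites, most of them far from any promoter, and it is rarely obvious
which binding events matter or which genes they act on.  `reginfluence`
addresses this with a simple, fully linear model: every putative
regulatory region near a gene contributes additively to that gene's log
expression, and the size of the contribution is a smooth function of the
site's signed distance from the TSS — the **influence function** *f(d)* —
learned from the data.  The package is aimed at regulatory genomicists who
want to relate ChIP-seq/ChIP-chip binding maps to expression measurements,
and at methodologists who want a compact, testable reference
implementation of penalized-spline influence modelling.

## The model

A gene *i* with enhancers at signed distances *d₁ … d_m* (negative =
upstream in the transcription direction) has predicted centered log
expression

    ŷᵢ = Σⱼ αⱼ f(dⱼ),        f(d) = Σₖ cₖ Bₖ(d),

where *Bₖ* are cubic B-splines on ±100 kb and *αⱼ* is an optional per-site
modifier (regulator-identity weight and/or ChIP-enrichment affinity;
default 1).  The coefficients minimize the penalized mean squared error

    F(c) = (1/N) ‖y − Bc‖² + σ·cᵀDc,

with *D* the second-order difference penalty (the P-spline approximation
to ∫ f″(d)² dd) and σ the smoothness parameter, solved exactly by the
normal equations.  The log fold change between two tissues is the
difference of the two tissues' contribution sums, assuming shared basal
transcription and decay rates.

Around this core the package implements:

* regulatory-region calling from per-regulator peak sets (bound by the
  p300-style coactivator or by ≥2 other factors), signed TSS distances,
  and both multi-gene and nearest-gene-only site-to-gene assignment;
* conservation scoring (maximum 100 bp moving average of per-base
  PhastCons-style scores), data-driven conservation thresholds, and
  conserved/non-conserved site partitions;
* competing model variants: uniform site weighting, conservation-based
  weighting, per-regulator influence weights (alternating least squares),
  and enrichment-based affinity weighting;
* the evaluation protocol: repeated 2/3–1/3 train/test splits, bootstrap
  influence-curve confidence bands, permutation controls, and paired
  model comparisons;
* a synthetic-data generator with known ground truth, so the entire
  analysis runs and validates itself with no external data.

## Worked example

Simulate a two-tissue dataset (1,000 genes, binding within ±100 kb,
influence decaying linearly to zero at 50 kb with a 1.2× upstream excess,
noise sd 0.5), fit the position model, and compare it with uniform
weighting:

```bash
reginfluence simulate --n-genes 1000 --seed 7 --out-dir demo
# wrote 1000 genes, 4642 site records to demo

reginfluence fit --tss demo/tss.tsv --sites-a demo/sites_tissueA.bed \
    --sites-b demo/sites_tissueB.bed --expression demo/expression.tsv \
    --out demo/model.json --curve-out demo/curve.tsv
# fitted position model on 992 genes -> demo/model.json

reginfluence evaluate --tss demo/tss.tsv --sites-a demo/sites_tissueA.bed \
    --sites-b demo/sites_tissueB.bed --expression demo/expression.tsv \
    --n-trials 25 --out demo/report.json
# position @ 100000 bp, 25 trials: median held-out MSE 0.127, median Spearman 0.922

reginfluence evaluate --model uniform --tss demo/tss.tsv \
    --sites-a demo/sites_tissueA.bed --sites-b demo/sites_tissueB.bed \
    --expression demo/expression.tsv --n-trials 25 --out demo/report_uniform.json
# uniform @ 100000 bp, 25 trials: median held-out MSE 0.649, median Spearman 0.606
```

The numbers are read as follows: of the 1,000 simulated genes, 992 are
differentially expressed and bound within 100 kb and enter the analysis.
On held-out genes the position-aware model explains most of the
(standardized) expression variance — MSE 0.127, Spearman 0.92 — while the
model that counts binding events but ignores where they are does far
worse (MSE 0.649).  `demo/curve.tsv` contains the fitted influence
function on a 1 kb grid; its peak near d = 0 and approximately linear
decay toward ±50 kb reproduce the shape that generated the data, with
the upstream side elevated.

The same workflow runs on real data given a TSS table (TSV: `gene_id`,
`chrom`, `pos`, `strand`), per-tissue BED files of binding sites, and a
log-expression table; see `reginfluence --help` for the `predict`,
`bootstrap` and `compare` subcommands.

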