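# cdscreen

In-silico drug repositioning by connectivity-signature screening.

`cdscreen` implements the computational arm of a transcriptome-driven drug
screen of the kind used to nominate repurposing candidates for inflammatory
conditions such as sepsis: two-group gene-expression studies are reduced to
disease signatures, matched against a library of drug-perturbation
signatures to find compounds whose transcriptional effect *reverses* the
disease state, and the per-study candidate lists are merged into one
consensus ranking.  Companion analyses place the differentially expressed
genes on a protein–protein interaction (PPI) network and test them for
pathway over-representation.  A synthetic-data generator with planted
ground truth replaces the public GEO/LINCS/STRING downloads, so every stage
is verifiable by planted-signal recovery.

## The method

**Probe collapse.** Array probes without a gene symbol are discarded; for a
gene with several probes, the probe with the largest interquartile range
across samples is kept.

**Differential expression.** Per gene, an empirical-Bayes moderated
two-sample *t*: the pooled residual variance s²_g (d_g degrees of freedom)
is shrunk toward a prior s₀² learned from all genes,

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t̃_g = (x̄_case − x̄_ctrl) / (s̃_g · √(1/n₁ + 1/n₂)),

with t̃_g ~ t(d₀ + d_g) under the null.  (d₀, s₀²) are fit by method of
moments on log s² with a Newton trigamma inversion.  Genes pass at
Benjamini–Hochberg adjusted p < 0.05.

**Characteristic Direction.** The disease signature is the unit normal
**b** of the regularized linear-discriminant hyperplane separating case
from control:

    R b = δ,   R = γ·Σ̂ + (1 − γ)·ν·I,   ν = tr(Σ̂)/p,

where δ is the case-minus-control mean difference and Σ̂ the pooled
within-group covariance; γ = 0 gives b ∝ δ exactly.

**Connectivity scoring.** Each library drug is compared to the disease
signature by cosine distance d = 1 − cos ∈ [0, 2] on their shared genes;
the reverse-mode match score is d/2 (1 = perfect reverser), mimic-mode
(2 − d)/2.

**Borda consensus.** With base score B (default 50), the drug at rank r in
a list earns max(0, B − r + 1) points; totals across lists give the
consensus order, rewarding drugs that are consistently high-ranked.

**Network & enrichment.** DEGs induce a subgraph of a STRING-like edge list
(combined score ≥ 800); degree and unnormalized Brandes betweenness flag
topological bottlenecks.  Gene sets are tested by the one-sided
hypergeometric upper tail with BH adjustment.

## Worked example

Generate a synthetic bundle (5 studies of 500 genes sharing one planted
disease pattern, a 200-drug library with one planted reverser at cosine
fidelity 0.8), then run the full screen:

```sh
cdscreen simulate --out-dir demo --seed 1 --n-genes 500
cd demo && cdscreen run-all --config config.yaml
```

which prints

```
top consensus drug: DRUG0001
```

and writes per-study DEG tables, signatures and ranked lists, plus:

```
$ head -4 results/consensus.tsv
rank    drug_id    points    n_lists
1       DRUG0001   250       5
2       DRUG0139   244       5
3       DRUG0106   235       5
```

`DRUG0001` is the planted reverser (see `ground_truth.json`); it is ranked
first in all five per-study lists, hence the maximal 5 × 50 = 250 Borda
points.  `results/manifest.json` records the funnel per study — e.g.
study1: 695 probes in, 500 genes after collapse, 51 DEGs at adjusted
p < 0.05, 200 drugs scored, 0 skipped — and the merged DEG union (62 genes
here) feeds `results/centrality.tsv` and `results/enrichment.tsv`.

Every stage is also available as its own subcommand (`collapse`, `dge`,
`signature`, `screen`, `merge`, `network`, `enrich`) operating on the same
TSV formats, and as plain library functions.

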