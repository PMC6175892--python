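# Methods

This note documents the models, defaults and numerical conventions behind
`cdscreen`, and what the synthetic-data tests do and do not establish.

## Pipeline model

The screen assumes two-condition expression studies (control vs case) of
log-scale, already-normalized intensities; the package performs no
normalization of its own.  Stages are composed as: probe→gene collapse,
moderated-t DEG selection, ortholog mapping of DEG symbols, Characteristic
Direction signature on the DEG gene space, cosine connectivity scoring
against a drug-signature library, and truncated-Borda consensus across
studies.  The DEG union additionally feeds PPI centrality and gene-set
over-representation.

### Probe collapse

Probes without a gene symbol are discarded.  Among a gene's probes the one
with the largest interquartile range across all samples is kept — the IQR
is computed as Q3 − Q1 with linear-interpolation (type-7) quantiles, the
common default; the quantile rule is isolated in `preprocess.iqr` so a
different convention is a one-line change.  IQR ties break by ascending
probe id so outputs are deterministic.

### Moderated t and the variance prior

The two-group design uses the equal-variance pooled t within the
empirical-Bayes framework: no array weights, no mean–variance trend, no
multi-factor contrasts.  The prior (d0, s0²) is fit by method of moments on
log s²: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of
var(e) over ψ′(d_g/2) equals ψ′(d0/2), inverted by Newton iteration
(started at x = 0.5 + 1/y, converged to 1e−12, hard-failure after 100
iterations); the mean of e then fixes s0².  When the excess is ≤ 0 the
genes are compatible with a single variance and d0 = ∞: the posterior
variance is s0² for every gene and p-values are normal-referenced.  The
d0 = 0 (no-moderation) limit is exposed as `ordinary_t`, which equals the
classical pooled two-sample t.

Zero-variance genes: with a nonzero mean difference the statistic is ±∞
and p = 0 (the gene is perfectly separated); with zero difference the
statistic is undefined and p is set to 1.  Both cases are logged.

Significance uses Benjamini–Hochberg adjusted p < α, with α = 0.05 the
config default; an optional |log FC| cutoff supports stricter selection
settings per study.  Cross-study sign conflicts in the merged DEG union are
kept but marked `ambiguous` and excluded from direction-dependent uses —
silently choosing a sign would bias the signature.

### Characteristic Direction

The signature solves (γΣ̂ + (1−γ)νI) b = δ with ν = tr(Σ̂)/p, pooled
equal-covariance LDA across the two groups, b normalized to unit length.
The νI target keeps the regularizer on the scale of Σ̂, so R is
well-conditioned even when p ≫ n, and makes γ = 0 the exact closed form
b = δ/‖δ‖.  Default γ = 0.5 — an even compromise between the mean-shift
direction and the covariance-reweighted direction; it is a config knob
because no single value is canonical.  For p above a cap (default 2000)
the solve is restricted to the cap's most variable genes, the rest getting
coefficient 0; the cap is recorded in the signature's provenance.  The
orientation convention sign(bᵀδ) > 0 makes positive coefficients mean
"up in case" in aggregate; label swap negates b up to this convention.
The solve uses a symmetric positive-definite factorization; tests verify
agreement with an independent dense LU solve to 1e−8 and the γ = 0 closed
form to 1e−10.

In the orchestrated run the direction is computed on the study restricted
to its unambiguous DEG genes (renamed to human symbols through the
ortholog map first).  Mapping symbols rather than matrices avoids mixing
expression scales across species; when two source symbols map to one
target, the lexicographically first is kept.

### Connectivity scoring and Borda consensus

Cosine distance is computed on the intersection of defined (non-NaN)
entries of the two vectors; drugs sharing fewer than `min_overlap`
(default 5) genes with the signature's top-`top_n` (default 500,
by |coefficient|) genes are skipped and counted in the manifest — a cosine
on a handful of genes is noise.  Reverse score d/2 and mimic score
(2−d)/2 sum to 1, so both modes rank identically downstream with
"higher = better".

Borda merging awards max(0, B − r + 1) points at rank r with base score
B = 50 by default: only the top B entries of each list contribute, so the
consensus rewards drugs that appear consistently near the top.  Ties break
by number of contributing lists, then drug id.

### Network and enrichment

The DEG union induces a subgraph of the score-filtered edge list
(combined score ≥ 800, threshold inclusive, matching the convention of
reporting interactions at-or-above a confidence).  Isolated query genes
are kept as degree-0 nodes.  Betweenness is unnormalized, endpoints
excluded, each unordered pair counted once (Brandes, via networkx);
disconnected pairs contribute nothing.  Over-representation is the
one-sided hypergeometric upper tail, BH-adjusted across sets, with the
universe defaulting to all post-collapse genes observed across studies —
the universe changes every p-value, so it is exposed as an input rather
than fixed.

## Synthetic data: what it emulates and what it does not

`simulate_study` draws per-gene baselines uniform on [4, 12] log units
(typical RMA intensity range), adds i.i.d. Gaussian per-cell noise of
sd 0.5, and shifts planted DEGs (10% of genes, half up half down) by
±1.5 log units in case samples — a clear but not trivial effect at the
default 10 + 10 samples.  Genes expand to 1–3 probes (probabilities
0.7/0.2/0.1) with probe-level Gaussian jitter of sd noise_sd/2; 5% of
probes lose their annotation, but never a gene's first probe, so planted
ground truth remains recoverable by construction.  Heavier-tailed noise,
batch effects, platform artifacts and correlated genes are *not*
simulated, so passing recovery tests demonstrates correctness of the
machinery, not robustness to real-array pathologies.

`simulate_library` builds planted drugs by projection decomposition,
s = ±fid·d + √(1−fid²)·u with u a unit vector orthogonal to the disease
direction d, so the planted cosine is exactly ∓fidelity rather than
approximately so — the recovery threshold is then analytic, not empirical.
Null drugs are isotropic Gaussian (cosines concentrate near 0 at width
≈ 1/√p).  Real L1000 signatures are neither isotropic nor unit-norm;
absolute score values in real libraries will differ, ranks are the
meaningful output.

`simulate_ppi` is an Erdős–Rényi background (scores uniform in
[800, 1000]) with hub nodes wired to extra random neighbours — enough to
test induced-subgraph and centrality code, not a model of real PPI degree
distributions.  `simulate_gene_sets` plants one set at a stated overlap
with a query list, the rest uniform.

Every generator is a pure function of its spec including the seed
(bit-reproducible); in bundles, per-stage seeds fan out deterministically
from one global seed.

## Problem sizes and determinism

The test suite and acceptance script run the end-to-end screen at 5
studies × 1000 genes × 20 samples with a 200-drug library — small enough
for laptop-speed iteration while keeping the covariance solve (p up to the
DEG-set size) and the multiple-testing stack non-trivial.  All ranked
outputs break ties lexicographically and all writers emit deterministic
text, so identical config + seed yields a byte-identical output bundle;
this is asserted, not assumed.

## Known limitations

* Two-group contrasts only; no multi-factor designs or covariates.
* The Characteristic Direction significance bootstrap is out of scope; the
  signature ranks genes but carries no per-gene p-value.
* Ortholog mapping is symbol-level and many-to-one; paralog-aware mapping
  is not attempted.
* The [0, 1] match-score normalization and the truncated-Borda points rule
  are repository conventions; both are config-exposed where alternatives
  are plausible.
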