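# Methods

`responderomics` re-implements, as a tested and reusable pipeline, the
analysis pattern used to contrast low (LRE) and high (RES) responders to an
endurance-training intervention in a small paired multi-omics cohort:
moderated-t differential expression and methylation, hypergeometric
enrichment and list-overlap statistics, a stability-LASSO search for
baseline genes predictive of insulin-sensitivity improvement, and
promoter-methylation/expression integration. This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Responder phenotype

Whole-body insulin sensitivity is the Matsuda–DeFronzo index

    ISI = 10000 / sqrt(G0 · I0 · Gmean · Imean)

with glucose in mg/dL and insulin in µU/mL; declared SI inputs are
converted first (glucose ×18.016, insulin ÷6.0; both constants are
overridable). The responder label is driven entirely by the fold change
FC = ISI_post / ISI_pre: **RES iff FC ≥ 1.15** (boundary inclusive — the
defining phrase is "15% or greater"), otherwise LRE. No intermediate class
is modeled because the target cohort design has none.

## Moderated t-tests

Both omics layers use the standard empirical-Bayes moderation of gene-wise
variances. For feature g a contrast yields an effect estimate β̂_g, a
residual variance s_g² on d_g degrees of freedom, and an SE multiplier u:

* paired (w10 − w0 within a group): β̂ = mean within-subject difference,
  s² = sample variance of the differences, d = n−1, u = 1/√n;
* unpaired (RES − LRE at one timepoint): pooled two-sample quantities,
  d = n₁+n₂−2, u = √(1/n₁+1/n₂).

The prior (d₀, s₀²) is fitted by moment matching on
e_g = log s_g² − ψ(d_g/2) + log(d_g/2): the excess of the sample variance
of e over mean ψ′(d_g/2) equals ψ′(d₀/2), inverted by a monotone Newton
iteration (residual < 1e-10); s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)). A
non-positive excess returns d₀ = ∞ with s₀² = exp(ē). Then

    s²_post = (d₀ s₀² + d_g s_g²) / (d₀ + d_g),
    t = β̂ / (u √s²_post),  df = d₀ + d_g,

with two-sided Student-t p-values (normal in the d₀ = ∞ limit). Features
with zero posterior variance are flagged invalid rather than given p = 0.

Open choices resolved here: pre/post contrasts are **paired within
subject** (the design has repeated biopsies per subject); DEG selection
uses **raw p ≤ .05** (Benjamini–Hochberg available behind a flag);
methylation is tested on **M-values** log2(β/(1−β)) for variance
stability, with the beta-scale mean difference reported alongside; no
covariates enter the model.

## Enrichment and overlap

For a list of n genes from a universe of N (default: every gene on the
array/matrix), a term with K members and overlap k has fold enrichment
(k/n)/(K/N) and p = P(X ≥ k) under Hypergeometric(N, K, n). The tail is
accumulated in log space; when the upper tail carries most of the mass the
complement of the lower tail is used instead so the absolute error stays
near machine precision. Filters follow the DAVID-style convention:
overlap ≥ 5 and p ≤ .05. The conservative EASE variant (k replaced by
k−1; k ≤ 1 ⇒ p = 1) is available because DAVID defaults to it and which
variant produced any given published table is usually unknowable;
`standard` is the package default. The Venn overlap test is the same
statistic with one list as the term and the other as the draw (symmetric).

## Stability-LASSO

The predictive-marker engine repeats, `n_iter` = 1000 times:

1. **Split** the cohort into stratified 50/50 train/test halves: within
   each responder group ⌊size/2⌋ or ⌈size/2⌉ subjects go to train, the
   ceiling side alternating with the parity of the iteration seed so a
   7 + 11 cohort always yields 9/9.
2. **Standardize on the training half only** (columns centered, unit 1/n
   variance; outcome centered); the frozen transform is applied to the
   test half, preventing leakage.
3. **Tune λ by 5-fold CV** over a 100-point log-spaced path from
   λ_max = max_j |x_j·ỹ|/n down to 0.01·λ_max; λ* minimizes mean held-out
   squared error (ties to the larger λ; a one-standard-error rule is a
   flag). Each fold adds its own intercept on the centered outcome.
4. **Fit** the lasso (1/(2n))‖y − β₀ − Xβ‖² + λ‖β‖₁ at λ* on the full
   training half by cyclic coordinate descent with soft-thresholding,
   warm-started along the path; convergence when no coefficient moves by
   ≥ 1e-7 in a full sweep (cap 1e5 sweeps); every returned fit records its
   KKT violation (≤ 1e-6 in all tests).
5. **Score**: the model is *successful* when |ŷᵢ − yᵢ| ≤ 0.10·|yᵢ| for at
   least 50% of test subjects (both boundaries inclusive — "within" and
   "at least").

Genes are ranked by the percentage of **successful** models in which their
coefficient is nonzero; ties break by descending mean |standardized
coefficient|, then gene id. Per-iteration seeds derive from the master
seed through a fixed counter scheme (`SeedSequence(master, spawn_key=(i,))`),
so a whole run is reproducible from one integer and any iteration can be
replayed.

## Integration

A DEG counts as putatively epigenetically regulated when at least
`min_cpgs` (default 1) of its annotated CpGs (default: any region) are
differentially methylated at p ≤ .05 in the matching contrast. The
criterion behind published "fraction regulated" percentages is rarely
stated precisely, so region restriction, CpG count, p threshold, and an
optional inverse-promoter direction requirement are all explicit
configuration rather than hidden conventions. Predictive markers get the
stricter promoter check: ≥ 2 differentially methylated promoter CpGs, each
annotated with its direction relation to the expression effect (inverse /
parallel / mixed).

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, with full
ground truth:

* **Cohort**: 7 LRE + 11 RES subjects, two samples each (w0, w10), sex
  alternating within group. Outcomes are truncated normals per group —
  RES ~ N(1.35, 0.25²) truncated to ≥ 1.15, LRE ~ N(0.82, 0.12²)
  truncated to (0, 1.15) — so the classification boundary is respected by
  construction. Baseline Matsuda is log-normal with median 8 (log-sd 0.4,
  covering the ~7–11 range typical of such cohorts); post = pre · FC.
* **Expression** (log2 scale): x = μ_g + baseline + response +
  γ_g(y−1) + ε with μ_g ~ N(7, 1.5²); ±0.8 baseline shifts on 200 genes
  applied to RES at both timepoints (signs split evenly); ±0.7 response
  shifts at w10 only, 150 genes per group with a 15% shared overlap; 10
  predictive genes drawn from the baseline set with slope γ = ±1.5 log2
  units per unit of outcome, and ε ~ N(0, σ_g²) with σ_g² ~ 4·0.25²/χ²₄
  (scaled inverse chi-square, the heteroscedastic law the moderation model
  assumes). The predictive slope's sign is set **concordant** with the
  gene's baseline direction: since high responders have the higher
  outcomes by definition, a baseline-different gene that predicts the
  outcome necessarily has its group difference and outcome association in
  the same direction; an independent sign would make half the planted
  predictive genes marginally invisible.
* **Methylation**: 1–6 CpGs per gene (≥ 1 promoter), baseline beta
  ~ U(0.1, 0.9), logit-normal noise (sd 0.15). For 60% of truly
  differential genes the first promoter CpG's mean beta shifts by
  −0.08 × (the gene's log2 effect) in the matching contrast — the planted
  inverse promoter-methylation/expression coupling.
* **Gene sets**: terms of 20–80 genes; enriched terms draw 80% of members
  from one planted label, null terms draw uniformly; term ids record which.
* Outcomes are simulated directly as fold changes (not via simulated OGTT
  curves) because the pipeline consumes only the fold change.

What the simulator does **not** model: probe-level array artifacts, batch
effects, sex chromosomes, missing values, correlated co-expression
modules, or mQTL structure. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the assumed generative
laws, not robustness to real-data pathologies.

## Numerical choices and problem sizes

* Beta values are clipped to [1e-6, 1−1e-6] on input (rounded EPIC exports
  legitimately contain 0/1); the clip count is logged.
* The coordinate-descent kernel is compiled (numba) and alternates full
  sweeps with active-set sweeps; convergence is only declared on a full
  sweep. λ_max is computed with the solver's own reduction so the first
  path point yields the exactly-zero model.
* Hierarchical clustering of the 4-cell mean profiles (LRE-w0, LRE-w10,
  RES-w0, RES-w10; rows standardized; constant rows dropped with a log
  entry) uses Euclidean distance and Ward linkage, with labels 1..k
  assigned by descending cluster size. Distance, linkage, and k = 4 are
  conventional choices; nothing in the analysis depends on them elsewhere.
* Tests exercise the stability loop at 200 iterations and the end-to-end
  determinism check at reduced cohort sizes (600 genes, 15 iterations);
  the full default (5000 genes, 1000 iterations) runs in the
  reproduction script.

## Known limitations

* With 18 subjects, every baseline-shifted gene correlates with the
  group-separated outcome, so selection-frequency rankings mix genuinely
  predictive genes with group-informative ones; the planted predictive
  genes dominate but perfect top-k recovery is realization-dependent.
* Raw (unadjusted) p ≤ .05 thresholds are used throughout by design
  parity with the emulated analysis; at 5000 features this admits ~250
  false positives per contrast, which visibly dilutes downstream
  fractions computed over detected (rather than planted) gene lists.
* The integration criterion is associational; no causal or mediation
  claim is implied by the "regulated" flag.
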