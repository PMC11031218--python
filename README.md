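# responderomics

Not everyone who exercises gets healthier. In supervised endurance-training
studies a sizable minority of participants — *low responders* (LRE) — fail
to improve whole-body insulin sensitivity, while *high responders* (RES)
gain 15% or more on the Matsuda index. `responderomics` is a Python
package for the statistical analysis that contrasts these two groups in a
small paired pre/post cohort with skeletal-muscle gene expression and DNA
methylation arrays. It is written for computational biologists who want
the full analysis — responder classification, differential testing,
enrichment, predictive-marker discovery, methylation integration — as
tested, seedable library code rather than a one-off script.

## What it computes

**Responder phenotype.** The Matsuda insulin-sensitivity index
ISI = 10000/√(G₀·I₀·G_mean·I_mean) and its fold change FC = ISI_post/ISI_pre;
subjects with FC ≥ 1.15 are RES, the rest LRE.

**Moderated t-tests** (expression and methylation). Gene-wise variances
s_g² with d_g degrees of freedom are shrunk toward an empirical-Bayes
prior (d₀, s₀²) fitted by digamma/trigamma moment matching:

    s²_post = (d₀·s₀² + d_g·s_g²)/(d₀ + d_g),   t = β̂/(u·√s²_post)

with Student-t tails on d₀ + d_g degrees of freedom. Four contrasts are
built in: RES vs LRE at w0 and at w10 (unpaired), and w10 vs w0 within
each group (paired by subject). Methylation is tested on M-values.

**Enrichment and overlap.** Hypergeometric tail p-values and fold
enrichment (k/n)/(K/N) for gene-set terms (DAVID-style filters: overlap
≥ 5, p ≤ .05; EASE variant available) and for the overlap of two DEG
lists (the Venn statistic).

**Stability-LASSO.** 1000 stratified 50/50 cohort splits; per split a
5-fold cross-validated lasso of Matsuda fold change on baseline expression
of baseline DEGs (coordinate descent, warm-started λ path); a model counts
as *successful* when its test-half predictions fall within 10% of the
measured outcome for at least half the test subjects; genes are ranked by
selection frequency among successful models.

**Integration.** DEGs flagged as putatively epigenetically regulated when
enough of their CpGs are differentially methylated, with an optional
inverse-promoter direction requirement; top markers get a stricter ≥ 2
DM-promoter-CpG check.

**Synthetic cohorts.** A generator that emulates the study structure —
7 LRE + 11 RES, paired samples, scaled-inverse-chi-square gene noise,
planted baseline/response/predictive genes, promoter CpGs inversely
coupled to expression, truncated-normal outcomes — with full ground truth,
so the whole pipeline is testable offline.

See `docs/methods.md` for models, assumptions, and design decisions.

## Worked example

```python
from responderomics import (
    SimulationParams, simulate_all, run_contrast, select_deg,
    stability_run, top_markers,
)
from responderomics.diff_analysis import STANDARD_CONTRASTS
import pandas as pd

sim = simulate_all(SimulationParams(seed=1))        # 18 subjects, 5000 genes
sheet, expr = sim["sheet"], sim["expression"]

baseline = STANDARD_CONTRASTS[0]                    # RES vs LRE at w0
de = run_contrast(expr, sheet, baseline)
degs = select_deg(de)                               # p <= .05
print(len(degs), de.prior.d0, de.prior.s0_sq ** 0.5)
# 439 4.064964414623046 0.2499961585636429

w0 = sheet.table[sheet.table.timepoint == "w0"]
X = expr.subset_features(degs).subset_samples(list(w0.sample_id)).to_frame().T
X.index = list(w0.subject_id)
y = pd.Series(sheet.subject_outcome()).loc[X.index]
res = stability_run(X, y, sheet, n_iter=1000, master_seed=1)
print(res.n_successful)
# 562
print(top_markers(res, 3)[["frequency_percent"]].round(1))
#          frequency_percent
# gene_id
# g2312                 61.7
# g0695                 60.1
# g0793                 39.7
```

Reading: 439 of 5000 genes separate the groups at baseline (200 were
planted; the excess is the expected false-positive load of an unadjusted
p ≤ .05 threshold), the variance prior recovers the generating law
(d₀ ≈ 4, s₀ ≈ 0.25), and 562 of 1000 split/fit/test cycles produce a
model that predicts insulin-sensitivity improvement within the 10%/50%
success rule. The top-ranked markers are selected by a majority of those
successful models; seven of the ten planted predictive genes land in the
top 20.

The same pipeline runs from the shell:

```sh
responderomics run-all --config config.yaml        # or: --seed 1 --outdir out
responderomics simulate --seed 1 --outdir sim
responderomics de --expression sim/expression.tsv --samples sim/samples.csv \
    --contrast RES_vs_LRE_w0 --out de_w0.tsv
```

Every run writes a `manifest.json` with SHA-256 checksums of all outputs;
identical configuration and seed reproduce identical bytes.

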