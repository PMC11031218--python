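"""Synthetic paired pre/post multi-omics cohorts with full ground truth.

The generator emulates the data structure the analysis assumes: a small
cohort (default 7 low responders, 11 high responders) sampled at two
timepoints (w0, w10), a log2 expression matrix with gene-wise
heteroscedastic noise whose variances follow a scaled inverse chi-square
law, planted baseline / response / predictive genes, promoter CpGs
inversely coupled to expression effects, and truncated-normal Matsuda
fold-change outcomes (high responders >= 1.15 by construction, low
responders below).  Every planted label is returned as ground truth so
downstream recovery can be scored.

Randomness uses one master seed; per-purpose child generators are derived
with fixed spawn keys (cohort=0, expression=1, methylation=2, genesets=3)
so each layer can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from responderomics.errors import ConfigError
from responderomics.io_formats import (
    BETA_EPS,
    CpGAnnotation,
    GeneSetCollection,
    OmicsMatrix,
    SampleSheet,
)


@dataclass(frozen=True)
class OutcomeParams:
    """Truncated-normal law for one group's Matsuda fold change."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults are the emulated study conditions."""

    n_lre: int = 7
    n_res: int = 11
    n_genes: int = 5000
    n_baseline_diff: int = 200
    n_response_lre: int = 150
    n_response_res: int = 150
    response_overlap: float = 0.15
    n_predictive: int = 10
    predictive_effect: float = 1.5  # log2 units per unit of outcome
    baseline_effect_log2: float = 0.8
    response_effect_log2: float = 0.7
    d0_true: float = 4.0  # prior df of the variance law
    s0_true: float = 0.25  # prior sd, log2 units
    mu_mean: float = 7.0  # baseline log2 abundance
    mu_sd: float = 1.5
    cpgs_per_gene: tuple[int, int] = (1, 6)
    coupling_fraction: float = 0.6
    coupling_slope: float = -0.08  # beta shift per log2 unit of expression effect
    methyl_logit_sd: float = 0.15
    outcome_res: OutcomeParams = field(
        default_factory=lambda: OutcomeParams(1.35, 0.25, lower=1.15)
    )
    outcome_lre: OutcomeParams = field(
        default_factory=lambda: OutcomeParams(0.82, 0.12, lower=0.0, upper=1.15)
    )
    matsuda_pre_median: float = 8.0
    matsuda_pre_log_sd: float = 0.4
    n_enriched_terms: int = 9
    n_null_terms: int = 15
    term_size_range: tuple[int, int] = (20, 80)
    enriched_draw_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lre", "n_res", "n_genes", "n_baseline_diff", "n_predictive"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_baseline_diff + self.n_predictive > self.n_genes:
            raise ConfigError("n_baseline_diff + n_predictive exceeds n_genes")
        if self.n_predictive > self.n_baseline_diff:
            raise ConfigError("predictive genes are drawn from the baseline-different set")
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ConfigError("coupling_fraction must lie in [0, 1]")
        lo, hi = self.cpgs_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid cpgs_per_gene range {self.cpgs_per_gene}")

    def rng(self, purpose: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(purpose,)))


@dataclass
class GroundTruth:
    """Planted labels: per-gene effects, per-CpG coupling, per-subject outcomes."""

    genes: pd.DataFrame  # baseline_diff, response_lre, response_res, predictive_gamma, sigma2
    outcomes: pd.Series  # Matsuda fold change per subject
    cpgs: pd.DataFrame | None = None  # gene_id, region, coupled

    @property
    def baseline_diff_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["baseline_diff"] != 0])

    @property
    def predictive_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["predictive_gamma"] != 0.0])

    def response_genes(self, group: str) -> list[str]:
        col = {"LRE": "response_lre", "RES": "response_res"}[group]
        return list(self.genes.index[self.genes[col] != 0])

    def to_frame(self) -> pd.DataFrame:
        gene_part = self.genes.copy()
        gene_part.insert(0, "feature_type", "gene")
        gene_part.index.name = "feature_id"
        if self.cpgs is None:
            return gene_part.reset_index()
        cpg_part = pd.DataFrame(
            {
                "feature_type": "cpg",
                "coupled": self.cpgs["coupled"].astype(bool),
                "gene_id": self.cpgs["gene_id"],
            },
            index=self.cpgs.index,
        )
        cpg_part.index.name = "feature_id"
        out = pd.concat([gene_part.reset_index(), cpg_part.reset_index()])
        return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _sample_truncnorm(rng: np.random.Generator, p: OutcomeParams, size: int) -> np.ndarray:
    a = (p.lower - p.mean) / p.sd
    b = (p.upper - p.mean) / p.sd
    mass = norm.cdf(b) - norm.cdf(a)
    if mass < 1e-3:
        raise ConfigError(
            f"outcome truncation to ({p.lower}, {p.upper}) keeps only {mass:.2e} "
            f"of N({p.mean}, {p.sd}^2) mass"
        )
    return truncnorm.rvs(a, b, loc=p.mean, scale=p.sd, size=size, random_state=rng)


def generate_cohort(params: SimulationParams) -> tuple[SampleSheet, pd.Series]:
    """Subjects, paired samples, and truncated-normal Matsuda outcomes.

    Returns the sample sheet (two samples per subject) and the outcome
    series y (fold change) indexed by subject.  Baseline Matsuda is
    log-normal around the configured median; post = pre * y.  Sex is
    assigned alternately F/M within each group.
    """
    rng = params.rng(0)
    rows = []
    outcomes = {}
    for grp, n, oc in (("LRE", params.n_lre, params.outcome_lre),
                       ("RES", params.n_res, params.outcome_res)):
        y = _sample_truncnorm(rng, oc, n)
        pre = np.exp(rng.normal(math.log(params.matsuda_pre_median),
                                params.matsuda_pre_log_sd, size=n))
        for i in range(n):
            subject = f"{grp}{i + 1:02d}"
            outcomes[subject] = float(y[i])
            sex = "F" if i % 2 == 0 else "M"
            for tp in ("w0", "w10"):
                rows.append(
                    {
                        "sample_id": f"{subject}_{tp}",
                        "subject_id": subject,
                        "group": grp,
                        "timepoint": tp,
                        "sex": sex,
                        "matsuda_pre": pre[i],
                        "matsuda_post": pre[i] * y[i],
                    }
                )
    sheet = SampleSheet(pd.DataFrame(rows))
    return sheet, pd.Series(outcomes, name="matsuda_fc")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _signed(rng: np.random.Generator, ids: np.ndarray) -> pd.Series:
    """+1/-1 labels split evenly (extra one at random) over the given ids."""
    signs = np.ones(len(ids), dtype=int)
    signs[: len(ids) // 2] = -1
    rng.shuffle(signs)
    return pd.Series(signs, index=ids)


def generate_expression(
    sheet: SampleSheet,
    outcomes: pd.Series,
    params: SimulationParams,
) -> tuple[OmicsMatrix, GroundTruth]:
    """Plant baseline, response, and predictive effects on a log2 matrix.

    Per gene g, subject i, timepoint t:

        x = mu_g + baseline + response + gamma_g * (y_i - 1) + eps

    where the baseline term (+-baseline_effect_log2) applies to RES
    subjects at both timepoints for baseline-different genes, the response
    term (+-response_effect_log2) applies at w10 only for the subject's
    group's response genes, the predictive slope gamma_g is nonzero for a
    subset of baseline-different genes at both timepoints, and
    eps ~ N(0, sigma_g^2) with sigma_g^2 ~ d0 * s0^2 / chi2_{d0}.
    """
    rng = params.rng(1)
    width = len(str(params.n_genes))
    genes = np.array([f"g{i + 1:0{width}d}" for i in range(params.n_genes)])

    baseline_ids = rng.choice(genes, size=params.n_baseline_diff, replace=False)
    baseline_sign = _signed(rng, baseline_ids)
    predictive_ids = rng.choice(baseline_ids, size=params.n_predictive, replace=False)
    # predictive slope concordant with the gene's baseline direction: a
    # baseline-different gene that predicts the outcome has its group
    # difference and outcome association in the same direction (high
    # responders have the higher outcomes by definition)
    gamma_sign = baseline_sign.loc[predictive_ids]

    n_shared = int(round(params.response_overlap
                         * min(params.n_response_lre, params.n_response_res)))
    pool = rng.permutation(genes)
    shared = pool[:n_shared]
    lre_only = pool[n_shared: n_shared + params.n_response_lre - n_shared]
    res_pool_start = n_shared + (params.n_response_lre - n_shared)
    res_only = pool[res_pool_start: res_pool_start + params.n_response_res - n_shared]
    resp_lre_ids = np.concatenate([shared, lre_only])
    resp_res_ids = np.concatenate([shared, res_only])
    resp_lre_sign = _signed(rng, resp_lre_ids)
    resp_res_sign = _signed(rng, resp_res_ids)

    sigma2 = params.d0_true * params.s0_true ** 2 / rng.chisquare(params.d0_true, params.n_genes)
    mu = rng.normal(params.mu_mean, params.mu_sd, params.n_genes)

    truth = pd.DataFrame(
        {
            "baseline_diff": 0,
            "response_lre": 0,
            "response_res": 0,
            "predictive_gamma": 0.0,
            "sigma2": sigma2,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth.loc[baseline_sign.index, "baseline_diff"] = baseline_sign
    truth.loc[resp_lre_sign.index, "response_lre"] = resp_lre_sign
    truth.loc[resp_res_sign.index, "response_res"] = resp_res_sign
    truth.loc[gamma_sign.index, "predictive_gamma"] = gamma_sign * params.predictive_effect

    meta = sheet.table
    sample_ids = meta["sample_id"].tolist()
    is_res = (meta["group"] == "RES").to_numpy()
    is_w10 = (meta["timepoint"] == "w10").to_numpy()
    is_lre = ~is_res
    y_sample = outcomes.loc[meta["subject_id"]].to_numpy()

    base_vec = (truth["baseline_diff"].to_numpy() * params.baseline_effect_log2)[:, None]
    resp_lre_vec = (truth["response_lre"].to_numpy() * params.response_effect_log2)[:, None]
    resp_res_vec = (truth["response_res"].to_numpy() * params.response_effect_log2)[:, None]
    gamma_vec = truth["predictive_gamma"].to_numpy()[:, None]

    means = (
        mu[:, None]
        + base_vec * is_res[None, :]
        + resp_lre_vec * (is_lre & is_w10)[None, :]
        + resp_res_vec * (is_res & is_w10)[None, :]
        + gamma_vec * (y_sample - 1.0)[None, :]
    )
    noise = rng.standard_normal(means.shape) * np.sqrt(sigma2)[:, None]
    matrix = OmicsMatrix(list(genes), sample_ids, means + noise, layer="expression_log2")
    return matrix, GroundTruth(genes=truth, outcomes=outcomes)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def generate_methylation(
    sheet: SampleSheet,
    expr_truth: GroundTruth,
    params: SimulationParams,
) -> tuple[OmicsMatrix, CpGAnnotation, GroundTruth]:
    """CpG beta matrix with promoter CpGs coupled to planted expression effects.

    Each gene receives 1-6 CpGs, at least one in its promoter.  For a
    ``coupling_fraction`` of truly differential genes, the first promoter
    CpG's mean beta shifts by ``coupling_slope`` times the gene's log2
    effect in the corresponding contrast (a negative slope plants the
    inverse promoter-methylation/expression relation).  All CpGs carry
    logit-normal noise around a per-CpG baseline beta ~ U(0.1, 0.9).
    """
    rng = params.rng(2)
    genes = expr_truth.genes.index.to_numpy()
    lo, hi = params.cpgs_per_gene
    n_per_gene = rng.integers(lo, hi + 1, size=len(genes))
    total = int(n_per_gene.sum())

    cpg_gene = np.repeat(genes, n_per_gene)
    is_first = np.concatenate([[True] + [False] * (k - 1) for k in n_per_gene])
    region = np.where(
        is_first, "promoter", rng.choice(["promoter", "body"], size=total)
    )
    cpg_ids = np.array([f"cg{i + 1:08d}" for i in range(total)])
    annotation = CpGAnnotation(
        pd.DataFrame(
            {
                "cpg_id": cpg_ids,
                "chrom": [f"chr{c}" for c in rng.integers(1, 23, size=total)],
                "pos": rng.integers(1, 10**8, size=total),
                "gene_id": cpg_gene,
                "region": region,
            }
        )
    )

    gt = expr_truth.genes
    differential = gt.index[
        (gt["baseline_diff"] != 0) | (gt["response_lre"] != 0) | (gt["response_res"] != 0)
    ].to_numpy()
    n_coupled = int(round(params.coupling_fraction * len(differential)))
    coupled_genes = set(
        rng.choice(differential, size=n_coupled, replace=False) if n_coupled else []
    )
    coupled_cpg = is_first & np.isin(cpg_gene, list(coupled_genes))

    meta = sheet.table
    sample_ids = meta["sample_id"].tolist()
    is_res = (meta["group"] == "RES").to_numpy()
    is_w10 = (meta["timepoint"] == "w10").to_numpy()
    is_lre = ~is_res

    base = rng.uniform(0.1, 0.9, size=total)
    gene_base = gt["baseline_diff"].reindex(cpg_gene).to_numpy() * params.baseline_effect_log2
    gene_rlre = gt["response_lre"].reindex(cpg_gene).to_numpy() * params.response_effect_log2
    gene_rres = gt["response_res"].reindex(cpg_gene).to_numpy() * params.response_effect_log2

    shift = np.zeros((total, len(sample_ids)))
    slope = params.coupling_slope
    shift += np.where(coupled_cpg, slope * gene_base, 0.0)[:, None] * is_res[None, :]
    shift += np.where(coupled_cpg, slope * gene_rlre, 0.0)[:, None] * (is_lre & is_w10)[None, :]
    shift += np.where(coupled_cpg, slope * gene_rres, 0.0)[:, None] * (is_res & is_w10)[None, :]

    mean_beta = np.clip(base[:, None] + shift, 0.01, 0.99)
    values = expit(logit(mean_beta) + rng.normal(0.0, params.methyl_logit_sd, mean_beta.shape))
    values = np.clip(values, BETA_EPS, 1.0 - BETA_EPS)
    matrix = OmicsMatrix(list(cpg_ids), sample_ids, values, layer="methylation_beta")

    cpg_truth = pd.DataFrame(
        {"gene_id": cpg_gene, "region": region, "coupled": coupled_cpg},
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    full_truth = GroundTruth(genes=gt, outcomes=expr_truth.outcomes, cpgs=cpg_truth)
    return matrix, annotation, full_truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def generate_genesets(truth: GroundTruth, params: SimulationParams) -> GeneSetCollection:
    """Planted-enrichment gene sets: some terms favor a truth label, some are null.

    Enriched terms draw ``enriched_draw_frac`` of their members from one
    planted label (cycling over baseline / LRE-response / RES-response) and
    the rest uniformly; null terms draw uniformly.  Term ids record which.
    """
    rng = params.rng(3)
    genes = truth.genes.index.to_numpy()
    lo, hi = params.term_size_range
    if hi > len(genes):
        raise ConfigError(f"term size {hi} exceeds the {len(genes)}-gene universe")
    labels = {
        "baseline": truth.baseline_diff_genes,
        "response_lre": truth.response_genes("LRE"),
        "response_res": truth.response_genes("RES"),
    }
    label_names = [k for k, v in labels.items() if v]
    sets: dict[str, tuple[str, list[str]]] = {}
    for i in range(params.n_enriched_terms):
        label = label_names[i % len(label_names)]
        pool = np.asarray(labels[label])
        size = int(rng.integers(lo, hi + 1))
        n_label = min(int(round(params.enriched_draw_frac * size)), len(pool))
        members = set(rng.choice(pool, size=n_label, replace=False))
        rest = np.setdiff1d(genes, list(members), assume_unique=False)
        members |= set(rng.choice(rest, size=size - n_label, replace=False))
        term = f"ENR_{label}_{i + 1:03d}"
        sets[term] = (f"planted enrichment over {label} genes", sorted(members))
    for i in range(params.n_null_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        term = f"NULL_{i + 1:03d}"
        sets[term] = ("uniformly drawn null term", sorted(members))
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------


def simulate_all(params: SimulationParams) -> dict:
    """Generate cohort, expression, methylation, and gene sets in one call."""
    sheet, outcomes = generate_cohort(params)
    expression, truth = generate_expression(sheet, outcomes, params)
    methylation, annotation, truth = generate_methylation(sheet, truth, params)
    genesets = generate_genesets(truth, params)
    return {
        "params": params,
        "sheet": sheet,
        "outcomes": outcomes,
        "expression": expression,
        "methylation": methylation,
        "annotation": annotation,
        "genesets": genesets,
        "truth": truth,
    }
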