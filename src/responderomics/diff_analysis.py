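"""Empirical-Bayes moderated t-tests, DEG selection, and profile clustering.

The test statistic follows the standard empirical-Bayes moderation scheme:
per-feature residual variances s_g^2 with d_g degrees of freedom are shrunk
toward a prior variance s0^2 with d0 prior degrees of freedom,

    s2_post = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_mod   = beta_hat / (u * sqrt(s2_post)),   df = d0 + d_g

where (d0, s0^2) are estimated from all features by moment matching on
log variances (digamma/trigamma), and u is the unscaled standard-error
multiplier of the contrast.  Pre/post contrasts are paired within subject
(one difference per subject); group contrasts at a fixed timepoint are
unpaired two-sample comparisons reported as RES minus LRE.

Methylation is tested on M-values, log2(beta / (1 - beta)), for variance
stability; the beta-scale mean difference is reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import digamma, polygamma

from responderomics.errors import ConfigError, DataError, DesignError
from responderomics.io_formats import OmicsMatrix, SampleSheet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contrasts and per-feature statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSpec:
    """Which comparison to run.

    ``paired_within_group``: w10 minus w0 within subjects of ``group``.
    ``unpaired_between_groups``: RES minus LRE at ``timepoint``.
    """

    kind: str
    group: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "paired_within_group":
            if self.group not in ("LRE", "RES"):
                raise ConfigError(f"paired contrast needs group LRE or RES, got {self.group!r}")
        elif self.kind == "unpaired_between_groups":
            if self.timepoint not in ("w0", "w10"):
                raise ConfigError(
                    f"unpaired contrast needs timepoint w0 or w10, got {self.timepoint!r}"
                )
        else:
            raise ConfigError(f"unknown contrast kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "paired_within_group":
            return f"{self.group}_w10_vs_w0"
        return f"RES_vs_LRE_{self.timepoint}"


STANDARD_CONTRASTS = (
    ContrastSpec("unpaired_between_groups", timepoint="w0"),
    ContrastSpec("unpaired_between_groups", timepoint="w10"),
    ContrastSpec("paired_within_group", group="LRE"),
    ContrastSpec("paired_within_group", group="RES"),
)


@dataclass
class GeneStats:
    """Per-feature effect, residual variance, residual df, and SE multiplier."""

    feature_ids: list[str]
    beta_hat: np.ndarray
    s2: np.ndarray
    df_res: float
    u: float
    contrast: ContrastSpec
    effect_beta: np.ndarray | None = None  # beta-scale effect for methylation


@dataclass(frozen=True)
class Prior:
    """Empirical-Bayes variance prior: d0 may be +inf (all variances equal)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise DataError(f"prior df must be positive, got {self.d0}")
        if not (self.s0_sq > 0):
            raise DataError(f"prior variance must be positive, got {self.s0_sq}")


@dataclass
class DiffResult:
    """Moderated-t results, one row per feature."""

    table: pd.DataFrame
    prior: Prior | None = None
    contrast: ContrastSpec | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.table

    @property
    def p_value(self) -> pd.Series:
        return self.table["p_value"]


def _m_values(beta: np.ndarray) -> np.ndarray:
    return np.log2(beta / (1.0 - beta))


def fit_gene_stats(
    matrix: OmicsMatrix,
    sheet: SampleSheet,
    contrast: ContrastSpec,
    *,
    use_m_values: bool = True,
) -> GeneStats:
    """Per-feature effect size and residual variance for one contrast.

    Paired: beta_hat is the mean within-subject (w10 - w0) difference,
    s2 its sample variance, df = n - 1, u = 1/sqrt(n).  Unpaired:
    beta_hat = mean(RES) - mean(LRE), s2 the pooled variance,
    df = n1 + n2 - 2, u = sqrt(1/n1 + 1/n2).
    """
    df = sheet.table.set_index("sample_id")
    values = matrix.values
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    is_beta = matrix.layer == "methylation_beta"
    if is_beta and use_m_values:
        test_values = _m_values(values)
    else:
        test_values = values

    if contrast.kind == "paired_within_group":
        sub = df[df["group"] == contrast.group]
        by_subject: dict[str, dict[str, str]] = {}
        for sid, row in sub.iterrows():
            by_subject.setdefault(row["subject_id"], {})[row["timepoint"]] = sid
        pairs = []
        for subject, tps in by_subject.items():
            if "w0" not in tps or "w10" not in tps:
                raise DesignError(
                    f"subject {subject!r} lacks a "
                    f"{'w0' if 'w0' not in tps else 'w10'} sample for paired contrast"
                )
            if tps["w0"] not in col or tps["w10"] not in col:
                raise DesignError(f"samples of subject {subject!r} missing from matrix")
            pairs.append((col[tps["w0"]], col[tps["w10"]]))
        n = len(pairs)
        if n < 2:
            raise DesignError(f"paired contrast needs >= 2 complete subjects, found {n}")
        i0 = [p[0] for p in pairs]
        i1 = [p[1] for p in pairs]
        diffs = test_values[:, i1] - test_values[:, i0]
        beta_hat = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        df_res = float(n - 1)
        u = 1.0 / math.sqrt(n)
        effect_beta = (values[:, i1] - values[:, i0]).mean(axis=1) if is_beta else None
    else:
        sub = df[df["timepoint"] == contrast.timepoint]
        res_ids = [s for s in sub.index[sub["group"] == "RES"] if s in col]
        lre_ids = [s for s in sub.index[sub["group"] == "LRE"] if s in col]
        n1, n2 = len(res_ids), len(lre_ids)
        if n1 < 2 or n2 < 2:
            raise DesignError(
                f"unpaired contrast needs >= 2 samples per group, found RES={n1}, LRE={n2}"
            )
        a = test_values[:, [col[s] for s in res_ids]]
        b = test_values[:, [col[s] for s in lre_ids]]
        beta_hat = a.mean(axis=1) - b.mean(axis=1)
        s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / (
            n1 + n2 - 2
        )
        df_res = float(n1 + n2 - 2)
        u = math.sqrt(1.0 / n1 + 1.0 / n2)
        if is_beta:
            av = values[:, [col[s] for s in res_ids]]
            bv = values[:, [col[s] for s in lre_ids]]
            effect_beta = av.mean(axis=1) - bv.mean(axis=1)
        else:
            effect_beta = None

    return GeneStats(
        feature_ids=list(matrix.feature_ids),
        beta_hat=beta_hat,
        s2=s2,
        df_res=df_res,
        u=u,
        contrast=contrast,
        effect_beta=effect_beta,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes prior
# ---------------------------------------------------------------------------


def trigamma_inverse(x: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve psi'(y) = x for y > 0 by monotone Newton iteration.

    psi' is strictly decreasing on (0, inf) with range (0, inf), so the
    root is unique.  The iteration is the standard one for this problem
    and converges to machine precision in a handful of steps.
    """
    if not (x > 0):
        raise DataError(f"trigamma_inverse requires a positive target, got {x}")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float | np.ndarray) -> Prior:
    """Estimate (d0, s0^2) by moment matching on log variances.

    With s_g^2 ~ s0^2 * chi^2_{d_g}/d_g scaled by an F-prior, the statistic
    e_g = log s_g^2 - psi(d_g/2) + log(d_g/2) has mean log s0^2 - psi(d0/2)
    + log(d0/2) and variance psi'(d_g/2) + psi'(d0/2).  Matching the sample
    mean and variance of e_g and inverting the trigamma gives the prior.
    A non-positive excess variance means the variances are essentially
    equal across features: d0 = +inf and s0^2 = exp(mean e).
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    keep = (s2 > 0) & (df_arr >= 1)
    if int(keep.sum()) == 0:
        raise DataError("all residual variances are zero; cannot fit a variance prior")
    if int(keep.sum()) < 10:
        raise DataError(f"need >= 10 features with positive variance, found {int(keep.sum())}")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("estimate_prior: excluded %d zero-variance features", n_dropped)
    s2k, dfk = s2[keep], df_arr[keep]
    e = np.log(s2k) - digamma(dfk / 2.0) + np.log(dfk / 2.0)
    e_bar = float(e.mean())
    n = e.size
    target = float(np.mean((e - e_bar) ** 2 * n / (n - 1) - polygamma(1, dfk / 2.0)))
    if target <= 0:
        return Prior(d0=math.inf, s0_sq=float(np.exp(e_bar)))
    d0 = 2.0 * trigamma_inverse(target)
    s0_sq = float(np.exp(e_bar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return Prior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def moderated_t(gene_stats: GeneStats, prior: Prior | None) -> DiffResult:
    """Moderated t-statistics and two-sided p-values for one contrast.

    ``prior=None`` forces the d0 = 0 limit, i.e. the ordinary t-statistic
    with s2_post = s_g^2 and df = d_g.
    """
    if prior is None:
        d0, s0_sq = 0.0, 1.0  # unmoderated: s2_post = s_g^2
    else:
        d0, s0_sq = prior.d0, prior.s0_sq
    s2 = gene_stats.s2
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + gene_stats.df_res * s2) / (d0 + gene_stats.df_res)
        df_total = d0 + gene_stats.df_res

    invalid = s2_post <= 0
    if invalid.any():
        bad = [gene_stats.feature_ids[i] for i in np.flatnonzero(invalid)[:5]]
        logger.warning(
            "%d feature(s) with zero posterior variance flagged invalid (e.g. %s)",
            int(invalid.sum()),
            bad,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = gene_stats.beta_hat / (gene_stats.u * np.sqrt(s2_post))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.where(invalid, np.nan, p)
    t_mod = np.where(invalid, np.nan, t_mod)

    table = pd.DataFrame(
        {
            "beta_hat": gene_stats.beta_hat,
            "t_mod": t_mod,
            "p_value": p,
            "df_total": df_total,
            "s2_post": s2_post,
            "valid": ~invalid,
        },
        index=pd.Index(gene_stats.feature_ids, name="feature_id"),
    )
    if gene_stats.effect_beta is not None:
        table.insert(1, "effect_beta", gene_stats.effect_beta)
    return DiffResult(table=table, prior=prior, contrast=gene_stats.contrast)


def run_contrast(
    matrix: OmicsMatrix,
    sheet: SampleSheet,
    contrast: ContrastSpec,
    *,
    use_m_values: bool = True,
) -> DiffResult:
    """Convenience: fit per-feature stats, estimate the prior, moderate."""
    gs = fit_gene_stats(matrix, sheet, contrast, use_m_values=use_m_values)
    prior = estimate_prior(gs.s2, gs.df_res)
    return moderated_t(gs, prior)


def select_deg(
    result: DiffResult,
    p_threshold: float = 0.05,
    *,
    adjust: str | None = None,
) -> list[str]:
    """Features with p <= threshold, ascending p, ties broken by feature id.

    ``adjust="bh"`` applies Benjamini-Hochberg and thresholds the adjusted
    p-values instead; the default (None) uses raw p-values, which is the
    convention for every threshold in this pipeline.
    """
    tab = result.table.dropna(subset=["p_value"])
    p = tab["p_value"]
    if adjust == "bh":
        p = pd.Series(_bh_adjust(p.to_numpy()), index=p.index)
    elif adjust is not None:
        raise ConfigError(f"unknown adjustment {adjust!r}; use None or 'bh'")
    hits = p[p <= p_threshold]
    order = sorted(hits.index, key=lambda f: (hits[f], f))
    return list(order)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------


def cluster_profiles(
    matrix: OmicsMatrix,
    sheet: SampleSheet,
    gene_subset: list[str],
    k: int = 4,
) -> pd.Series:
    """Cluster genes on their 4-cell mean-expression profiles.

    For each gene the profile is (mean over LRE-w0, LRE-w10, RES-w0,
    RES-w10 samples), row-standardized to mean 0 / sd 1.  Hierarchical
    clustering with Euclidean distance and Ward linkage; the tree is cut
    into ``k`` clusters and labels 1..k are assigned in order of
    descending cluster size.  Constant rows are dropped with a log entry.
    """
    if not gene_subset:
        raise ConfigError("gene_subset must be non-empty")
    sub = matrix.subset_features(gene_subset)
    cells = []
    for group in ("LRE", "RES"):
        for tp in ("w0", "w10"):
            ids = [s for s in sheet.samples_for(group, tp) if s in set(sub.sample_ids)]
            if not ids:
                raise DesignError(f"no samples for {group} at {tp}")
            cells.append(sub.subset_samples(ids).values.mean(axis=1))
    profile = np.column_stack(cells)  # genes x 4

    keep = profile.std(axis=1) > 0
    if (~keep).any():
        dropped = [g for g, k_ in zip(gene_subset, keep) if not k_]
        logger.info("cluster_profiles: dropped %d constant profile(s): %s",
                    len(dropped), dropped[:5])
    genes = [g for g, k_ in zip(gene_subset, keep) if k_]
    profile = profile[keep]
    if k > len(genes):
        raise ConfigError(f"k={k} exceeds the {len(genes)} usable genes")
    z = (profile - profile.mean(axis=1, keepdims=True)) / profile.std(axis=1, keepdims=True)
    if k == 1:
        raw = np.ones(len(genes), dtype=int)
    else:
        tree = linkage(z, method="ward", metric="euclidean")
        raw = fcluster(tree, t=k, criterion="maxclust")
    # relabel 1..k by descending cluster size; ties by original label
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series([remap[c] for c in raw], index=genes, name="cluster")
    return labels
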