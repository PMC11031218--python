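"""Stability-LASSO discovery of baseline genes predictive of training outcome.

The estimator is the lasso,

    (1/(2n)) * sum_i (y_i - b0 - x_i . beta)^2 + lambda * sum_j |beta_j|,

solved by cyclic coordinate descent with soft-thresholding
S(rho, lambda) = sign(rho) * max(|rho| - lambda, 0) on a standardized
design (columns centered, unit 1/n variance; outcome centered).  The
penalty is chosen per fit by 5-fold cross-validation over a log-spaced
lambda path starting at lambda_max = max_j |x_j . y| / n.

Stability selection here means: split the cohort into stratified 50/50
train/test halves many times; on each train half fit a CV-tuned lasso of
Matsuda fold change on baseline expression; call the model successful when
its test-half predictions land within 10% of the measured outcome for at
least half of the test subjects; and rank genes by how often successful
models give them a nonzero coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from responderomics.errors import ConfigError, DataError, DesignError
from responderomics.io_formats import SampleSheet

logger = logging.getLogger(__name__)

CD_TOL = 1e-7
CD_MAX_SWEEPS = 100_000
KKT_TOL = 1e-6


# ---------------------------------------------------------------------------
# design standardization
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Standardized subjects x genes design with its transformation record."""

    X: np.ndarray  # standardized columns, 1/n variance 1
    y: np.ndarray  # centered outcome
    gene_ids: list[str]
    subject_ids: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    dropped: list[str] = field(default_factory=list)

    @property
    def XT(self) -> np.ndarray:
        """p x n contiguous transpose, cached for the solver kernel."""
        if not hasattr(self, "_XT"):
            self._XT = np.ascontiguousarray(self.X.T)
        return self._XT

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def transform(self, X_new: pd.DataFrame) -> np.ndarray:
        """Apply the frozen standardization to new subjects (no refitting)."""
        sub = X_new[self.gene_ids].to_numpy(dtype=float)
        return (sub - self.x_mean) / self.x_scale


def standardize(X: pd.DataFrame, y: pd.Series) -> DesignMatrix:
    """Center/scale each gene to unit 1/n variance and center the outcome.

    Constant genes are dropped with a warning; an all-constant design is an
    error.  The transformation is recorded so coefficients can be mapped
    back to the original scale and test subjects can be projected without
    leakage.
    """
    if len(X) < 2:
        raise DataError(f"standardize needs >= 2 subjects, got {len(X)}")
    if not X.index.equals(y.index):
        y = y.loc[X.index]
    vals = X.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    scale = vals.std(axis=0)  # ddof=0: the 1/n convention
    keep = scale > 1e-12 * np.maximum(1.0, np.abs(mean))
    dropped = [g for g, k in zip(X.columns, keep) if not k]
    if dropped:
        logger.warning("standardize: dropped %d constant gene(s): %s", len(dropped), dropped[:5])
    if not keep.any():
        raise DataError("all genes constant across subjects; nothing to standardize")
    Xs = (vals[:, keep] - mean[keep]) / scale[keep]
    y_arr = y.to_numpy(dtype=float)
    y_mean = float(y_arr.mean())
    return DesignMatrix(
        X=np.ascontiguousarray(Xs),
        y=y_arr - y_mean,
        gene_ids=[g for g, k in zip(X.columns, keep) if k],
        subject_ids=list(X.index),
        x_mean=mean[keep],
        x_scale=scale[keep],
        y_mean=y_mean,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# coordinate descent
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cd_kernel(XT, y, beta, lam, tol, max_sweeps):  # pragma: no cover - jitted
    """Cyclic coordinate descent on a standardized design.

    ``XT`` is the p x n transposed design so each coordinate's data are
    contiguous.  Passes alternate glmnet-style between full sweeps and
    sweeps over the current active set (nonzero coefficients); convergence
    is declared only when a full sweep moves no coefficient by >= tol.
    """
    p, n = XT.shape
    r = y.copy()
    for j in range(p):
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                r[i] -= bj * XT[j, i]
    sweeps = 0
    converged = False
    full = True
    while sweeps < max_sweeps:
        sweeps += 1
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            if not full and bj == 0.0:
                continue
            s = 0.0
            for i in range(n):
                s += XT[j, i] * r[i]
            rho = bj + s / n
            if rho > lam:
                bnew = rho - lam
            elif rho < -lam:
                bnew = rho + lam
            else:
                bnew = 0.0
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * XT[j, i]
                beta[j] = bnew
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            if full:
                converged = True
                break
            full = True  # active set stable; verify with a full sweep
        else:
            full = False  # polish the active set before rescanning
    return sweeps, converged


@dataclass
class LassoFit:
    """One converged lasso solution, on both scales."""

    lambda_: float
    gene_ids: list[str]
    coef_std: np.ndarray  # standardized scale
    coef: np.ndarray  # original scale
    intercept: float
    n_iter: int
    converged: bool
    kkt_violation: float

    def nonzero_genes(self) -> list[str]:
        return [g for g, b in zip(self.gene_ids, self.coef_std) if b != 0.0]

    def predict_std(self, X_std: np.ndarray, y_mean: float) -> np.ndarray:
        return y_mean + X_std @ self.coef_std


def _kkt_violation(design: DesignMatrix, beta: np.ndarray, lam: float) -> float:
    """Max violation of the lasso stationarity conditions at (beta, lam)."""
    n = design.n
    r = design.y - design.X @ beta
    grad = design.X.T @ r / n
    active = beta != 0.0
    viol_zero = np.maximum(np.abs(grad[~active]) - lam, 0.0)
    viol_active = np.abs(grad[active] - lam * np.sign(beta[active]))
    parts = [v.max() for v in (viol_zero, viol_active) if v.size]
    return float(max(parts)) if parts else 0.0


def lasso_fit(
    design: DesignMatrix,
    lam: float,
    *,
    warm_start: np.ndarray | None = None,
    tol: float = CD_TOL,
    max_sweeps: int = CD_MAX_SWEEPS,
) -> LassoFit:
    """Cyclic coordinate descent at one penalty value.

    Deterministic given the design and lambda.  Non-convergence is flagged
    and logged but the fit is still returned.
    """
    if lam < 0:
        raise ConfigError(f"lambda must be >= 0, got {lam}")
    beta = np.zeros(design.p) if warm_start is None else warm_start.astype(float).copy()
    n_iter, converged = _cd_kernel(design.XT, design.y, beta, lam, tol, max_sweeps)
    if not converged:
        logger.warning("lasso_fit: no convergence at lambda=%g after %d sweeps", lam, n_iter)
    coef = beta / design.x_scale
    intercept = design.y_mean - float(coef @ design.x_mean)
    return LassoFit(
        lambda_=float(lam),
        gene_ids=list(design.gene_ids),
        coef_std=beta,
        coef=coef,
        intercept=intercept,
        n_iter=n_iter,
        converged=converged,
        kkt_violation=_kkt_violation(design, beta, lam),
    )


@njit(cache=True)
def _lambda_max_kernel(XT, y):  # pragma: no cover - jitted
    # same loop order as _cd_kernel so rho == lambda_max compares exactly
    p, n = XT.shape
    best = 0.0
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += XT[j, i] * y[i]
        a = abs(s) / n
        if a > best:
            best = a
    return best


def lambda_path(design: DesignMatrix, n_lambda: int = 100, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced descending penalty sequence from lambda_max down.

    lambda_max = max_j |x_j . y| / n is the smallest penalty at which the
    all-zero model is optimal; it is computed with the solver's own
    reduction so the first path entry yields the exactly-zero model.  A
    centered outcome of exactly zero yields the degenerate path [0].
    """
    lam_max = float(_lambda_max_kernel(design.XT, design.y))
    if lam_max == 0.0:
        return np.array([0.0])
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def fit_path(design: DesignMatrix, lambdas: np.ndarray) -> np.ndarray:
    """Warm-started coefficient matrix (len(lambdas) x p), standardized scale."""
    betas = np.zeros((len(lambdas), design.p))
    beta = np.zeros(design.p)
    for i, lam in enumerate(lambdas):
        _cd_kernel(design.XT, design.y, beta, float(lam), CD_TOL, CD_MAX_SWEEPS)
        betas[i] = beta
    return betas


def cv_lambda(
    design: DesignMatrix,
    k: int = 5,
    seed: int = 0,
    *,
    n_lambda: int = 100,
    ratio: float = 0.01,
    rule: str = "min",
) -> float:
    """Pick lambda by k-fold cross-validation over the shared path.

    Subjects are partitioned into k folds (sizes differing by at most 1,
    seeded shuffle).  For every lambda of the path computed on the full
    design, the mean held-out squared error is accumulated over folds;
    ``rule="min"`` returns the minimizer (ties go to the larger lambda),
    ``rule="1se"`` the largest lambda within one standard error of it.
    """
    n = design.n
    if k > n:
        raise ConfigError(f"cannot make {k} folds from {n} subjects")
    if k < 2:
        raise ConfigError("cross-validation needs k >= 2")
    if rule not in ("min", "1se"):
        raise ConfigError(f"unknown CV rule {rule!r}")
    lambdas = lambda_path(design, n_lambda=n_lambda, ratio=ratio)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    sq_err = np.zeros((len(lambdas), n))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        XT_tr = np.ascontiguousarray(design.X[mask].T)
        y_tr = design.y[mask]
        X_te, y_te = design.X[fold], design.y[fold]
        off = float(y_tr.mean())  # fold-level intercept on the centered outcome
        y_tr = y_tr - off
        beta = np.zeros(design.p)
        for i, lam in enumerate(lambdas):
            _cd_kernel(XT_tr, y_tr, beta, float(lam), CD_TOL, CD_MAX_SWEEPS)
            sq_err[i, fold] = (y_te - off - X_te @ beta) ** 2
    cv_mean = sq_err.mean(axis=1)
    i_min = int(np.argmin(cv_mean))  # first occurrence = largest lambda on ties
    if rule == "1se":
        se = sq_err[i_min].std(ddof=1) / math.sqrt(n)
        within = np.flatnonzero(cv_mean <= cv_mean[i_min] + se)
        i_min = int(within[0])
    return float(lambdas[i_min])


# ---------------------------------------------------------------------------
# cohort splitting and the model-success rule
# ---------------------------------------------------------------------------


def split_cohort(sheet: SampleSheet, seed: int) -> tuple[list[str], list[str]]:
    """Stratified 50/50 split of subjects into train and test halves.

    Within each responder group, floor(size/2) or ceil(size/2) subjects go
    to train; which group takes the ceiling alternates with seed parity so
    the overall train/test sizes stay balanced (7 LRE + 11 RES always
    yields 9/9).  The partition is disjoint and exhaustive.
    """
    groups = sheet.subject_group()
    by_group: dict[str, list[str]] = {}
    for subj, grp in groups.items():
        by_group.setdefault(grp, []).append(subj)
    if len(by_group) < 2:
        raise DesignError(f"split needs both responder groups, found {sorted(by_group)}")
    for grp, members in by_group.items():
        if len(members) < 2:
            raise DesignError(f"group {grp} has {len(members)} subject(s); cannot split")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for gi, grp in enumerate(sorted(by_group)):
        members = sorted(by_group[grp])
        perm = rng.permutation(len(members))
        half = len(members) / 2
        n_train = math.ceil(half) if (seed + gi) % 2 == 0 else math.floor(half)
        chosen = set(perm[:n_train])
        train += [m for i, m in enumerate(members) if i in chosen]
        test += [m for i, m in enumerate(members) if i not in chosen]
    return sorted(train), sorted(test)


def model_success(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    tol: float = 0.10,
    min_frac: float = 0.5,
) -> tuple[bool, np.ndarray]:
    """The 10%/50% success rule for one train/test iteration.

    Test subject i is "within" iff |yhat_i - y_i| <= tol * |y_i|; the model
    is successful iff at least ``min_frac`` of test subjects are within.
    Both boundaries are inclusive.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise DataError("empty test set")
    if y_true.shape != y_pred.shape:
        raise DataError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    within = np.abs(y_pred - y_true) <= tol * np.abs(y_true)
    return bool(within.mean() >= min_frac), within


# ---------------------------------------------------------------------------
# the stability loop
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """Selection frequencies across successful models, plus replay logs."""

    n_iterations: int
    n_successful: int
    gene_table: pd.DataFrame  # index gene_id: selection_count, frequency_percent, mean_abs_coef
    iterations: pd.DataFrame  # per-iteration log

    def to_frame(self) -> pd.DataFrame:
        return self.gene_table


def _child_seed(master_seed: int, i: int) -> int:
    """Deterministic per-iteration integer seed (counter scheme)."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(1)[0] & 0x7FFFFFFF)


def stability_run(
    X: pd.DataFrame,
    y: pd.Series,
    sheet: SampleSheet,
    n_iter: int = 1000,
    master_seed: int = 0,
    *,
    tol: float = 0.10,
    min_frac: float = 0.5,
    cv_folds: int = 5,
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
    cv_rule: str = "min",
) -> StabilityResult:
    """Repeated split / CV-lasso / success-filter loop.

    ``X`` is the subjects x genes baseline-expression design (rows indexed
    by subject id), ``y`` the Matsuda fold change per subject.  Each
    iteration derives a child seed from ``master_seed``, splits the cohort,
    standardizes on the training half only, tunes lambda by ``cv_folds``-fold
    CV, refits on the full training half, predicts the test half through
    the frozen training standardization, and applies the success rule.
    Gene counts accumulate over successful models only.
    """
    if n_iter < 1:
        raise ConfigError(f"n_iter must be >= 1, got {n_iter}")
    subjects = set(sheet.subjects)
    if set(X.index) != subjects:
        raise DataError("design rows do not match the subjects in the sample sheet")
    y = y.loc[X.index]
    genes = list(X.columns)
    counts = pd.Series(0, index=genes, dtype=int)
    abs_coef_sum = pd.Series(0.0, index=genes)
    log_rows = []
    n_successful = 0
    for i in range(n_iter):
        seed_i = _child_seed(master_seed, i)
        train, test = split_cohort(sheet, seed_i)
        success = False
        lam = math.nan
        n_within = -1
        selected: list[str] = []
        try:
            design = standardize(X.loc[train], y.loc[train])
            lam = cv_lambda(
                design, k=cv_folds, seed=seed_i, n_lambda=n_lambda,
                ratio=lambda_ratio, rule=cv_rule,
            )
            lambdas = lambda_path(design, n_lambda=n_lambda, ratio=lambda_ratio)
            path_to_lam = lambdas[lambdas >= lam - 1e-15]
            betas = fit_path(design, path_to_lam)
            fit = lasso_fit(design, lam, warm_start=betas[-1])
            X_te = design.transform(X.loc[test])
            y_pred = fit.predict_std(X_te, design.y_mean)
            success, within = model_success(y.loc[test].to_numpy(), y_pred, tol, min_frac)
            n_within = int(within.sum())
            if success:
                n_successful += 1
                selected = fit.nonzero_genes()
                for g, b in zip(fit.gene_ids, fit.coef_std):
                    if b != 0.0:
                        counts[g] += 1
                        abs_coef_sum[g] += abs(b)
        except DataError as exc:
            logger.warning("iteration %d failed (%s); counted unsuccessful", i, exc)
        log_rows.append(
            {
                "iteration": i,
                "seed": seed_i,
                "train_ids": ";".join(train),
                "lambda": lam,
                "success": success,
                "n_within": n_within,
                "n_test": len(test),
                "n_selected": len(selected),
            }
        )
    freq = counts / n_successful * 100.0 if n_successful else counts * 0.0
    mean_abs = abs_coef_sum / counts.where(counts > 0, 1)
    mean_abs[counts == 0] = 0.0
    gene_table = pd.DataFrame(
        {
            "selection_count": counts,
            "frequency_percent": freq,
            "mean_abs_coef": mean_abs,
        },
    )
    gene_table.index.name = "gene_id"
    return StabilityResult(
        n_iterations=n_iter,
        n_successful=n_successful,
        gene_table=gene_table,
        iterations=pd.DataFrame(log_rows),
    )


def top_markers(result: StabilityResult, n: int = 20) -> pd.DataFrame:
    """Top-n genes by selection frequency among successful models.

    Ties are broken by descending mean absolute standardized coefficient,
    then by gene id.  Raises when no model was successful.
    """
    if result.n_successful == 0:
        raise DataError("no successful models; cannot rank markers")
    tab = result.gene_table
    order = sorted(
        tab.index,
        key=lambda g: (-tab.at[g, "frequency_percent"], -tab.at[g, "mean_abs_coef"], g),
    )
    ranked = tab.loc[order[: max(n, 0)]].copy()
    ranked.insert(0, "rank", range(1, len(ranked) + 1))
    return ranked
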