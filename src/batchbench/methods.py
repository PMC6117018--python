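"""Per-gene association testing under four batch-handling strategies.

All fitters operate on a genes x samples value matrix and a per-sample
covariate, vectorized across genes:

* ``fit_lm`` — ordinary least squares of each gene on the covariate,
  ignoring batch (the uncorrected control);
* ``fit_lm_batch`` — OLS with batch indicator columns (fixed effects,
  equivalent to a genewise one-way ANOVA adjustment);
* ``fit_lmm`` — random-intercept mixed model, each batch contributing an
  additive N(0, sigma_u^2) shift, fitted by maximum likelihood through a
  one-dimensional profile over the variance ratio;
* ``eb_batch_adjust`` — parametric empirical-Bayes location/scale batch
  adjustment (standardize per gene, estimate per-(gene,batch) shifts and
  scale factors, shrink toward normal / inverse-gamma priors, remove),
  followed by plain OLS on the adjusted values.

Thin per-gene wrappers (``fit_gene_lm`` etc.) return a ``GeneFit`` for a
single response vector.  ``denoise_matrix`` turns a fitted batch structure
back into a corrected matrix for the diagnostic analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ExpressionMatrix

__all__ = [
    "GeneFit",
    "FitTable",
    "EBAdjustment",
    "fit_lm",
    "fit_lm_batch",
    "fit_lmm",
    "eb_batch_adjust",
    "fit_gene_lm",
    "fit_gene_lm_batch",
    "fit_gene_lmm",
    "fit_gene_lm_on_adjusted",
    "denoise_matrix",
]


@dataclass
class GeneFit:
    slope: float
    intercept: float
    p_value: float
    batch_variance: float = 0.0
    residual_variance: float = 0.0
    converged: bool = True


@dataclass
class FitTable:
    """Vectorized per-gene fit results (arrays aligned to the gene axis)."""

    slope: np.ndarray
    intercept: np.ndarray
    p_value: np.ndarray
    batch_variance: np.ndarray
    residual_variance: np.ndarray
    converged: np.ndarray

    def gene(self, i: int) -> GeneFit:
        return GeneFit(float(self.slope[i]), float(self.intercept[i]),
                       float(self.p_value[i]), float(self.batch_variance[i]),
                       float(self.residual_variance[i]), bool(self.converged[i]))

    def to_frame(self, gene_ids, method: str) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": gene_ids, "method": method, "beta1": self.slope,
            "p_value": self.p_value, "converged": self.converged,
        })


# ---------------------------------------------------------------------------
# OLS


def _ols(Y: np.ndarray, X: np.ndarray, slope_col: int) -> FitTable:
    """OLS of every row of Y on design X; t-test on column ``slope_col``."""
    m, p = X.shape
    if m <= p:
        raise ValueError(f"need more samples ({m}) than parameters ({p})")
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        raise ValueError("design matrix is rank-deficient (collinear columns)")
    XtXinv = np.linalg.inv(XtX)
    beta = Y @ X @ XtXinv.T                      # w x p
    resid = Y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / (m - p)
    se = np.sqrt(np.maximum(s2 * XtXinv[slope_col, slope_col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, slope_col] / se, np.inf * np.sign(beta[:, slope_col]))
        t = np.where((se == 0) & (beta[:, slope_col] == 0), 0.0, t)
    pvals = 2.0 * sps.t.sf(np.abs(t), df=m - p)
    return FitTable(
        slope=beta[:, slope_col],
        intercept=beta[:, 0],
        p_value=pvals,
        batch_variance=np.zeros(Y.shape[0]),
        residual_variance=s2,
        converged=np.ones(Y.shape[0], dtype=bool),
    )


def fit_lm(Y: np.ndarray, covariate: np.ndarray) -> FitTable:
    """Per-gene OLS on the covariate with intercept, no batch term."""
    covariate = np.asarray(covariate, float)
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant; slope is not identifiable")
    Y = np.atleast_2d(np.asarray(Y, float))
    X = np.column_stack([np.ones_like(covariate), covariate])
    return _ols(Y, X, slope_col=1)


def _batch_dummies(batch: np.ndarray) -> tuple[np.ndarray, list]:
    labels = list(pd.unique(pd.Series(batch)))
    idx = pd.Index(labels).get_indexer(batch)
    D = np.zeros((len(batch), len(labels) - 1))
    for j in range(1, len(labels)):
        D[idx == j, j - 1] = 1.0
    return D, labels


def fit_lm_batch(Y: np.ndarray, covariate: np.ndarray,
                 batch: np.ndarray) -> FitTable:
    """Per-gene OLS on the covariate plus batch fixed effects.

    With a single batch the dummies vanish and the fit is identical to
    ``fit_lm``.  A covariate collinear with the batch indicators (fully
    confounded design) raises rather than reporting spurious slopes.
    """
    covariate = np.asarray(covariate, float)
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant; slope is not identifiable")
    Y = np.atleast_2d(np.asarray(Y, float))
    D, _ = _batch_dummies(np.asarray(batch))
    X = np.column_stack([np.ones_like(covariate), covariate, D])
    return _ols(Y, X, slope_col=1)


# ---------------------------------------------------------------------------
# Random-intercept LMM by 1-D profile maximum likelihood

_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-8, 8, 49)])


class _ProfileLMM:
    """Profile ML machinery for y = X beta + u_batch + eps, u ~ N(0, lam*s2).

    For the block covariance V = I + lam * J (per batch), Woodbury gives
    ``a' V^-1 b = a'b - sum_j c_j (sum_j a)(sum_j b)`` with
    ``c_j = lam / (1 + n_j lam)``, so all per-gene quantities reduce to
    per-batch sums and the profile deviance can be evaluated for every gene
    at once, with a gene-specific variance ratio.
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, batch: np.ndarray):
        self.Y = Y
        self.X = X
        self.m, self.p = X.shape
        idx = pd.Index(pd.unique(pd.Series(batch))).get_indexer(batch)
        self.n_batches = idx.max() + 1
        self.nj = np.bincount(idx).astype(float)          # (b,)
        # per-batch sums
        onehot = np.zeros((self.m, self.n_batches))
        onehot[np.arange(self.m), idx] = 1.0
        self.SX = onehot.T @ X                            # b x p
        self.SY = Y @ onehot                              # w x b
        self.XtX = X.T @ X                                # p x p
        self.XtY = Y @ X                                  # w x p
        self.yy = np.einsum("ij,ij->i", Y, Y)             # (w,)

    def profile(self, lam: np.ndarray):
        """Deviance and GLS quantities at a per-gene variance ratio ``lam``.

        Returns (deviance, beta, var_beta_unit, rss_v) where ``var_beta_unit``
        is ``(X'V^-1 X)^{-1}`` rows for the slope, per gene.
        """
        lam = np.asarray(lam, float)
        c = lam[:, None] * (1.0 / (1.0 + self.nj[None, :] * lam[:, None]))  # w x b
        A = self.XtX[None] - np.einsum("gj,jp,jq->gpq", c, self.SX, self.SX)
        r = self.XtY - np.einsum("gj,gj,jp->gp", c, self.SY, self.SX)
        q = self.yy - np.einsum("gj,gj->g", c, self.SY ** 2)
        beta = np.linalg.solve(A, r[..., None])[..., 0]    # w x p
        rss = q - np.einsum("gp,gp->g", beta, r)
        rss = np.maximum(rss, 1e-300)
        logdet = np.log1p(self.nj[None, :] * lam[:, None]).sum(axis=1)
        dev = self.m * np.log(rss / self.m) + logdet
        Ainv = np.linalg.inv(A)
        return dev, beta, Ainv, rss

    def fit_lambda(self, refine_iters: int = 35) -> np.ndarray:
        """Per-gene ML variance ratio: coarse grid then golden-section."""
        w = self.Y.shape[0]
        devs = np.empty((len(_LAMBDA_GRID), w))
        for k, lam in enumerate(_LAMBDA_GRID):
            devs[k], _, _, _ = self.profile(np.full(w, lam))
        best = devs.argmin(axis=0)
        # golden-section refinement between grid neighbours, in log space
        eps = 1e-12
        lo = _LAMBDA_GRID[np.maximum(best - 1, 0)]
        hi = _LAMBDA_GRID[np.minimum(best + 1, len(_LAMBDA_GRID) - 1)]
        a = np.log(lo + eps)
        bnd = np.log(hi + eps)
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        for _ in range(refine_iters):
            x1 = bnd - invphi * (bnd - a)
            x2 = a + invphi * (bnd - a)
            f1, _, _, _ = self.profile(np.maximum(np.exp(x1) - eps, 0.0))
            f2, _, _, _ = self.profile(np.maximum(np.exp(x2) - eps, 0.0))
            take1 = f1 < f2
            bnd = np.where(take1, x2, bnd)
            a = np.where(take1, a, x1)
        lam_hat = np.maximum(np.exp((a + bnd) / 2.0) - eps, 0.0)
        # snap near-boundary solutions to exactly zero (OLS limit)
        lam_hat[lam_hat < 1e-10] = 0.0
        return lam_hat

    def fit(self, refine_iters: int = 35) -> tuple[np.ndarray, FitTable]:
        lam_hat = self.fit_lambda(refine_iters)
        dev, beta, Ainv, rss = self.profile(lam_hat)
        s2 = rss / (self.m - self.p)  # df-corrected residual variance for the Wald test
        se = np.sqrt(np.maximum(s2 * Ainv[:, 1, 1], 0.0))
        slope = beta[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
            t = np.where((se == 0) & (slope == 0), 0.0, t)
        pvals = 2.0 * sps.t.sf(np.abs(t), df=self.m - self.p)
        ok = np.isfinite(pvals) & np.isfinite(slope)
        pvals = np.where(ok, pvals, np.nan)
        return lam_hat, FitTable(
            slope=slope, intercept=beta[:, 0], p_value=pvals,
            batch_variance=lam_hat * rss / self.m,
            residual_variance=rss / self.m,
            converged=ok,
        )


def fit_lmm(Y: np.ndarray, covariate: np.ndarray, batch: np.ndarray,
            refine_iters: int = 40) -> FitTable:
    """Per-gene random-intercept mixed model by profile maximum likelihood.

    The variance ratio ``sigma_u^2 / sigma^2`` is profiled on a coarse grid
    followed by golden-section refinement (both vectorized across genes);
    the boundary ``sigma_u^2 = 0`` is allowed, where the fit reduces exactly
    to OLS.  Inference is a Wald t-test on the slope with m - 2 degrees of
    freedom and a df-corrected residual variance, so the boundary case
    matches ``fit_lm`` to machine precision.
    """
    covariate = np.asarray(covariate, float)
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant; slope is not identifiable")
    Y = np.atleast_2d(np.asarray(Y, float))
    batch = np.asarray(batch)
    if len(pd.unique(pd.Series(batch))) < 2:
        raise ValueError("random intercept needs >= 2 batches")
    X = np.column_stack([np.ones_like(covariate), covariate])
    if Y.shape[1] != X.shape[0]:
        raise ValueError("Y columns must match covariate length")
    _, table = _ProfileLMM(Y, X, batch).fit(refine_iters)
    return table


# ---------------------------------------------------------------------------
# Parametric empirical-Bayes batch adjustment


@dataclass
class EBAdjustment:
    """Estimated and shrunken per-(gene, batch) batch effects.

    ``gamma_star``/``delta_star`` are the posterior location shifts and
    scale factors actually removed (batches x genes); ``gamma_hat``/
    ``delta_hat`` the unshrunk per-batch estimates; priors are per batch.
    """

    batches: list
    gamma_star: np.ndarray
    delta_star: np.ndarray
    gamma_hat: np.ndarray
    delta_hat: np.ndarray
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    pooled_mean: np.ndarray
    pooled_var: np.ndarray
    n_iterations: np.ndarray
    floored_genes: np.ndarray


def _eb_iterate(s_data: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                g_bar: float, t2: float, a: float, b: float, n: int,
                tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Coupled posterior-mean iteration for one batch (all genes at once)."""
    g_old, d_old = g_hat.copy(), d_hat.copy()
    count = 0
    change = np.inf
    while change > tol and count < max_iter:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                         np.max(np.abs(d_new - d_old) / np.abs(d_old)))
        g_old, d_old = g_new, d_new
        count += 1
    return g_old, d_old, count


def eb_batch_adjust(Y: np.ndarray, batch: np.ndarray, tol: float = 1e-4,
                    max_iter: int = 100) -> tuple[np.ndarray, EBAdjustment]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Steps: (1) per gene, estimate batch means by least squares and pool the
    residual variance; standardize.  (2) per (gene, batch), estimate the
    location shift (batch mean of standardized data) and scale factor
    (within-batch sample variance).  (3) shrink locations toward a normal
    prior and scales toward an inverse-gamma prior, hyperparameters by
    method of moments, iterating the coupled posterior equations.
    (4) remove the shrunken effects and restore the pooled scale and mean.

    The design matrix is intercept-only: no covariate is protected, so the
    adjustment is strictly a pre-processing step before association testing.
    A single-batch input is returned unchanged.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if not np.all(np.isfinite(Y)):
        raise ValueError("input matrix contains non-finite values")
    batch = np.asarray(batch)
    labels = list(pd.unique(pd.Series(batch)))
    w, m = Y.shape
    if len(labels) == 1:
        adj = EBAdjustment(labels, np.zeros((1, w)), np.ones((1, w)),
                           np.zeros((1, w)), np.ones((1, w)),
                           np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1),
                           Y.mean(axis=1), Y.var(axis=1),
                           np.zeros(1, int), np.zeros(w, dtype=bool))
        return Y.copy(), adj
    idx = pd.Index(labels).get_indexer(batch)
    nj = np.bincount(idx)
    if np.any(nj < 2):
        bad = [labels[j] for j in np.flatnonzero(nj < 2)]
        raise ValueError(f"batch(es) with <= 1 sample cannot be adjusted: {bad}")

    onehot = np.zeros((m, len(labels)))
    onehot[np.arange(m), idx] = 1.0
    batch_means = (Y @ onehot) / nj                       # w x b
    grand = batch_means @ (nj / m)                        # size-weighted pooled mean
    fitted = batch_means[:, idx]
    pooled_var = ((Y - fitted) ** 2).mean(axis=1)
    pooled_sd = np.sqrt(pooled_var)
    zero_var = pooled_sd <= 0
    safe_sd = np.where(zero_var, 1.0, pooled_sd)
    s_data = (Y - grand[:, None]) / safe_sd[:, None]

    b_n = len(labels)
    gamma_hat = np.empty((b_n, w))
    delta_hat = np.empty((b_n, w))
    for j in range(b_n):
        block = s_data[:, idx == j]
        gamma_hat[j] = block.mean(axis=1)
        delta_hat[j] = block.var(axis=1, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = np.where(d_var > 0, (2 * d_var + d_mean ** 2) / d_var, np.inf)
        b_prior = np.where(d_var > 0,
                           (d_mean * d_var + d_mean ** 3) / d_var, np.inf)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    iters = np.zeros(b_n, dtype=int)
    for j in range(b_n):
        if not (np.isfinite(a_prior[j]) and tau2[j] > 0):
            # degenerate prior (e.g. too few genes): no shrinkage
            gamma_star[j], delta_star[j] = gamma_hat[j], delta_hat[j]
            continue
        gamma_star[j], delta_star[j], iters[j] = _eb_iterate(
            s_data[:, idx == j], gamma_hat[j], delta_hat[j],
            gamma_bar[j], tau2[j], a_prior[j], b_prior[j], int(nj[j]),
            tol, max_iter)
    # zero within-batch variance cannot be scale-adjusted meaningfully:
    # flag those genes and keep the posterior scale away from zero
    flagged = (delta_hat <= 0).any(axis=0) | (delta_star < 1e-8).any(axis=0)
    delta_star = np.maximum(delta_star, 1e-8)

    adjusted = ((s_data - gamma_star[idx].T.reshape(w, m))
                / np.sqrt(delta_star)[idx].T.reshape(w, m))
    adjusted = adjusted * safe_sd[:, None] + grand[:, None]
    adjusted[zero_var] = Y[zero_var]

    adj = EBAdjustment(labels, gamma_star, delta_star, gamma_hat, delta_hat,
                       gamma_bar, tau2, a_prior, b_prior, grand, pooled_var,
                       iters, flagged)
    return adjusted, adj


# ---------------------------------------------------------------------------
# Per-gene wrappers


def fit_gene_lm(y: np.ndarray, covariate: np.ndarray) -> GeneFit:
    return fit_lm(np.asarray(y, float)[None, :], covariate).gene(0)


def fit_gene_lm_batch(y: np.ndarray, covariate: np.ndarray,
                      batch: np.ndarray) -> GeneFit:
    return fit_lm_batch(np.asarray(y, float)[None, :], covariate, batch).gene(0)


def fit_gene_lmm(y: np.ndarray, covariate: np.ndarray,
                 batch: np.ndarray) -> GeneFit:
    return fit_lmm(np.asarray(y, float)[None, :], covariate, batch).gene(0)


def fit_gene_lm_on_adjusted(adjusted_row: np.ndarray,
                            covariate: np.ndarray) -> GeneFit:
    return fit_gene_lm(adjusted_row, covariate)


# ---------------------------------------------------------------------------
# Denoising


def denoise_matrix(matrix: ExpressionMatrix, method: str,
                   batch: np.ndarray | None = None) -> ExpressionMatrix:
    """Remove the fitted batch structure from a matrix.

    ``lm_batch`` subtracts per-gene batch means re-centered so each gene's
    overall mean is preserved; ``lmm`` subtracts per-gene predicted random
    intercepts (batch means shrunken by the estimated variance ratio);
    ``eb`` returns the empirical-Bayes-adjusted matrix.
    """
    Y = matrix.values.to_numpy()
    if batch is None:
        batch = matrix.samples["batch"].to_numpy()
    labels = list(pd.unique(pd.Series(batch)))
    idx = pd.Index(labels).get_indexer(batch)
    if method == "eb":
        adjusted, _ = eb_batch_adjust(Y, batch)
    elif method == "lm_batch":
        nj = np.bincount(idx)
        onehot = np.zeros((len(batch), len(labels)))
        onehot[np.arange(len(batch)), idx] = 1.0
        bm = (Y @ onehot) / nj
        overall = bm @ (nj / len(batch))
        adjusted = Y - bm[:, idx] + overall[:, None]
    elif method == "lmm":
        X = np.ones((Y.shape[1], 1))
        lam = _ProfileLMM(Y, X, batch).fit_lambda()
        nj = np.bincount(idx).astype(float)
        onehot = np.zeros((len(batch), len(labels)))
        onehot[np.arange(len(batch)), idx] = 1.0
        # GLS mean under the fitted variance ratio, then BLUP shrinkage
        c = lam[:, None] / (1.0 + nj[None, :] * lam[:, None])
        sums = Y @ onehot
        denom = len(batch) - (c * nj[None, :] ** 2).sum(axis=1)
        mu = (Y.sum(axis=1) - (c * nj[None, :] * sums).sum(axis=1)) / denom
        shrink = (nj[None, :] * lam[:, None]) / (1.0 + nj[None, :] * lam[:, None])
        blup = shrink * (sums / nj[None, :] - mu[:, None])
        adjusted = Y - blup[:, idx]
    else:
        raise ValueError(f"unknown denoising method {method!r}")
    return ExpressionMatrix(
        pd.DataFrame(adjusted, index=matrix.gene_ids,
                     columns=matrix.values.columns),
        matrix.samples,
    )
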