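"""Per-gene ANOVA / ANCOVA fits on a shared design.

The baseline model for gene g and sample s is

    y_gs = a_g + d_g * 1[variety(s) = 2] + e_gs,

a reparameterisation of the classical gene + variety + gene-by-variety
two-way layout in which the testable differential-expression effect is the
gene-specific contrast d_g.  The ANCOVA variant appends K surrogate score
vectors t_1..t_K with gene-specific coefficients phi_g1..phi_gK:

    y_gs = a_g + d_g * 1[variety(s) = 2] + sum_l phi_gl t_ls + e_gs.

All genes share one design matrix, so the per-gene least-squares problems
collapse into a single multi-right-hand-side solve; the error variance is
pooled across genes (one sigma^2, one AIC per candidate model).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GroupDesign, LinearFit
from .exceptions import (
    CollinearScoreError,
    DegenerateDesignError,
    DimensionMismatchError,
    ZeroRssError,
)
from .fdr import bh_adjust

__all__ = [
    "fit_anova",
    "fit_ancova",
    "model_aic",
    "gene_tests",
    "corrected_matrix",
]

#: condition-number bound above which the shared design is declared collinear
COLLINEARITY_THRESHOLD = 1e8

#: RSS below this (times the number of observations) is treated as exactly zero
_ZERO_RSS_TOL = 1e-12


def _build_design(design: GroupDesign, scores: np.ndarray) -> np.ndarray:
    n = design.n_samples
    cols = [np.ones(n), design.indicator()]
    if scores.size:
        cols.extend(scores.T)
    return np.column_stack(cols)


def _check_collinearity(X: np.ndarray) -> None:
    cond = np.linalg.cond(X)
    if cond > COLLINEARITY_THRESHOLD:
        # identify the offending column as the one whose removal restores rank
        for j in range(X.shape[1] - 1, 0, -1):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.cond(reduced) <= COLLINEARITY_THRESHOLD:
                raise CollinearScoreError(
                    f"design condition number {cond:.3g} exceeds "
                    f"{COLLINEARITY_THRESHOLD:.0e}; column {j} is collinear "
                    "with the remaining design",
                    column=j,
                )
        raise CollinearScoreError(
            f"design condition number {cond:.3g} exceeds "
            f"{COLLINEARITY_THRESHOLD:.0e}",
            column=None,
        )


def fit_ancova(
    Y: ExpressionMatrix,
    design: GroupDesign,
    scores: np.ndarray | None = None,
    n_surrogates: int | None = None,
) -> LinearFit:
    """Fit the surrogate-augmented ANCOVA (plain ANOVA when K = 0).

    Parameters
    ----------
    Y
        Log-scale expression, genes x samples.
    design
        Two-variety sample assignment; each variety needs >= 2 samples.
    scores
        Surrogate score matrix, samples x K.  ``None`` or zero columns give
        the baseline ANOVA.
    n_surrogates
        Expected K; defaults to ``scores.shape[1]`` and is validated
        against it when given.

    Returns
    -------
    LinearFit
        Per-gene coefficients, pooled variance, RSS, AIC and residuals.

    Raises
    ------
    DimensionMismatchError
        If design or score dimensions do not match the matrix.
    CollinearScoreError
        If the shared design has condition number above 1e8 (e.g. a score
        duplicating the centred variety indicator).
    """
    if design.n_samples != Y.n_samples:
        raise DimensionMismatchError(
            f"design has {design.n_samples} samples, matrix has {Y.n_samples}"
        )
    if scores is None:
        scores = np.empty((Y.n_samples, 0))
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] != Y.n_samples and scores.size:
        raise DimensionMismatchError(
            f"scores have {scores.shape[0]} rows, matrix has {Y.n_samples} samples"
        )
    k = scores.shape[1]
    if n_surrogates is not None and n_surrogates != k:
        raise DimensionMismatchError(
            f"n_surrogates={n_surrogates} but scores supply {k} columns"
        )

    X = _build_design(design, scores)
    _check_collinearity(X)

    p, n = Y.n_genes, Y.n_samples
    q = X.shape[1]  # 2 + K shared columns per gene
    # one multi-RHS least-squares solve stands in for p independent fits
    coefs, _, _, _ = np.linalg.lstsq(X, Y.values.T, rcond=None)
    fitted = (X @ coefs).T
    residuals = Y.values - fitted
    rss = float(np.sum(residuals**2))
    df_resid = p * n - p * q
    if df_resid <= 0:
        raise DegenerateDesignError(
            f"no residual degrees of freedom: {p}x{n} observations, {p * q} parameters"
        )
    sigma2 = rss / df_resid
    aic = _aic_value(rss, p, n, q)
    xtx = X.T @ X
    return LinearFit(
        n_surrogates=k,
        intercept=coefs[0],
        contrast=coefs[1],
        surrogate_coefs=coefs[2:].T.copy() if k else np.empty((p, 0)),
        sigma2=sigma2,
        df_resid=df_resid,
        rss=rss,
        aic=aic,
        residuals=residuals,
        design=X,
        xtx_inv=np.linalg.inv(xtx),
        gene_ids=Y.gene_ids,
        sample_ids=Y.sample_ids,
    )


def fit_anova(Y: ExpressionMatrix, design: GroupDesign) -> LinearFit:
    """Fit the baseline gene-by-variety ANOVA (no surrogate variables)."""
    return fit_ancova(Y, design, scores=None)


def _is_zero_rss(rss: float, n_obs: int) -> bool:
    return rss <= _ZERO_RSS_TOL * max(1.0, float(n_obs))


def _aic_value(rss: float, p: int, n: int, q: int) -> float | None:
    n_obs = p * n
    if _is_zero_rss(rss, n_obs):
        return None
    n_params = p * q + 1  # gene-specific mean parameters + pooled sigma^2
    return n_obs * np.log(rss / n_obs) + 2.0 * n_params


def model_aic(fit: LinearFit) -> float:
    """Gaussian AIC of a fit, additive constants dropped.

    AIC = N log(RSS / N) + 2 (q + 1) with N = genes * samples observations
    and q = p (2 + K) estimated mean parameters; the +1 counts the pooled
    error variance.  Dropping the 2*pi constants leaves the argmin over
    candidate K unchanged.
    """
    if fit.aic is None or _is_zero_rss(fit.rss, fit.n_genes * fit.n_samples):
        raise ZeroRssError("RSS is zero: AIC undefined for a saturated fit")
    return float(fit.aic)


def gene_tests(fit: LinearFit, fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene differential-expression t-tests with BH adjustment.

    For each gene, t_g = d_g / SE(d_g) where SE comes from the pooled error
    variance and the contrast entry of (X'X)^{-1}; two-sided p-values use a
    Student t with the pooled residual df (typically large enough to be
    effectively normal).

    Returns a frame with columns ``gene_id, estimate, se, t, p_raw, p_adj,
    significant`` (significant means adjusted p <= fdr).
    """
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    if _is_zero_rss(fit.rss, fit.n_genes * fit.n_samples):
        raise ZeroRssError("RSS is zero: no error variance to test against")
    se = float(np.sqrt(fit.sigma2 * fit.xtx_inv[1, 1]))
    t = fit.contrast / se
    p_raw = 2.0 * stats.t.sf(np.abs(t), df=fit.df_resid)
    p_adj, reject = bh_adjust(p_raw, fdr)
    return pd.DataFrame(
        {
            "gene_id": list(fit.gene_ids),
            "estimate": fit.contrast,
            "se": se,
            "t": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": reject,
        }
    )


def corrected_matrix(
    fit: LinearFit, Y: ExpressionMatrix, scores: np.ndarray | None = None
) -> ExpressionMatrix:
    """Expression matrix with the estimated hidden effect removed.

    Subtracts H with ``H[g, s] = sum_l phi_gl t_ls``; by construction
    Y = corrected + H exactly.  With K = 0 the matrix is returned unchanged.
    """
    if scores is None:
        scores = fit.design[:, 2:]
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (Y.n_samples, fit.n_surrogates):
        raise DimensionMismatchError(
            f"scores shape {scores.shape} does not match "
            f"({Y.n_samples}, {fit.n_surrogates})"
        )
    if fit.n_surrogates == 0:
        return Y
    hidden = fit.surrogate_coefs @ scores.T
    return ExpressionMatrix(
        values=Y.values - hidden, gene_ids=Y.gene_ids, sample_ids=Y.sample_ids
    )
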