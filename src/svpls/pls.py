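"""NIPALS partial least squares on the ANOVA residual matrix.

Latent sample-level heterogeneity (batch membership, demographic or
environmental factors) leaves a shared low-rank imprint on the residuals of
the baseline gene-by-variety ANOVA.  The nonlinear iterative partial least
squares (NIPALS) algorithm extracts that structure one component at a time:
alternating weight/score updates converge to the dominant singular direction
of X'Y, after which both blocks are deflated and the next component is
extracted from what remains.

The per-sample score vectors are the surrogate-variable candidates fed to
the ANCOVA.  Everything here is deterministic: initialisation uses the
response column of largest variance and a fixed sign convention, so repeated
runs on identical input agree bit for bit.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import ExpressionMatrix, GroupDesign, PlsDecomposition
from .exceptions import (
    DimensionMismatchError,
    NonConvergenceWarning,
    NoResidualVariationError,
    NoVariationError,
    RankLimitError,
)
from .linear_model import fit_anova

__all__ = ["center_columns", "nipals", "extract_scores"]

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 500


def center_columns(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract column means; return the centred matrix and the means."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise DimensionMismatchError("need a 2-d matrix with at least 2 rows")
    means = M.mean(axis=0)
    return M - means, means


def nipals(
    X: np.ndarray,
    Yresp: np.ndarray,
    ncomp: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PlsDecomposition:
    """Extract ``ncomp`` PLS components from column-centred blocks.

    Per component: initialise u as the response column of largest variance,
    then iterate

        w = X'u / ||X'u||,   t = X w,   c = Y't / t't,   u = Y c / c'c

    until the relative L2 change of t drops below ``tol`` (or ``max_iter``
    is hit, which raises :class:`NonConvergenceWarning` but keeps the
    component).  Both blocks are then deflated: X -= t p' with p = X't/t't,
    Y -= t c'.  Components are returned in extraction order; each is signed
    so its largest-|entry| weight is positive.

    Parameters
    ----------
    X, Yresp
        Predictor and response blocks, samples in rows, both column-centred
        with the same row count.
    ncomp
        Number of components, ``1 <= ncomp <= min(rows - 1, X columns)``.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Yresp, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise DimensionMismatchError(
            f"X has {X.shape[0]} rows, response has {Y.shape[0]}"
        )
    n = X.shape[0]
    if not 1 <= ncomp <= min(n - 1, X.shape[1]):
        raise RankLimitError(
            f"ncomp={ncomp} outside [1, min(rows - 1, cols)] = "
            f"[1, {min(n - 1, X.shape[1])}]"
        )

    scores, weights, x_loadings, y_loadings, u_scores, iters = [], [], [], [], [], []
    for comp in range(ncomp):
        if np.linalg.norm(X) < 1e-12:
            raise NoVariationError(
                f"predictor block exhausted before component {comp + 1}"
            )
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if np.linalg.norm(u) < 1e-12:  # degenerate response: fall back to X
            u = X[:, int(np.argmax(X.var(axis=0)))].copy()
        t_prev = None
        n_iter = max_iter
        for it in range(1, max_iter + 1):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            c = Y.T @ t / (t @ t)
            u = Y @ c / (c @ c)
            if t_prev is not None and np.linalg.norm(t - t_prev) <= tol * np.linalg.norm(t):
                n_iter = it
                break
            t_prev = t
        else:
            warnings.warn(
                f"component {comp + 1}: score vector did not stabilise in "
                f"{max_iter} iterations",
                NonConvergenceWarning,
                stacklevel=2,
            )
        # deterministic sign: largest-|entry| weight made positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, c, u = -w, -t, -c, -u
        p_load = X.T @ t / (t @ t)
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, c)
        scores.append(t)
        weights.append(w)
        x_loadings.append(p_load)
        y_loadings.append(c)
        u_scores.append(u)
        iters.append(n_iter)

    return PlsDecomposition(
        scores=np.column_stack(scores),
        weights=np.column_stack(weights),
        x_loadings=np.column_stack(x_loadings),
        y_loadings=np.column_stack(y_loadings),
        response_scores=np.column_stack(u_scores),
        iterations=tuple(iters),
    )


def extract_scores(
    Y: ExpressionMatrix,
    design: GroupDesign,
    ncomp: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PlsDecomposition:
    """Surrogate-variable candidates from the ANOVA residual matrix.

    Fits the baseline ANOVA, transposes its residual matrix to samples x
    genes, column-centres it and runs NIPALS with the (column-centred,
    transposed) expression matrix as the response block.  The predictor-side
    scores t_1 .. t_ncomp locate the latent directions within the residual
    space; the response-side scores u_1 .. u_ncomp re-read those directions
    from the raw expression and are the surrogate-variable candidates fed to
    the ANCOVA.  The distinction matters: every t is a linear combination of
    per-gene residual vectors and hence exactly orthogonal to the variety
    contrast, so t alone could never absorb the group-correlated component
    of a hidden factor, while u retains it.
    """
    max_comp = min(Y.n_samples - 1, Y.n_genes)
    if not 1 <= ncomp <= max_comp:
        raise RankLimitError(
            f"ncomp={ncomp} outside [1, min(samples - 1, genes)] = [1, {max_comp}]"
        )
    fit = fit_anova(Y, design)
    resid = fit.residuals
    if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(Y.values)):
        raise NoResidualVariationError(
            "ANOVA residuals are identically zero; nothing to extract"
        )
    Xc, x_means = center_columns(resid.T)
    Yc, y_means = center_columns(Y.values.T)
    decomp = nipals(Xc, Yc, ncomp, tol=tol, max_iter=max_iter)
    return PlsDecomposition(
        scores=decomp.scores,
        weights=decomp.weights,
        x_loadings=decomp.x_loadings,
        y_loadings=decomp.y_loadings,
        response_scores=decomp.response_scores,
        iterations=decomp.iterations,
        x_column_means=x_means,
        y_column_means=y_means,
    )
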