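"""The svpls pipeline: candidate models, AIC selection, testing, correction.

Surrogate score vectors are extracted once with ``pmax`` NIPALS components;
candidate ANCOVA models for K = 0 .. pmax then use the first K scores, so
the candidates are nested and share one extraction.  The model with minimum
AIC wins (ties break toward smaller K), its variety contrasts are tested
gene by gene, and Benjamini-Hochberg adjustment controls the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroupDesign, SvplsResult
from .exceptions import RankLimitError, ZeroRssError
from .fdr import bh_adjust
from .linear_model import corrected_matrix, fit_ancova, gene_tests, model_aic
from .pls import DEFAULT_MAX_ITER, DEFAULT_TOL, extract_scores

__all__ = ["SvplsConfig", "svpls", "bh_adjust", "pvalue_histogram_data"]


@dataclass(frozen=True)
class SvplsConfig:
    """Pipeline settings.

    pmax
        Maximum number of surrogate variables to consider (candidate models
        K = 0 .. pmax).  Default 3.
    fdr
        Target false discovery rate for the significance calls.  Default 0.05.
    tol, max_iter
        NIPALS convergence controls, passed through to the extraction.
    """

    pmax: int = 3
    fdr: float = 0.05
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER

    def __post_init__(self) -> None:
        if self.pmax < 0:
            raise ValueError(f"pmax must be >= 0, got {self.pmax}")
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")


def svpls(
    Y: ExpressionMatrix, design: GroupDesign, config: SvplsConfig | None = None
) -> SvplsResult:
    """Run the full surrogate-variable analysis on one expression matrix.

    Parameters
    ----------
    Y
        Log-scale expression, genes x samples.
    design
        Variety-1 / variety-2 sample assignment.
    config
        Pipeline settings; defaults to ``SvplsConfig()``.

    Returns
    -------
    SvplsResult
        Selected surrogate count, AIC trajectory, per-gene test table,
        corrected matrix and hidden-effect matrix.  With ``pmax = 0`` the
        pipeline reduces to plain ANOVA + BH.
    """
    if config is None:
        config = SvplsConfig()
    if config.pmax > min(Y.n_samples - 1, Y.n_genes):
        raise RankLimitError(
            f"pmax={config.pmax} exceeds min(samples - 1, genes) = "
            f"{min(Y.n_samples - 1, Y.n_genes)}"
        )

    decomposition = None
    if config.pmax > 0:
        decomposition = extract_scores(
            Y, design, config.pmax, tol=config.tol, max_iter=config.max_iter
        )
        all_scores = decomposition.response_scores
    else:
        all_scores = np.empty((Y.n_samples, 0))

    fits = []
    aics = []
    for k in range(config.pmax + 1):
        fit = fit_ancova(Y, design, scores=all_scores[:, :k])
        fits.append(fit)
        aics.append(model_aic(fit))
    aic_by_k = np.asarray(aics)
    selected_k = int(np.argmin(aic_by_k))  # argmin takes the first minimum: ties -> smaller K
    best = fits[selected_k]
    scores_used = all_scores[:, :selected_k]

    tests = gene_tests(best, fdr=config.fdr)
    corrected = corrected_matrix(best, Y, scores_used)
    hidden = Y.values - corrected.values
    significant = tuple(tests.loc[tests["significant"], "gene_id"])

    try:
        anova_p = (
            tests["p_raw"].to_numpy()
            if selected_k == 0
            else gene_tests(fits[0], fdr=config.fdr)["p_raw"].to_numpy()
        )
    except ZeroRssError:  # saturated baseline: diagnostics unavailable
        anova_p = None

    return SvplsResult(
        selected_k=selected_k,
        aic_by_k=aic_by_k,
        fit=best,
        tests=tests,
        scores_used=scores_used,
        corrected=corrected,
        hidden_effects=hidden,
        significant_genes=significant,
        anova_pvalues=anova_p,
        decomposition=decomposition,
        fdr=config.fdr,
    )


def pvalue_histogram_data(
    raw_anova_p: np.ndarray, adjusted_model_p: np.ndarray, bins: int = 20
) -> pd.DataFrame:
    """Paired bin counts for before/after p-value histograms.

    A well-corrected analysis pushes the null part of the p-value
    distribution toward uniformity; plotting both histograms side by side is
    the standard diagnostic.  Bins partition [0, 1] left-closed/right-open
    with the last bin closed; counts in each column sum to the length of the
    corresponding input.
    """
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    raw = np.asarray(raw_anova_p, dtype=float)
    adj = np.asarray(adjusted_model_p, dtype=float)
    for name, v in (("raw", raw), ("adjusted", adj)):
        if v.size and (np.any((v < 0) | (v > 1)) or not np.all(np.isfinite(v))):
            raise ValueError(f"{name} p-values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    raw_counts, _ = np.histogram(raw, bins=edges)
    adj_counts, _ = np.histogram(adj, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count_unadjusted": raw_counts,
            "count_adjusted": adj_counts,
        }
    )
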