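"""Core data containers.

The package works on a log-scale expression matrix (genes x samples) with a
two-level sample grouping (``variety`` 1 or 2, e.g. two tissue types or
phenotypes).  Containers validate their invariants on construction so that
downstream numerical code can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDesignError,
    DimensionMismatchError,
    DuplicateIdError,
    MissingValueError,
)

__all__ = [
    "ExpressionMatrix",
    "GroupDesign",
    "LinearFit",
    "PlsDecomposition",
    "SvplsResult",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise DuplicateIdError(f"duplicate {what} identifier: {i!r}")
            seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``; all entries finite.
    gene_ids, sample_ids
        Row / column identifiers; unique, lengths matching ``values``.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise DimensionMismatchError("expression values must be a 2-d matrix")
        p, n = values.shape
        if p != len(self.gene_ids):
            raise DimensionMismatchError(
                f"{p} rows but {len(self.gene_ids)} gene identifiers"
            )
        if n != len(self.sample_ids):
            raise DimensionMismatchError(
                f"{n} columns but {len(self.sample_ids)} sample identifiers"
            )
        if p < 2:
            raise DimensionMismatchError("need at least 2 genes")
        if n < 4:
            raise DimensionMismatchError("need at least 4 samples")
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise MissingValueError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
        )


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of each sample to variety 1 or variety 2.

    Each variety must occur at least twice: within-cell replication is what
    creates the ANOVA residuals the surrogate extraction feeds on.
    """

    variety: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.variety, dtype=int)
        object.__setattr__(self, "variety", v)
        if v.ndim != 1:
            raise DimensionMismatchError("variety must be a 1-d vector")
        if not np.all(np.isin(v, (1, 2))):
            raise DegenerateDesignError("variety labels must be 1 or 2")
        if np.sum(v == 1) < 2 or np.sum(v == 2) < 2:
            raise DegenerateDesignError("each variety needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.variety.shape[0]

    def indicator(self) -> np.ndarray:
        """0/1 indicator of membership in variety 2 (the tested contrast)."""
        return (self.variety == 2).astype(float)


@dataclass(frozen=True)
class LinearFit:
    """A fitted per-gene linear model sharing one design across genes.

    The shared design columns are ``[intercept, variety-2 indicator,
    t_1 .. t_K]`` where the ``t_l`` are surrogate score vectors.  Coefficients
    are gene-specific; the error variance is pooled across genes (one global
    model, one AIC).

    Attributes
    ----------
    n_surrogates
        K, the number of surrogate covariates (0 for plain ANOVA).
    intercept
        Per-gene intercept ``a_g`` (variety-1 mean level of gene g).
    contrast
        Per-gene variety contrast ``d_g`` = expected variety-2 minus
        variety-1 value; the differential-expression effect being tested.
    surrogate_coefs
        Gene-specific surrogate coefficients, shape ``(n_genes, K)``.
    sigma2
        Pooled error variance RSS / df.
    df_resid
        Pooled residual degrees of freedom, ``p*n - p*(2+K)``.
    rss
        Total residual sum of squares.
    aic
        Gaussian AIC with additive constants dropped; ``None`` when RSS is
        numerically zero (saturated fit).
    residuals
        Residual matrix, genes x samples.
    design
        The shared design matrix, samples x (2+K).
    xtx_inv
        ``(X'X)^{-1}`` of the shared design, used for standard errors.
    """

    n_surrogates: int
    intercept: np.ndarray
    contrast: np.ndarray
    surrogate_coefs: np.ndarray
    sigma2: float
    df_resid: int
    rss: float
    aic: float | None
    residuals: np.ndarray
    design: np.ndarray
    xtx_inv: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.residuals.shape[1]

    def fitted(self) -> np.ndarray:
        coefs = np.column_stack(
            [self.intercept, self.contrast]
            + ([self.surrogate_coefs] if self.n_surrogates else [])
        )
        return coefs @ self.design.T


@dataclass(frozen=True)
class PlsDecomposition:
    """NIPALS partial-least-squares decomposition of a residual matrix.

    ``scores`` holds the predictor-block component values T (orthogonal by
    deflation), ``weights``/``x_loadings`` per-gene projection coefficients
    of the predictor block, ``y_loadings`` the response-block loadings.
    ``response_scores`` holds the response-block scores U; these are the
    surrogate-variable candidates, because only the response block (the raw
    expression) retains the group-correlated part of a hidden factor that
    the residual block has projected out.
    """

    scores: np.ndarray  # samples x K, predictor-block scores T
    weights: np.ndarray  # genes x K
    x_loadings: np.ndarray  # genes x K
    y_loadings: np.ndarray  # genes x K
    response_scores: np.ndarray  # samples x K, response-block scores U
    iterations: tuple[int, ...]
    x_column_means: np.ndarray | None = None
    y_column_means: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class SvplsResult:
    """Output bundle of the full surrogate-variable pipeline.

    ``corrected.values + hidden_effects`` reproduces the input matrix; the
    hidden-effect matrix ``H[g, s] = sum_l phi_{gl} t_{ls}`` is the
    model-estimated contribution of the latent factors.
    """

    selected_k: int
    aic_by_k: np.ndarray
    fit: LinearFit
    tests: pd.DataFrame
    scores_used: np.ndarray
    corrected: ExpressionMatrix
    hidden_effects: np.ndarray
    significant_genes: tuple[str, ...]
    anova_pvalues: np.ndarray | None = None
    decomposition: PlsDecomposition | None = None
    fdr: float = 0.05
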