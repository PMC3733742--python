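"""Benjamini-Hochberg false-discovery-rate control."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyInputError

__all__ = ["bh_adjust"]


def bh_adjust(pvalues: np.ndarray, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Adjusted values are ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted
    scale, capped at 1 and returned in the original order; a gene is rejected
    iff its adjusted value is <= ``fdr``.

    Parameters
    ----------
    pvalues
        Raw p-values in [0, 1].
    fdr
        Target false discovery rate in (0, 1).

    Returns
    -------
    (adjusted, reject)
        Adjusted p-values and boolean rejection flags, both aligned with the
        input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise EmptyInputError("cannot adjust an empty p-value vector")
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return adjusted, reject
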