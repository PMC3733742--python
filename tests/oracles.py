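"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the code paths they check: ordinary least squares
via explicit normal equations, Benjamini-Hochberg by direct step-up
enumeration, and AIC by direct evaluation of its formula.
"""

import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve one least-squares problem by inverting X'X explicitly."""
    return np.linalg.inv(X.T @ X) @ (X.T @ y)


def stacked_ols(X: np.ndarray, Y_rows: np.ndarray) -> np.ndarray:
    """Solve the per-gene problems as one block-diagonal stacked system."""
    p = Y_rows.shape[0]
    q = X.shape[1]
    big = np.kron(np.eye(p), X)  # block-diagonal design
    beta = ols_normal_equations(big, Y_rows.reshape(-1))
    return beta.reshape(p, q)


def bh_stepup(pvalues: np.ndarray, fdr: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg by literal enumeration of the step-up rule."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # adjusted values: running minimum from the right of p_(j) * m / j
    adj_sorted = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    # rejection: largest j with p_(j) <= j/m * fdr, reject all smaller ranks
    thresh = np.arange(1, m + 1) / m * fdr
    passing = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return adjusted, reject


def aic_formula(rss: float, n_genes: int, n_samples: int, q_per_gene: int) -> float:
    n_obs = n_genes * n_samples
    return n_obs * np.log(rss / n_obs) + 2.0 * (n_genes * q_per_gene + 1)
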