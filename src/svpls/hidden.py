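"""Display of the estimated hidden-variation pattern (the ``hfp`` view).

The hidden-effect matrix H[g, s] = sum_l phi_gl t_ls is the model-based
estimate of how intensely the latent factors push the expression of gene g
in sample s.  Restricting H to a chosen set of genes and samples, and
rendering it as a heatmap, shows which gene blocks and which subjects carry
the unwanted variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SvplsResult
from .exceptions import DuplicateIdError, EmptyInputError, NoSurrogatesError, UnknownIdError

__all__ = ["HiddenPatternSelection", "hidden_effect_matrix", "hfp", "plot_hidden_heatmap"]


@dataclass(frozen=True)
class HiddenPatternSelection:
    """User-chosen genes and samples to display, in the order given."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        object.__setattr__(self, "samples", tuple(str(s) for s in self.samples))
        if not self.genes or not self.samples:
            raise EmptyInputError("gene and sample selections must be non-empty")
        for name, ids in (("gene", self.genes), ("sample", self.samples)):
            if len(set(ids)) != len(ids):
                raise DuplicateIdError(f"duplicate {name} identifier in selection")


def hidden_effect_matrix(result: SvplsResult) -> np.ndarray:
    """Full genes x samples hidden-effect matrix H of a fitted result."""
    if result.selected_k == 0:
        raise NoSurrogatesError(
            "selected model has no surrogate variables; hidden effect is empty"
        )
    return result.hidden_effects


def hfp(result: SvplsResult, selection: HiddenPatternSelection) -> pd.DataFrame:
    """Hidden-effect submatrix for the selected genes and samples.

    Rows and columns follow the order of the selection.  Raises
    :class:`UnknownIdError` naming the first identifier absent from the
    fitted result.
    """
    H = hidden_effect_matrix(result)
    gene_index = {g: i for i, g in enumerate(result.fit.gene_ids)}
    sample_index = {s: j for j, s in enumerate(result.fit.sample_ids)}
    for g in selection.genes:
        if g not in gene_index:
            raise UnknownIdError(g)
    for s in selection.samples:
        if s not in sample_index:
            raise UnknownIdError(s)
    rows = [gene_index[g] for g in selection.genes]
    cols = [sample_index[s] for s in selection.samples]
    sub = H[np.ix_(rows, cols)]
    return pd.DataFrame(sub, index=list(selection.genes), columns=list(selection.samples))


def plot_hidden_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Render a basic diverging heatmap of a hidden-effect submatrix to file.

    Genes and samples stay in the given order (no clustering); the colour
    scale is symmetric about zero so positive and negative latent pushes are
    visually comparable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.max(np.abs(matrix.to_numpy()))) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.3 * matrix.shape[1]), max(3.0, 0.25 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), labels=list(matrix.columns), rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), labels=list(matrix.index), fontsize=6)
    ax.set_xlabel("sample")
    ax.set_ylabel("gene")
    fig.colorbar(im, ax=ax, label="estimated hidden effect")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
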