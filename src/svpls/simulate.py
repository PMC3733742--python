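"""Synthetic two-group expression data with planted hidden variation.

The generator emulates a two-variety microarray-style study in which a
block of genes is contaminated by subject-specific confounders, and scores
how well the surrogate-variable pipeline recovers the true differential
expression.  Two hidden-variation regimes are provided:

* setting 1 — one subject-specific confounder h drawn from a two-component
  normal mixture with small component variance, whose mixing probability is
  linked to group membership (a subtle, partially confounded factor);
* setting 2 — the same normal-mixture confounder with large variance plus a
  second, independent confounder w from a centred two-component exponential
  mixture (two strong, heterogeneous factors).

For gene g and sample s the observed log-scale value is

    y_gs = baseline + gamma_g + delta 1[g <= n_de] 1[group(s) = 2]
           + h_s 1[g in A1] + w_s 1[g in A2]  (setting 2 only)
           + eps_gs,

with gamma_g ~ N(0, gene_effect_sd^2) the per-gene level, and
eps_gs ~ N(0, eta * gene_effect_sd^2): ``eta`` is the noise-to-signal
variance ratio.  The first ``n_de`` genes are truly differentially
expressed; the affected block A1 deliberately overlaps them so that hidden
and real signal are partially confounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroupDesign
from .exceptions import InvalidSpecError, SvplsError, UnknownIdError
from .pipeline import SvplsConfig, svpls

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "PerformanceSummary",
    "simulate_dataset",
    "evaluate_performance",
    "run_study",
]

_SETTING_DEFAULTS = {
    # (component means, component variance) of the subject confounder h
    1: ((-0.5, 0.5), 0.1),
    2: ((-1.0, 1.0), 2.0),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Generator parameters; defaults are the benchmark study conditions.

    Attributes
    ----------
    setting
        1 (single small-variance confounder) or 2 (two high-variance
        confounders).
    n_genes, n_subjects
        Matrix dimensions; subjects split equally into groups 1 and 2.
    n_de
        Genes 1 .. n_de carry the true group effect.
    eta
        Noise-to-signal variance ratio (error variance / gene-effect
        variance); the benchmark grid uses 0.05, 0.10, 0.15.
    de_effect
        delta, the group-2 shift of the truly differential genes (log scale).
    gene_effect_sd
        Standard deviation of the per-gene baseline levels; the primary
        signal scale, normalised to 1.
    baseline
        Grand mean of the log expression values.
    conf1_means, conf1_var
        Component means and common component variance of the normal-mixture
        confounder h; ``None`` picks the setting default.
    group_link_prob
        Probability that a group-1 subject draws the first mixture
        component (group 2 uses the complement), linking the confounder to
        the design.
    affected_set1
        1-based inclusive gene range (lo, hi) hit by h; overlaps the
        differential genes.  ``None`` disables the confounder.
    conf2_means, conf2_mix
        Means of the two exponential components of w and the probability of
        the first; w is centred at its mixture mean.  Setting 2 only.
    affected_set2
        1-based inclusive gene range hit by w; ``None`` disables it.
    seed
        Seed for the single random generator driving all draws.
    """

    setting: int = 1
    n_genes: int = 1000
    n_subjects: int = 20
    n_de: int = 70
    eta: float = 0.05
    de_effect: float = 1.0
    gene_effect_sd: float = 1.0
    baseline: float = 6.0
    conf1_means: tuple[float, float] | None = None
    conf1_var: float | None = None
    group_link_prob: float = 0.7
    affected_set1: tuple[int, int] | None = (51, 150)
    conf2_means: tuple[float, float] = (1.0, 3.0)
    conf2_mix: float = 0.5
    affected_set2: tuple[int, int] | None = (701, 850)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in (1, 2):
            raise InvalidSpecError("setting", "must be 1 or 2")
        if self.n_genes < 2:
            raise InvalidSpecError("n_genes", "need at least 2 genes")
        if self.n_subjects < 4 or self.n_subjects % 2:
            raise InvalidSpecError("n_subjects", "must be even and >= 4")
        if not 1 <= self.n_de <= self.n_genes:
            raise InvalidSpecError("n_de", "must be in [1, n_genes]")
        if self.eta < 0:
            raise InvalidSpecError("eta", "must be >= 0")
        if self.gene_effect_sd <= 0:
            raise InvalidSpecError("gene_effect_sd", "must be > 0")
        if not 0 <= self.group_link_prob <= 1:
            raise InvalidSpecError("group_link_prob", "must be in [0, 1]")
        checked = ("affected_set1", "affected_set2") if self.setting == 2 else ("affected_set1",)
        for name in checked:
            rng = getattr(self, name)
            if rng is not None:
                lo, hi = rng
                if not 1 <= lo <= hi <= self.n_genes:
                    raise InvalidSpecError(name, f"range {rng} not within 1..{self.n_genes}")
        if self.conf1_var is not None and self.conf1_var < 0:
            raise InvalidSpecError("conf1_var", "must be >= 0")
        if not 0 <= self.conf2_mix <= 1:
            raise InvalidSpecError("conf2_mix", "must be in [0, 1]")

    @property
    def confounder1_means(self) -> tuple[float, float]:
        return self.conf1_means if self.conf1_means is not None else _SETTING_DEFAULTS[self.setting][0]

    @property
    def confounder1_var(self) -> float:
        return self.conf1_var if self.conf1_var is not None else _SETTING_DEFAULTS[self.setting][1]


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated study with its ground truth exposed."""

    expression: ExpressionMatrix
    design: GroupDesign
    truth: pd.Series  # bool per gene id, True = truly differential
    confounder1: np.ndarray  # h per subject
    confounder2: np.ndarray | None  # w per subject (setting 2)
    spec: SimulationSpec


@dataclass(frozen=True)
class PerformanceSummary:
    """Detection metrics, averaged per-replicate ratios.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    fdr = FP/(TP+FP) (0 when nothing declared) and
    fnr = FN/(FN+TN), the false non-discovery rate.
    """

    sensitivity: float
    specificity: float
    fdr: float
    fnr: float
    n_replicates: int
    per_replicate: pd.DataFrame | None = None
    standard_errors: Mapping[str, float] | None = None
    n_failed: int = 0


def _range_mask(n_genes: int, rng_1based: tuple[int, int] | None) -> np.ndarray:
    mask = np.zeros(n_genes, dtype=bool)
    if rng_1based is not None:
        lo, hi = rng_1based
        mask[lo - 1 : hi] = True
    return mask


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one dataset from the generator.

    All randomness flows from ``spec.seed``; identical specs give
    bit-identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    p, n = spec.n_genes, spec.n_subjects
    variety = np.repeat([1, 2], n // 2)
    group2 = variety == 2

    gamma = rng.normal(0.0, spec.gene_effect_sd, size=p)

    # subject confounder h: two-component normal mixture, component choice
    # linked to group membership
    m1, m2 = spec.confounder1_means
    comp1_prob = np.where(group2, 1.0 - spec.group_link_prob, spec.group_link_prob)
    take_first = rng.random(n) < comp1_prob
    h = rng.normal(np.where(take_first, m1, m2), np.sqrt(spec.confounder1_var))

    w = None
    if spec.setting == 2:
        e1, e2 = spec.conf2_means
        first = rng.random(n) < spec.conf2_mix
        raw = np.where(first, rng.exponential(e1, size=n), rng.exponential(e2, size=n))
        mix_mean = spec.conf2_mix * e1 + (1.0 - spec.conf2_mix) * e2
        w = raw - mix_mean

    error_sd = np.sqrt(spec.eta) * spec.gene_effect_sd
    eps = rng.normal(0.0, error_sd, size=(p, n)) if error_sd > 0 else np.zeros((p, n))

    de_mask = np.zeros(p, dtype=bool)
    de_mask[: spec.n_de] = True
    a1 = _range_mask(p, spec.affected_set1)
    a2 = _range_mask(p, spec.affected_set2) if spec.setting == 2 else np.zeros(p, bool)

    y = spec.baseline + gamma[:, None] + eps
    y += spec.de_effect * np.outer(de_mask, group2.astype(float))
    y += np.outer(a1.astype(float), h)
    if w is not None:
        y += np.outer(a2.astype(float), w)

    gene_ids = tuple(f"g{i}" for i in range(1, p + 1))
    sample_ids = tuple(f"s{j}" for j in range(1, n + 1))
    return SimulatedDataset(
        expression=ExpressionMatrix(y, gene_ids, sample_ids),
        design=GroupDesign(variety),
        truth=pd.Series(de_mask, index=list(gene_ids), name="truth"),
        confounder1=h,
        confounder2=w,
        spec=spec,
    )


def evaluate_performance(declared: Iterable[str], truth: pd.Series) -> PerformanceSummary:
    """Score one replicate's declared gene set against the ground truth.

    ``declared`` must be a subset of the gene universe indexed by ``truth``;
    0/0 ratios (nothing declared, or everything declared) resolve to 0 for
    FDR and FNR respectively.
    """
    declared = set(declared)
    universe = set(truth.index)
    for g in declared:
        if g not in universe:
            raise UnknownIdError(g)
    truth_set = set(truth.index[truth.to_numpy(dtype=bool)])
    tp = len(declared & truth_set)
    fp = len(declared - truth_set)
    fn = len(truth_set - declared)
    tn = len(universe) - tp - fp - fn
    return PerformanceSummary(
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 1.0,
        fdr=fp / (tp + fp) if tp + fp else 0.0,
        fnr=fn / (fn + tn) if fn + tn else 0.0,
        n_replicates=1,
    )


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Deterministic per-replicate child seed below 2^31."""
    ss = np.random.SeedSequence([int(base_seed), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_study(
    spec: SimulationSpec,
    n_reps: int,
    config: SvplsConfig | None = None,
    progress: bool = False,
) -> PerformanceSummary:
    """Monte-Carlo evaluation of the pipeline under one study condition.

    Each replicate simulates a fresh dataset (seed derived deterministically
    from ``spec.seed`` and the replicate index), runs the full pipeline and
    scores the declared genes.  Metrics are means of per-replicate ratios;
    standard errors of those means are reported alongside.  A replicate that
    fails with a package error is recorded, excluded and counted in
    ``n_failed``.
    """
    if n_reps < 1:
        raise InvalidSpecError("n_reps", "need at least one replicate")
    if config is None:
        config = SvplsConfig()
    rows = []
    n_failed = 0
    for r in range(1, n_reps + 1):
        ds = simulate_dataset(replace(spec, seed=replicate_seed(spec.seed, r)))
        try:
            result = svpls(ds.expression, ds.design, config)
        except SvplsError as exc:  # pragma: no cover - defensive
            warnings.warn(f"replicate {r} excluded: {exc}", stacklevel=2)
            n_failed += 1
            continue
        m = evaluate_performance(result.significant_genes, ds.truth)
        rows.append(
            {
                "replicate": r,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "fdr": m.fdr,
                "fnr": m.fnr,
                "selected_k": result.selected_k,
            }
        )
        if progress and r % 10 == 0:  # pragma: no cover
            print(f"  replicate {r}/{n_reps}", flush=True)
    per_rep = pd.DataFrame(rows)
    metrics = ["sensitivity", "specificity", "fdr", "fnr"]
    means = per_rep[metrics].mean()
    ses = per_rep[metrics].sem() if len(per_rep) > 1 else per_rep[metrics].mul(0.0).iloc[0]
    return PerformanceSummary(
        sensitivity=float(means["sensitivity"]),
        specificity=float(means["specificity"]),
        fdr=float(means["fdr"]),
        fnr=float(means["fnr"]),
        n_replicates=len(per_rep),
        per_replicate=per_rep,
        standard_errors={k: float(ses[k]) for k in metrics},
        n_failed=n_failed,
    )
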