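# Methods

## Model

Let Y be a p × n log-scale expression matrix over two sample varieties.
The classical two-way layout μ + γ_g + α_i + (γα)_gi is over-parameterised;
we fit the identifiable reference coding

    y_gs = a_g + d_g · v_s + Σ_{l=1..K} φ_gl u_ls + ε_gs,

with v_s the variety-2 indicator, a_g absorbing the grand mean and gene
level, d_g absorbing the variety main effect and the gene-by-variety
interaction (d_g is the expected variety-2 minus variety-1 difference for
gene g, the quantity under test), and u_1..u_K surrogate covariates shared
across genes with gene-specific coefficients φ_gl. All genes share one
design matrix [1, v, u_1..u_K], so the p ordinary-least-squares problems are
solved as a single multi-right-hand-side `lstsq`; this is numerically
identical to the stacked block-diagonal OLS (tested against that oracle).

Errors are homoscedastic across genes: one pooled σ² = RSS / df with
df = p·n − p·(2+K). This matches the "one global model, one AIC" selection
logic; gene-specific variances or empirical-Bayes moderation are
deliberately out of scope. The t-test for d_g uses SE² = σ²·[(X′X)⁻¹]₂₂ and
df equal to the pooled residual df (≥ several thousand in practice, so the
reference distribution is effectively normal).

## Surrogate extraction

NIPALS partial least squares runs on X = centred Rᵀ (samples × genes, R the
ANOVA residual matrix) with response block Yc = centred Yᵀ. Per component:
u is initialised to the response column of largest variance (deterministic),
the iteration w = X′u/‖X′u‖, t = Xw, c = Y′t/t′t, u = Yc/c′c runs until the
relative L2 change of t falls below `tol` (default 1e-10, `max_iter` 500;
hitting the cap raises a non-fatal warning), then both blocks are deflated
by the rank-one terms t p′ and t c′. Each component is sign-fixed so the
largest-magnitude weight entry is positive, making the output bit-for-bit
reproducible. Columns are centred but not scaled to unit variance: the
residuals of one expression matrix share a scale, and autoscaling would
distort gene loadings.

**Which score is the surrogate.** The predictor-side score t_l is a linear
combination of per-gene residual vectors. OLS residuals are orthogonal to
every design column, so t_l is *exactly* orthogonal to the centred variety
indicator — adding t_l to the ANCOVA cannot change any d_g, only shrink σ².
A hidden factor that is partially confounded with the grouping (the
motivating case) would therefore be uncorrectable. The response-side score
u_l = Yc/c′c re-reads the same latent direction from the raw expression and
retains its group-correlated component, so u_1..u_K are the surrogate
candidates handed to the ANCOVA. The decomposition exposes both T and U;
T keeps the classical NIPALS properties (mutual orthogonality, deflation
reconstruction, equivalence to principal components when the response block
equals the predictor block — all tested against SVD oracles).

## Model selection and testing

Scores are extracted once with pmax components; candidate models use the
first K, K = 0..pmax, so candidates are nested and share one extraction.
AIC = N·ln(RSS/N) + 2(q+1), N = p·n, q = p(2+K), additive Gaussian
constants dropped (they cancel in comparisons); ties break toward smaller
K. RSS = 0 makes AIC and the tests undefined and raises an explicit error.
Benjamini–Hochberg adjustment (step-up, via statsmodels) converts raw
p-values to q-values; `significant` means q ≤ fdr. Defaults pmax = 3,
fdr = 0.05.

Degenerate-input policy: each variety needs ≥ 2 samples (no within-cell
replication, no residuals); ncomp is capped at min(samples − 1, genes);
identically-zero residual matrices are rejected; a design condition number
above 1e8 raises a collinearity error naming the offending column (e.g. a
score duplicating the centred variety indicator).

## Hidden-effect display

The "hidden pattern" matrix is the model-based estimate
H[g,s] = Σ_l φ̂_gl u_ls — exactly what the corrected matrix subtracts, so
input = corrected + H holds to machine precision. The alternative reading
(the raw PLS reconstruction T·P′ of the residual matrix) was rejected to
keep H, the corrected matrix and the input mutually consistent. Heatmaps
use a symmetric diverging palette and preserve the user's gene/sample
order; no clustering.

## Synthetic generator

`SimulationSpec` defaults define the benchmark conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_subjects | 1000 / 20 | matrix size; subjects split 10/10 (or 20/20 at n=40) |
| n_de, de_effect | 70, δ = 1.0 | genes 1..70 shifted by δ in group 2 (log scale) |
| gene_effect_sd | 1.0 | per-gene level spread; the primary-signal scale |
| eta | 0.05 | error variance = η × gene_effect_sd² (error sd √η) |
| baseline | 6.0 | grand mean of log expression |
| confounder h | means ∓0.5, var 0.1 (setting 1); ∓1.0, var 2.0 (setting 2) | two-component normal mixture per subject |
| group_link_prob | 0.7 | P(first component) for group-1 subjects; complement for group 2 |
| affected_set1 | genes 51..150 | block receiving h; overlaps the DE set by 20 genes |
| confounder w (setting 2) | exp means 1 and 3, mix 0.5, centred | heavy-tailed second factor |
| affected_set2 | genes 701..850 | block receiving w |

η is a variance ratio against the primary-signal variance (normalised to
1), so the benchmark grid η = 0.05/0.1/0.15 spans error sd 0.22–0.39. The
group-linked mixture makes the confounder partially confounded with the
grouping (expected between-group shift 0.4·|m₂−m₁|·(2·link−1)); the overlap
of the affected block with the DE set creates genes whose true signal and
hidden signal mix. Metrics (sensitivity, specificity, FDR, and FNR = false
non-discovery rate FN/(FN+TN)) are averaged as per-replicate ratios, with
0/0 → 0 for FDR and empty declarations scored as specificity 1. Replicate
seeds derive from `SeedSequence([base_seed, replicate])`; identical spec +
seed is bit-reproducible.

What the generator does *not* emulate: gene–gene correlation beyond the
planted block structure, gene-specific error variances, heavy-tailed
measurement noise, intensity-dependent (mean–variance) trends, and
confounder loadings that vary by gene (the planted factors enter every
affected gene with coefficient 1, making each factor exactly rank one).
Passing benchmarks therefore demonstrate correct behaviour under idealised
block-structured hidden variation, not performance on real microarray data.

## Benchmark behaviour and known limitations

Under these defaults the planted factors are individually rank one, so one
surrogate per factor removes them almost completely; with δ = 1 against
error sd √η the per-gene contrast t-statistics for truly differential genes
are ≈ 6–10 and sensitivity saturates near 1.0 across the grid, while the
published study this benchmark mirrors reports mean sensitivities between
0.64 and 0.99 across the same grid — its generator constants (not public)
evidently place the signal nearer the detection threshold. The qualitative
directions (sensitivity falls with η, rises with sample size; specificity
stays ≈ 0.99) reproduce; the setting-2 sensitivity levels do not, and the
corresponding acceptance checks are left failing rather than retuning the
generator.

Two structural effects bound the attainable error rates under these
defaults. First, the DE/affected-block overlap leaks true signal into the
surrogate (u₁ ≈ h + 0.2δ·v for setting 1), which biases the contrasts of
non-differential affected genes and keeps the mean FDR near 0.1–0.25
instead of ≤ 0.05. Second, a surrogate can only remove the part of a
group-linked confounder it can estimate; the per-replicate realised
group-mean difference of h enters u with its sampling noise. Both effects
shrink as the affected blocks and the DE set decouple (set
`affected_set1=(71, 170)` to see FDR collapse toward zero).

Problem sizes in the shipped tests and the acceptance script — 100
Monte-Carlo replicates per condition (the original study used 1000) and the
5-condition target grid plus the 12-cell direction grid — were chosen to
keep a full run in the tens of seconds on a single CPU while holding the
Monte-Carlo standard error of each reported mean below 0.01.
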