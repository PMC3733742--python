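# svpls

Surrogate-variable correction of hidden heterogeneity in two-group gene
expression studies, with an AIC-selected ANCOVA and Benjamini–Hochberg
FDR-controlled differential expression testing.

## The problem

Tissue samples in a two-group expression study (two phenotypes, tissue
types, "varieties") often carry unobserved sample-level factors — batch
membership, demographics, environment — that leave a shared imprint on the
expression of whole blocks of genes. Left unmodelled, these hidden factors
distort the per-gene group contrasts: truly differential genes are missed
and unaffected genes are flagged, inflating both false-negative and
false-discovery rates.

## The method

For a log-scale expression matrix *Y* (genes × samples) and a two-level
group factor, the baseline model per gene *g* and sample *s* is the
gene-by-variety ANOVA, reparameterised as

    y_gs = a_g + d_g · 1[variety(s) = 2] + ε_gs,

where *d_g* is the differential-expression contrast under test. Hidden
variation is recovered in three steps:

1. **Extraction.** The residual matrix of the baseline ANOVA is fed to the
   nonlinear iterative partial least squares (NIPALS) algorithm with the raw
   expression matrix as the response block. The predictor-side scores
   *t_l* locate the dominant latent directions in residual space; the
   response-side scores *u_l* re-read those directions from the raw data and
   serve as the surrogate-variable candidates (only *u* retains any
   group-correlated component of a hidden factor — *t* is exactly orthogonal
   to the group contrast by construction).
2. **Selection.** Candidate ANCOVA models

        y_gs = a_g + d_g · 1[variety(s) = 2] + Σ_{l≤K} φ_gl u_ls + ε_gs

   for K = 0 … pmax (nested, one extraction) are compared by Gaussian AIC
   with a single pooled error variance; the minimum-AIC K wins, ties going
   to the smaller model.
3. **Testing and correction.** Per-gene t-statistics d_g / SE(d_g) with the
   pooled residual degrees of freedom give raw p-values; Benjamini–Hochberg
   step-up adjustment controls the FDR. The *corrected matrix* Y − H, with
   H[g,s] = Σ_l φ̂_gl u_ls the estimated hidden effect, visualises and
   removes the latent structure; `hfp` exports H for chosen genes/samples
   as a table or heatmap.

A seeded generator reproduces the method's Monte-Carlo power study: 1000
genes over 20 or 40 subjects split into two equal groups, the first 70
genes truly differential (shift δ = 1), noise-to-signal variance ratio
η ∈ {0.05, 0.1, 0.15}, and subject-specific confounders planted on gene
blocks — a group-linked two-component normal mixture (setting 1: small
variance; setting 2: large variance plus an independent centred exponential
mixture). `run_study` scores sensitivity, specificity, FDR and FNR over
replicates.

## Worked example

```python
import svpls

ds = svpls.simulate_dataset(svpls.SimulationSpec(setting=1, eta=0.05, seed=7))
res = svpls.svpls(ds.expression, ds.design, svpls.SvplsConfig(pmax=3, fdr=0.05))
print("selected_k:", res.selected_k)
print("n significant:", len(res.significant_genes))
m = svpls.evaluate_performance(res.significant_genes, ds.truth)
print(f"sens={m.sensitivity:.4f} spec={m.specificity:.4f} "
      f"fdr={m.fdr:.4f} fnr={m.fnr:.4f}")
```

prints

```
selected_k: 1
n significant: 76
sens=1.0000 spec=0.9935 fdr=0.0789 fnr=0.0000
```

The AIC trajectory over K = 0…3 was (−46955.0, −57385.1, −56936.5,
−56552.9): one surrogate variable captures the planted confounder (adding
it drops AIC by ~10400; further components only pay penalty). All 70 truly
differential genes are recovered; the 6 false positives sit in the
confounder-affected block, where the planted factor partially overlaps the
true signal. The same pipeline is available from the shell:

```sh
svpls simulate --setting 1 --eta 0.05 --seed 7 --out-dir data/
svpls svpls --expression data/expression.tsv --design data/design.tsv --out-dir out/
svpls hfp --expression data/expression.tsv --design data/design.tsv \
      --genes g51,g52,g53 --samples s1,s2,s3,s4 --plot --out-dir out/
svpls study --setting 1 --subjects 20 --eta 0.05 --reps 100 --seed 7 --out-dir bench/
```

Each command writes a JSON manifest with the configuration, seed, input
digests and output list.

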