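# hidgenome

Tumor site-of-origin classification from somatic single-nucleotide-variant
catalogs, built for the regime where almost every observed variant is rare or
previously unseen — the "hidden genome". Instead of estimating millions of
per-variant effects, the classifier condenses each tumor's ultra-sparse binary
mutation profile into a handful of **meta-feature scalar projections** and fits
a **group-lasso-penalized multinomial logistic regression** on them, which
keeps every effect interpretable as an odds ratio.

## Who this is for

Cancer genomics analysts who have per-tumor SNV calls (MAF-like TSV), site
labels for a training cohort, and standard context annotations (gene
intervals, chromosome lengths, optionally bin-level epigenomic read totals),
and who want calibrated site-of-origin probabilities plus per-feature effect
sizes — not a black box.

## The model

For tumor *i* with binary mutation profile **x**_i over *d* variants, let
**x̃**_i = **x**_i/‖**x**_i‖ (the norm is √burden). Each variant *j* carries a
meta-feature row **u**_j — cancer-gene membership, its SBS-96 trinucleotide
substitution category, its 1-Mb chromosome bin, site-specific epigenomic
scores of that bin, and an intercept — stacked into the meta-design matrix
**U**. The predictors for tumor *i* are

* the normalized indicators x̃_{ih} of the top-d₀ variants ranked by mutual
  information MI(X_j, C) with the site label ("residual effects", d₀ = 250),
* the scalar projections **x̃**_iᵀ**U**_{∘,l} — the tumor's mutation burden
  attributable to each meta-feature, normalized by √burden (the intercept
  column yields √burden itself).

With class intercepts α_k and coefficient matrix γ, the fit maximizes

```
Σ_i log softmax_{c_i}(α + z_iᵀγ)  −  λ Σ_l ‖γ_{l,·}‖₂
```

the maximum marginal a posteriori estimate of a hierarchical Bayesian model
whose scale-mixture priors collapse to this group-lasso objective. The L2
group penalty spans all K classes per predictor, so a feature is either
selected for every class or excluded entirely. λ is tuned by stratified
cross-validated multinomial deviance. Effects are reported as one-vs-rest
odds ratios for a one-SD increase of a predictor from its mean; performance
as one-vs-rest precision-recall curves, per-class PR-AUC, and the macro
PR-AUC (null baseline exactly 1/K).

## Worked example

Everything runs on synthetic cohorts with known planted structure — no
controlled-access data needed:

```python
import numpy as np
import hidgenome as hg

cfg = hg.SimulationConfig()                       # 4 sites x 100 tumors, 3000 bins
catalog, tables, truth = hg.simulate_cohort(cfg, seed=1)
meta   = hg.assemble_meta_design(catalog, chrom_lengths=cfg.chrom_lengths,
                                 gene_intervals=tables["genes"])
screen = hg.screen_catalog(catalog, d0=250)       # MI screening
design = hg.assemble_design(catalog, meta, screen)
model  = hg.fit(design, catalog.labels, n_lambda=15, lambda_min_ratio=3e-3,
                cv_folds=3, seed=1, tol=1e-6, max_iter=800)

active = set(np.asarray(model.columns)[model.active_groups])
planted = truth.planted_region_columns + truth.planted_sbs_columns + truth.hotspot_variants
print(sorted(hg.selection_summary(model)["active"].to_dict().items()))
print("planted recovered:", sum(c in active for c in planted), "/", len(planted))
```

prints (seed 1):

```
[('gene', 2), ('intercept-mf', 0), ('region', 12), ('sbs96', 7), ('variant', 4)]
planted recovered: 10 / 10
```

i.e. the fit selects a small set of predictor groups — among them all five
planted 1-Mb regions, all three planted SBS-96 categories, and both planted
hotspot variants — while thousands of noise groups stay at exactly zero.
Cross-validated performance and odds ratios:

```python
res = hg.run_cv(catalog, meta, folds=5, reps=1, d0=250, seed=1)
print(round(res.mean_macro_auc, 3))   # 1.0 on this strong-signal cohort
ors = hg.odds_ratio_table(model)
print(hg.top_predictors(ors, m=5)[["family", "max_abs_log_or"]])
```

A command-line interface mirrors the library
(`hidgenome simulate | build | metafeatures | screen | project | fit |
predict | evaluate | cv | odds-ratios | embed | arm-assoc`); every stochastic
subcommand takes `--seed` and outputs echo the seed and a config hash.

## Layout

```
src/hidgenome/
  catalog.py        MAF/BED/label I/O, sparse incidence, coverage restriction
  metafeatures.py   SBS-96, 1-Mb regions, gene indicators, epigenome scores, U
  screening.py      mutual-information variant screening
  projection.py     profile normalization, scalar projections, model matrix
  model.py          group-lasso multinomial solver, CV tuning, prediction
  interpretation.py one-vs-rest odds ratios, top predictors, selection summary
  evaluation.py     PR curves, macro AUC, one-vs-one matrices, replicated CV
  downstream.py     PCA+t-SNE embedding, arm-level R2/Spearman, specificity
  synthetic.py      cohort generator with planted discriminative structure
  cli.py            command-line entry point
docs/methods.md     model, assumptions, parameter choices, limitations
```
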