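# Methods

## Model

The classifier predicts the cancer site c ∈ {1..K} of a tumor from its binary
somatic SNV profile **x** (presence/absence over the d variants observed in
the training and test cohorts combined). Two facts shape the design: almost
every variant is observed in at most one tumor, and per-tumor burdens span
orders of magnitude. Per-variant coefficients are therefore hopeless for all
but a handful of recurrent variants; everything else must act through shared
mutational context.

Each variant j carries a meta-feature vector **u**_j: cancer-gene membership
indicators, its SBS-96 substitution category, its 1-Mb chromosome bin, the
(log-log transformed, site-specific) epigenomic scores of that bin, and an
intercept. Writing the per-variant coefficient for class k as
β_{j,k} = β⁰_{j,k} + **u**_jᵀω_{·,k} splits each effect into a part explained
by context (ω) and a residual (β⁰). With the normalized profile
**x̃** = **x**/‖**x**‖ (‖**x**‖ = √burden), the linear predictor becomes

    α_k + Σ_h x̃_h β⁰_{h,k} + Σ_l (x̃ᵀU_{∘,l}) ω_{l,k}

so the model's actual inputs are the screened normalized variant indicators
and the **scalar projections** x̃ᵀU_{∘,l} — the burden attributable to
meta-feature l, normalized by √burden. For a binary meta-feature the
projection is (count in category)/√burden; for the intercept column it is
√burden itself. This condenses tens of thousands of columns into a few
thousand interpretable ones while still letting every singleton variant
contribute through its contexts.

A hierarchical Bayesian treatment places zero-mean normal priors with
Gamma((K+1)/2, λ²/2) scale mixing on each predictor's K-vector of
coefficients; maximizing the marginal posterior in (α, β⁰, ω) is exactly the
group-lasso problem

    max Σ_i log softmax_{c_i}(α + z_iᵀγ) − λ Σ_l ‖γ_{l,·}‖₂,

with one group per predictor spanning all K classes. The package implements
this MAP objective directly; full posterior sampling is out of scope.

### Identifiability

The softmax is invariant to adding a constant across classes. Class
intercepts α are unpenalized and reported sum-to-zero; for penalized rows the
group penalty itself breaks the shift invariance (a shifted row has a larger
norm), so the solution is unique in practice. The prior on a stray intercept
parameter in the hierarchy is read as the prior on α, and α is left
unpenalized.

## Screening

Variants are ranked by the plug-in mutual information between their binary
indicator and the site label (natural log, 0·log 0 = 0), computed from
per-class presence counts in O(nnz + dK). The top d₀ = 250 enter the model as
individual residual-effect predictors. Ties break by higher total count, then
lexicographic variant key, so results are reproducible bit-for-bit. Screening
runs on training rows only and is repeated inside every cross-validation
fold; variants never observed in the training split are ineligible, so a
test-fold-only variant can never be screened in.

## Solver

Block proximal gradient (FISTA) with gradient-based adaptive restart on the
internally standardized design (training mean 0, sample SD 1; coefficients
are transformed back to the original scale, so predictions and odds ratios do
not depend on this choice). The step size is 1/L with
L = ½·σ_max([1 Z])². A decreasing λ path is solved with warm starts behind
glmnet-style sequential strong rules: at each λ, FISTA runs only on the
groups surviving the screen ‖∇_g‖ > 2λ − λ_prev plus all currently active
groups; the full-problem KKT conditions are then checked and any violating
group is added before re-solving. Every returned solution therefore satisfies
the full KKT system: inactive groups have ‖∇_g NLL‖ ≤ λ, active groups have
∇_g NLL + λγ_g/‖γ_g‖ ≈ 0; the maximum residual is stored on the model
(`kkt_violation`). λ_max (all groups zero, intercepts at the class
log-proportions) is computed in closed form and anchors the default grid of
100 log-spaced values down to λ_max·10⁻⁴. λ is selected by minimum mean
stratified-CV multinomial deviance (a one-SE rule is available).

Constant predictor columns (zero training SD) are excluded from the fit and
reported with zero coefficients and undefined odds ratios.

## Evaluation

One-vs-rest precision-recall curves use every distinct score as a threshold;
the AUC is step-wise average precision, Σ(R_t − R_{t−1})P_t, which avoids the
optimistic linear interpolation of trapezoids on PR curves. The macro AUC is
the unweighted mean of per-class AUCs; its null baseline is the mean
prevalence, exactly 1/K. The macro curve averages per-class recall on a
common 101-point descending precision grid with step interpolation (the
averaging direction is fixed by the definition; the grid is a package
choice). One-vs-one analyses condition probabilities on each ordered class
pair, p_i/(p_i+p_j); the resulting K×K PR-AUC matrix is not symmetric.

The replicated CV harness re-runs screening, moment computation, λ tuning,
and fitting inside every training split, pools out-of-fold probabilities per
replication, and averages summaries over replications. Fold assignment is
stratified by site and fully seeded.

## Interpretation

Per-predictor effects are one-vs-rest odds ratios for a one-SD increase from
the mean with all other predictors at their means, computed in closed form
from (α, γ, z̄, s) and verified (in tests, to 1e−10) against direct two-point
recomputation from the predictive probabilities. Moments are training-sample
moments (SD with n−1 denominator). Inactive groups give OR = 1 exactly.
`top_predictors` ranks by max-over-classes |log OR| (natural log) and groups
the report by feature family.

## Synthetic cohorts

The generator emulates the statistical regime the method targets, not any
particular tumor biology: a variant universe so large that ≥ 90% (typically
> 99%) of observed variants are singletons; log-normal burdens with
site-specific means (defaults 50, 120, 250, 500 mutations; log-SD 0.5,
minimum 1); site-specific 1-Mb bin propensities; site-specific SBS-96
spectra; two recurrent hotspot variants with site-dependent occurrence
probabilities; and in-gene enrichment for two of twenty genes. Mutations are
placed at distinct positions (binary incidence is native), with strand
randomization exercising the pyrimidine-collapsing of SBS categories.
Epigenome tracks are generated per mark and site as affine transforms of the
standardized bin propensities blended with noise at a configurable
correlation r, with ≥ 2 pseudo-samples per site.

Default planted-effect sizes — a planted bin carrying 12% of its site's bin
mass, a planted SBS category carrying 30% of its site's spectrum, hotspot
occurrence 0.8 in the enriched site vs 0.01 elsewhere, in-gene extras 0.8 vs
0.02 — were chosen so that each planted feature is individually separable at
100 tumors/site, i.e. they operationalize "strong, clearly recoverable
signal". The default genome is 3 chromosomes × 1000 Mb (3000 bins), large
enough that regional indicators vastly outnumber true signals.

What the generator does **not** emulate: replication-timing or
transcription-coupled mutational gradients, signature mixtures per tumor,
germline variation, copy-number-driven burden changes, or caller noise.
Passing tests therefore demonstrate that the pipeline recovers planted
context-level structure under its own assumptions — not field performance on
real cohorts, which depends on how strongly real regional/spectral signals
discriminate sites.

## Problem sizes and numerical settings

Simulation studies use the default cohort (400 tumors, ~90k variants, ~3360
predictors after projection) with a 15-point λ path down to λ_max·3·10⁻³,
3-fold internal CV for λ, FISTA tolerance 1e−6, and ≤ 800 iterations per
subproblem; these settings reproduce the same selected λ and active set as
much longer runs on this cohort family and keep a full CV replication under
a minute. Oracle-equivalence checks run the solver much tighter (tol 1e−10,
≤ 20000 iterations, KKT exit 1e−7). Coverage-attrition studies restrict the
cohort to the first 1% of every bin, emulating a panel-scale footprint; this
thins burdens ~100-fold and removes tumors left with no covered variant.

## Degenerate inputs and tie-breaks

Duplicate (sample, variant) calls collapse silently to 1. Non-SNV and
ref = alt rows are dropped with counts. Variants with ambiguous flanks are
SBS-unassignable (all-zero SBS row, logged) but keep their gene/region
contexts. Zero-burden samples are rejected at normalization; coverage
restriction removes them with a report. A tumor whose selected region
projections are all equal has undefined tissue-specificity scaling and is
excluded with a warning. PR curves require both classes present; one-vs-one
entries with an empty class are missing; the OR of a zero-SD predictor is
missing.

## Known limitations

* The MAP point estimate carries no uncertainty; odds-ratio confidence
  intervals would require the full Bayesian machinery.
* Linearity of log-odds in the projections is an interpretability choice;
  nonlinear classifiers may score higher on raw accuracy.
* The macro-curve precision grid and the mean-over-replications AUC
  aggregation are package conventions; AUC values are unaffected by the
  former.
* t-SNE coordinates are for visualization only; only seed-fixed determinism
  and coarse geometry (class separation) are guaranteed.
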