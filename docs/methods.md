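# Methods

This note documents the models, rules and numerical choices behind
`akiwatch`, and what the synthetic data can and cannot show.

## Cohort phenotyping

A person is *exposed* at the first recorded exposure to a target drug; that
date is day 0. AKI is the first serum creatinine (SCr) at or above
`ratio × baseline` in the half-open window `(index, index + 60 d]`. The
default `baseline_policy="uln_fixed"` substitutes the upper limit of normal
(ULN, 1.2 mg/dL) for the baseline, so the crossing level is 2.4 mg/dL; this
is self-consistent because eligibility already excludes anyone with a
pre-index SCr above the ULN. The alternative `observed_mean_capped` policy
uses `min(mean pre-index SCr, ULN)` and is kept for sensitivity analyses.
A spike on the index day itself is not attributed to the drug (half-open
interval). Multiple same-day SCr values are averaged before labeling.

Eligibility is checked in a fixed order and each excluded person carries
exactly one reason: `no_prior_visit` (no event ≥ 30 days before index), then
`insufficient_preobs_scr` (< 2 SCr tests in `[index − 60 d, index)`), then
`preobs_scr_above_uln`. The pre-observation window excludes the index day.
One cohort row exists per (person, drug); a person exposed to two target
drugs enters both drug cohorts, because models are trained per drug.

## Propensity matching

Covariates are age, sex (0/1) and mean pre-index SCr, standardized jointly
(population SD). The propensity model is a Newton–Raphson logistic
regression iterated to gradient norm < 1e-8; under (near) separation an L2
penalty of 1e-6 keeps the solution bounded and a warning is raised. Matching
is greedy 1:k (k = 3) nearest-neighbor on the propensity score, without
replacement, cases processed in descending score order, ties in |Δscore|
broken by the smaller person id; matching runs within site and results are
pooled. No caliper by default (an optional caliper in propensity-SD units is
available). Balance is reported as raw mean differences and absolute
standardized mean differences, SMD = |m₁ − m₀| / √((s₁² + s₀²)/2), before
and after matching.

## Featurization

Daily grids hold one row per calendar day and one column per variable. Labs
and diagnoses are forward-filled (diagnoses switch from 0 to 1 at the first
recorded date); drugs and procedures are binary, 1 only on event days. Lab
days before the first in-grid observation take the last pre-grid value if
one exists, else the cohort median of that lab. Same-day duplicate labs are
averaged.

Windows are `T = 28` days long and advance by a 14-day stride. The grid
extends `lookback = 28` days before the index date, so windows may start at
day −28: the target drugs' AKI onset medians are 12–23 days, and a
forward-from-index-only scheme could almost never place a whole window ahead
of onset. A window is labeled positive when the person's onset falls in
`(window end, window end + 14 d]` — one prediction cycle ahead; windows that
would cross the onset day are not emitted, so no window contains post-onset
information. With `lookback = 0` the scheme reduces to windows anchored at
the index date.

Predictors are screened per variable by pairing the value at day 0 with the
value at the onset day across cases: paired *t* test for continuous
variables (zero-variance differences report p = 1 with a warning), McNemar's
χ² = (b − c)²/(b + c) for binary ones. Selection at α = 0.05 without
multiplicity correction; Benjamini–Hochberg is available by flag. Variables
with fewer than 10 complete pairs are skipped.

Splits are 6:2:2 at person level (all windows of a person stay together),
stratified by case status, with a seeded shuffle. Continuous channels are
standardized with moments from the training split only.

## The IMV-LSTM

Each of the V variables owns a d-unit hidden block (d = 4 by default; the
hidden size is a free choice at this data scale). The candidate update for
block v sees only x_t[v]:

    j_t[v] = tanh(W[v] h_{t−1}[v] + U[v] x_t[v] + b[v])

Gates come in two arrangements. The default (`gate_mode="per_variable"`)
computes input/forget/output gates per block from (h_{t−1}[v], x_t[v]), so
block v is provably a function of variable v's history alone. The
alternative (`gate_mode="shared"`) uses affine maps over the concatenated
hidden state and full input. We default to per-variable gates because shared
gates leak cross-variable signal into every block, after which the variable
attention can concentrate on an arbitrary block and stops tracking
importance — we observed exactly this failure on planted-signal data.

Temporal attention scores each block's trajectory through a per-variable
tanh layer, α[v, ·] = softmax_t(u_a[v]·tanh(F_a[v] h_t[v] + f_a[v])), and
forms the context g_v = Σ_t α[v, t] h_t[v]. Variable attention applies a
shared tanh scorer to [g_v; h_T[v]] and normalizes over variables. The
output is a mixture of per-variable experts,

    p = Σ_v β[v] · σ(w_h[v]·[g_v; h_T[v]] + b_h[v]).

Mixing *probabilities* rather than logits is deliberate: an uninformative
expert then contributes the same probability to both classes, so loss
reduction requires moving β onto informative variables. The aggregated
variable importance is the mean β over windows of **both** classes: β is
sample-dependent and can act as a class switch (pointing at the signal
variable for one class and away for the other), and averaging over one class
alone can misrank; averaging over all windows is stable (verified on
planted-signal data).

Training minimizes class-weighted binary cross-entropy (positive weight
n_neg/n_pos, disabled by flag) with Adam (lr 1e-3) plus decoupled weight
decay 1e-3, shuffled mini-batches of 64, up to 200 epochs with early
stopping after 20 epochs without validation-loss improvement; the parameters
of the best validation epoch are restored. Forward pass, backpropagation
through time and the optimizer are NumPy throughout; gradients are analytic
and are checked against central finite differences (ε = 1e-5, relative error
< 1e-4) in the test suite, and the forward pass against an independent
scalar-loop reference implementation (1e-8). Training is deterministic for a
fixed seed on a single thread.

## Evaluation and statistics

AUROC uses the Mann–Whitney midrank formulation (equal to the trapezoidal
ROC area; both identities are asserted in tests); AUPRC is step-wise average
precision; accuracy/precision/F1 use a 0.5 threshold by default, with
precision 0 (and a warning) when nothing is predicted positive. The AUROC CI
is a stratified percentile bootstrap (default 1000 resamples, seeded;
degenerate single-class resamples cannot occur because strata are resampled
separately).

Attention aggregation: S[v, t] = Σ_s β_s[v] α_s[v, t] / Σ_s β_s[v], binned
into four weekly means (weeks −4..−1 relative to the window end); rows with
all-zero β are dropped with a warning; an unweighted per-variable mean of α
is available by flag. The pipeline pools attention over the test split's
windows of case patients.

Repeated-measures ANOVA is the one-way within-subject decomposition,
F = MS_time/MS_error with df (k−1, (n−1)(k−1)); MS_error = 0 (perfectly
parallel profiles) is reported as F = ∞, p = 0, and a zero time effect as
F = 0, p = 1. Group comparisons use the uncorrected Pearson χ² on 2×2 counts
(a warning flags expected cells < 1) and Welch's t for continuous variables.
Onset-day summaries use linear-interpolation quantiles; (drug, site) cells
with fewer than 20 cases are dropped, mirroring the pipeline's rule of
skipping models with under 20 cases; pairwise drug and site comparisons are
independent two-sided t tests without multiplicity correction.

## Synthetic data: what it emulates and what it does not

Each site draws ages ~ N(60.5, 15.5²) years, 57% male, baseline SCr clipped
below the ULN, ~15 labs on irregular per-variable schedules (mean gaps 3–7
days, so forward-filling is genuinely exercised), ~10 comorbidities at
realistic prevalences, 8 co-medications and 3 procedures. Case status is
Bernoulli with log-odds linear in standardized age, sex and baseline SCr
(slopes 1.0/0.8/0.6 × `confound_strength`, default 0.6); the intercept is
solved numerically (Brent) so the marginal case rate equals `aki_frac`
despite the nonlinearity. The default `aki_frac` is 0.12 — a realistic
60-day incidence of drug-associated AKI among exposed, initially
normal-creatinine patients — which leaves roughly a 7:1 control pool, the
slack 1:3 matching needs. Onset days are lognormal per drug (medians 12–23
days, e.g. vancomycin 12, acyclovir 23), rejection-sampled into (0, 60];
rejection keeps planted cases consistent with the labeler but slightly
shifts late-onset medians downward (≈1 day for acyclovir). Cases cross
2 × ULN exactly on the drawn onset day and stay elevated; all other SCr
values are clipped below the threshold. Case labs drift linearly over the
28 days before onset (lymphocytes −2.5 %/wk, albumin −0.12 g/dL/wk,
hemoglobin −0.35 g/dL/wk, urine pH +0.15/wk, prothrombin time +0.55 s/wk);
control labs are stationary noise around their baselines. A configurable
`spoiler_frac` plants patients who each violate exactly one eligibility
rule. Dates anchor at 2015-01-01 (simulation day 0).

Because eligibility, onset times, confounding and drift are planted, passing
tests demonstrate that each stage recovers a known ground truth under
realistic sparsity and confounding — not that the model would reach the same
discrimination on real EHRs, where missingness is informative, drift need
not be linear, controls are not stationary, and coding practices differ by
site. Multi-site here means independent synthetic bundles; no federated
execution is modeled.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by design: sites of a few
hundred to 1500 patients, 10 (site, drug) models, 60 training epochs with
early stopping. Softmaxes subtract the row maximum before exponentiation;
probabilities are clipped at 1e-7 inside the loss only; the pipeline skips
(site, drug) cells with fewer than 20 cases (configurable) or single-class
window sets, recording the reason in the manifest. The global seed fans out
to per-stage seeds via `SeedSequence([seed, sha256(site|drug|stage)])`, so
partial reruns reproduce exactly.

## Known limitations

KDIGO urine-output criteria, AKI staging beyond the doubling rule, learned
imputation, calipered/optimal matching, GPU-scale training and federated
execution are out of scope. The attention surface is an interpretation
aid — attention is not causal attribution, and variable importance from β
is only trustworthy when hidden blocks are variable-separated (the default
gate mode).
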