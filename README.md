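# akiwatch

Multicenter surveillance of **drug-induced acute kidney injury (AKI)** from
OMOP-CDM-style electronic health records: cohort phenotyping, propensity
matching, clinical time-series featurization, an **interpretable
multivariable LSTM (IMV-LSTM)** with temporal and variable attention, and the
onset-time / feature-importance statistics that summarize where and when the
risk signal lives.

The package is aimed at pharmacoepidemiologists and clinical-ML researchers
who want a fully testable, end-to-end version of this analysis. Hospital EHRs
cannot be shared, so the package ships a seeded synthetic multi-site
generator that emulates the study conditions (per-site demographics,
comorbidity prevalences, five nephrotoxic target drugs — acetaminophen,
vancomycin, naproxen, celecoxib, acyclovir — drug-specific AKI onset-day
distributions, case/control confounding on age/sex/baseline creatinine, and
prodromal laboratory drift), and every stage is exercised against it.

## The analysis

**Phenotype.** A patient enters follow-up at the first exposure to a target
drug (the *index date*). AKI is labeled at the first serum creatinine (SCr)
reaching twice the baseline within 60 days after index; following KDIGO-style
practice with the upper limit of normal (ULN = 1.2 mg/dL) as the surrogate
baseline, the crossing level is 2 × 1.2 = **2.4 mg/dL**. Eligibility requires
a visit record ≥ 30 days before index and ≥ 2 SCr tests in the 60-day
pre-observation window, none above the ULN.

**Matching.** Cases are matched 1:3 to controls by greedy nearest-neighbor on
a logistic propensity score over standardized age, sex and baseline SCr,
without replacement, within site.

**Features.** Events are pivoted to per-person daily grids (labs/diagnoses
forward-filled, drugs/procedures zero-filled); predictors are screened by
paired *t* (continuous) and McNemar (binary) tests comparing each variable at
enrollment vs at AKI onset; 28-day windows advance by a 14-day stride and a
window is positive when onset falls within the next 14 days.

**Model.** The IMV-LSTM keeps a separate hidden-state block per variable with
variable-wise gates, scores each block's trajectory with temporal attention
α[v, t], mixes per-variable experts with variable attention β[v], and
predicts p = Σ_v β[v]·σ(head_v). α and β are then aggregated across windows
into a variable × week importance surface
S[v, t] = Σ_s β_s[v] α_s[v, t] / Σ_s β_s[v].

**Evaluation.** AUROC (Mann–Whitney), AUPRC, accuracy/precision/F1 and a
stratified percentile-bootstrap 95% CI, per (site, drug) model; onset-day
medians/IQRs per drug and site with pairwise *t* tests; repeated-measures
ANOVA for temporal differences; χ²/Welch tests for group comparisons.

## Worked example

```python
import akiwatch as aw

cfg = aw.RunConfig(
    sites=[aw.SiteSimConfig(site_id="A", n_patients=300, seed=1,
                            drug_mix={"vancomycin": 1.0}, aki_frac=0.3)],
    drugs=["vancomycin"],
    hyperparams=aw.ImvHyperparams(epochs=40, patience=12),
    min_cases=10, seed=7, output_dir="runs/demo")
manifest = aw.run_pipeline(cfg)
cell = manifest["cells"]["A/vancomycin"]
print(cell["counts"])
print(round(cell["metrics_test"]["auroc"], 3))
print(manifest["onset"]["overall"])
```

prints (seed 7):

```
{'exposed': 300, 'excluded': {'no_prior_visit': 0, 'insufficient_preobs_scr': 0,
 'preobs_scr_above_uln': 0}, 'cases': 90, 'controls': 210, 'matched_cases': 70,
 'matched_controls': 210, 'windows': 1157, 'positive_windows': 70,
 'split': {'train': 694, 'val': 228, 'test': 235}}
0.823
{'n': 90, 'median': 12.0, 'q1': 9.0, 'q3': 16.0}
```

All 300 simulated patients pass eligibility (the generator plants it), 90
develop AKI within follow-up, matching keeps 3 controls per matched case
until the control pool is exhausted, and the model separates held-out
windows with AUROC 0.823 at this small training budget. The onset median of
12 days reproduces the configured vancomycin onset distribution.

A CLI mirrors the stages (`akiwatch simulate | cohort | match | featurize |
train | evaluate | interpret | run-all`); each subcommand reads and writes
plain CSV/JSON artifacts.

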