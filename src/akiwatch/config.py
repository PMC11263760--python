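"""Configuration objects for the AKI surveillance pipeline.

Every stage of the pipeline is driven by one of the dataclasses below.
Validation happens eagerly in ``__post_init__`` so that a malformed
configuration fails before any data is generated or touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

TARGET_DRUGS = (
    "acetaminophen",
    "vancomycin",
    "naproxen",
    "celecoxib",
    "acyclovir",
)

#: Default AKI onset distributions per drug, as (median days, log-scale sd) of a
#: lognormal. Medians follow the onset patterns reported for these nephrotoxic
#: drugs: vancomycin is earliest (12 d) and acyclovir latest (23 d).
DEFAULT_ONSET_LOGNORMAL: dict[str, tuple[float, float]] = {
    "acetaminophen": (19.0, 0.60),
    "vancomycin": (12.0, 0.55),
    "naproxen": (18.0, 0.60),
    "celecoxib": (22.0, 0.65),
    "acyclovir": (23.0, 0.65),
}

#: Prodromal lab drift for planted cases: value change per week over the 28 days
#: before AKI onset. Lymphocytes/albumin/hemoglobin fall; urine pH and
#: prothrombin time rise. Units are the lab's own units per week.
DEFAULT_DRIFT_EFFECTS: dict[str, float] = {
    "lymphocytes": -2.5,       # % of WBC per week
    "albumin": -0.12,          # g/dL per week
    "hemoglobin": -0.35,       # g/dL per week
    "urine_ph": +0.15,         # pH units per week
    "prothrombin_time": +0.55, # seconds per week
}

DEFAULT_COMORBIDITY_PREV: dict[str, float] = {
    "sepsis": 0.03,
    "diabetes_mellitus": 0.16,
    "chronic_kidney_disease": 0.015,
    "chronic_liver_disease": 0.08,
    "hypertension": 0.24,
    "neoplasm": 0.52,
    "heart_failure": 0.035,
    "anemia": 0.06,
    "hypotension": 0.002,
    "peripheral_vascular_disease": 0.008,
}


class ConfigurationError(ValueError):
    """Raised when a pipeline configuration violates its invariants."""


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {p!r}")


@dataclass
class SiteSimConfig:
    """Simulation settings for one synthetic hospital site.

    Parameters
    ----------
    site_id : str
        Site label (e.g. ``"SH"``).
    n_patients : int
        Number of exposed patients to simulate.
    drug_mix : mapping drug -> probability
        Must sum to 1; each patient is assigned one target drug.
    age_mean, age_sd : float
        Age distribution in years at index date.
    male_frac : float
        Proportion of male patients.
    comorbidity_prev : mapping condition -> prevalence
    aki_frac : float
        Marginal fraction of exposed patients planted as AKI cases.
    onset_lognormal : mapping drug -> (median days, log sd)
        AKI onset-day distribution after the index date.
    confound_strength : float
        Log-odds-per-SD coupling of age, sex and baseline SCr to case status.
    drift_effects : mapping variable -> slope per week
        Prodromal drift applied to case trajectories in the 28 days pre-onset.
    spoiler_frac : float
        Fraction of patients deliberately violating an eligibility rule, to
        exercise the cohort exclusions. 0 means eligibility by construction.
    uln : float
        Upper limit of normal for serum creatinine, mg/dL.
    seed : int
    """

    site_id: str
    n_patients: int = 500
    drug_mix: Mapping[str, float] = field(
        default_factory=lambda: {d: 0.2 for d in TARGET_DRUGS}
    )
    age_mean: float = 60.5
    age_sd: float = 15.5
    male_frac: float = 0.57
    comorbidity_prev: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREV)
    )
    aki_frac: float = 0.12
    onset_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ONSET_LOGNORMAL)
    )
    confound_strength: float = 0.6
    drift_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRIFT_EFFECTS)
    )
    spoiler_frac: float = 0.0
    uln: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError(f"n_patients must be > 0, got {self.n_patients}")
        for drug, p in self.drug_mix.items():
            _check_prob(f"drug_mix[{drug}]", p)
        total = sum(self.drug_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"drug_mix must sum to 1, got {total}")
        _check_prob("male_frac", self.male_frac)
        _check_prob("aki_frac", self.aki_frac)
        _check_prob("spoiler_frac", self.spoiler_frac)
        for cond, p in self.comorbidity_prev.items():
            _check_prob(f"comorbidity_prev[{cond}]", p)
        for drug, (med, lsd) in self.onset_lognormal.items():
            if med <= 0:
                raise ConfigurationError(
                    f"onset_lognormal[{drug}] median must be positive, got {med}"
                )
            if lsd <= 0:
                raise ConfigurationError(
                    f"onset_lognormal[{drug}] log-sd must be positive, got {lsd}"
                )
        if self.uln <= 0:
            raise ConfigurationError(f"uln must be positive, got {self.uln}")


@dataclass
class AkiCriteria:
    """Serum-creatinine AKI definition and cohort eligibility rules.

    The default criterion labels AKI at the first SCr reaching
    ``ratio x uln`` (2 x 1.2 = 2.4 mg/dL) within ``followup_days`` after the
    index date. ``baseline_policy`` switches between the fixed-ULN surrogate
    baseline and the capped observed pre-index mean.
    """

    uln: float = 1.2
    ratio: float = 2.0
    followup_days: int = 60
    preobs_days: int = 60
    min_preobs_scr: int = 2
    min_prior_visit_days: int = 30
    baseline_policy: str = "uln_fixed"

    def __post_init__(self) -> None:
        if self.ratio <= 1:
            raise ConfigurationError(f"ratio must be > 1, got {self.ratio}")
        for name in ("followup_days", "preobs_days", "min_prior_visit_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.min_preobs_scr < 1:
            raise ConfigurationError("min_preobs_scr must be >= 1")
        if self.baseline_policy not in ("uln_fixed", "observed_mean_capped"):
            raise ConfigurationError(
                f"unknown baseline_policy {self.baseline_policy!r}"
            )


@dataclass
class ImvHyperparams:
    """Training hyperparameters for the interpretable multivariable LSTM."""

    hidden_per_var: int = 4
    epochs: int = 200
    batch: int = 64
    lr: float = 1e-3
    patience: int = 20
    seed: int = 0
    threshold: float = 0.5
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.hidden_per_var < 1:
            raise ConfigurationError("hidden_per_var must be >= 1")
        if self.lr <= 0:
            raise ConfigurationError("lr must be > 0")
        if self.epochs < 1 or self.batch < 1 or self.patience < 1:
            raise ConfigurationError("epochs, batch and patience must be >= 1")
        _check_prob("threshold", self.threshold)


@dataclass
class WindowSpec:
    """Sliding-window settings: 4-week windows advanced by a 2-week stride,
    labels looking one prediction cycle (horizon) past the window end.

    ``lookback`` lets windows begin up to that many days before the index
    date, using pre-index history; without it, drugs whose AKI onset median
    is below the window length could never yield a positive window.
    """

    length: int = 28
    stride: int = 14
    horizon: int = 14
    lookback: int = 28

    def __post_init__(self) -> None:
        if self.length < 1 or self.stride < 1 or self.horizon < 1:
            raise ConfigurationError("window length, stride and horizon must be >= 1")
        if self.lookback < 0:
            raise ConfigurationError("lookback must be >= 0")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: sites, drugs and per-stage settings."""

    sites: Sequence[SiteSimConfig] = ()
    drugs: Sequence[str] = TARGET_DRUGS
    criteria: AkiCriteria = field(default_factory=AkiCriteria)
    match_ratio: int = 3
    alpha: float = 0.05
    window: WindowSpec = field(default_factory=WindowSpec)
    hyperparams: ImvHyperparams = field(default_factory=ImvHyperparams)
    min_cases: int = 20
    output_dir: str = "akiwatch_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ConfigurationError("at least one site is required")
        if not self.drugs:
            raise ConfigurationError("at least one drug is required")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate site_id in {ids}")
        if self.match_ratio < 1:
            raise ConfigurationError("match_ratio must be >= 1")
        _check_prob("alpha", self.alpha)
        if self.min_cases < 1:
            raise ConfigurationError("min_cases must be >= 1")


def asdict(cfg) -> dict:
    """Dataclass config -> plain nested dict (for YAML / JSON round-trips)."""
    return dataclasses.asdict(cfg)
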