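"""Synthetic claims-like cohort generator.

Emulates the structure of a nationwide PCI claims cohort of stable /
unstable angina patients: per-patient arm assignment (FFR-guided vs
angiography-guided index PCI), binary comorbidity covariates, event
times for all-cause death, spontaneous MI and unplanned
revascularization, administrative right-censoring from a uniform
accrual window with a fixed study end date, and a cumulative yearly
cost stream.

Event times are independent exponentials with hazard
``baseline * exp(arm effect + covariate effects)``; the default
baseline hazards are calibrated so the angiography arm reproduces the
observed 4-year cumulative incidences via r = -ln(1 - P4)/4, and the
default arm log-hazard-ratios are the adjusted ones from the source
cohort (death 0.798, MI 0.751, revascularization 0.996).  Covariate
effects default to zero so regression-adjustment tests can inject known
confounding.

Times are in years from the index PCI.  The cost stream is cumulative
USD at integer years 0..ceil(study end): a constant annual accrual over
observed follow-up, lump sums at observed events, and the FFR add-on at
time zero in the FFR arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "default_config", "generate_cohort", "COVARIATE_NAMES"]

#: Binary baseline covariates and their default prevalences (fractions of
#: the source cohort; age_ge_70 from a normal approximation to the
#: reported age distribution, 66.8 +/- 10.3 years).
DEFAULT_PREVALENCES = {
    "hypertension": 0.717,
    "diabetes": 0.493,
    "hyperlipidemia": 0.696,
    "atrial_fibrillation": 0.069,
    "chf": 0.221,
    "ckd": 0.091,
    "copd": 0.163,
    "prior_cva": 0.279,
    "pvd": 0.198,
    "stable_angina": 0.516,
    "age_ge_70": 0.38,
    "female": 0.341,
}

COVARIATE_NAMES = tuple(DEFAULT_PREVALENCES)

EVENTS = ("death", "mi", "revasc")


def _rate_from_4y(p4: float) -> float:
    """Constant hazard reproducing a 4-year cumulative incidence."""
    return -math.log1p(-p4) / 4.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator."""

    n_patients: int = 20_000
    p_ffr: float = 0.038
    covariate_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    # angiography-arm constant hazards, events per year
    baseline_hazards: dict = field(
        default_factory=lambda: {
            "death": _rate_from_4y(0.077),
            "mi": _rate_from_4y(0.022),
            "revasc": _rate_from_4y(0.152),
        }
    )
    # FFR-vs-angio log hazard ratios per event
    arm_log_hazard_ratios: dict = field(
        default_factory=lambda: {
            "death": math.log(0.798),
            "mi": math.log(0.751),
            "revasc": math.log(0.996),
        }
    )
    # covariate -> {event -> log HR}; empty means no covariate effects
    covariate_log_hazard_ratios: dict = field(default_factory=dict)
    annual_cost_mean: float = 1483.0
    event_cost_means: dict = field(
        default_factory=lambda: {"death": 6441.0, "mi": 1483.0, "revasc": 1473.0}
    )
    ffr_addon: float = 194.0
    accrual_window_years: float = 7.0
    admin_end: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.p_ffr <= 1:
            raise ValueError("p_ffr must be in [0, 1]")
        for k, v in self.covariate_prevalences.items():
            if not 0 <= v <= 1:
                raise ValueError(f"prevalence of {k!r} must be in [0, 1]")
        for k, v in self.baseline_hazards.items():
            if v < 0:
                raise ValueError(f"baseline hazard for {k!r} must be >= 0")
        if not 0 < self.accrual_window_years <= self.admin_end:
            raise ValueError("need 0 < accrual_window_years <= admin_end")

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(**overrides) -> GeneratorConfig:
    """The default study-calibrated generator configuration."""
    return GeneratorConfig(**overrides)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a patient-per-row DataFrame.

    Columns: ``id``, ``arm`` ('angio'/'ffr'), one 0/1 column per
    covariate, ``time_death`` / ``time_mi`` / ``time_revasc`` (years
    from index PCI, NaN if the event never occurs), ``time_censor``
    (administrative censoring), and ``cost_year_0`` .. ``cost_year_K``
    (cumulative observed cost at integer years).

    Reproducible: the output is a deterministic function of the config,
    including its ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    is_ffr = rng.random(n) < config.p_ffr

    cov = {}
    for name in COVARIATE_NAMES:
        prev = config.covariate_prevalences.get(name, 0.0)
        cov[name] = (rng.random(n) < prev).astype(np.int8)

    # linear predictor per event on the log-hazard scale
    times = {}
    for ev in EVENTS:
        lp = np.where(is_ffr, config.arm_log_hazard_ratios.get(ev, 0.0), 0.0)
        for cname, effects in config.covariate_log_hazard_ratios.items():
            lp = lp + effects.get(ev, 0.0) * cov[cname]
        hazard = config.baseline_hazards.get(ev, 0.0) * np.exp(lp)
        with np.errstate(divide="ignore"):
            t = np.where(
                hazard > 0,
                rng.exponential(1.0, n) / np.where(hazard > 0, hazard, 1.0),
                np.inf,
            )
        times[ev] = t

    entry = rng.uniform(0.0, config.accrual_window_years, n)
    time_censor = config.admin_end - entry

    t_death, t_mi, t_revasc = times["death"], times["mi"], times["revasc"]
    t_obs = np.minimum(t_death, time_censor)  # end of cost observation

    n_years = int(math.ceil(config.admin_end))
    cost_cols = {}
    addon = np.where(is_ffr, config.ffr_addon, 0.0)
    lump_mi = np.where(t_mi <= t_obs, config.event_cost_means["mi"], 0.0)
    lump_revasc = np.where(t_revasc <= t_obs, config.event_cost_means["revasc"], 0.0)
    lump_death = np.where(t_death <= time_censor, config.event_cost_means["death"], 0.0)
    for y in range(n_years + 1):
        c = addon + config.annual_cost_mean * np.minimum(float(y), t_obs)
        c += np.where(t_mi <= np.minimum(y, t_obs), lump_mi, 0.0)
        c += np.where(t_revasc <= np.minimum(y, t_obs), lump_revasc, 0.0)
        c += np.where(t_death <= np.minimum(y, time_censor), lump_death, 0.0)
        cost_cols[f"cost_year_{y}"] = c

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": np.where(is_ffr, "ffr", "angio"),
            **cov,
            # only events observed in the claims window are recorded:
            # death before administrative censoring, non-fatal events
            # before death and censoring
            "time_death": np.where(t_death <= time_censor, t_death, np.nan),
            "time_mi": np.where(t_mi <= t_obs, t_mi, np.nan),
            "time_revasc": np.where(t_revasc <= t_obs, t_revasc, np.nan),
            "time_censor": time_censor,
            **cost_cols,
        }
    )
    return df
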