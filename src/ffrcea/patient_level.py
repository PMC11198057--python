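"""Individual patient-level cost-effectiveness analysis.

Works on claims-style patient tables (one row per patient, the schema
written by :mod:`ffrcea.synthetic`): per-patient QALYs decomposed into
years lived with angina and years lived after spontaneous MI, truncated
by death, censoring or the analysis horizon (default 4 years,
undiscounted, following observed person-time); cumulative observed
costs up to the first qualifying event; Kaplan-Meier cumulative
incidence; multivariable Cox proportional-hazards regression; and
two-group incremental cost-effectiveness with percentile-bootstrap
intervals resampling whole patients.

Survival estimation and Cox fitting are delegated to ``lifelines``
(Breslow tie handling); the test suite cross-checks the Cox fit against
direct maximization of a hand-written partial likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .economics import compute_icer
from .model_inputs import UtilityInputs

__all__ = [
    "HazardModelFit",
    "GroupCEAResult",
    "patient_qaly",
    "patient_cost",
    "event_durations",
    "km_cumulative_incidence",
    "cox_fit",
    "group_cea",
    "bootstrap_icer",
    "subgroup_cea",
]

EVENT_TIME_COLUMNS = {"death": "time_death", "mi": "time_mi", "revasc": "time_revasc"}


def _col(df: pd.DataFrame, name: str) -> np.ndarray:
    return df[name].to_numpy(dtype=float)


def patient_qaly(records: pd.DataFrame, utilities: UtilityInputs, horizon: float = 4.0) -> np.ndarray:
    """Undiscounted per-patient QALYs over the analysis horizon.

    Years from entry to the first of MI / death / censoring / horizon
    are weighted by the angina utility; years from MI to the first of
    death / censoring / horizon by the post-MI utility; nothing accrues
    after death.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    t_death = np.nan_to_num(_col(records, "time_death"), nan=np.inf)
    t_mi = np.nan_to_num(_col(records, "time_mi"), nan=np.inf)
    t_censor = _col(records, "time_censor")
    both = np.isfinite(t_death) & np.isfinite(t_mi)
    if np.any(t_mi[both] > t_death[both]):
        raise ValueError("inconsistent event times: MI recorded after death")
    stop = np.minimum(np.minimum(t_death, t_censor), horizon)
    angina_years = np.minimum(t_mi, stop)
    mi_years = stop - angina_years
    return utilities.u_angina * angina_years + utilities.u_mi * mi_years


def patient_cost(records: pd.DataFrame, horizon: float = 4.0) -> np.ndarray:
    """Cumulative observed cost per patient up to the first qualifying event.

    The cost stream is read from the cumulative ``cost_year_*`` columns
    and evaluated, with linear interpolation within years, at the first
    of death / spontaneous MI / unplanned revascularization / censoring
    / horizon.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    cost_cols = sorted(
        (c for c in records.columns if c.startswith("cost_year_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not cost_cols:
        return np.zeros(len(records))
    years = np.array([int(c.rsplit("_", 1)[1]) for c in cost_cols], dtype=float)
    C = records[cost_cols].to_numpy(dtype=float)  # (n, K) cumulative at `years`
    stop = np.full(len(records), float(horizon))
    for col in ("time_death", "time_mi", "time_revasc", "time_censor"):
        if col in records.columns:
            t = np.nan_to_num(_col(records, col), nan=np.inf)
            stop = np.minimum(stop, t)
    stop = np.clip(stop, years[0], years[-1])
    # piecewise-linear interpolation of each row's cumulative stream
    out = np.empty(len(records))
    for i in range(len(records)):
        out[i] = np.interp(stop[i], years, C[i])
    return out


def event_durations(records: pd.DataFrame, event: str) -> tuple[np.ndarray, np.ndarray]:
    """Follow-up duration and event indicator for one event type.

    For non-fatal events, death acts as censoring (product-limit
    analysis of the event-specific hazard, as in the source analyses).
    """
    if event not in EVENT_TIME_COLUMNS:
        raise ValueError(f"event must be one of {sorted(EVENT_TIME_COLUMNS)}, got {event!r}")
    t_event = np.nan_to_num(_col(records, EVENT_TIME_COLUMNS[event]), nan=np.inf)
    t_censor = _col(records, "time_censor")
    if event != "death" and "time_death" in records.columns:
        t_death = np.nan_to_num(_col(records, "time_death"), nan=np.inf)
        t_censor = np.minimum(t_censor, t_death)
    duration = np.minimum(t_event, t_censor)
    observed = t_event <= t_censor
    return duration, observed


def km_cumulative_incidence(records: pd.DataFrame, event: str, t_eval: float) -> float:
    """Product-limit (Kaplan-Meier) cumulative incidence at ``t_eval`` years."""
    duration, observed = event_durations(records, event)
    if len(duration) == 0 or duration.max() <= 0:
        raise ValueError("need at least one record with positive follow-up")
    if t_eval > duration.max():
        warnings.warn(
            f"t_eval={t_eval} exceeds the longest follow-up {duration.max():.3g}; "
            "returning the last product-limit estimate",
            stacklevel=2,
        )
    kmf = KaplanMeierFitter()
    kmf.fit(duration, event_observed=observed)
    return float(1.0 - kmf.predict(min(t_eval, duration.max())))


@dataclass(frozen=True)
class HazardModelFit:
    """A fitted Cox proportional-hazards model."""

    coefficients: pd.Series
    standard_errors: pd.Series
    hazard_ratios: pd.DataFrame  # columns hr, ci_low, ci_high
    log_partial_likelihood: float

    def hr(self, name: str) -> tuple[float, float, float]:
        row = self.hazard_ratios.loc[name]
        return float(row["hr"]), float(row["ci_low"]), float(row["ci_high"])


def cox_fit(records: pd.DataFrame, covariate_names: list[str], event: str) -> HazardModelFit:
    """Multivariable Cox regression for one event (Breslow tie handling).

    ``arm`` may be included in ``covariate_names``; it enters as a 0/1
    indicator for FFR-guided PCI.
    """
    duration, observed = event_durations(records, event)
    X = pd.DataFrame(index=records.index)
    for name in covariate_names:
        if name == "arm":
            X["arm"] = (records["arm"] == "ffr").astype(float)
        else:
            X[name] = records[name].astype(float)
    for name in X.columns:
        if X[name].nunique() < 2:
            raise ValueError(f"covariate {name!r} is constant; cannot be estimated")
    if np.unique(duration[observed]).size < 2:
        raise ValueError("need at least two distinct event times")
    frame = X.copy()
    frame["duration"] = duration
    frame["observed"] = observed.astype(int)
    cph = CoxPHFitter()
    cph.fit(
        frame,
        duration_col="duration",
        event_col="observed",
        show_progress=False,
        fit_options={"precision": 1e-9},
    )
    coefs = cph.params_.rename(None)
    ses = cph.standard_errors_.rename(None)
    hrs = pd.DataFrame(
        {
            "hr": np.exp(coefs),
            "ci_low": np.exp(coefs - 1.959963984540054 * ses),
            "ci_high": np.exp(coefs + 1.959963984540054 * ses),
        }
    )
    return HazardModelFit(
        coefficients=coefs,
        standard_errors=ses,
        hazard_ratios=hrs,
        log_partial_likelihood=float(cph.log_likelihood_),
    )


@dataclass(frozen=True)
class GroupCEAResult:
    """Two-group incremental cost-effectiveness summary."""

    n_angio: int
    n_ffr: int
    mean_cost_angio: float
    mean_cost_ffr: float
    mean_qaly_angio: float
    mean_qaly_ffr: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    n_bootstrap: int = 0
    seed: int | None = None
    ci_delta_cost: tuple[float, float] | None = None
    ci_delta_qaly: tuple[float, float] | None = None
    boot_delta_cost: np.ndarray | None = None
    boot_delta_qaly: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "n_angio": self.n_angio,
            "n_ffr": self.n_ffr,
            "mean_cost_angio": self.mean_cost_angio,
            "mean_cost_ffr": self.mean_cost_ffr,
            "mean_qaly_angio": self.mean_qaly_angio,
            "mean_qaly_ffr": self.mean_qaly_ffr,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "ci_delta_cost": list(self.ci_delta_cost) if self.ci_delta_cost else None,
            "ci_delta_qaly": list(self.ci_delta_qaly) if self.ci_delta_qaly else None,
        }


def _arm_arrays(records, utilities, horizon):
    qaly = patient_qaly(records, utilities, horizon)
    cost = patient_cost(records, horizon)
    is_ffr = (records["arm"] == "ffr").to_numpy()
    if is_ffr.all() or (~is_ffr).all():
        raise ValueError("both arms must be non-empty")
    return qaly, cost, is_ffr


def group_cea(records: pd.DataFrame, utilities: UtilityInputs, horizon: float = 4.0) -> GroupCEAResult:
    """Arm-mean costs and QALYs, their differences, and the ICER."""
    qaly, cost, is_ffr = _arm_arrays(records, utilities, horizon)
    mc_a, mc_f = cost[~is_ffr].mean(), cost[is_ffr].mean()
    mq_a, mq_f = qaly[~is_ffr].mean(), qaly[is_ffr].mean()
    dc, de = mc_f - mc_a, mq_f - mq_a
    return GroupCEAResult(
        n_angio=int((~is_ffr).sum()),
        n_ffr=int(is_ffr.sum()),
        mean_cost_angio=float(mc_a),
        mean_cost_ffr=float(mc_f),
        mean_qaly_angio=float(mq_a),
        mean_qaly_ffr=float(mq_f),
        delta_cost=float(dc),
        delta_qaly=float(de),
        icer=compute_icer(dc, de),
    )


def bootstrap_icer(
    records: pd.DataFrame,
    utilities: UtilityInputs,
    horizon: float = 4.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> GroupCEAResult:
    """Percentile-bootstrap intervals for the incremental cost and effect.

    Whole patients (cost and QALY jointly) are resampled with
    replacement from the pooled cohort; each replicate recomputes the
    arm means and their differences; 2.5/97.5 percentiles are reported.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = group_cea(records, utilities, horizon)
    qaly, cost, is_ffr = _arm_arrays(records, utilities, horizon)
    n = len(qaly)
    rng = np.random.default_rng(seed)
    dc = np.empty(n_boot)
    de = np.empty(n_boot)
    chunk = max(1, int(2e7 // n))
    done = 0
    w_ffr = is_ffr.astype(float)
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        w = w_ffr[idx]
        nf = w.sum(axis=1)
        na = n - nf
        # replicates with an empty arm are redrawn one by one (vanishingly
        # rare unless an arm is tiny)
        bad = (nf == 0) | (na == 0)
        while bad.any():
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
            w = w_ffr[idx]
            nf = w.sum(axis=1)
            na = n - nf
            bad = (nf == 0) | (na == 0)
        cost_b = cost[idx]
        qaly_b = qaly[idx]
        dc[done:done + b] = (cost_b * w).sum(axis=1) / nf - (cost_b * (1 - w)).sum(axis=1) / na
        de[done:done + b] = (qaly_b * w).sum(axis=1) / nf - (qaly_b * (1 - w)).sum(axis=1) / na
        done += b
    pct = lambda x: (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))
    return GroupCEAResult(
        n_angio=point.n_angio,
        n_ffr=point.n_ffr,
        mean_cost_angio=point.mean_cost_angio,
        mean_cost_ffr=point.mean_cost_ffr,
        mean_qaly_angio=point.mean_qaly_angio,
        mean_qaly_ffr=point.mean_qaly_ffr,
        delta_cost=point.delta_cost,
        delta_qaly=point.delta_qaly,
        icer=point.icer,
        n_bootstrap=n_boot,
        seed=seed,
        ci_delta_cost=pct(dc),
        ci_delta_qaly=pct(de),
        boot_delta_cost=dc,
        boot_delta_qaly=de,
    )


def subgroup_cea(
    records: pd.DataFrame,
    predicate,
    utilities: UtilityInputs,
    horizon: float = 4.0,
    name: str = "subgroup",
) -> GroupCEAResult:
    """Group CEA restricted to the patients satisfying ``predicate``.

    ``predicate`` is a boolean mask aligned with ``records`` or a
    callable mapping the DataFrame to one.
    """
    mask = predicate(records) if callable(predicate) else np.asarray(predicate, dtype=bool)
    sub = records[mask]
    if sub.empty or (sub["arm"] == "ffr").all() or (sub["arm"] == "angio").all():
        raise ValueError(f"subgroup {name!r} leaves an empty arm")
    return group_cea(sub, utilities, horizon)
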