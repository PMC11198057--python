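"""Three-state annual-cycle cohort simulation.

The model follows a closed cohort of angina patients through three
states — angina, spontaneous MI, and death — with one-year cycles.
Patients in angina may stay, suffer a spontaneous MI, or die; patients
in the post-MI state may die at an elevated annual probability;
death is absorbing.  Unplanned revascularization does not change state:
it is a recurring cost event applied to the angina occupancy at the
arm's annual revascularization probability.

Valuation convention: end-of-cycle.  Costs and utilities for cycle t
(t = 1..T) are weighted by the state occupancy *after* the cycle's
transitions and discounted by 1/(1+r)**t.  No half-cycle correction is
applied.  The one-time FFR add-on cost is charged at cycle 0,
undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_inputs import (
    ArmTransitionInputs,
    CostInputs,
    HealthSystemConfig,
    UtilityInputs,
    derive_ffr_arm,
)

__all__ = [
    "STATE_NAMES",
    "CohortTrace",
    "CohortOutcome",
    "build_transition_matrix",
    "run_cohort",
    "discount_factor",
    "accrue_qalys",
    "accrue_costs",
    "evaluate_arm",
    "compare_arms",
]

STATE_NAMES = ("angina", "mi", "dead")
_CONS_TOL = 1e-12


def build_transition_matrix(arm: ArmTransitionInputs, p_death_post_mi: float) -> np.ndarray:
    """Build the 3x3 row-stochastic transition matrix for one arm.

    Rows/columns are ordered (angina, mi, dead).  Competing transitions
    out of angina are simultaneous with the marginal annual
    probabilities; the remainder stays in angina.
    """
    p_mi, p_death = arm.p_mi_annual, arm.p_death_annual
    if p_mi + p_death >= 1:
        raise ValueError(f"p_mi + p_death = {p_mi + p_death} >= 1")
    if not 0 <= p_death_post_mi <= 1:
        raise ValueError(f"p_death_post_mi must be in [0, 1], got {p_death_post_mi}")
    P = np.array(
        [
            [1.0 - p_mi - p_death, p_mi, p_death],
            [0.0, 1.0 - p_death_post_mi, p_death_post_mi],
            [0.0, 0.0, 1.0],
        ]
    )
    assert np.allclose(P.sum(axis=1), 1.0, atol=_CONS_TOL)
    return P


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy and incident flows over cycles 0..T.

    ``occupancy`` has shape (T+1, 3) with columns (angina, mi, dead);
    row 0 is the initial distribution (1, 0, 0).  ``new_mi[t]`` and
    ``new_deaths[t]`` are the fractions newly entering the MI and dead
    states during cycle t (index 0 is zero by convention).
    """

    occupancy: np.ndarray
    new_mi: np.ndarray
    new_deaths: np.ndarray
    p_revasc_annual: float = 0.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cumulative_mortality(self) -> float:
        return float(self.occupancy[-1, 2])

    @property
    def cumulative_mi_incidence(self) -> float:
        return float(self.new_mi.sum())

    def to_frame(self):
        """Trace as a DataFrame with one row per cycle."""
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles + 1),
                "angina": self.occupancy[:, 0],
                "mi": self.occupancy[:, 1],
                "dead": self.occupancy[:, 2],
                "new_mi": self.new_mi,
                "new_deaths": self.new_deaths,
            }
        )


def run_cohort(
    matrix: np.ndarray,
    n_cycles: int,
    p_revasc_annual: float = 0.0,
    start: np.ndarray | None = None,
) -> CohortTrace:
    """Evolve the cohort for ``n_cycles`` annual cycles.

    occupancy[t] = occupancy[t-1] @ matrix; the incident MI flow in
    cycle t is occupancy[t-1, angina] * P[angina, mi], and the incident
    death flow is the increase of the dead fraction.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError("transition matrix must be 3x3")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    state = np.array([1.0, 0.0, 0.0]) if start is None else np.asarray(start, dtype=float)
    occ = np.empty((n_cycles + 1, 3))
    new_mi = np.zeros(n_cycles + 1)
    new_deaths = np.zeros(n_cycles + 1)
    occ[0] = state
    for t in range(1, n_cycles + 1):
        prev = occ[t - 1]
        occ[t] = prev @ matrix
        new_mi[t] = prev[0] * matrix[0, 1]
        new_deaths[t] = occ[t, 2] - prev[2]
    return CohortTrace(
        occupancy=occ, new_mi=new_mi, new_deaths=new_deaths, p_revasc_annual=p_revasc_annual
    )


def discount_factor(rate: float, t) -> float | np.ndarray:
    """Present-value factor 1/(1+rate)**t for cycle index t."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** -np.asarray(t, dtype=float)


def accrue_qalys(trace: CohortTrace, utilities: UtilityInputs, rate: float) -> float:
    """Discounted QALYs over the trace (end-of-cycle convention).

    Each cycle contributes occupancy-weighted utility — angina occupancy
    times u_angina plus MI occupancy times u_mi — valued at the
    end-of-cycle occupancy and discounted at the cycle index.  The dead
    state contributes nothing.
    """
    T = trace.n_cycles
    t = np.arange(1, T + 1)
    df = discount_factor(rate, t)
    per_cycle = (
        trace.occupancy[1:, 0] * utilities.u_angina
        + trace.occupancy[1:, 1] * utilities.u_mi
    )
    return float(np.sum(df * per_cycle))


def accrue_costs(
    trace: CohortTrace,
    costs: CostInputs,
    rate: float,
    include_ffr_addon: bool = False,
    p_revasc_annual: float | None = None,
) -> float:
    """Discounted costs over the trace.

    Per cycle: annual state costs on the end-of-cycle angina and MI
    occupancies; revascularization cost on angina occupancy times the
    annual revascularization probability; the with-MI revascularization
    cost on the incident-MI flow; the death-related cost on the
    incident-death flow.  The FFR add-on, if requested, is charged once
    at cycle 0 undiscounted.
    """
    if p_revasc_annual is None:
        p_revasc_annual = trace.p_revasc_annual
    T = trace.n_cycles
    t = np.arange(1, T + 1)
    df = discount_factor(rate, t)
    angina = trace.occupancy[1:, 0]
    mi = trace.occupancy[1:, 1]
    per_cycle = (
        angina * costs.annual_angina
        + mi * costs.annual_mi
        + angina * p_revasc_annual * costs.revasc_no_mi
        + trace.new_mi[1:] * costs.revasc_with_mi
        + trace.new_deaths[1:] * costs.death_related
    )
    total = float(np.sum(df * per_cycle))
    if include_ffr_addon:
        total += costs.ffr_addon
    return total


@dataclass(frozen=True)
class CohortOutcome:
    """Per-arm totals from one cohort run."""

    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    cumulative_mortality: float
    cumulative_mi_incidence: float
    trace: CohortTrace


def evaluate_arm(config: HealthSystemConfig, arm: str) -> CohortOutcome:
    """Run one arm of the model under a health-system configuration.

    ``arm`` is ``"angio"`` or ``"ffr"``; the FFR arm's transition
    probabilities are derived per ``config.ffr_arm_mode`` and the FFR
    add-on cost is charged to that arm only.
    """
    if arm == "angio":
        arm_inputs = config.transitions.angio
        addon = False
    elif arm == "ffr":
        arm_inputs = derive_ffr_arm(config.transitions, config.ffr_arm_mode)
        addon = True
    else:
        raise ValueError(f"arm must be 'angio' or 'ffr', got {arm!r}")
    P = build_transition_matrix(arm_inputs, config.transitions.p_death_post_mi)
    trace = run_cohort(P, config.horizon_years, p_revasc_annual=arm_inputs.p_revasc_annual)
    r = config.discount_rate_annual
    return CohortOutcome(
        discounted_cost=accrue_costs(trace, config.costs, r, include_ffr_addon=addon),
        discounted_qaly=accrue_qalys(trace, config.utilities, r),
        undiscounted_cost=accrue_costs(trace, config.costs, 0.0, include_ffr_addon=addon),
        undiscounted_qaly=accrue_qalys(trace, config.utilities, 0.0),
        cumulative_mortality=trace.cumulative_mortality,
        cumulative_mi_incidence=trace.cumulative_mi_incidence,
        trace=trace,
    )


def compare_arms(config: HealthSystemConfig):
    """Run both arms and classify FFR-guided vs angiography-guided PCI.

    Returns ``(outcome_angio, outcome_ffr, comparison)`` where the
    comparison holds the incremental cost/QALY, ICER, dominance class
    and net monetary benefit at the configuration's WTP threshold.
    """
    from .economics import classify

    angio = evaluate_arm(config, "angio")
    ffr = evaluate_arm(config, "ffr")
    comparison = classify(
        ffr.discounted_cost - angio.discounted_cost,
        ffr.discounted_qaly - angio.discounted_qaly,
        config.wtp_per_qaly,
    )
    return angio, ffr, comparison
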