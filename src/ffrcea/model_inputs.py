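"""Model inputs for the decision-analytic comparison of FFR-guided vs
angiography-guided PCI.

Holds every parameter of the annual-cycle cohort model for one health
system — transition probabilities, treatment-effect hazard ratios with
95% CIs, per-state and per-event costs (USD), state utilities, the
discount rate, the willingness-to-pay threshold and the time horizon —
and the conversions between probabilities, rates and hazard-ratio-scaled
probabilities that the simulation engine relies on.

Three health-system parameterizations (``korea``, ``us``, ``uk``) are
bundled as JSON and loadable by name via :func:`load_bundled_config`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "ValidationError",
    "HazardRatioEstimate",
    "ArmTransitionInputs",
    "TransitionInputs",
    "CostInputs",
    "UtilityInputs",
    "HealthSystemConfig",
    "FFR_ARM_MODES",
    "load_model_config",
    "load_bundled_config",
    "bundled_config_names",
    "probability_to_rate",
    "rate_to_probability",
    "apply_hazard_ratio",
    "derive_ffr_arm",
]

#: How the FFR-arm transition probabilities are derived from the inputs.
#: ``observed``                — use the FFR-arm row of the input table verbatim.
#: ``hr_scaled_probability``   — multiply each angiography-arm probability by
#:                               the hazard-ratio point estimate (p * hr).
#: ``hr_scaled_rate``          — apply the hazard ratio on the rate scale,
#:                               1 - (1 - p)**hr.
FFR_ARM_MODES = ("observed", "hr_scaled_probability", "hr_scaled_rate")


class ValidationError(ValueError):
    """An input failed a domain-validity check; the message names the field."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class HazardRatioEstimate:
    """A hazard ratio with its 95% confidence interval."""

    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        _check(self.ci_low > 0, f"hazard ratio ci_low must be > 0, got {self.ci_low}")
        _check(
            self.ci_low <= self.point <= self.ci_high,
            f"hazard ratio CI must bracket the point estimate: "
            f"{self.ci_low} <= {self.point} <= {self.ci_high} fails",
        )


@dataclass(frozen=True)
class ArmTransitionInputs:
    """Annual transition probabilities out of the angina state for one arm."""

    p_mi_annual: float
    p_death_annual: float
    p_revasc_annual: float

    def __post_init__(self) -> None:
        for name in ("p_mi_annual", "p_death_annual", "p_revasc_annual"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")
        _check(
            self.p_mi_annual + self.p_death_annual < 1.0,
            "p_mi_annual + p_death_annual must be < 1 "
            f"(got {self.p_mi_annual} + {self.p_death_annual})",
        )


@dataclass(frozen=True)
class TransitionInputs:
    """Both arms' probabilities plus the between-arm hazard ratios."""

    angio: ArmTransitionInputs
    ffr_observed: ArmTransitionInputs
    hr_death: HazardRatioEstimate
    hr_mi: HazardRatioEstimate
    hr_revasc: HazardRatioEstimate
    p_death_post_mi: float

    def __post_init__(self) -> None:
        _check(
            0.0 <= self.p_death_post_mi <= 1.0,
            f"p_death_post_mi must be in [0, 1], got {self.p_death_post_mi}",
        )


@dataclass(frozen=True)
class CostInputs:
    """Per-state and per-event medical costs in USD."""

    ffr_addon: float          # one-time cost of the pressure-wire study
    annual_angina: float      # USD per year lived in the angina state
    annual_mi: float          # USD per year lived in the post-MI state
    revasc_no_mi: float       # USD per unplanned revascularization, no MI
    revasc_with_mi: float     # USD per revascularization with MI
    death_related: float      # USD attached to the cycle of death

    def __post_init__(self) -> None:
        for name in (
            "ffr_addon", "annual_angina", "annual_mi",
            "revasc_no_mi", "revasc_with_mi", "death_related",
        ):
            _check(getattr(self, name) >= 0, f"cost {name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "ffr_addon": self.ffr_addon,
            "annual_angina": self.annual_angina,
            "annual_mi": self.annual_mi,
            "revasc_no_mi": self.revasc_no_mi,
            "revasc_with_mi": self.revasc_with_mi,
            "death_related": self.death_related,
        }


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utility weights, with optional comorbidity decrements.

    The decrements (atrial fibrillation, heart failure, diabetes) are
    scenario modifiers: they are not applied in the base case but can be
    subtracted from ``u_angina`` / ``u_mi`` via :meth:`with_disutility`.
    """

    u_angina: float
    u_mi: float
    disutilities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check(0.0 <= self.u_angina <= 1.0, f"u_angina must be in [0, 1], got {self.u_angina}")
        _check(0.0 <= self.u_mi <= 1.0, f"u_mi must be in [0, 1], got {self.u_mi}")
        for key, dec in self.disutilities.items():
            _check(dec >= 0, f"disutility {key!r} must be a magnitude >= 0, got {dec}")
            _check(
                self.u_angina - dec >= 0,
                f"disutility {key!r}={dec} would push u_angina below 0",
            )

    def with_disutility(self, *names: str) -> "UtilityInputs":
        """Return utilities with the named decrements applied.

        Decrements whose name ends in ``_with_mi`` reduce ``u_mi``;
        ``_with_angina`` reduce ``u_angina``; any other name reduces both
        states (e.g. congestive heart failure).
        """
        ua, um = self.u_angina, self.u_mi
        for name in names:
            if name not in self.disutilities:
                raise KeyError(f"unknown disutility {name!r}")
            dec = self.disutilities[name]
            if name.endswith("_with_mi"):
                um -= dec
            elif name.endswith("_with_angina"):
                ua -= dec
            else:
                ua -= dec
                um -= dec
        return UtilityInputs(u_angina=ua, u_mi=um, disutilities=self.disutilities)


@dataclass(frozen=True)
class HealthSystemConfig:
    """All model inputs for one health system."""

    name: str
    discount_rate_annual: float
    wtp_per_qaly: float
    horizon_years: int
    transitions: TransitionInputs
    costs: CostInputs
    utilities: UtilityInputs
    ffr_arm_mode: str = "hr_scaled_probability"
    cycle_length_years: float = 1.0

    def __post_init__(self) -> None:
        _check(self.discount_rate_annual >= 0, "discount_rate_annual must be >= 0")
        _check(self.wtp_per_qaly > 0, "wtp_per_qaly must be > 0")
        _check(self.horizon_years >= 1, "horizon_years must be >= 1")
        _check(
            self.ffr_arm_mode in FFR_ARM_MODES,
            f"unknown ffr_arm_mode {self.ffr_arm_mode!r}; expected one of {FFR_ARM_MODES}",
        )
        _check(self.cycle_length_years == 1.0, "only annual cycles are supported")


# ---------------------------------------------------------------------------
# JSON loading


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ValidationError(f"missing field {key!r} in {where}")
    return mapping[key]


def _parse_config(raw: Mapping, source: str) -> HealthSystemConfig:
    traw = _require(raw, "transitions", source)
    transitions = TransitionInputs(
        angio=ArmTransitionInputs(**_require(traw, "angio", "transitions")),
        ffr_observed=ArmTransitionInputs(**_require(traw, "ffr_observed", "transitions")),
        hr_death=HazardRatioEstimate(**_require(traw, "hr_death", "transitions")),
        hr_mi=HazardRatioEstimate(**_require(traw, "hr_mi", "transitions")),
        hr_revasc=HazardRatioEstimate(**_require(traw, "hr_revasc", "transitions")),
        p_death_post_mi=_require(traw, "p_death_post_mi", "transitions"),
    )
    uraw = _require(raw, "utilities", source)
    utilities = UtilityInputs(
        u_angina=_require(uraw, "u_angina", "utilities"),
        u_mi=_require(uraw, "u_mi", "utilities"),
        disutilities=dict(uraw.get("disutilities", {})),
    )
    return HealthSystemConfig(
        name=_require(raw, "name", source),
        discount_rate_annual=_require(raw, "discount_rate_annual", source),
        wtp_per_qaly=_require(raw, "wtp_per_qaly", source),
        horizon_years=_require(raw, "horizon_years", source),
        transitions=transitions,
        costs=CostInputs(**_require(raw, "costs", source)),
        utilities=utilities,
        ffr_arm_mode=raw.get("ffr_arm_mode", "hr_scaled_probability"),
        cycle_length_years=raw.get("cycle_length_years", 1),
    )


def load_model_config(path: str | Path) -> HealthSystemConfig:
    """Load and validate a health-system configuration from a JSON file."""
    path = Path(path)
    with path.open() as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path} is not valid JSON: {exc}") from exc
    try:
        return _parse_config(raw, str(path))
    except TypeError as exc:  # unexpected/missing dataclass kwargs
        raise ValidationError(f"bad field in {path}: {exc}") from exc


def bundled_config_names() -> list[str]:
    """Names of the health-system configurations shipped with the package."""
    pkg = resources.files("ffrcea") / "configs"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".json"))


def load_bundled_config(name: str) -> HealthSystemConfig:
    """Load one of the bundled configurations (``korea``, ``us``, ``uk``)."""
    ref = resources.files("ffrcea") / "configs" / f"{name}.json"
    if not ref.is_file():
        raise ValidationError(
            f"no bundled config named {name!r}; available: {bundled_config_names()}"
        )
    raw = json.loads(ref.read_text())
    return _parse_config(raw, f"bundled:{name}")


# ---------------------------------------------------------------------------
# Probability / rate / hazard-ratio conversions


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Convert a cumulative probability over ``t`` years to a constant rate.

    r = -ln(1 - p) / t, the standard actuarial conversion assuming a
    constant hazard over the interval.
    """
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if p < 0:
        raise ValueError(f"probability must be >= 0, got {p}")
    if p >= 1:
        raise ValueError(f"probability {p} >= 1 implies an infinite rate")
    return -math.log1p(-p) / t


def rate_to_probability(r: float, t: float = 1.0) -> float:
    """Inverse of :func:`probability_to_rate`: p = 1 - exp(-r t)."""
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if r < 0:
        raise ValueError(f"rate must be >= 0, got {r}")
    return -math.expm1(-r * t)


def apply_hazard_ratio(p_ref: float, hr: float, mode: str = "hr_scaled_probability") -> float:
    """Scale a reference-arm annual probability by a hazard ratio.

    ``hr_scaled_probability`` multiplies on the probability scale (p * hr);
    ``hr_scaled_rate`` applies the ratio on the hazard scale,
    1 - (1 - p)**hr, which is exact for proportional hazards over one
    cycle.  The two agree to first order for small p.
    """
    if not 0 <= p_ref < 1:
        raise ValueError(f"p_ref must be in [0, 1), got {p_ref}")
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    if mode == "hr_scaled_probability":
        out = p_ref * hr
        if out >= 1:
            raise ValueError(
                f"p_ref * hr = {out} >= 1; use hr_scaled_rate for large effects"
            )
        return out
    if mode == "hr_scaled_rate":
        return -math.expm1(hr * math.log1p(-p_ref))
    raise ValueError(f"unknown mode {mode!r}")


def derive_ffr_arm(transitions: TransitionInputs, mode: str) -> ArmTransitionInputs:
    """Derive the FFR-arm annual probabilities under the requested mode."""
    if mode == "observed":
        return transitions.ffr_observed
    if mode not in ("hr_scaled_probability", "hr_scaled_rate"):
        raise ValueError(f"unknown ffr_arm_mode {mode!r}")
    a = transitions.angio
    return ArmTransitionInputs(
        p_mi_annual=apply_hazard_ratio(a.p_mi_annual, transitions.hr_mi.point, mode),
        p_death_annual=apply_hazard_ratio(a.p_death_annual, transitions.hr_death.point, mode),
        p_revasc_annual=apply_hazard_ratio(a.p_revasc_annual, transitions.hr_revasc.point, mode),
    )
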