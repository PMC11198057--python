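"""Incremental cost-effectiveness quantities and decisions.

Given the costs and QALYs of two strategies (here FFR-guided PCI vs
angiography-guided PCI), computes the incremental cost ΔC, incremental
effect ΔE, the ICER = ΔC/ΔE, the net monetary benefit NMB = λ·ΔE − ΔC
at a willingness-to-pay threshold λ, the dominance class, and the
cost-effectiveness acceptability curve over a λ grid.

A negative ICER is reported as computed (its magnitude is not
decision-meaningful on its own, which is why the dominance class and
NMB are always reported alongside it).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ComparisonResult", "compute_icer", "classify", "ceac"]


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental comparison of one strategy against a reference."""

    delta_cost: float
    delta_qaly: float
    icer: float | None          # None when delta_qaly == 0
    dominance: str
    cost_effective_at_wtp: bool
    nmb: float
    wtp: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_icer(delta_cost: float, delta_qaly: float) -> float | None:
    """ΔC/ΔE, or None when ΔE is exactly zero (undefined ratio)."""
    if delta_qaly == 0:
        return None
    return delta_cost / delta_qaly


def _dominance(delta_cost: float, delta_qaly: float) -> str:
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    if delta_qaly >= 0:
        return "tradeoff_more_costly_more_effective"
    return "tradeoff_less_costly_less_effective"


def classify(delta_cost: float, delta_qaly: float, wtp: float) -> ComparisonResult:
    """Classify an incremental comparison at a willingness-to-pay threshold.

    ``cost_effective_at_wtp`` is NMB > 0, which coincides with the
    "ICER below λ" rule whenever ΔE > 0 and extends it consistently to
    the other quadrants.
    """
    if wtp <= 0:
        raise ValueError(f"wtp must be > 0, got {wtp}")
    nmb = wtp * delta_qaly - delta_cost
    return ComparisonResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=compute_icer(delta_cost, delta_qaly),
        dominance=_dominance(delta_cost, delta_qaly),
        cost_effective_at_wtp=bool(nmb > 0),
        nmb=nmb,
        wtp=wtp,
    )


def ceac(
    samples: Iterable[tuple[float, float]] | np.ndarray,
    lambda_grid: Sequence[float],
) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each λ in ``lambda_grid``, the fraction of (ΔC, ΔE) samples with
    positive net monetary benefit λ·ΔE − ΔC.  Returns an array the same
    length as the grid, with values in [0, 1].
    """
    arr = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("samples must be a non-empty sequence of (delta_cost, delta_qaly) pairs")
    dc, de = arr[:, 0], arr[:, 1]
    grid = np.asarray(lambda_grid, dtype=float)
    return np.array([(lam * de - dc > 0).mean() for lam in grid])
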