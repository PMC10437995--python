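"""Deterministic cost-effectiveness algebra.

Two strategies are compared: the education intervention and current
practice.  With incremental cost ΔC (USD per child) and incremental effect
ΔE (cognitive composite score units), the incremental cost-effectiveness
ratio is ICER = ΔC / ΔE, reported only in the north-east quadrant of the
cost-effectiveness plane where both increments are positive; elsewhere a
dominance flag replaces the ratio.  The net monetary benefit at
willingness-to-pay λ is NMB = λ·ΔE − ΔC.  No discounting is applied: the
analysis horizon (18 months) is too short for differential timing to
matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class Quadrant(str, Enum):
    """Quadrant of the cost-effectiveness plane, x = ΔE, y = ΔC."""

    NE = "NE"  # more effective, more costly: ICER meaningful
    SE = "SE"  # more effective, cost-saving: dominant
    NW = "NW"  # less effective, more costly: dominated
    SW = "SW"  # less effective, cost-saving


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost, incremental effect, and their ratio or dominance flag."""

    delta_c: float
    delta_e: float
    icer: float | None
    quadrant: Quadrant
    dominance: str | None = None  # "dominant" | "dominated" | None

    def to_dict(self, rounding: int | None = 2) -> dict:
        icer = self.icer
        if icer is not None and rounding is not None:
            icer = round(icer, rounding)
        return {
            "delta_c": round(self.delta_c, 2) if rounding is not None else self.delta_c,
            "delta_e": self.delta_e,
            "icer": icer,
            "quadrant": self.quadrant.value,
            "dominance": self.dominance,
        }


def classify_quadrant(delta_c: float, delta_e: float) -> Quadrant:
    """Sign-based quadrant; zero ΔE counts toward the costly/dominated side."""
    if delta_e > 0:
        return Quadrant.NE if delta_c >= 0 else Quadrant.SE
    return Quadrant.NW if delta_c >= 0 else Quadrant.SW


def icer(delta_c: float, delta_e: float) -> CEAResult:
    """Incremental cost-effectiveness ratio with dominance handling.

    A finite ratio is reported when ΔE > 0 and ΔC ≥ 0 (NE quadrant).  A
    more effective, cheaper intervention (SE) is flagged "dominant"; a less
    effective, costlier one (NW) "dominated"; ΔE = 0 at positive cost is
    dominated with an infinite ICER.
    """
    if not (math.isfinite(delta_c) and math.isfinite(delta_e)):
        raise ValueError("delta_c and delta_e must be finite")
    if delta_e > 0:
        if delta_c >= 0:
            return CEAResult(delta_c, delta_e, delta_c / delta_e, Quadrant.NE)
        return CEAResult(delta_c, delta_e, None, Quadrant.SE, dominance="dominant")
    if delta_e == 0:
        if delta_c > 0:
            return CEAResult(delta_c, delta_e, None, Quadrant.NW, dominance="dominated")
        return CEAResult(delta_c, delta_e, None, classify_quadrant(delta_c, delta_e))
    # delta_e < 0
    if delta_c >= 0:
        return CEAResult(delta_c, delta_e, None, Quadrant.NW, dominance="dominated")
    return CEAResult(delta_c, delta_e, None, Quadrant.SW)


def nmb(delta_c: float, delta_e: float, wtp: float) -> float:
    """Net monetary benefit λ·ΔE − ΔC at willingness-to-pay λ ≥ 0.

    Positive NMB means the intervention is cost-effective at that
    willingness to pay; NMB vanishes exactly at λ = ICER.
    """
    if wtp < 0:
        raise ValueError(f"willingness to pay must be >= 0, got {wtp}")
    return wtp * delta_e - delta_c


def daly_weight_threshold(
    delta_c: float, wtp_per_daly: float, duration_years: float
) -> float:
    """Smallest avoided-disability weight making the intervention cost-effective.

    The cognitive gain has no established DALY mapping, so invert the
    question: if the intervention averts ``w × duration_years`` DALYs per
    child, its cost per DALY averted is ΔC / (w · T); it meets a
    willingness-to-pay of λ per DALY iff w ≥ ΔC / (λ · T).  Returns that
    threshold weight w*.
    """
    if delta_c <= 0 or wtp_per_daly <= 0 or duration_years <= 0:
        raise ValueError("delta_c, wtp_per_daly and duration_years must be positive")
    return delta_c / (wtp_per_daly * duration_years)
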