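"""Incremental cost-effectiveness comparison of two strategy outcomes."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .markov import ModelConventions, Strategy, StrategyOutcome, run_cohort
from .params import ParameterSet

__all__ = ["Dominance", "CEAResult", "icer", "salvage_reduction", "evaluate"]


class Dominance(str, Enum):
    """Sign-pattern classification of an incremental comparison.

    Ratios are reported only in the north-east quadrant (costlier and more
    effective); in dominance quadrants the ratio's sign is misleading, so a
    flag replaces it.
    """

    NONE = "none"
    DOMINANT = "dominant"  # reference cheaper and at least as effective
    DOMINATED = "dominated"  # reference costlier and no more effective


@dataclass
class CEAResult:
    reference_cost: float
    reference_qaly: float
    comparator_cost: float
    comparator_qaly: float
    delta_cost: float
    delta_qaly: float
    icer: float | None  # CNY/QALY; None in dominance/SW quadrants, inf when delta_qaly = 0
    dominance: Dominance
    wtp: float
    nmb_at_wtp: float
    cost_effective: bool
    salvage_reduction: float | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["dominance"] = self.dominance.value
        if self.icer is not None and math.isinf(self.icer):
            d["icer"] = "inf" if self.icer > 0 else "-inf"
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def icer(
    reference: StrategyOutcome,
    comparator: StrategyOutcome,
    wtp: float = 140_000.0,
) -> CEAResult:
    """Incremental comparison ``reference - comparator`` at a WTP threshold.

    The ICER ``delta_cost / delta_qaly`` is reported when the reference is
    costlier and more effective; otherwise dominance flags apply.  The net
    monetary benefit ``wtp * delta_qaly - delta_cost`` carries the decision
    in every quadrant; ``cost_effective`` is True for a dominant reference
    and whenever the NMB is non-negative outside dominated comparisons.
    """
    dc = reference.total_cost - comparator.total_cost
    dq = reference.total_qaly - comparator.total_qaly
    nmb = wtp * dq - dc

    if dc == 0.0 and dq == 0.0:
        return CEAResult(
            reference.total_cost, reference.total_qaly,
            comparator.total_cost, comparator.total_qaly,
            dc, dq, math.inf, Dominance.NONE, wtp, nmb, False,
        )
    if dq >= 0.0 and dc <= 0.0:
        dominance, ratio, ce = Dominance.DOMINANT, None, True
    elif dq <= 0.0 and dc >= 0.0:
        dominance, ce = Dominance.DOMINATED, False
        ratio = math.copysign(math.inf, dc) if dq == 0.0 else None
    elif dq > 0.0 and dc > 0.0:
        dominance, ratio = Dominance.NONE, dc / dq
        ce = ratio <= wtp
    else:  # dq < 0 and dc < 0: cheaper and worse; ratio misleading
        dominance, ratio = Dominance.NONE, None
        ce = nmb >= 0.0
    return CEAResult(
        reference.total_cost, reference.total_qaly,
        comparator.total_cost, comparator.total_qaly,
        dc, dq, ratio, dominance, wtp, nmb, ce,
    )


def salvage_reduction(reference: StrategyOutcome, comparator: StrategyOutcome) -> float:
    """Relative reduction in cumulative salvage incidence vs the comparator."""
    if comparator.salvage_rate <= 0.0:
        raise ValueError("comparator salvage rate is zero; reduction undefined")
    return (comparator.salvage_rate - reference.salvage_rate) / comparator.salvage_rate


def evaluate(
    params: ParameterSet,
    conventions: ModelConventions | None = None,
    wtp: float | None = None,
) -> tuple[StrategyOutcome, StrategyOutcome, CEAResult]:
    """Run both arms and compare navigated against traditional IMN."""
    nav = run_cohort(Strategy.NAVIGATED, params, conventions)
    trad = run_cohort(Strategy.TRADITIONAL, params, conventions)
    result = icer(nav, trad, wtp if wtp is not None else params.economics.wtp)
    result.salvage_reduction = salvage_reduction(nav, trad)
    return nav, trad, result
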