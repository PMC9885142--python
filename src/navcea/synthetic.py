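"""Synthetic stand-ins for inputs the source data do not include.

The background-mortality table the analysis cites (a national census life
table) is not published with it, and property-based tests need whole
randomized parameter scenarios.  This module generates both: Gompertz-shaped
life tables (exponentially increasing hazard with age, the standard shape of
adult human mortality) and uniformly perturbed parameter sets that always
satisfy the model's validation invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .params import (
    ClinicalProbabilities,
    CostInputs,
    EconomicSettings,
    LifeTable,
    ParameterSet,
    Utilities,
    default_parameter_set,
)

__all__ = ["LifeTableSpec", "ScenarioSpec", "gompertz_life_table", "random_parameter_set"]


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz life-table shape: ``qx(age) = min(1, q0 * exp(slope*(age-age_lo)))``."""

    q_at_start_age: float = 0.02
    gompertz_slope: float = 0.09  # per-year log-hazard increment
    age_lo: int = 40
    age_hi: int = 110

    def __post_init__(self) -> None:
        if not 0.0 < self.q_at_start_age < 1.0:
            raise ValueError("q_at_start_age must lie in (0, 1)")
        if self.age_hi < self.age_lo:
            raise ValueError("age_hi < age_lo")


def gompertz_life_table(spec: LifeTableSpec) -> LifeTable:
    """Life table with exponentially increasing annual death probability."""
    ages = np.arange(spec.age_lo, spec.age_hi + 1)
    qx = np.minimum(
        1.0, spec.q_at_start_age * np.exp(spec.gompertz_slope * (ages - spec.age_lo))
    )
    return LifeTable(ages, qx)


def _pm50(value: float, lo_cap: float | None = None, hi_cap: float | None = None):
    lo, hi = 0.5 * value, 1.5 * value
    if lo_cap is not None:
        lo = max(lo, lo_cap)
    if hi_cap is not None:
        hi = min(hi, hi_cap)
    return (min(lo, hi), max(lo, hi))


@dataclass(frozen=True)
class ScenarioSpec:
    """Per-parameter uniform ranges for randomized scenarios.

    Defaults are ±50% of the reference-case values, clipped to each
    parameter's valid domain.  ``ranges`` maps dotted field names
    (``"clinical.p_safe_nav"``) to ``(lo, hi)``.
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def resolved(self) -> dict[str, tuple[float, float]]:
        base = default_parameter_set()
        out: dict[str, tuple[float, float]] = {}
        for block_name, block in (
            ("clinical", base.clinical),
            ("utilities", base.utilities),
            ("costs", base.costs),
        ):
            for f in fields(block):
                name = f"{block_name}.{f.name}"
                v = float(getattr(block, f.name))
                if block_name == "clinical" and f.name != "odds_ratio_unsafe":
                    out[name] = _pm50(v, 0.0, 0.999)
                elif name == "utilities.disutility_salvage":
                    out[name] = (1.5 * v, 0.5 * v)  # v is negative
                elif block_name == "utilities" and f.name.startswith("u_"):
                    out[name] = _pm50(v, 0.0, 1.0)
                elif block_name == "utilities":
                    continue  # Harris scores are derivation inputs, not model inputs
                elif f.name in ("amortization_years", "annual_volume"):
                    out[name] = _pm50(v, 1.0, None)
                else:
                    out[name] = _pm50(v, 0.0, None)
        out.update(self.ranges)
        return out


def random_parameter_set(
    spec: ScenarioSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> ParameterSet:
    """Draw a validated random scenario around the reference case.

    Uniform draws within the spec ranges; the safe/unsafe failure
    probabilities are re-ordered if a draw inverts them, and the background
    mortality is a random Gompertz table.  Zero-width ranges reproduce the
    reference case exactly.
    """
    spec = spec or ScenarioSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in spec.resolved().items()}
    f_lo = draws.get("clinical.annual_fail_safe")
    f_hi = draws.get("clinical.annual_fail_unsafe")
    if f_lo is not None and f_hi is not None and f_hi < f_lo:
        draws["clinical.annual_fail_safe"], draws["clinical.annual_fail_unsafe"] = f_hi, f_lo
    lt = gompertz_life_table(
        LifeTableSpec(q_at_start_age=float(rng.uniform(0.005, 0.05)),
                      gompertz_slope=float(rng.uniform(0.0, 0.12)))
    )
    ps = default_parameter_set().with_overrides(life_table=lt, **draws)
    ps.validate()
    return ps
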