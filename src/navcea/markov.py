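"""Four-state annual-cycle Markov cohort engine.

States
------
``SAFE_FIX``     successful fixation, lag screw inside the safe zone (TAD < 20 mm)
``UNSAFE_FIX``   successful fixation, lag screw outside the safe zone
``SALVAGE_THA``  converted to salvage total hip arthroplasty after fixation failure
``DEAD``         absorbing

Each cycle is one year.  Within a cycle events occur in a fixed order:
(a) background death — elevated first-postoperative-year mortality in cycle 1
for fixation states, age-specific mortality otherwise; (b) fixation failure
among the survivors, with perioperative THA mortality, the THA procedure cost
and a one-time disutility on conversion; (c) utility accrual.  Salvage THA
never fails within the horizon, so ``SALVAGE_THA`` is absorbing but for death.

Discrete modelling conventions that decision-analysis software leaves to the
analyst (utility accrual timing, partial-cycle utility of decedents, discount
treatment of effectiveness, the cycle at which fixation failure becomes
possible, and whether first-year mortality subsumes the perioperative deaths)
are collected in :class:`ModelConventions` and resolved against published
reference-case outputs by :mod:`navcea.calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum

import numpy as np
import pandas as pd

from .params import ParameterSet, nav_cost_per_patient

__all__ = [
    "Strategy",
    "State",
    "AccrualTiming",
    "ModelConventions",
    "CohortTrace",
    "StrategyOutcome",
    "MicrosimOutcome",
    "initial_distribution",
    "cycle_transition",
    "run_cohort",
    "microsim_oracle",
]


class Strategy(str, Enum):
    NAVIGATED = "navigated"
    TRADITIONAL = "traditional"


class State(IntEnum):
    SAFE_FIX = 0
    UNSAFE_FIX = 1
    SALVAGE_THA = 2
    DEAD = 3


class AccrualTiming(str, Enum):
    """When within a cycle state utilities are credited.

    ``END``         end-of-cycle occupancy; decedents get a configurable
                    fraction of the annual utility.
    ``START``       start-of-cycle occupancy (events of the cycle do not
                    reduce that cycle's accrual).
    ``HALF_CYCLE``  mean of start- and end-of-cycle occupancy (the classic
                    half-cycle correction applied to rewards).
    """

    END = "end"
    START = "start"
    HALF_CYCLE = "half_cycle"


@dataclass(frozen=True)
class ModelConventions:
    """Discrete conventions of the cycle arithmetic.

    first_year_mortality_includes_periop
        If True, the 20% first-postoperative-year mortality is read as
        including the 6% perioperative deaths, so the cycle-1 conditional
        probability is ``(p1 - pp) / (1 - pp)``; if False the full 20%
        applies on top of perioperative mortality.
    accrual_timing
        See :class:`AccrualTiming`.
    dying_cycle_utility_fraction
        Fraction of the annual utility accrued by patients who die within
        the cycle (0, 0.5 or 1); used only with END timing (START and
        HALF_CYCLE already credit decedents at cycle start).
    failures_from_cycle
        First cycle in which fixation failure is possible.  2 means the
        fixation is considered at risk only after the first postoperative
        year (the year dominated by excess mortality).
    discount_qalys
        Whether effectiveness is discounted alongside costs.
    discount_first_cycle
        If True, cycle-t flows are discounted by ``(1+r)^-t``; if False
        discounting starts one cycle later (``(1+r)^-(t-1)``).  Not part of
        the calibration grid: with undiscounted effectiveness it is
        unidentifiable from the calibration anchors, so the conventional
        choice (True) is fixed.
    """

    first_year_mortality_includes_periop: bool = False
    accrual_timing: AccrualTiming = AccrualTiming.END
    dying_cycle_utility_fraction: float = 0.5
    failures_from_cycle: int = 1
    discount_qalys: bool = True
    discount_first_cycle: bool = True

    def __post_init__(self) -> None:
        if self.dying_cycle_utility_fraction not in (0.0, 0.5, 1.0):
            raise ValueError("dying_cycle_utility_fraction must be 0, 0.5 or 1")
        if self.failures_from_cycle not in (1, 2):
            raise ValueError("failures_from_cycle must be 1 or 2")

    def discount_exponent(self, cycle: int) -> float:
        e = float(cycle) - (0.0 if self.discount_first_cycle else 1.0)
        return max(e, 0.0)


@dataclass
class CohortTrace:
    """Per-cycle record of a cohort run (row 0 = post-surgery baseline)."""

    occupancy: np.ndarray  # (horizon+1, 4)
    cycle_cost: np.ndarray  # undiscounted; index 0 = surgery cost
    cycle_qaly: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    new_salvage: np.ndarray
    start_age: int

    @property
    def cum_salvage(self) -> np.ndarray:
        return np.cumsum(self.new_salvage)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.occupancy.shape[0]
        return pd.DataFrame(
            {
                "cycle": np.arange(n),
                "age": self.start_age + np.maximum(np.arange(n) - 1, 0),
                "safe_fix": self.occupancy[:, State.SAFE_FIX],
                "unsafe_fix": self.occupancy[:, State.UNSAFE_FIX],
                "salvage_tha": self.occupancy[:, State.SALVAGE_THA],
                "dead": self.occupancy[:, State.DEAD],
                "cycle_cost": self.cycle_cost,
                "cycle_qaly": self.cycle_qaly,
                "disc_cost": self.disc_cost,
                "disc_qaly": self.disc_qaly,
                "new_salvage": self.new_salvage,
                "cum_salvage": self.cum_salvage,
            }
        )


@dataclass
class StrategyOutcome:
    """Totals for one strategy: discounted cost, effectiveness, salvage incidence."""

    strategy: Strategy
    total_cost: float
    total_qaly: float
    salvage_rate: float  # undiscounted cumulative incidence of salvage THA
    trace: CohortTrace | None = None


@dataclass
class MicrosimOutcome(StrategyOutcome):
    """Monte-Carlo estimate from individual-level simulation, with standard errors."""

    n_patients: int = 0
    se_cost: float = float("nan")
    se_qaly: float = float("nan")
    se_salvage: float = float("nan")


def _p_safe(strategy: Strategy, params: ParameterSet) -> float:
    return (
        params.clinical.p_safe_nav
        if strategy is Strategy.NAVIGATED
        else params.clinical.p_safe_trad
    )


def _u_fix(strategy: Strategy, params: ParameterSet) -> float:
    return (
        params.utilities.u_nav
        if strategy is Strategy.NAVIGATED
        else params.utilities.u_trad
    )


def initial_distribution(strategy: Strategy, params: ParameterSet) -> np.ndarray:
    """State occupancy immediately after the index IMN surgery.

    The whole cohort undergoes IMN; a fraction ``p_periop_death_imn`` dies
    perioperatively, and survivors split between the safe and unsafe zones
    according to the strategy's safe-zone probability.
    """
    pp = params.clinical.p_periop_death_imn
    p_safe = _p_safe(strategy, params)
    v = np.zeros(4)
    v[State.DEAD] = pp
    v[State.SAFE_FIX] = (1.0 - pp) * p_safe
    v[State.UNSAFE_FIX] = (1.0 - pp) * (1.0 - p_safe)
    return v


def _fixation_death_prob(
    cycle: int, age: int, params: ParameterSet, conventions: ModelConventions
) -> float:
    if cycle == 1:
        p1 = params.clinical.p_death_first_year
        if conventions.first_year_mortality_includes_periop:
            pp = params.clinical.p_periop_death_imn
            p1 = max(0.0, (p1 - pp) / (1.0 - pp)) if pp < 1.0 else 0.0
        return p1
    return params.life_table.lookup(age)


def cycle_transition(
    state: np.ndarray,
    cycle_index: int,
    strategy: Strategy,
    params: ParameterSet,
    conventions: ModelConventions,
) -> tuple[np.ndarray, float, float, float]:
    """Advance the cohort one cycle.

    Returns ``(new_state, cycle_cost, cycle_qaly, new_salvage)`` with cost
    and QALY undiscounted; the caller applies discount factors.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index starts at 1; cycle 0 is the index surgery")
    cl, ut = params.clinical, params.utilities
    age = params.economics.start_age + cycle_index - 1
    q_fix = _fixation_death_prob(cycle_index, age, params, conventions)
    q_salv = params.life_table.lookup(age)
    u_fix = _u_fix(strategy, params)

    s, u, v = state[State.SAFE_FIX], state[State.UNSAFE_FIX], state[State.SALVAGE_THA]
    start_living_u = (s + u) * u_fix + v * ut.u_tha

    d_s, d_u, d_v = s * q_fix, u * q_fix, v * q_salv
    at_risk = 1.0 if cycle_index >= conventions.failures_from_cycle else 0.0
    f_in = cl.annual_fail_safe * at_risk
    f_out = cl.annual_fail_unsafe * at_risk
    fail_s = s * (1.0 - q_fix) * f_in
    fail_u = u * (1.0 - q_fix) * f_out
    new_salvage = fail_s + fail_u  # every failure undergoes the salvage operation
    d_tha = new_salvage * cl.p_periop_death_tha
    to_salvage = new_salvage - d_tha

    new = np.empty(4)
    new[State.SAFE_FIX] = s * (1.0 - q_fix) * (1.0 - f_in)
    new[State.UNSAFE_FIX] = u * (1.0 - q_fix) * (1.0 - f_out)
    new[State.SALVAGE_THA] = v * (1.0 - q_salv) + to_salvage
    new[State.DEAD] = state[State.DEAD] + d_s + d_u + d_v + d_tha

    cycle_cost = new_salvage * params.costs.cost_tha

    end_living_u = (
        (new[State.SAFE_FIX] + new[State.UNSAFE_FIX]) * u_fix
        + new[State.SALVAGE_THA] * ut.u_tha
    )
    timing = conventions.accrual_timing
    if timing is AccrualTiming.END:
        frac = conventions.dying_cycle_utility_fraction
        cycle_qaly = end_living_u + frac * (
            (d_s + d_u + d_tha) * u_fix + d_v * ut.u_tha
        )
    elif timing is AccrualTiming.START:
        cycle_qaly = start_living_u
    else:  # HALF_CYCLE
        cycle_qaly = 0.5 * (start_living_u + end_living_u)
    cycle_qaly += to_salvage * ut.disutility_salvage

    return new, cycle_cost, cycle_qaly, new_salvage


def run_cohort(
    strategy: Strategy,
    params: ParameterSet,
    conventions: ModelConventions | None = None,
    keep_trace: bool = True,
) -> StrategyOutcome:
    """Run the cohort over the full horizon and return strategy totals.

    The index-surgery cost (IMN procedure plus, for the navigated arm, the
    per-patient navigation allocation) is charged to the whole cohort at
    cycle 0, undiscounted.  Cycle ``t >= 1`` costs are discounted by
    ``(1 + r)^-e(t)``; effectiveness is discounted the same way iff the
    conventions say so.  ``salvage_rate`` is the undiscounted cumulative
    incidence of the salvage operation.
    """
    if conventions is None:
        conventions = ModelConventions()
    params.validate()
    econ = params.economics
    horizon = econ.horizon
    r = econ.discount_rate

    surgery_cost = params.costs.cost_imn
    if strategy is Strategy.NAVIGATED:
        surgery_cost += nav_cost_per_patient(params.costs)

    occ = np.zeros((horizon + 1, 4))
    cycle_cost = np.zeros(horizon + 1)
    cycle_qaly = np.zeros(horizon + 1)
    disc_cost = np.zeros(horizon + 1)
    disc_qaly = np.zeros(horizon + 1)
    new_salvage = np.zeros(horizon + 1)

    occ[0] = initial_distribution(strategy, params)
    cycle_cost[0] = disc_cost[0] = surgery_cost

    state = occ[0]
    for t in range(1, horizon + 1):
        state, c, q, ns = cycle_transition(state, t, strategy, params, conventions)
        df = (1.0 + r) ** (-conventions.discount_exponent(t))
        occ[t] = state
        cycle_cost[t], cycle_qaly[t], new_salvage[t] = c, q, ns
        disc_cost[t] = c * df
        disc_qaly[t] = q * df if conventions.discount_qalys else q

    trace = CohortTrace(
        occupancy=occ,
        cycle_cost=cycle_cost,
        cycle_qaly=cycle_qaly,
        disc_cost=disc_cost,
        disc_qaly=disc_qaly,
        new_salvage=new_salvage,
        start_age=econ.start_age,
    )
    return StrategyOutcome(
        strategy=strategy,
        total_cost=float(disc_cost.sum()),
        total_qaly=float(disc_qaly.sum()),
        salvage_rate=float(new_salvage.sum()),
        trace=trace if keep_trace else None,
    )


def microsim_oracle(
    strategy: Strategy,
    params: ParameterSet,
    conventions: ModelConventions | None = None,
    n_patients: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> MicrosimOutcome:
    """Individual-level Monte-Carlo simulation of the identical event sequence.

    Draws each patient's perioperative survival, zone assignment, annual
    deaths, fixation failures and salvage perioperative deaths with a
    pseudo-random stream; sample means converge to the :func:`run_cohort`
    expectations.  Serves as an independent check of the cohort arithmetic.
    """
    if conventions is None:
        conventions = ModelConventions()
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cl, ut, econ = params.clinical, params.utilities, params.economics
    r = econ.discount_rate
    u_fix = _u_fix(strategy, params)
    p_safe = _p_safe(strategy, params)
    timing = conventions.accrual_timing
    frac = conventions.dying_cycle_utility_fraction

    surgery_cost = params.costs.cost_imn
    if strategy is Strategy.NAVIGATED:
        surgery_cost += nav_cost_per_patient(params.costs)

    n = n_patients
    alive = rng.random(n) >= cl.p_periop_death_imn
    safe = rng.random(n) < p_safe
    in_fix = alive.copy()
    in_salvage = np.zeros(n, dtype=bool)
    ever_salvage = np.zeros(n, dtype=bool)
    cost = np.full(n, surgery_cost)
    qaly = np.zeros(n)

    for t in range(1, econ.horizon + 1):
        age = econ.start_age + t - 1
        df = (1.0 + r) ** (-conventions.discount_exponent(t))
        dfq = df if conventions.discount_qalys else 1.0
        q_fix = _fixation_death_prob(t, age, params, conventions)
        q_salv = params.life_table.lookup(age)

        start_u = u_fix * in_fix + ut.u_tha * in_salvage  # per-patient utility weight

        u_draw = rng.random(n)
        die_fix = in_fix & (u_draw < q_fix)
        die_salv = in_salvage & (u_draw < q_salv)
        in_fix &= ~die_fix
        in_salvage &= ~die_salv

        if t >= conventions.failures_from_cycle:
            f_prob = np.where(safe, cl.annual_fail_safe, cl.annual_fail_unsafe)
            fails = in_fix & (rng.random(n) < f_prob)
        else:
            fails = np.zeros(n, dtype=bool)
        cost += params.costs.cost_tha * df * fails
        ever_salvage |= fails
        die_tha = fails & (rng.random(n) < cl.p_periop_death_tha)
        survive_tha = fails & ~die_tha
        in_fix &= ~fails
        in_salvage |= survive_tha

        end_u = u_fix * in_fix + ut.u_tha * in_salvage
        if timing is AccrualTiming.END:
            cyc = end_u + frac * (u_fix * (die_fix | die_tha) + ut.u_tha * die_salv)
        elif timing is AccrualTiming.START:
            cyc = start_u
        else:
            cyc = 0.5 * (start_u + end_u)
        qaly += dfq * (cyc + ut.disutility_salvage * survive_tha)

    return MicrosimOutcome(
        strategy=strategy,
        total_cost=float(cost.mean()),
        total_qaly=float(qaly.mean()),
        salvage_rate=float(ever_salvage.mean()),
        trace=None,
        n_patients=n,
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)),
        se_salvage=float(ever_salvage.std(ddof=1) / np.sqrt(n)),
    )
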