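"""Deterministic sensitivity analyses and threshold searches.

One-way analyses perturb a single model input over a range and record the
ICER of navigated vs traditional IMN; the ICER-vs-volume curve follows a
closed-form inverse-volume law because only the per-patient navigation
allocation depends on the annual case volume; threshold searches find the
parameter value at which the ICER crosses the willingness-to-pay line
(equivalently, where the incremental net monetary benefit changes sign).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cea import evaluate
from .markov import ModelConventions, Strategy, run_cohort
from .params import ParameterSet

__all__ = [
    "OneWayResult",
    "TwoWayResult",
    "ThresholdResult",
    "one_way",
    "icer_vs_volume",
    "inverse_volume_coefficients",
    "two_way",
    "threshold_search",
    "tornado",
    "DEFAULT_ONEWAY_RANGES",
]

#: Relative ICER spread below which a one-way relationship is called flat.
#: Parameters the source analysis found consequential move the ICER by tens
#: of percent over their plausible ranges; ones it called inconsequential
#: move it by under ten percent.
FLAT_TOLERANCE = 0.10


def apply_parameter(
    params: ParameterSet, name: str, value: float, linked_tha_cost: bool = True
) -> ParameterSet:
    """Return a parameter set with ``name`` set to ``value``.

    Names are the scalar field names of the parameter blocks.  Two composite
    names reflect how the inputs were derived: ``p_periop_death`` sets the
    (equal) IMN and THA perioperative mortalities together, and varying
    ``cost_imn`` with ``linked_tha_cost`` carries the salvage THA cost along
    at twice the IMN cost, the relation used to set it.  Varying
    ``nav_purchase`` moves annual maintenance with it automatically, since
    maintenance is a fraction of the purchase price.
    """
    if name == "p_periop_death":
        return params.with_overrides(
            **{"clinical.p_periop_death_imn": value, "clinical.p_periop_death_tha": value}
        )
    if name == "cost_imn" and linked_tha_cost:
        return params.with_overrides(
            **{"costs.cost_imn": value, "costs.cost_tha": 2.0 * value}
        )
    for block in ("clinical", "utilities", "costs", "economics"):
        block_obj = getattr(params, block)
        if hasattr(block_obj, name):
            return params.with_overrides(**{f"{block}.{name}": value})
    raise KeyError(f"unknown model parameter: {name!r}")


@dataclass
class OneWayResult:
    parameter: str
    grid: np.ndarray
    icers: np.ndarray
    direction: str  # positive | negative | flat

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.parameter: self.grid, "icer": self.icers})


@dataclass
class TwoWayResult:
    x_parameter: str
    y_parameter: str
    x_grid: np.ndarray
    y_grid: np.ndarray
    navigated_ce: np.ndarray  # bool, shape (len(y_grid), len(x_grid))

    def boundary(self) -> np.ndarray:
        """For each x, the smallest y at which the navigated arm is
        cost-effective (NaN when none is)."""
        out = np.full(self.x_grid.shape, np.nan)
        for j in range(self.x_grid.size):
            idx = np.nonzero(self.navigated_ce[:, j])[0]
            if idx.size:
                out[j] = self.y_grid[idx[0]]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, y in enumerate(self.y_grid):
            for j, x in enumerate(self.x_grid):
                rows.append((x, y, bool(self.navigated_ce[i, j])))
        return pd.DataFrame(rows, columns=[self.x_parameter, self.y_parameter, "navigated_ce"])


@dataclass
class ThresholdResult:
    parameter: str
    volume: float
    bracket: tuple[float, float]
    threshold: float | None  # None = no solution within the bracket
    direction: str  # greater_than | less_than
    icer_at_threshold: float | None = None
    no_solution: bool = field(default=False)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "volume": self.volume,
            "bracket": list(self.bracket),
            "threshold": self.threshold,
            "direction": self.direction,
            "icer_at_threshold": self.icer_at_threshold,
            "no_solution": self.no_solution,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _icer_value(params: ParameterSet, conventions: ModelConventions | None) -> float:
    """Raw incremental ratio for curves and grids.

    Sensitivity curves need a continuous quantity, so the plain ratio is
    returned even in dominance quadrants (where :func:`navcea.cea.icer`
    deliberately reports a flag instead); it is NaN only when the QALY
    increment is exactly zero.
    """
    _, _, res = evaluate(params, conventions)
    if res.delta_qaly == 0.0:
        return float("nan")
    return res.delta_cost / res.delta_qaly


def _nmb_value(params: ParameterSet, conventions: ModelConventions | None, wtp: float) -> float:
    nav = run_cohort(Strategy.NAVIGATED, params, conventions, keep_trace=False)
    trad = run_cohort(Strategy.TRADITIONAL, params, conventions, keep_trace=False)
    return wtp * (nav.total_qaly - trad.total_qaly) - (nav.total_cost - trad.total_cost)


def one_way(
    params: ParameterSet,
    parameter: str,
    lo: float,
    hi: float,
    n_points: int = 11,
    conventions: ModelConventions | None = None,
    flat_tolerance: float = FLAT_TOLERANCE,
) -> OneWayResult:
    """ICER of navigated vs traditional IMN over a one-parameter grid.

    The direction is the sign of the least-squares slope of ICER on the
    parameter, called flat when the relative ICER spread over the whole
    range is below ``flat_tolerance``.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    grid = np.linspace(lo, hi, n_points)
    icers = np.array(
        [_icer_value(apply_parameter(params, parameter, float(x)), conventions) for x in grid]
    )
    finite = np.isfinite(icers)
    if finite.sum() < 2:
        raise ValueError(f"ICER undefined over most of the range for {parameter!r}")
    spread = np.ptp(icers[finite]) / abs(np.mean(icers[finite]))
    if spread < flat_tolerance:
        direction = "flat"
    else:
        slope = np.polyfit(grid[finite], icers[finite], 1)[0]
        direction = "positive" if slope > 0 else "negative"
    return OneWayResult(parameter, grid, icers, direction)


def icer_vs_volume(
    params: ParameterSet,
    volumes: Sequence[float],
    conventions: ModelConventions | None = None,
) -> OneWayResult:
    """ICER at each annual navigated-surgery volume (direct cohort runs)."""
    volumes = np.asarray(sorted(volumes), dtype=float)
    icers = np.array(
        [
            _icer_value(params.with_overrides(**{"costs.annual_volume": float(v)}), conventions)
            for v in volumes
        ]
    )
    direction = "negative" if icers[0] > icers[-1] else ("positive" if icers[0] < icers[-1] else "flat")
    return OneWayResult("annual_volume", volumes, icers, direction)


def inverse_volume_coefficients(
    params: ParameterSet, conventions: ModelConventions | None = None
) -> tuple[float, float]:
    """Closed-form ``ICER(V) = A + B / V``.

    Only the per-patient navigation allocation depends on the volume, so one
    cohort run per arm with the navigation system costed at zero yields the
    clinical increments, and the annualized system cost divided by the QALY
    increment is the slope:  ``A = dCost_clinical / dQALY``,
    ``B = annual_system_cost / dQALY``.
    """
    zero_nav = params.with_overrides(**{"costs.nav_purchase": 0.0})
    nav = run_cohort(Strategy.NAVIGATED, zero_nav, conventions, keep_trace=False)
    trad = run_cohort(Strategy.TRADITIONAL, zero_nav, conventions, keep_trace=False)
    dq = nav.total_qaly - trad.total_qaly
    dc_clin = nav.total_cost - trad.total_cost
    c = params.costs
    annual_system = c.nav_purchase / c.amortization_years + c.nav_maintenance_rate * c.nav_purchase
    return dc_clin / dq, annual_system / dq


def two_way(
    params: ParameterSet,
    x_values: Sequence[float],
    y_values: Sequence[float],
    x_parameter: str = "nav_purchase",
    y_parameter: str = "p_safe_nav",
    conventions: ModelConventions | None = None,
    wtp: float | None = None,
) -> TwoWayResult:
    """Cost-effectiveness classification over a two-parameter grid.

    Default axes reproduce the published map: navigation-system price
    against the probability of a safe navigated IMN, at the configured
    volume.  Each cell is classified by the sign of the incremental net
    monetary benefit at the WTP threshold.
    """
    wtp = wtp if wtp is not None else params.economics.wtp
    x_grid = np.asarray(sorted(x_values), dtype=float)
    y_grid = np.asarray(sorted(y_values), dtype=float)
    ce = np.zeros((y_grid.size, x_grid.size), dtype=bool)
    for j, x in enumerate(x_grid):
        px = apply_parameter(params, x_parameter, float(x))
        for i, y in enumerate(y_grid):
            pxy = apply_parameter(px, y_parameter, float(y))
            ce[i, j] = _nmb_value(pxy, conventions, wtp) >= 0.0
    return TwoWayResult(x_parameter, y_parameter, x_grid, y_grid, ce)


def threshold_search(
    params: ParameterSet,
    target_parameter: str,
    bracket: tuple[float, float],
    volume: float | None = None,
    wtp: float | None = None,
    conventions: ModelConventions | None = None,
    n_monotonicity_points: int = 9,
    xtol: float = 1e-10,
) -> ThresholdResult:
    """Find the parameter value at which the ICER equals the WTP threshold.

    Solves for the sign change of the incremental net monetary benefit
    (zero exactly where ICER = WTP) by Brent's method, after verifying on a
    coarse grid that the NMB is monotone over the bracket.  When the NMB
    does not change sign across the bracket the result carries the
    no-solution sentinel (``threshold=None``) — e.g. a low-volume centre
    where no attainable safe-zone probability makes navigation
    cost-effective.
    """
    if volume is not None:
        params = params.with_overrides(**{"costs.annual_volume": float(volume)})
    wtp = wtp if wtp is not None else params.economics.wtp
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("invalid bracket")

    def nmb(x: float) -> float:
        return _nmb_value(apply_parameter(params, target_parameter, x), conventions, wtp)

    grid = np.linspace(lo, hi, n_monotonicity_points)
    values = np.array([nmb(float(x)) for x in grid])
    diffs = np.diff(values)
    scale = max(abs(values).max(), 1.0)
    if not (np.all(diffs >= -1e-9 * scale) or np.all(diffs <= 1e-9 * scale)):
        raise ValueError(
            f"NMB is not monotone in {target_parameter!r} over {bracket}; "
            "split the bracket and search the monotone pieces"
        )
    increasing = values[-1] > values[0]
    direction = "greater_than" if increasing else "less_than"
    if values[0] * values[-1] > 0:
        return ThresholdResult(
            parameter=target_parameter,
            volume=float(params.costs.annual_volume),
            bracket=(lo, hi),
            threshold=None,
            direction=direction,
            no_solution=True,
        )
    root = float(brentq(nmb, lo, hi, xtol=xtol * (hi - lo) + 1e-300, rtol=8.9e-16))
    at = apply_parameter(params, target_parameter, root)
    return ThresholdResult(
        parameter=target_parameter,
        volume=float(params.costs.annual_volume),
        bracket=(lo, hi),
        threshold=root,
        direction=direction,
        icer_at_threshold=_icer_value(at, conventions),
    )


#: Ranges for the standard one-way analyses: ±50% around the base value
#: (clipped to the valid domain), with the perioperative mortalities varied
#: jointly and the salvage disutility spanning down to double its base.
DEFAULT_ONEWAY_RANGES: dict[str, tuple[float, float]] = {
    "p_safe_trad": (0.37, 0.99),
    "annual_fail_safe": (0.0135, 0.0405),
    "annual_fail_unsafe": (0.0375, 0.1125),
    "u_tha": (0.3, 0.9),
    "cost_imn": (27_000.0, 81_000.0),
    "disutility_salvage": (-0.3, 0.0),
    "p_periop_death": (0.03, 0.09),
}


def tornado(
    params: ParameterSet,
    conventions: ModelConventions | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    n_points: int = 5,
) -> pd.DataFrame:
    """One-way summary across the standard parameter list."""
    ranges = ranges or DEFAULT_ONEWAY_RANGES
    rows = []
    for name, (lo, hi) in ranges.items():
        res = one_way(params, name, lo, hi, n_points=n_points, conventions=conventions)
        rows.append(
            {
                "parameter": name,
                "low": lo,
                "high": hi,
                "icer_at_low": res.icers[0],
                "icer_at_high": res.icers[-1],
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows)
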