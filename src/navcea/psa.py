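"""Probabilistic sensitivity analysis (Monte-Carlo over parameter distributions).

Each sample draws every uncertain parameter from its assigned Beta or
Gamma distribution (independently, as published), evaluates both strategy
arms on the perturbed parameter set, and records the incremental cost and
effectiveness.  Draws of parameters common to both arms (failure rates,
THA utility and cost, IMN cost) are shared within a sample, so the arms
differ only through arm-specific inputs.  The summary ICER is the ratio of
means — mean incremental cost over mean incremental QALY — which stays
stable when individual QALY increments approach zero; the acceptability
curve is the fraction of samples with positive net monetary benefit at
each willingness-to-pay value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import ModelConventions, Strategy, run_cohort
from .params import DistributionSpec, ParameterSet, default_psa_distributions

__all__ = ["PSASample", "PSAResult", "CEACCurve", "draw_sample", "run_psa", "ceac"]


_FIELD_PATHS = {
    "annual_fail_safe": "clinical.annual_fail_safe",
    "annual_fail_unsafe": "clinical.annual_fail_unsafe",
    "p_safe_nav": "clinical.p_safe_nav",
    "p_safe_trad": "clinical.p_safe_trad",
    "u_nav": "utilities.u_nav",
    "u_trad": "utilities.u_trad",
    "u_tha": "utilities.u_tha",
    "cost_imn": "costs.cost_imn",
    "cost_tha": "costs.cost_tha",
}


def draw_sample(
    dists: Mapping[str, DistributionSpec | float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """One joint draw of all sampled parameters.

    A plain float in ``dists`` is a point mass (the parameter is held
    fixed), which reduces the PSA to the deterministic reference case.
    """
    out: dict[str, float] = {}
    for name, spec in dists.items():
        if isinstance(spec, DistributionSpec):
            out[name] = float(spec.sample(rng))
        else:
            out[name] = float(spec)
    return out


#: alias kept for symmetry with the result types
PSASample = dict


@dataclass
class PSAResult:
    """Per-sample incremental outcomes and their summaries."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_samples: int
    seed: int
    wtp: float
    annual_volume: float
    samples: pd.DataFrame = field(repr=False, default=None)

    @property
    def icer_ratio_of_means(self) -> float:
        return float(self.delta_cost.mean() / self.delta_qaly.mean())

    @property
    def icer_mean_of_ratios(self) -> float:
        """Mean of per-sample ratios; unstable when QALY increments cross zero."""
        return float(np.mean(self.delta_cost / self.delta_qaly))

    def acceptance_at(self, wtp: float | None = None) -> float:
        wtp = self.wtp if wtp is None else wtp
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame({"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly})
        if self.samples is not None:
            base = pd.concat([self.samples.reset_index(drop=True), base], axis=1)
        return base

    def manifest(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "wtp": self.wtp,
            "annual_volume": self.annual_volume,
            "icer_ratio_of_means": self.icer_ratio_of_means,
            "acceptance": self.acceptance_at(),
        }


def run_psa(
    params: ParameterSet,
    conventions: ModelConventions | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    wtp: float | None = None,
    dists: Mapping[str, DistributionSpec | float] | None = None,
    keep_samples: bool = True,
) -> PSAResult:
    """Monte-Carlo PSA of navigated vs traditional IMN.

    All parameters absent from ``dists`` (mortalities, discount rate,
    navigation system cost, volume) stay at their base values.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    params.validate()
    wtp = wtp if wtp is not None else params.economics.wtp
    dists = dists if dists is not None else default_psa_distributions()
    rng = np.random.default_rng(seed)

    delta_cost = np.empty(n_samples)
    delta_qaly = np.empty(n_samples)
    records: list[dict[str, float]] = []
    for i in range(n_samples):
        sample = draw_sample(dists, rng)
        overrides = {_FIELD_PATHS[k]: v for k, v in sample.items()}
        # failure probabilities may invert under independent sampling; the
        # parameter-set invariant ties them through the odds ratio, so the
        # sampled pair is applied as-is with the ordering guard relaxed
        ps = params.with_overrides(**{"clinical.odds_ratio_unsafe": 1.0}, **overrides) \
            if sample.get("annual_fail_unsafe", 1.0) < sample.get("annual_fail_safe", 0.0) \
            else params.with_overrides(**overrides)
        nav = run_cohort(Strategy.NAVIGATED, ps, conventions, keep_trace=False)
        trad = run_cohort(Strategy.TRADITIONAL, ps, conventions, keep_trace=False)
        delta_cost[i] = nav.total_cost - trad.total_cost
        delta_qaly[i] = nav.total_qaly - trad.total_qaly
        if keep_samples:
            records.append(sample)

    return PSAResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        n_samples=n_samples,
        seed=seed,
        wtp=wtp,
        annual_volume=float(params.costs.annual_volume),
        samples=pd.DataFrame(records) if keep_samples else None,
    )


@dataclass
class CEACCurve:
    wtp_grid: np.ndarray
    acceptance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "acceptance": self.acceptance})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curve from one fixed sample set."""
    grid = np.asarray(wtp_grid, dtype=float)
    acc = np.array([psa.acceptance_at(w) for w in grid])
    return CEACCurve(grid, acc)
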