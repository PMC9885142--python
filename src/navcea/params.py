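"""Model parameters for the navigated-IMN cost-effectiveness model.

All monetary values are 2020 Chinese Yuan (CNY); utilities are annual
QALY weights in [0, 1]; probabilities are per-cycle (annual) unless noted.
The reference case describes a 70-year-old patient with an intertrochanteric
hip fracture treated by intramedullary nailing (IMN), with or without a
surgical navigation system, followed for five annual cycles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ClinicalProbabilities",
    "Utilities",
    "CostInputs",
    "EconomicSettings",
    "LifeTable",
    "ParameterSet",
    "DistributionSpec",
    "DistributionFamily",
    "or_to_probability",
    "hhs_to_utility",
    "fit_beta_moments",
    "fit_gamma_moments",
    "beta_moments",
    "gamma_moments",
    "nav_cost_per_patient",
    "load_parameters",
    "default_parameter_set",
    "default_psa_distributions",
    "moment_fitted_psa_distributions",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a parameter set violates a domain invariant."""


def _check(condition: bool, message: str, errors: list[str]) -> None:
    if not condition:
        errors.append(message)


# ---------------------------------------------------------------------------
# conversions


def or_to_probability(p0: float, odds_ratio: float) -> float:
    """Convert a baseline probability to the probability implied by an odds ratio.

    Computes ``p1 = OR * p0 / (1 - p0 + OR * p0)``, i.e. applies the odds
    ratio in odds space and maps back to a probability.  Used to derive the
    annual fixation-failure probability outside the radiographic safe zone
    (tip-apex distance > 20 mm) from the inside-zone baseline.

    Parameters
    ----------
    p0
        Baseline probability, ``0 <= p0 < 1``.
    odds_ratio
        Odds ratio relative to baseline, ``> 0``.

    Returns
    -------
    float
        The converted probability in ``[0, 1)``.
    """
    if not 0.0 <= p0 < 1.0:
        raise ValueError(f"p0 must be in [0, 1); got {p0}")
    if odds_ratio <= 0.0:
        raise ValueError(f"odds_ratio must be positive; got {odds_ratio}")
    odds1 = odds_ratio * p0 / (1.0 - p0)
    return odds1 / (1.0 + odds1)


#: Default anchor pairs (Harris Hip Score, annual utility) for the linear
#: HHS -> utility map: navigated 86.7 -> 0.82, freehand 82.7 -> 0.79.
DEFAULT_HHS_ANCHORS: tuple[tuple[float, float], tuple[float, float]] = (
    (86.7, 0.82),
    (82.7, 0.79),
)


def hhs_to_utility(
    hhs: float,
    anchors: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_HHS_ANCHORS,
) -> float:
    """Map a Harris Hip Score (0-100) to an annual utility by linear interpolation.

    The line passes through the two ``(score, utility)`` anchor pairs;
    scores outside the anchor interval extrapolate linearly.
    """
    (s0, u0), (s1, u1) = anchors
    if s0 == s1:
        raise ValueError("anchor scores must be distinct")
    return u0 + (hhs - s0) * (u1 - u0) / (s1 - s0)


# ---------------------------------------------------------------------------
# distributions (probabilistic sensitivity analysis inputs)


class DistributionFamily(str, Enum):
    BETA = "beta"
    GAMMA = "gamma"


@dataclass(frozen=True)
class DistributionSpec:
    """A Beta(alpha, beta) or Gamma(shape, rate) parameter distribution.

    ``shape2`` is the Beta beta parameter or the Gamma *rate* (inverse
    scale).  ``mean``/``sd`` store the moments the spec was fitted from
    (or the published moments when the shape parameters are given directly).
    """

    family: DistributionFamily
    shape1: float
    shape2: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.shape1 <= 0 or self.shape2 <= 0:
            raise ValueError("distribution shape parameters must be positive")

    def analytic_mean(self) -> float:
        if self.family is DistributionFamily.BETA:
            return self.shape1 / (self.shape1 + self.shape2)
        return self.shape1 / self.shape2

    def analytic_sd(self) -> float:
        if self.family is DistributionFamily.BETA:
            a, b = self.shape1, self.shape2
            return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0))))
        return float(np.sqrt(self.shape1) / self.shape2)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family is DistributionFamily.BETA:
            return rng.beta(self.shape1, self.shape2, size=size)
        return rng.gamma(self.shape1, 1.0 / self.shape2, size=size)


def beta_moments(alpha: float, beta: float) -> tuple[float, float]:
    """Mean and standard deviation of Beta(alpha, beta)."""
    spec = DistributionSpec(DistributionFamily.BETA, alpha, beta, 0.0, 0.0)
    return spec.analytic_mean(), spec.analytic_sd()


def gamma_moments(shape: float, rate: float) -> tuple[float, float]:
    """Mean and standard deviation of Gamma(shape, rate)."""
    spec = DistributionSpec(DistributionFamily.GAMMA, shape, rate, 0.0, 0.0)
    return spec.analytic_mean(), spec.analytic_sd()


def fit_beta_moments(mean: float, sd: float) -> DistributionSpec:
    """Method-of-moments Beta fit: alpha = m*nu, beta = (1-m)*nu with
    nu = m(1-m)/sd^2 - 1.  Requires ``sd^2 < mean * (1 - mean)``."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"Beta mean must lie in (0, 1); got {mean}")
    if sd <= 0.0:
        raise ValueError("sd must be positive")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible Beta moments: sd^2 = {var:g} >= mean(1-mean) = "
            f"{mean * (1.0 - mean):g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return DistributionSpec(DistributionFamily.BETA, mean * nu, (1.0 - mean) * nu, mean, sd)


def fit_gamma_moments(mean: float, sd: float) -> DistributionSpec:
    """Method-of-moments Gamma fit: shape = (mean/sd)^2, rate = mean/sd^2."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError("Gamma moments must be positive")
    return DistributionSpec(
        DistributionFamily.GAMMA, (mean / sd) ** 2, mean / sd / sd, mean, sd
    )


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class ClinicalProbabilities:
    """Transition probabilities of the four-state cohort model."""

    p_periop_death_imn: float = 0.06
    p_periop_death_tha: float = 0.06
    p_death_first_year: float = 0.20
    annual_fail_safe: float = 0.027
    annual_fail_unsafe: float = 0.075
    odds_ratio_unsafe: float = 2.94
    p_safe_nav: float = 0.956
    p_safe_trad: float = 0.74

    def validate(self) -> list[str]:
        errors: list[str] = []
        for f in fields(self):
            if f.name == "odds_ratio_unsafe":
                continue
            v = getattr(self, f.name)
            _check(0.0 <= v <= 1.0, f"clinical.{f.name} = {v} outside [0, 1]", errors)
        _check(self.odds_ratio_unsafe > 0, "clinical.odds_ratio_unsafe must be > 0", errors)
        if self.odds_ratio_unsafe >= 1.0:
            _check(
                self.annual_fail_unsafe >= self.annual_fail_safe,
                "annual_fail_unsafe < annual_fail_safe despite odds ratio >= 1",
                errors,
            )
        return errors


@dataclass(frozen=True)
class Utilities:
    """Annual health-state utilities and the one-time salvage disutility.

    Fixation-state utilities derive from Harris Hip Scores (86.7 navigated,
    82.7 freehand) through the linear HHS -> utility map.  The salvage-THA
    utility defaults to 0.6; an alternative published value of 0.76 can be
    selected via ``load_parameters`` for scenario analysis.
    """

    u_nav: float = 0.82
    u_trad: float = 0.79
    u_tha: float = 0.6
    disutility_salvage: float = -0.15
    hhs_nav: float = 86.7
    hhs_trad: float = 82.7

    def validate(self) -> list[str]:
        errors: list[str] = []
        for name in ("u_nav", "u_trad", "u_tha"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"utilities.{name} = {v} outside [0, 1]", errors)
        _check(
            self.disutility_salvage <= 0.0,
            "utilities.disutility_salvage must be <= 0",
            errors,
        )
        return errors


@dataclass(frozen=True)
class CostInputs:
    """Procedure and navigation-system costs (2020 CNY).

    The navigation system is a capital purchase; its annual cost is
    straight-line amortization over ``amortization_years`` plus maintenance
    at ``nav_maintenance_rate`` of the purchase price, spread over
    ``annual_volume`` navigated cases.  ``amortization_years`` is resolved
    by the calibration stage (see :mod:`navcea.calibration`).
    """

    cost_imn: float = 54_000.0
    cost_tha: float = 108_000.0
    nav_purchase: float = 7_000_000.0
    nav_maintenance_rate: float = 0.05
    amortization_years: float = 5.0
    annual_volume: float = 200.0

    def validate(self) -> list[str]:
        errors: list[str] = []
        for name in ("cost_imn", "cost_tha", "nav_purchase", "nav_maintenance_rate"):
            _check(getattr(self, name) >= 0.0, f"costs.{name} must be >= 0", errors)
        _check(self.annual_volume > 0.0, "costs.annual_volume must be > 0", errors)
        _check(self.amortization_years > 0.0, "costs.amortization_years must be > 0", errors)
        return errors


@dataclass(frozen=True)
class EconomicSettings:
    discount_rate: float = 0.03
    wtp: float = 140_000.0
    horizon: int = 5
    start_age: int = 70

    def validate(self) -> list[str]:
        errors: list[str] = []
        _check(self.discount_rate >= 0.0, "economics.discount_rate must be >= 0", errors)
        _check(self.horizon >= 1, "economics.horizon must be >= 1", errors)
        _check(self.wtp > 0.0, "economics.wtp must be > 0", errors)
        return errors


class LifeTable:
    """Age-indexed annual background death probabilities ``qx``.

    Lookups outside the tabulated age range clamp to the nearest end of the
    table.  Ages are integer years.
    """

    def __init__(self, ages: Sequence[int], qx: Sequence[float]):
        ages = np.asarray(ages, dtype=int)
        qx = np.asarray(qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("ages and qx must be equal-length non-empty 1-d sequences")
        order = np.argsort(ages)
        self.ages = ages[order]
        self.qx = qx[order]
        if np.any(np.diff(self.ages) == 0):
            raise ValueError("duplicate ages in life table")
        if np.any((self.qx < 0.0) | (self.qx > 1.0)):
            raise ValueError("life-table qx values must lie in [0, 1]")

    @classmethod
    def flat(cls, q: float, start_age: int = 40, end_age: int = 110) -> "LifeTable":
        ages = np.arange(start_age, end_age + 1)
        return cls(ages, np.full(ages.shape, q))

    def lookup(self, age: int | float) -> float:
        idx = int(np.clip(np.searchsorted(self.ages, age, side="right") - 1, 0, self.ages.size - 1))
        return float(self.qx[idx])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("age,qx\n")
            for a, q in zip(self.ages, self.qx):
                fh.write(f"{a},{float(q)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        rows = Path(path).read_text().strip().splitlines()
        header = [c.strip() for c in rows[0].split(",")]
        if header != ["age", "qx"]:
            raise ValueError(f"expected life-table header 'age,qx'; got {rows[0]!r}")
        ages, qx = [], []
        for line in rows[1:]:
            a, q = line.split(",")
            ages.append(int(a))
            qx.append(float(q))
        return cls(ages, qx)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.qx, other.qx)
        )

    def __repr__(self) -> str:
        return f"LifeTable(ages {self.ages[0]}..{self.ages[-1]})"


@dataclass(frozen=True)
class ParameterSet:
    """Complete model input: probabilities, utilities, costs, economics, mortality."""

    clinical: ClinicalProbabilities = field(default_factory=ClinicalProbabilities)
    utilities: Utilities = field(default_factory=Utilities)
    costs: CostInputs = field(default_factory=CostInputs)
    economics: EconomicSettings = field(default_factory=EconomicSettings)
    life_table: LifeTable = field(default_factory=lambda: LifeTable.flat(0.03))
    provenance: Mapping[str, str] = field(default_factory=dict, compare=False)

    def validate(self) -> None:
        errors = (
            self.clinical.validate()
            + self.utilities.validate()
            + self.costs.validate()
            + self.economics.validate()
        )
        if errors:
            raise ValidationError("; ".join(errors))

    def with_overrides(self, **kwargs) -> "ParameterSet":
        """Return a copy with dotted-name overrides, e.g.
        ``with_overrides(**{"clinical.p_safe_nav": 0.9})`` or block
        replacements (``costs=...``)."""
        blocks = {f.name: getattr(self, f.name) for f in fields(self)}
        for key, value in kwargs.items():
            if "." in key:
                block_name, leaf = key.split(".", 1)
                blocks[block_name] = replace(blocks[block_name], **{leaf: value})
            else:
                blocks[key] = value
        out = ParameterSet(**blocks)
        out.validate()
        return out


def default_parameter_set() -> ParameterSet:
    """The published reference-case parameter set (flat placeholder mortality)."""
    ps = ParameterSet()
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# navigation cost allocation


def nav_cost_per_patient(costs: CostInputs) -> float:
    """Per-patient navigation-system cost at the configured annual volume.

    Annualizes the capital cost as straight-line amortization over
    ``amortization_years`` plus annual maintenance (a fixed fraction of the
    purchase price), then divides by the annual navigated-case volume:

        (purchase / amortization_years + maintenance_rate * purchase) / volume

    Strictly decreasing in volume; linear in the purchase price.
    """
    if costs.annual_volume <= 0:
        raise ValueError("annual_volume must be positive")
    if costs.amortization_years <= 0:
        raise ValueError("amortization_years must be positive")
    annual = (
        costs.nav_purchase / costs.amortization_years
        + costs.nav_maintenance_rate * costs.nav_purchase
    )
    return annual / costs.annual_volume


# ---------------------------------------------------------------------------
# configuration loading

_BLOCK_TYPES = {
    "clinical": ClinicalProbabilities,
    "utilities": Utilities,
    "costs": CostInputs,
    "economics": EconomicSettings,
}


def load_parameters(source: str | Path | Mapping | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a YAML/JSON file or mapping.

    Missing keys fall back to the reference-case defaults; unknown keys are
    rejected.  The config mirrors the parameter blocks::

        clinical: {p_safe_nav: 0.956, ...}
        utilities: {u_tha: 0.6, ...}
        costs: {annual_volume: 200, ...}
        economics: {wtp: 140000, ...}
        life_table: path/to/table.csv   # CSV with header age,qx

    Each field's provenance ("default" or "user") is recorded on the
    returned set.
    """
    if source is None:
        return default_parameter_set()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        config = yaml.safe_load(text) if not str(source).endswith(".json") else json.loads(text)
    else:
        config = dict(source)
    if config is None:
        return default_parameter_set()
    if not isinstance(config, Mapping):
        raise ValidationError("parameter config must be a mapping")

    provenance: dict[str, str] = {}
    blocks: dict[str, object] = {}
    unknown = set(config) - set(_BLOCK_TYPES) - {"life_table"}
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")
    for block_name, block_type in _BLOCK_TYPES.items():
        overrides = config.get(block_name, {}) or {}
        known = {f.name for f in fields(block_type)}
        bad = set(overrides) - known
        if bad:
            raise ValidationError(f"unknown keys in '{block_name}': {sorted(bad)}")
        blocks[block_name] = block_type(**overrides)
        for name in known:
            provenance[f"{block_name}.{name}"] = (
                "user" if name in overrides else "default"
            )
    lt_source = config.get("life_table")
    if lt_source is None:
        life_table = LifeTable.flat(0.03)
        provenance["life_table"] = "default"
    elif isinstance(lt_source, (str, Path)):
        life_table = LifeTable.from_csv(lt_source)
        provenance["life_table"] = "user"
    elif isinstance(lt_source, LifeTable):
        life_table = lt_source
        provenance["life_table"] = "user"
    else:
        life_table = LifeTable(lt_source["age"], lt_source["qx"])
        provenance["life_table"] = "user"

    ps = ParameterSet(life_table=life_table, provenance=provenance, **blocks)
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# published PSA distributions

#: (name, family, shape1, shape2, mean, sd) of every sampled parameter, as
#: published.  Probabilities/utilities are Beta(alpha, beta); costs are
#: Gamma(shape, rate).  Standard deviations are 10% of the mean where no
#: empirical SD exists; the IMN procedure cost has an empirical SD of
#: 37,000.  Note the THA-utility row is internally inconsistent at source:
#: its printed Beta(3999.4, 2666.3) implies sd 0.006, ten-fold below its
#: printed sd 0.06 (a moment fit of mean/sd would give ~Beta(39.99, 26.66));
#: the printed shape parameters are taken as authoritative.
PSA_TABLE: tuple[tuple[str, DistributionFamily, float, float, float, float], ...] = (
    ("annual_fail_safe", DistributionFamily.BETA, 97.27, 3505.43, 0.027, 0.0027),
    ("annual_fail_unsafe", DistributionFamily.BETA, 92.43, 1139.91, 0.075, 0.0075),
    ("p_safe_nav", DistributionFamily.BETA, 3.44, 0.16, 0.956, 0.0956),
    ("p_safe_trad", DistributionFamily.BETA, 25.26, 8.88, 0.74, 0.074),
    ("u_nav", DistributionFamily.BETA, 17.18, 3.77, 0.82, 0.082),
    ("u_trad", DistributionFamily.BETA, 20.21, 5.37, 0.79, 0.079),
    ("u_tha", DistributionFamily.BETA, 3999.4, 2666.3, 0.6, 0.06),
    ("cost_imn", DistributionFamily.GAMMA, 2.13, 0.000039, 54_000.0, 37_000.0),
    ("cost_tha", DistributionFamily.GAMMA, 100.0, 0.00093, 108_000.0, 10_800.0),
)


def default_psa_distributions() -> dict[str, DistributionSpec]:
    """Distributions for the probabilistic sensitivity analysis, as published."""
    return {
        name: DistributionSpec(family, s1, s2, mean, sd)
        for name, family, s1, s2, mean, sd in PSA_TABLE
    }


def moment_fitted_psa_distributions() -> dict[str, DistributionSpec]:
    """Method-of-moments refits of the published means and standard
    deviations — the derivation route for the published shape parameters."""
    out: dict[str, DistributionSpec] = {}
    for name, family, _s1, _s2, mean, sd in PSA_TABLE:
        fit = fit_beta_moments if family is DistributionFamily.BETA else fit_gamma_moments
        out[name] = fit(mean, sd)
    return out
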