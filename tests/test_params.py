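import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navcea.params import (
    DistributionFamily,
    LifeTable,
    ValidationError,
    beta_moments,
    default_parameter_set,
    default_psa_distributions,
    fit_beta_moments,
    fit_gamma_moments,
    gamma_moments,
    hhs_to_utility,
    load_parameters,
    moment_fitted_psa_distributions,
    nav_cost_per_patient,
    or_to_probability,
    PSA_TABLE,
)


class TestOrToProbability:
    @pytest.mark.parametrize(
        "p0, odds_ratio, expected, tol",
        [
            (0.027, 2.94, 0.0754, 5e-5),  # outside-safe-zone failure rate
            (0.3, 1.0, 0.3, 1e-15),
            (0.5, 3.0, 0.75, 1e-15),
            (0.0, 7.0, 0.0, 1e-15),
        ],
    )
    def test_examples(self, p0, odds_ratio, expected, tol):
        assert or_to_probability(p0, odds_ratio) == pytest.approx(expected, abs=tol)

    def test_outside_zone_rate_prints_as_7_5_percent(self):
        assert round(100 * or_to_probability(0.027, 2.94), 1) == 7.5

    @given(
        p0=st.floats(0.0, 0.99),
        odds_ratio=st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_odds_space_computation(self, p0, odds_ratio):
        odds1 = odds_ratio * p0 / (1.0 - p0)
        assert or_to_probability(p0, odds_ratio) == odds1 / (1.0 + odds1)

    @given(p0=st.floats(0.01, 0.98), odds_ratio=st.floats(0.1, 50.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_both_arguments(self, p0, odds_ratio):
        base = or_to_probability(p0, odds_ratio)
        assert or_to_probability(p0 + 0.01, odds_ratio) > base
        assert or_to_probability(p0, odds_ratio * 1.1) > base

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError):
            or_to_probability(1.0, 2.0)
        with pytest.raises(ValueError):
            or_to_probability(0.5, 0.0)


class TestHHSToUtility:
    def test_published_anchor_scores(self):
        assert hhs_to_utility(86.7) == pytest.approx(0.82)
        assert hhs_to_utility(82.7) == pytest.approx(0.79)

    def test_linear_midpoint(self):
        assert hhs_to_utility(84.7) == pytest.approx(0.805)

    def test_identical_anchor_scores_rejected(self):
        with pytest.raises(ValueError):
            hhs_to_utility(80.0, anchors=((85.0, 0.8), (85.0, 0.9)))


class TestMomentFits:
    @pytest.mark.parametrize(
        "mean, sd, alpha, beta",
        [
            (0.027, 0.0027, 97.27, 3505.43),
            (0.956, 0.0956, 3.44, 0.16),
            (0.5, math.sqrt(1.0 / 12.0), 1.0, 1.0),  # uniform
        ],
    )
    def test_beta_examples(self, mean, sd, alpha, beta):
        spec = fit_beta_moments(mean, sd)
        assert spec.shape1 == pytest.approx(alpha, rel=2e-2)
        assert spec.shape2 == pytest.approx(beta, rel=2e-2)

    @pytest.mark.parametrize(
        "mean, sd, shape, rate",
        [
            (54_000.0, 37_000.0, 2.13, 3.9e-5),
            (108_000.0, 10_800.0, 100.0, 9.26e-4),
            (5.0, 5.0, 1.0, 0.2),  # exponential
        ],
    )
    def test_gamma_examples(self, mean, sd, shape, rate):
        # published rates carry two significant figures
        spec = fit_gamma_moments(mean, sd)
        assert spec.shape1 == pytest.approx(shape, rel=2e-2)
        assert spec.shape2 == pytest.approx(rate, rel=2e-2)

    def test_infeasible_beta_moments_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_moments(0.5, 0.6)
        with pytest.raises(ValueError):
            fit_beta_moments(0.027, 0.17)  # sd^2 > mean(1-mean)

    @given(
        a=st.floats(0.05, 1e4),
        b=st.floats(0.05, 1e4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_beta_round_trip(self, a, b):
        spec = fit_beta_moments(*beta_moments(a, b))
        assert spec.shape1 == pytest.approx(a, rel=1e-6)
        assert spec.shape2 == pytest.approx(b, rel=1e-6)

    @given(
        shape=st.floats(0.05, 1e4),
        rate=st.floats(1e-6, 1e3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_gamma_round_trip(self, shape, rate):
        spec = fit_gamma_moments(*gamma_moments(shape, rate))
        assert spec.shape1 == pytest.approx(shape, rel=1e-6)
        assert spec.shape2 == pytest.approx(rate, rel=1e-6)


class TestPublishedDistributionTable:
    def test_printed_shapes_match_printed_means(self):
        for spec in default_psa_distributions().values():
            assert spec.analytic_mean() == pytest.approx(spec.mean, rel=3e-2)

    def test_printed_shapes_match_printed_sds_except_tha_utility(self):
        """Every row's printed shape parameters reproduce its printed SD
        within 3% — except the THA-utility row, whose printed Beta implies
        an SD ten-fold below the printed one (a decimal slip at source)."""
        for name, spec in default_psa_distributions().items():
            if name == "u_tha":
                assert spec.analytic_sd() == pytest.approx(spec.sd / 10.0, rel=0.05)
            else:
                assert spec.analytic_sd() == pytest.approx(spec.sd, rel=3e-2)

    def test_moment_refits_agree_with_printed_shapes(self):
        fits = moment_fitted_psa_distributions()
        for name, family, s1, s2, _m, _sd in PSA_TABLE:
            if name == "u_tha":
                continue
            assert fits[name].shape1 == pytest.approx(s1, rel=3e-2)
            assert fits[name].shape2 == pytest.approx(s2, rel=3e-2)
            assert fits[name].family is family


class TestNavCostPerPatient:
    def test_inverse_volume_proportionality(self):
        base = default_parameter_set().costs
        half = nav_cost_per_patient(base)
        import dataclasses

        doubled = dataclasses.replace(base, annual_volume=2 * base.annual_volume)
        assert nav_cost_per_patient(doubled) == pytest.approx(half / 2.0)

    def test_zero_system_cost(self):
        import dataclasses

        costs = dataclasses.replace(default_parameter_set().costs, nav_purchase=0.0)
        assert nav_cost_per_patient(costs) == 0.0

    def test_invalid_volume(self):
        import dataclasses

        costs = dataclasses.replace(default_parameter_set().costs, annual_volume=0.0)
        with pytest.raises(ValueError):
            nav_cost_per_patient(costs)


class TestLoadParameters:
    def test_empty_config_gives_reference_case(self):
        ps = load_parameters({})
        base = default_parameter_set()
        assert ps.clinical == base.clinical
        assert ps.utilities == base.utilities
        assert ps.costs == base.costs

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError, match="p_safe_nav"):
            load_parameters({"clinical": {"p_safe_nav": 1.2}})

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValidationError):
            load_parameters({"clinical": {"p_safe": 0.9}})
        with pytest.raises(ValidationError):
            load_parameters({"mystery_block": {}})

    def test_partial_override_keeps_defaults_and_provenance(self):
        ps = load_parameters({"economics": {"wtp": 280_000}})
        assert ps.economics.wtp == 280_000
        assert ps.economics.discount_rate == 0.03
        assert ps.provenance["economics.wtp"] == "user"
        assert ps.provenance["economics.discount_rate"] == "default"

    def test_alternative_tha_utility_selectable(self):
        ps = load_parameters({"utilities": {"u_tha": 0.76}})
        assert ps.utilities.u_tha == 0.76

    def test_yaml_file_with_life_table_csv(self, tmp_path):
        lt_path = tmp_path / "lt.csv"
        LifeTable([70, 71, 72, 73, 74, 75], [0.02, 0.021, 0.023, 0.025, 0.027, 0.03]).to_csv(
            lt_path
        )
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            f"clinical:\n  p_safe_trad: 0.8\nlife_table: {lt_path}\n"
        )
        ps = load_parameters(cfg)
        assert ps.clinical.p_safe_trad == 0.8
        assert ps.life_table.lookup(72) == 0.023


class TestLifeTable:
    def test_lookup_clamps_outside_range(self):
        lt = LifeTable([70, 71, 72], [0.01, 0.02, 0.03])
        assert lt.lookup(60) == 0.01
        assert lt.lookup(71) == 0.02
        assert lt.lookup(99) == 0.03

    def test_rejects_invalid_qx(self):
        with pytest.raises(ValueError):
            LifeTable([70, 71], [0.5, 1.5])

    def test_csv_round_trip(self, tmp_path):
        lt = LifeTable(np.arange(60, 80), np.linspace(0.01, 0.2, 20))
        path = tmp_path / "lt.csv"
        lt.to_csv(path)
        assert LifeTable.from_csv(path) == lt
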