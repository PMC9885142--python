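import numpy as np
import pytest

from navcea.calibration import convention_grid
from navcea.markov import (
    AccrualTiming,
    ModelConventions,
    State,
    Strategy,
    cycle_transition,
    initial_distribution,
    microsim_oracle,
    run_cohort,
)
from navcea.params import LifeTable, default_parameter_set
from navcea.synthetic import random_parameter_set


def _no_event_params():
    """All mortality and failure switched off."""
    return default_parameter_set().with_overrides(
        **{
            "clinical.p_periop_death_imn": 0.0,
            "clinical.p_periop_death_tha": 0.0,
            "clinical.p_death_first_year": 0.0,
            "clinical.annual_fail_safe": 0.0,
            "clinical.annual_fail_unsafe": 0.0,
        },
        life_table=LifeTable.flat(0.0),
    )


class TestInitialDistribution:
    def test_reference_case_navigated(self):
        v = initial_distribution(Strategy.NAVIGATED, default_parameter_set())
        assert v == pytest.approx([0.89864, 0.04136, 0.0, 0.06])

    def test_reference_case_traditional(self):
        v = initial_distribution(Strategy.TRADITIONAL, default_parameter_set())
        assert v[State.DEAD] == pytest.approx(0.06)
        assert v[State.SAFE_FIX] / v[State.UNSAFE_FIX] == pytest.approx(74.0 / 26.0)

    def test_no_event_limit(self):
        ps = _no_event_params().with_overrides(**{"clinical.p_safe_nav": 1.0})
        v = initial_distribution(Strategy.NAVIGATED, ps)
        assert v == pytest.approx([1.0, 0.0, 0.0, 0.0])


class TestCycleTransition:
    def test_single_cycle_hand_computation(self):
        """From a fully safe cohort with no background death, 2.7% fail,
        6% of failures die perioperatively, and the THA cost accrues for
        every operation."""
        ps = _no_event_params()
        conv = ModelConventions()
        state = np.array([1.0, 0.0, 0.0, 0.0])
        ps = ps.with_overrides(**{"clinical.annual_fail_safe": 0.027,
                                  "clinical.annual_fail_unsafe": 0.075,
                                  "clinical.p_periop_death_tha": 0.06})
        new, cost, _qaly, new_salvage = cycle_transition(state, 1, Strategy.NAVIGATED, ps, conv)
        assert new_salvage == pytest.approx(0.027)
        assert new[State.SALVAGE_THA] == pytest.approx(0.027 * 0.94)
        assert new[State.DEAD] == pytest.approx(0.027 * 0.06)
        assert cost == pytest.approx(0.027 * 108_000)

    def test_cycle_zero_is_not_a_transition(self):
        with pytest.raises(ValueError):
            cycle_transition(
                np.array([1.0, 0, 0, 0]), 0, Strategy.NAVIGATED,
                default_parameter_set(), ModelConventions(),
            )

    def test_no_event_limit_preserves_state(self):
        ps = _no_event_params()
        conv = ModelConventions(dying_cycle_utility_fraction=0.5)
        state = np.array([0.7, 0.2, 0.1, 0.0])
        new, cost, qaly, ns = cycle_transition(state, 2, Strategy.NAVIGATED, ps, conv)
        assert new == pytest.approx(state)
        assert cost == 0.0 and ns == 0.0
        assert qaly == pytest.approx(0.9 * 0.82 + 0.1 * 0.6)


class TestRunCohort:
    def test_undiscounted_no_event_qaly_is_horizon_times_utility(self):
        ps = _no_event_params().with_overrides(**{"economics.discount_rate": 0.0})
        for conv in (ModelConventions(), ModelConventions(accrual_timing=AccrualTiming.START)):
            out = run_cohort(Strategy.NAVIGATED, ps, conv)
            assert out.total_qaly == pytest.approx(5 * 0.82)

    @pytest.mark.parametrize("seed", range(6))
    def test_occupancy_sums_to_one_every_cycle(self, seed):
        ps = random_parameter_set(rng=seed)
        conv = convention_grid()[seed * 5 % len(convention_grid())]
        for strategy in Strategy:
            trace = run_cohort(strategy, ps, conv).trace
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_salvage_incidence_monotone_and_bounded(self, seed):
        ps = random_parameter_set(rng=100 + seed)
        out = run_cohort(Strategy.TRADITIONAL, ps)
        cum = out.trace.cum_salvage
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] <= 1.0 - ps.clinical.p_periop_death_imn + 1e-12

    def test_discounting_never_increases_flows(self):
        ps = default_parameter_set()
        trace = run_cohort(Strategy.NAVIGATED, ps, ModelConventions()).trace
        assert np.all(trace.disc_cost <= trace.cycle_cost + 1e-12)
        assert np.all(trace.disc_qaly <= trace.cycle_qaly + 1e-12)

    def test_qaly_monotone_in_utilities_and_hazards(self, conventions):
        """Finite differences: effectiveness rises with any utility and
        falls with any mortality or failure probability."""
        rng = np.random.default_rng(7)
        for _ in range(3):
            ps = random_parameter_set(rng=rng)
            base = run_cohort(Strategy.NAVIGATED, ps, conventions).total_qaly
            for field, direction in [
                ("utilities.u_nav", +1),
                ("utilities.u_tha", +1),
                ("clinical.p_periop_death_imn", -1),
                ("clinical.p_death_first_year", -1),
                ("clinical.annual_fail_safe", -1),
                ("clinical.annual_fail_unsafe", -1),
            ]:
                block, leaf = field.split(".")
                value = getattr(getattr(ps, block), leaf)
                bumped = run_cohort(
                    Strategy.NAVIGATED,
                    ps.with_overrides(**{field: min(value + 0.02, 1.0)}),
                    conventions,
                ).total_qaly
                assert direction * (bumped - base) >= -1e-12, field

    def test_arms_identical_when_inputs_equalized(self, conventions):
        ps = default_parameter_set().with_overrides(
            **{
                "clinical.p_safe_trad": 0.956,
                "utilities.u_trad": 0.82,
                "costs.nav_purchase": 0.0,
            }
        )
        nav = run_cohort(Strategy.NAVIGATED, ps, conventions)
        trad = run_cohort(Strategy.TRADITIONAL, ps, conventions)
        assert nav.total_cost == pytest.approx(trad.total_cost)
        assert nav.total_qaly == pytest.approx(trad.total_qaly)
        assert nav.salvage_rate == pytest.approx(trad.salvage_rate)

    def test_trace_dataframe_round_trip(self, tmp_path, conventions):
        out = run_cohort(Strategy.NAVIGATED, default_parameter_set(), conventions)
        df = out.trace.to_dataframe()
        assert list(df["cycle"]) == [0, 1, 2, 3, 4, 5]
        assert df["age"].iloc[-1] == 74
        path = tmp_path / "trace.csv"
        df.to_csv(path, index=False)
        assert path.read_text().startswith("cycle,age,safe_fix")


class TestMicrosimOracle:
    def test_deterministic_probabilities_match_cohort_exactly(self):
        ps = _no_event_params()
        for conv in (ModelConventions(), ModelConventions(accrual_timing=AccrualTiming.START)):
            cohort = run_cohort(Strategy.NAVIGATED, ps, conv)
            micro = microsim_oracle(Strategy.NAVIGATED, ps, conv, n_patients=500, seed=1)
            assert micro.total_qaly == pytest.approx(cohort.total_qaly)
            assert micro.total_cost == pytest.approx(cohort.total_cost)
            assert micro.salvage_rate == 0.0 == cohort.salvage_rate

    def test_same_seed_reproducible(self, calibrated_params, conventions):
        a = microsim_oracle(Strategy.NAVIGATED, calibrated_params, conventions, 2000, seed=5)
        b = microsim_oracle(Strategy.NAVIGATED, calibrated_params, conventions, 2000, seed=5)
        assert (a.total_cost, a.total_qaly, a.salvage_rate) == (
            b.total_cost, b.total_qaly, b.salvage_rate,
        )

    def test_agrees_with_cohort_within_monte_carlo_error(self, calibrated_params, conventions):
        for strategy in Strategy:
            cohort = run_cohort(strategy, calibrated_params, conventions)
            micro = microsim_oracle(
                strategy, calibrated_params, conventions, n_patients=200_000, seed=11
            )
            assert abs(micro.total_cost - cohort.total_cost) < 3 * micro.se_cost
            assert abs(micro.total_qaly - cohort.total_qaly) < 3 * micro.se_qaly
            assert abs(micro.salvage_rate - cohort.salvage_rate) < 3 * micro.se_salvage
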