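"""Cash-flow model: NPV arithmetic, structure, and a hand-built oracle."""

import numpy as np
import pytest

from heatherdss import (
    CashFlowSeries,
    EstimateTable,
    MonitoringModel,
    VariableEstimate,
    builtin_table1,
    decision_delta,
    npv,
)

# A fully constant input set: the pipeline collapses to a deterministic
# closed form that the oracle below recomputes independently.
_CONST_VALUES = {
    "discount_rate": 4.0,
    "var_CV": 0.0,
    "n_years": 10.0,
    "production_area": 8.0,
    "chance_high_risk": 0.0,
    "lab_costs_per_sample": 40.0,
    "plant_value_of_discarded_plant": 0.4,
    "plant_value_of_A1_quality": 0.8,
    "initial_investment_B": 150.0,
    "additional_investment_B": 80.0,
    "labor_costs_B": 700.0,
    "post_processing_costs_B": 0.0,
    "sample_number_B": 2.6,
    "adjustment_sample_size_B": 30.0,
    "number_of_saved_high_quality_plants_B": 3000.0,
    "resource_savings_B": 300.0,
    "initial_investment_I": 350.0,
    "additional_investment_I": 75.0,
    "labor_costs_I": 2000.0,
    "post_processing_costs_I": 0.0,
    "sample_number_I": 8.4,
    "adjustment_sample_size_I": 20.0,
    "number_of_saved_high_quality_plants_I": 10000.0,
    "resource_savings_I": 750.0,
    "initial_investment_S": 59000.0,
    "additional_investment_S": 300.0,
    "labor_costs_S": 2750.0,
    "post_processing_costs_S": 300.0,
    "sample_number_S": 4.2,
    "adjustment_sample_size_S": 20.0,
    "number_of_saved_high_quality_plants_S": 5250.0,
    "resource_savings_S": 750.0,
}


def _const_table(**overrides):
    values = dict(_CONST_VALUES, **overrides)
    units = {name: builtin_table1()[name].unit for name in values}
    return EstimateTable(
        VariableEstimate(name, units[name], "const", v, v)
        for name, v in values.items()
    )


def _oracle_npv(values, code, high_risk_share=None):
    """Plain-Python spreadsheet-style recomputation of one strategy NPV.

    ``high_risk_share``: None uses the chance_high_risk constant as an
    all-or-nothing flag (0 -> all normal years, 100 -> all high-risk).
    """
    r = values["discount_rate"] / 100.0
    area = values["production_area"]
    high = values["chance_high_risk"] >= 50.0
    samples = (
        values[f"sample_number_{code}"]
        if high
        else round(values[f"sample_number_{code}"]
                   * values[f"adjustment_sample_size_{code}"] / 100.0)
    )
    yearly_cost = values[f"additional_investment_{code}"] + area * (
        values[f"labor_costs_{code}"]
        + values[f"post_processing_costs_{code}"]
        + samples * (values["lab_costs_per_sample"]
                     + values["plant_value_of_discarded_plant"])
    )
    yearly_benefit = (
        area * values[f"number_of_saved_high_quality_plants_{code}"]
        * values["plant_value_of_A1_quality"]
        if high
        else area * values[f"resource_savings_{code}"]
    )
    total = -values[f"initial_investment_{code}"]
    for i in range(1, int(values["n_years"]) + 1):
        total += (yearly_benefit - yearly_cost) / (1.0 + r) ** i
    return total


class TestNPV:
    def test_undiscounted_sum(self):
        series = CashFlowSeries(c0=0.0, flows=np.full(10, 100.0))
        assert npv(series, 0.0) == pytest.approx(1000.0)

    def test_pure_establishment_cost(self):
        series = CashFlowSeries(c0=100.0, flows=np.zeros(10))
        assert npv(series, 0.05) == pytest.approx(-100.0)

    def test_single_period_discounting(self):
        series = CashFlowSeries(c0=0.0, flows=np.array([110.0]))
        assert npv(series, 0.10) == pytest.approx(100.0)

    def test_rate_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            npv(CashFlowSeries(c0=0.0, flows=np.ones(3)), -1.5)


class TestDeterministicOracle:
    @pytest.mark.parametrize("chance", [0.0, 100.0])
    @pytest.mark.parametrize("code", ["B", "I", "S"])
    def test_collapsed_pipeline_equals_hand_computation(self, chance, code):
        """With all inputs constant and cv = 0 the simulated NPV equals the
        independently recomputed closed form exactly."""
        table = _const_table(chance_high_risk=chance)
        result = MonitoringModel(table).fit(iterations=4, seed=0)
        expected = _oracle_npv(dict(_CONST_VALUES, chance_high_risk=chance), code)
        assert result.outcome(f"NPV_{code}") == pytest.approx(
            np.full(4, expected), rel=1e-12
        )

    def test_no_high_risk_years_means_no_saved_plant_benefits(self):
        """p_high = 0: the NPV is insensitive to the saved-plant channel."""
        base = MonitoringModel(_const_table()).fit(iterations=3, seed=0)
        bumped = MonitoringModel(
            _const_table(number_of_saved_high_quality_plants_I=18000.0)
        ).fit(iterations=3, seed=0)
        assert np.array_equal(base.outcome("NPV_I"), bumped.outcome("NPV_I"))

    def test_all_high_risk_years_means_no_resource_savings(self):
        """p_high = 1: the NPV is insensitive to resource savings and the
        full sample number is taken every year."""
        base = MonitoringModel(_const_table(chance_high_risk=100.0)).fit(
            iterations=3, seed=0
        )
        bumped = MonitoringModel(
            _const_table(chance_high_risk=100.0, resource_savings_I=5000.0)
        ).fit(iterations=3, seed=0)
        assert np.array_equal(base.outcome("NPV_I"), bumped.outcome("NPV_I"))


class TestStructuralProperties:
    def test_raising_plant_value_never_lowers_npv(self, table1):
        """Monotonicity in the sale price of a high-quality plant."""
        lo = MonitoringModel(_replace(table1, "plant_value_of_A1_quality", 0.6)).fit(
            iterations=2000, seed=9
        )
        hi = MonitoringModel(_replace(table1, "plant_value_of_A1_quality", 0.9)).fit(
            iterations=2000, seed=9
        )
        for code in "BIS":
            assert np.all(hi.outcome(f"NPV_{code}") >= lo.outcome(f"NPV_{code}") - 1e-9)

    def test_raising_labor_costs_never_raises_npv(self, table1):
        lo = MonitoringModel(_replace(table1, "labor_costs_B", 100.0)).fit(
            iterations=2000, seed=9
        )
        hi = MonitoringModel(_replace(table1, "labor_costs_B", 1500.0)).fit(
            iterations=2000, seed=9
        )
        assert np.all(hi.outcome("NPV_B") <= lo.outcome("NPV_B") + 1e-9)

    def test_npv_linear_in_additive_cost_components(self):
        """Superposition: maintenance enters the NPV linearly."""
        outs = {
            v: MonitoringModel(_const_table(additional_investment_B=v))
            .fit(iterations=2, seed=0)
            .outcome("NPV_B")[0]
            for v in (0.0, 100.0, 400.0, 500.0)
        }
        assert outs[500.0] == pytest.approx(outs[100.0] + outs[400.0] - outs[0.0])


class TestDecisionDelta:
    def test_identical_strategies_give_zero(self):
        x = np.arange(5.0)
        assert np.array_equal(decision_delta(x, x), np.zeros(5))

    def test_elementwise_difference(self):
        assert decision_delta([10.0], [4.0])[0] == pytest.approx(6.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decision_delta(np.ones(4), np.ones(5))

    def test_pairing_reduces_decision_variance(self, result10k):
        """Common random numbers for the shared risk factors make the
        paired delta less variable than an unpaired subtraction."""
        paired = result10k.outcome("DoMoreVisual")
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(result10k.outcome("NPV_B"))
        unpaired = result10k.outcome("NPV_I") - shuffled
        assert paired.var() < unpaired.var()


def _replace(table, name, value):
    def swap(e):
        if e.name == name:
            return VariableEstimate(name, e.unit, "const", value, value)
        return e

    return EstimateTable(swap(e) for e in table.values())
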