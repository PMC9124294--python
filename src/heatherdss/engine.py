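"""Monte Carlo orchestration and the simulation results object.

`run_simulation` calibrates every estimate, draws all inputs for the
requested number of iterations, evaluates the three strategy cash flows
with common random numbers for the shared risk factors, and returns a
:class:`SimulationResult` holding the input draws, the NPV outcomes and
the paired decision deltas:

* ``DoMoreVisual`` = NPV(Improved) - NPV(Baseline)
* ``UseSensor``    = NPV(Sensor)   - NPV(Baseline)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cashflow import (
    ScenarioDraw,
    SharedBlock,
    SimulationConfig,
    StrategyBlock,
    decision_delta,
    npv,
    strategy_cashflow,
)
from .estimates import EstimateTable
from .sampling import RandomPlan, calibrate, draw

__all__ = [
    "DECISIONS",
    "OUTCOME_COLUMNS",
    "OutcomeSummary",
    "SimulationResult",
    "run_simulation",
]

#: Decision name -> (alternative strategy, baseline strategy).
DECISIONS = {"DoMoreVisual": ("I", "B"), "UseSensor": ("S", "B")}

OUTCOME_COLUMNS = ("NPV_B", "NPV_I", "NPV_S", "DoMoreVisual", "UseSensor")

_DEFAULT_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class OutcomeSummary:
    """Summary statistics of one outcome distribution."""

    outcome: str
    mean: float
    sd: float
    minimum: float
    maximum: float
    quantiles: dict[float, float]
    p_positive: float

    @classmethod
    def from_draws(cls, outcome: str, values: np.ndarray,
                   quantiles=_DEFAULT_QUANTILES) -> "OutcomeSummary":
        values = np.asarray(values, dtype=float)
        return cls(
            outcome=outcome,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
            minimum=float(values.min()),
            maximum=float(values.max()),
            quantiles={q: float(np.quantile(values, q)) for q in quantiles},
            p_positive=float(np.mean(values > 0.0)),
        )

    def to_dict(self) -> dict:
        out = {
            "outcome": self.outcome,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.minimum,
            "max": self.maximum,
            "p_positive": self.p_positive,
        }
        out.update({f"q{int(round(q * 100)):02d}": v for q, v in self.quantiles.items()})
        return out


class SimulationResult:
    """Input draws and NPV outcomes of one Monte Carlo simulation.

    Attributes
    ----------
    inputs : pandas.DataFrame
        Iteration x variable matrix of drawn input values (original units,
        percents on the 0-100 scale).
    outputs : pandas.DataFrame
        Iteration x outcome matrix with columns ``NPV_B``, ``NPV_I``,
        ``NPV_S``, ``DoMoreVisual`` and ``UseSensor`` (all in €).
    """

    def __init__(
        self,
        inputs: pd.DataFrame,
        outputs: pd.DataFrame,
        plan: RandomPlan,
        config: SimulationConfig,
        table: EstimateTable | None = None,
    ) -> None:
        if len(inputs) != len(outputs):
            raise ValueError("inputs and outputs must have the same number of rows")
        if not np.all(np.isfinite(outputs.to_numpy())):
            raise ValueError("simulation produced non-finite outcomes")
        self.inputs = inputs
        self.outputs = outputs
        self.plan = plan
        self.config = config
        self.table = table

    # -- summaries ----------------------------------------------------------

    @property
    def n_iterations(self) -> int:
        return len(self.outputs)

    def outcome(self, name: str) -> np.ndarray:
        if name not in self.outputs.columns:
            raise ValueError(
                f"unknown outcome {name!r}; available: {list(self.outputs.columns)}"
            )
        return self.outputs[name].to_numpy()

    def summarize(self, outcome: str) -> OutcomeSummary:
        return OutcomeSummary.from_draws(outcome, self.outcome(outcome))

    def summary(self) -> "SimulationSummary":
        return SimulationSummary(self)

    def prob_positive(self, outcome: str) -> float:
        return float(np.mean(self.outcome(outcome) > 0.0))

    def prob_negative(self, outcome: str) -> float:
        return float(np.mean(self.outcome(outcome) < 0.0))

    # -- downstream analyses -------------------------------------------------

    def decision_inputs(self, decision: str) -> pd.DataFrame:
        """Input draws entering a decision: shared + both strategy blocks.

        Variables declared constant in the estimate table are structural
        and excluded.
        """
        alt, base = _decision_codes(decision)
        if self.table is None:
            return self.inputs
        names = [
            n
            for n in self.table
            if not self.table[n].is_constant
            and self.table[n].strategy in (None, alt, base)
            and n in self.inputs.columns
        ]
        return self.inputs[names]

    def vip(self, decision: str = "UseSensor", n_components: int = 2):
        """PLS-VIP sensitivity report for a decision outcome."""
        from .vip import vip_for_decision

        return vip_for_decision(self, decision, n_components=n_components)

    def evpi(self, decision: str = "DoMoreVisual", bins: int = 20):
        """Expected value of perfect information per variable."""
        from .evpi import evpi_report

        return evpi_report(self, decision, bins=bins)

    def serf(self, grid=None, variant: str = "variance"):
        """Certainty-equivalent (SERF) analysis over a risk-aversion grid."""
        from .serf import serf_analysis

        return serf_analysis(self, grid=grid, variant=variant)

    # -- plotting / persistence ---------------------------------------------

    def plot_distributions(self, outcomes=None, ax=None):
        from .plots import plot_outcome_distributions

        return plot_outcome_distributions(self, outcomes=outcomes, ax=ax)

    def save(self, directory: str | Path) -> None:
        """Persist a tidy per-iteration CSV and a JSON summary."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tidy = pd.concat([self.outputs, self.inputs], axis=1)
        tidy.insert(0, "iteration", np.arange(1, len(tidy) + 1))
        tidy.to_csv(directory / "results.csv", index=False)
        summary = {
            "iterations": self.n_iterations,
            "seed": self.plan.seed,
            "n_years": self.config.n_years,
            "production_area": self.config.production_area,
            "outcomes": {c: self.summarize(c).to_dict() for c in self.outputs.columns},
        }
        with open(directory / "summary.json", "w", encoding="utf-8") as handle:
            json.dump(summary, handle, indent=2)


class SimulationSummary:
    """Printable summary table across all outcome columns."""

    def __init__(self, result: SimulationResult) -> None:
        self.result = result
        rows = [result.summarize(c).to_dict() for c in result.outputs.columns]
        self.frame = pd.DataFrame(rows).set_index("outcome")

    def __str__(self) -> str:
        cfg = self.result.config
        header = (
            f"Heather monitoring simulation: {self.result.n_iterations} iterations, "
            f"{cfg.n_years} years, {cfg.production_area:g} ha "
            f"(seed {self.result.plan.seed})"
        )
        with pd.option_context("display.width", 120, "display.float_format",
                               lambda v: f"{v:,.2f}" if abs(v) >= 1 else f"{v:.3f}"):
            body = str(self.frame)
        return header + "\n" + "-" * len(header) + "\n" + body

    def __repr__(self) -> str:
        return str(self)


def _decision_codes(decision: str) -> tuple[str, str]:
    try:
        return DECISIONS[decision]
    except KeyError:
        raise ValueError(
            f"unknown decision {decision!r}; available: {list(DECISIONS)}"
        ) from None


#: Percent-unit variables sampled on the 0-100 scale, divided by 100 at use.
_PERCENT_SCALE = 100.0


def run_simulation(
    table: EstimateTable,
    config: SimulationConfig | None = None,
    plan: RandomPlan | None = None,
) -> SimulationResult:
    """Run the full paired Monte Carlo simulation.

    Shared risk factors (discount rate, interannual CV, chance and
    incidence of high-risk years, lab fee, plant values) are drawn once
    per iteration and reused across strategies; strategy-specific inputs
    are drawn independently.  Deterministic given ``plan``.
    """
    table.validate_complete()
    if config is None:
        config = SimulationConfig.from_table(table)
    if plan is None:
        plan = RandomPlan(manifest=tuple(table))
    n = plan.iterations

    dists = {name: calibrate(table[name]) for name in table}
    draws = {name: draw(dists[name], plan, n, name=name) for name in table}
    inputs = pd.DataFrame(draws)

    p_high = draws["chance_high_risk"] / _PERCENT_SCALE
    flags = plan.rng("high_risk_years").random((n, config.n_years)) < p_high[:, None]
    shared = SharedBlock(
        discount_rate=draws["discount_rate"] / _PERCENT_SCALE,
        cv=draws["var_CV"] / _PERCENT_SCALE,
        p_high=p_high,
        high_risk=flags,
        lab_cost_per_sample=draws["lab_costs_per_sample"],
        plant_value_a1=draws["plant_value_of_A1_quality"],
        plant_value_discarded=draws["plant_value_of_discarded_plant"],
    )
    strategies = {
        code: StrategyBlock(
            initial_investment=draws[f"initial_investment_{code}"],
            additional_investment=draws[f"additional_investment_{code}"],
            labor_costs=draws[f"labor_costs_{code}"],
            post_processing_costs=draws[f"post_processing_costs_{code}"],
            sample_number=draws[f"sample_number_{code}"],
            adjustment_fraction=draws[f"adjustment_sample_size_{code}"] / _PERCENT_SCALE,
            saved_plants=draws[f"number_of_saved_high_quality_plants_{code}"],
            resource_savings=draws[f"resource_savings_{code}"],
        )
        for code in config.strategies
    }
    scenario = ScenarioDraw(shared=shared, strategies=strategies)

    outputs = {}
    for code in config.strategies:
        series = strategy_cashflow(scenario, code, config, plan.rng("value_varier", code))
        outputs[f"NPV_{code}"] = npv(series, shared.discount_rate)
    for decision, (alt, base) in DECISIONS.items():
        if f"NPV_{alt}" in outputs and f"NPV_{base}" in outputs:
            outputs[decision] = decision_delta(outputs[f"NPV_{alt}"],
                                               outputs[f"NPV_{base}"])

    return SimulationResult(inputs, pd.DataFrame(outputs), plan, config, table)
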