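"""Model object tying the pipeline together.

`MonitoringModel` is constructed from an estimate table (the data) and a
simulation configuration; `fit` runs the Monte Carlo simulation and
returns a :class:`~heatherdss.engine.SimulationResult`, from which the
summary table, sensitivity (VIP), value-of-information (EVPI) and
expected-utility (SERF) analyses are available.

    >>> from heatherdss import MonitoringModel
    >>> result = MonitoringModel.table1().fit(iterations=10_000, seed=42)
    >>> print(result.summary())            # doctest: +SKIP
    >>> result.serf().recommendation()     # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path

from .cashflow import SimulationConfig
from .engine import SimulationResult, run_simulation
from .estimates import EstimateTable, builtin_table1, parse_estimate_table
from .sampling import RandomPlan

__all__ = ["MonitoringModel"]


class MonitoringModel:
    """Probabilistic cost-benefit model of heather monitoring strategies."""

    def __init__(self, table: EstimateTable, config: SimulationConfig | None = None):
        table.validate_complete()
        self.table = table
        self.config = config if config is not None else SimulationConfig.from_table(table)

    @classmethod
    def from_csv(cls, path: str | Path, *, delimiter: str = ",",
                 config: SimulationConfig | None = None) -> "MonitoringModel":
        """Build a model from an estimate-table CSV file."""
        return cls(parse_estimate_table(path, delimiter=delimiter), config=config)

    @classmethod
    def table1(cls, config: SimulationConfig | None = None) -> "MonitoringModel":
        """Model over the built-in expert-elicited input set."""
        return cls(builtin_table1(), config=config)

    def fit(self, iterations: int = 10_000, seed: int = 42) -> SimulationResult:
        """Run the paired Monte Carlo simulation."""
        plan = RandomPlan(seed=seed, iterations=iterations,
                          manifest=tuple(self.table))
        return run_simulation(self.table, config=self.config, plan=plan)
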