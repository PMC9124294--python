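"""Ten-year cash-flow model for heather monitoring strategies.

Three strategies are compared on an 8-ha commercial heather nursery:

* **Baseline (B)** — occasional visual monitoring, few lab samples,
  routine prophylactic fungicide use;
* **Improved (I)** — intensified visual monitoring with many lab samples
  and risk-targeted fungicide use;
* **Sensor (S)** — hyperspectral-imaging monitoring, requiring an initial
  sensor investment and data post-processing.

Each simulated year is either *high-risk* (frequent high-humidity weather
favouring fungal infection) or normal-risk.  In high-risk years the full
lab-sample count is taken and monitoring pays off through high-quality
plants saved to the point of sale; in normal-risk years fewer samples are
taken and the benefit channel is resource savings (fungicide, water,
labour avoided when disease pressure is low).

Accounting conventions:

* the initial investment is the whole-farm establishment cost C0 (year 0,
  undiscounted);
* annual maintenance (``additional_investment``) is whole-farm;
* all further costs and benefits are per-hectare rates scaled by the
  production area: labor, post-processing, sampling costs (samples x
  (lab fee + value of the destroyed plant)), saved-plant benefits and
  resource savings;
* labor, post-processing, saved plants and resource savings receive
  interannual variation with the drawn coefficient of variation.

The outcome metric is the net present value
``NPV = -C0 + sum_{i=1..t} C_i / (1 + r)^i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .estimates import STRATEGY_CODES
from .sampling import _vv_matrix

__all__ = [
    "SimulationConfig",
    "SharedBlock",
    "StrategyBlock",
    "ScenarioDraw",
    "CashFlowSeries",
    "npv",
    "strategy_cashflow",
    "decision_delta",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Structural constants of the simulation."""

    n_years: int = 10
    production_area: float = 8.0
    strategies: tuple[str, ...] = STRATEGY_CODES

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError(f"n_years must be >= 1, got {self.n_years}")
        if self.production_area <= 0:
            raise ValueError(
                f"production_area must be positive, got {self.production_area}"
            )

    @classmethod
    def from_table(cls, table) -> "SimulationConfig":
        """Read horizon and area from an estimate table where present."""
        n_years = int(round(table["n_years"].lower)) if "n_years" in table else 10
        area = float(table["production_area"].lower) if "production_area" in table else 8.0
        return cls(n_years=n_years, production_area=area)


@dataclass(frozen=True)
class SharedBlock:
    """Inputs shared by all strategies within one iteration.

    All fields are scalars or per-iteration vectors; ``high_risk`` carries
    an extra trailing year axis.  Rates are fractions (not percents).
    """

    discount_rate: np.ndarray  # fraction / yr
    cv: np.ndarray  # interannual coefficient of variation, fraction
    p_high: np.ndarray  # chance of a high-risk year, fraction
    high_risk: np.ndarray  # bool, shape (..., n_years)
    lab_cost_per_sample: np.ndarray  # € / sample
    plant_value_a1: np.ndarray  # € / marketable high-quality plant
    plant_value_discarded: np.ndarray  # € / discarded (sampled) plant


@dataclass(frozen=True)
class StrategyBlock:
    """Strategy-specific inputs for one iteration (scalars or vectors)."""

    initial_investment: np.ndarray  # €, whole farm, year 0
    additional_investment: np.ndarray  # € / yr maintenance, whole farm
    labor_costs: np.ndarray  # € / ha / yr
    post_processing_costs: np.ndarray  # € / ha / yr
    sample_number: np.ndarray  # samples / yr in a high-risk year
    adjustment_fraction: np.ndarray  # normal-year sample-size multiplier
    saved_plants: np.ndarray  # plants / ha / yr in a high-risk year
    resource_savings: np.ndarray  # € / ha / yr in a normal year


@dataclass(frozen=True)
class ScenarioDraw:
    """One Monte Carlo realization: shared block + per-strategy blocks."""

    shared: SharedBlock
    strategies: Mapping[str, StrategyBlock]


@dataclass(frozen=True)
class CashFlowSeries:
    """Establishment cost C0 and net yearly cash flows C_1..C_t.

    ``flows`` has the year axis last; leading axes are Monte Carlo
    iterations.
    """

    c0: np.ndarray
    flows: np.ndarray

    @property
    def n_years(self) -> int:
        return self.flows.shape[-1]


def npv(series: CashFlowSeries, rate) -> np.ndarray:
    """Net present value ``-C0 + sum_i C_i / (1 + r)^i`` for years 1..t."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= -1.0):
        raise ValueError("discount rate must exceed -1")
    flows = np.asarray(series.flows, dtype=float)
    years = np.arange(1, flows.shape[-1] + 1)
    discount = (1.0 + rate[..., None]) ** years
    return -np.asarray(series.c0, dtype=float) + np.sum(flows / discount, axis=-1)


def strategy_cashflow(
    draw: ScenarioDraw,
    strategy: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CashFlowSeries:
    """Build the yearly cash-flow series of one strategy.

    ``rng`` supplies the interannual variation; within a call it is
    consumed in a fixed order (labor, post-processing, saved plants,
    resource savings) so results are deterministic given the generator
    state.
    """
    try:
        blk = draw.strategies[strategy]
    except KeyError:
        raise ValueError(f"unknown strategy code {strategy!r}") from None
    shared = draw.shared
    years = config.n_years
    area = config.production_area

    as_arr = lambda x: np.asarray(x, dtype=float)
    cv = as_arr(shared.cv)
    flags = np.asarray(shared.high_risk, dtype=bool)

    labor_y = _vv_matrix(as_arr(blk.labor_costs), cv, years, rng)
    post_y = _vv_matrix(as_arr(blk.post_processing_costs), cv, years, rng)
    saved_y = _vv_matrix(as_arr(blk.saved_plants), cv, years, rng)
    savings_y = _vv_matrix(as_arr(blk.resource_savings), cv, years, rng)

    sample_full = as_arr(blk.sample_number)
    sample_normal = np.rint(sample_full * as_arr(blk.adjustment_fraction))
    n_samples = np.where(flags, sample_full[..., None], sample_normal[..., None])

    sampling_cost = n_samples * (
        as_arr(shared.lab_cost_per_sample) + as_arr(shared.plant_value_discarded)
    )[..., None]
    costs = (
        as_arr(blk.additional_investment)[..., None]
        + area * (labor_y + post_y + sampling_cost)
    )
    benefits = np.where(
        flags,
        area * saved_y * as_arr(shared.plant_value_a1)[..., None],
        area * savings_y,
    )
    return CashFlowSeries(c0=as_arr(blk.initial_investment), flows=benefits - costs)


def decision_delta(npv_alternative, npv_baseline) -> np.ndarray:
    """Paired per-iteration difference alternative - baseline.

    Both vectors must come from the same Monte Carlo plan (common random
    numbers for the shared block) so the difference isolates the decision
    effect.
    """
    alt = np.asarray(npv_alternative, dtype=float)
    base = np.asarray(npv_baseline, dtype=float)
    if alt.shape != base.shape:
        raise ValueError(
            f"paired NPV vectors have mismatched shapes {alt.shape} vs {base.shape}"
        )
    return alt - base
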