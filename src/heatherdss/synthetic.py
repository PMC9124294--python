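"""Synthetic inputs with known ground truth.

Three generators support testing without the built-in expert table:

* :func:`generate_table` — structurally valid estimate tables over the
  heather variable manifest, with bounds drawn in unit-appropriate
  ranges (so synthetic runs exercise the same numeric regimes as the
  real inputs);
* :func:`toy_linear_scenario` — normal NPV draws whose certainty
  equivalents, risk premia and EVPI have closed forms;
* :func:`planted_driver_scenario` — a regression design with one known
  dominant driver, for recovery tests of the VIP and EVPI rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimates import HEATHER_MANIFEST, EstimateTable, VariableEstimate, builtin_table1

__all__ = [
    "SyntheticSpec",
    "generate_table",
    "toy_linear_scenario",
    "planted_driver_scenario",
]

# Bound ranges per unit class, calibrated to the magnitudes of the real
# inputs: investments 1e2-1e5 €, recurring per-ha costs 1e2-5e3 €,
# per-plant values 0.1-1 €, plant counts 5e2-2e4, sample counts 2-15,
# percents 5-60.
_EURO_LARGE = ("initial_investment",)
_COUNT_LARGE = ("number_of_saved_high_quality_plants",)
_SAMPLE = ("sample_number",)
_PLANT_VALUE = ("plant_value",)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic estimate table.

    ``all_const`` collapses every interval to its midpoint, making the
    whole downstream pipeline deterministic.  ``planted_driver`` widens
    one variable's interval by ``driver_multiplier`` so it dominates the
    NPV variance (a known ground truth for sensitivity rankings).
    """

    seed: int = 0
    all_const: bool = False
    planted_driver: str | None = None
    driver_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if self.planted_driver is not None and self.planted_driver not in HEATHER_MANIFEST:
            raise ValueError(f"unknown planted driver {self.planted_driver!r}")


def _bounds_for(name: str, unit: str, rng: np.random.Generator) -> tuple[float, float]:
    if name == "discount_rate":  # percent points, financially plausible range
        lo = rng.uniform(1.0, 4.0)
        return lo, lo + rng.uniform(0.5, 4.0)
    if unit == "%":
        lo = rng.uniform(5.0, 40.0)
        return lo, lo + rng.uniform(5.0, 60.0 - lo)
    if unit in ("years", "ha"):
        v = float(rng.integers(5, 15))
        return v, v
    if any(name.startswith(p) for p in _EURO_LARGE):
        lo = rng.uniform(1e2, 2e4)
        return lo, lo * rng.uniform(1.5, 5.0)
    if any(name.startswith(p) for p in _COUNT_LARGE):
        lo = rng.uniform(5e2, 5e3)
        return lo, lo * rng.uniform(2.0, 4.0)
    if any(name.startswith(p) for p in _SAMPLE):
        lo = rng.uniform(2.0, 5.0)
        return lo, lo + rng.uniform(1.0, 10.0)
    if any(name.startswith(p) for p in _PLANT_VALUE):
        lo = rng.uniform(0.1, 0.5)
        return lo, lo + rng.uniform(0.1, 0.5)
    if name.startswith("lab_costs"):  # per-sample fee, tens of €
        lo = rng.uniform(10.0, 40.0)
        return lo, lo + rng.uniform(10.0, 60.0)
    # recurring per-ha / whole-farm € flows
    lo = rng.uniform(1e2, 1e3)
    return lo, lo + rng.uniform(1e2, 4e3)


def generate_table(spec: SyntheticSpec) -> EstimateTable:
    """Generate a valid estimate table over the heather manifest.

    Distribution families and units follow the real table's schema;
    bounds are randomized within unit-class ranges.  Reproducible for a
    fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    schema = builtin_table1()
    estimates = []
    for name in HEATHER_MANIFEST:
        ref = schema[name]
        if ref.is_constant or spec.all_const:
            lo, hi = _bounds_for(name, ref.unit, rng)
            mid = 0.5 * (lo + hi)
            if ref.is_constant:  # keep structural constants at their real values
                mid = ref.lower
            # A fully constant table must make the whole pipeline
            # deterministic: no interannual noise, no random risk years.
            if spec.all_const and name == "var_CV":
                mid = 0.0
            if spec.all_const and name == "chance_high_risk":
                mid = 0.0
            estimates.append(
                VariableEstimate(name, ref.unit, "const", mid, mid, ref.description)
            )
            continue
        lo, hi = _bounds_for(name, ref.unit, rng)
        if name == spec.planted_driver:
            hi = lo + (hi - lo) * spec.driver_multiplier
            if ref.unit == "%":
                hi = min(hi, 100.0)
        estimates.append(
            VariableEstimate(name, ref.unit, ref.distribution, lo, hi, ref.description)
        )
    return EstimateTable(estimates)


def toy_linear_scenario(mu: float, sigma: float, n: int, seed: int = 0) -> np.ndarray:
    """Normal NPV draws with known mean and variance (closed-form oracle)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    return mu + sigma * rng.standard_normal(n)


def planted_driver_scenario(
    k_vars: int = 10,
    driver_coefficient: float = 1.0,
    noise_sd: float = 0.5,
    n: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Inputs and outcome with one planted dominant driver.

    Returns ``(inputs, outcome, driver_name)`` where
    ``outcome = coefficient * driver + noise`` and all ``k_vars`` inputs
    are independent standard normals.  With the defaults the driver
    straddles the adopt/reject boundary (E[outcome] = 0), so it is the
    top-ranked variable for both VIP and EVPI.
    """
    if k_vars < 2:
        raise ValueError(f"need at least 2 variables, got {k_vars}")
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, k_vars)),
        columns=[f"x{i + 1}" for i in range(k_vars)],
    )
    driver = "x1"
    y = driver_coefficient * X[driver].to_numpy() + noise_sd * rng.standard_normal(n)
    return X, y, driver
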