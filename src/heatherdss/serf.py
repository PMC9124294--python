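"""Expected-utility analysis: certainty equivalents and SERF curves.

A decision-maker with constant absolute risk aversion r_a (exponential
utility ``U(x) = 1 - exp(-r_a x)``) values a risky NPV distribution at
its certainty equivalent

    CE = E[NPV] - RP,

with the Arrow-Pratt risk premium ``RP = 1/2 * r_a * Var(NPV)`` (exact
for normal NPVs).  A downside-risk variant replaces the variance with
twice the semi-variance (the mean squared below-mean deviation):
``RP_down = r_a * SV``.  Negative r_a describes risk-taking preferences
and yields a negative premium, i.e. CE above the mean.

Stochastic efficiency with respect to a function (SERF) evaluates the CE
of every strategy on a grid of risk-aversion coefficients; at each grid
point the strategy with the highest CE is the recommendation, and a
strategy with CE <= 0 would not be adopted at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimates import STRATEGY_LABELS

__all__ = [
    "default_grid",
    "risk_premium_variance",
    "risk_premium_semivariance",
    "certainty_equivalent",
    "SERFAnalysis",
    "serf_analysis",
]

VARIANTS = ("variance", "semivariance")


def default_grid(k_max: int = 7) -> np.ndarray:
    """Signed log-spaced risk-aversion grid {±10^-k, k=1..k_max} plus 0.

    Spans -0.1 ... 0.1, the range over which farmer risk preferences are
    commonly discussed, with log spacing because behaviourally relevant
    coefficients differ by orders of magnitude.
    """
    pos = 10.0 ** (-np.arange(1, k_max + 1))
    return np.sort(np.concatenate([-pos, [0.0], pos]))


def risk_premium_variance(npv_draws, r_a: float) -> float:
    """Arrow-Pratt premium ``1/2 * r_a * Var(draws)`` (population variance)."""
    x = np.asarray(npv_draws, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    return 0.5 * r_a * float(np.var(x))


def risk_premium_semivariance(npv_draws, r_a: float) -> float:
    """Downside premium ``r_a * SV`` with SV = mean(min(0, x - mean)^2)."""
    x = np.asarray(npv_draws, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    below = np.minimum(0.0, x - x.mean())
    return r_a * float(np.mean(below**2))


def certainty_equivalent(npv_draws, r_a: float, variant: str = "variance") -> float:
    """CE = mean(draws) - risk premium; equals the mean at r_a = 0."""
    x = np.asarray(npv_draws, dtype=float).ravel()
    if variant == "variance":
        rp = risk_premium_variance(x, r_a)
    elif variant == "semivariance":
        rp = risk_premium_semivariance(x, r_a)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return float(x.mean()) - rp


@dataclass
class SERFAnalysis:
    """Certainty equivalents per strategy over a risk-aversion grid.

    ``table`` is indexed by r_a with one CE column per strategy.
    """

    table: pd.DataFrame
    variant: str

    @property
    def grid(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def best(self, r_a: float) -> str:
        """Strategy with the highest CE at a grid point."""
        return str(self.table.loc[r_a].idxmax())

    def recommendation(self) -> pd.DataFrame:
        """Per grid point: recommended strategy, its CE, ties, non-adoption.

        ``would_not_adopt`` lists the strategies whose CE is <= 0 at that
        level of risk aversion (a negative certainty equivalent means the
        activity would not be taken up at all).
        """
        rows = []
        for r_a, ces in self.table.iterrows():
            best_ce = ces.max()
            winners = tuple(ces.index[ces == best_ce])
            rows.append(
                {
                    "r_a": r_a,
                    "recommended": winners[0],
                    "ce": best_ce,
                    "tie": len(winners) > 1,
                    "would_not_adopt": tuple(ces.index[ces <= 0.0]),
                }
            )
        return pd.DataFrame(rows).set_index("r_a")

    def plot(self, axes=None):
        from .plots import plot_serf

        return plot_serf(self, axes=axes)


def _strategy_draws(source) -> dict[str, np.ndarray]:
    outputs = getattr(source, "outputs", None)
    if outputs is not None:
        draws = {}
        for code, label in STRATEGY_LABELS.items():
            column = f"NPV_{code}"
            if column in outputs.columns:
                draws[label] = outputs[column].to_numpy()
        if not draws:
            raise ValueError("simulation result contains no strategy NPV columns")
        return draws
    return {str(k): np.asarray(v, dtype=float) for k, v in dict(source).items()}


def serf_analysis(source, grid=None, variant: str = "variance") -> SERFAnalysis:
    """SERF curves for all strategies in a simulation result (or mapping).

    ``source`` is a :class:`~heatherdss.engine.SimulationResult` or any
    mapping of strategy name to NPV draw vector.
    """
    draws = _strategy_draws(source)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("risk-aversion grid is empty")
    table = pd.DataFrame(
        {
            name: [certainty_equivalent(x, r_a, variant) for r_a in grid]
            for name, x in draws.items()
        },
        index=pd.Index(grid, name="r_a"),
    )
    return SERFAnalysis(table=table, variant=variant)
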