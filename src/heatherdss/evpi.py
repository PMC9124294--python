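"""Expected Value of Perfect Information, estimated from Monte Carlo draws.

The decision considered is binary adopt / don't-adopt on a decision
outcome (a paired NPV difference): without further information the
decision-maker adopts only if the expected outcome is positive, so the
expected value under current knowledge is ``EMV = max(0, E[outcome])``.
With perfect information about one input variable x the decision can be
conditioned on x:

    EV|PI = E_x[ max(0, E[outcome | x]) ]

and ``EVPI = EV|PI - EMV`` is the most a decision-maker should pay to
learn x before deciding.  The conditional expectation is estimated with
equal-frequency binning of the x draws, which is transparent and easy to
check against closed forms; raw negative estimates (estimator noise) are
clipped to zero and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["conditional_mean", "evpi_for_variable", "EVPIReport", "evpi_report"]


def conditional_mean(
    variable_draws, outcome_draws, bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant estimate of E[outcome | variable].

    Returns ``(bin_means, bin_probs)`` over ``bins`` equal-frequency bins
    of the variable draws.
    """
    x = np.asarray(variable_draws, dtype=float).ravel()
    y = np.asarray(outcome_draws, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("variable and outcome draws must have equal length")
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    if x.size < bins:
        raise ValueError(f"need at least as many samples ({x.size}) as bins ({bins})")
    order = np.argsort(x, kind="stable")
    chunks = np.array_split(order, bins)
    means = np.array([y[c].mean() for c in chunks])
    probs = np.array([c.size for c in chunks], dtype=float) / x.size
    return means, probs


def evpi_for_variable(variable_draws, outcome_draws, bins: int = 20) -> float:
    """EVPI (€) of one input variable for an adopt/don't-adopt decision."""
    y = np.asarray(outcome_draws, dtype=float).ravel()
    emv = max(0.0, float(y.mean()))
    means, probs = conditional_mean(variable_draws, y, bins=bins)
    ev_pi = float(np.sum(probs * np.maximum(0.0, means)))
    raw = ev_pi - emv
    if raw < 0:
        logger.debug("negative raw EVPI estimate %.6g clipped to 0", raw)
    # When every conditional mean shares the sign of the overall mean,
    # EV|PI equals EMV analytically; snap float residue to an exact zero.
    if raw <= 1e-12 * max(1.0, abs(emv), float(np.abs(means).max())):
        return 0.0
    return raw


@dataclass
class EVPIReport:
    """Per-variable EVPI values for one decision.

    ``frame`` has one row per variable with column ``evpi`` (€);
    ``ranked()`` sorts by descending EVPI.
    """

    frame: pd.DataFrame
    decision: str
    emv: float
    bins: int

    @property
    def top(self) -> str:
        return str(self.frame["evpi"].idxmax())

    def ranked(self) -> pd.DataFrame:
        return self.frame.sort_values("evpi", ascending=False)

    def __getitem__(self, variable: str) -> float:
        return float(self.frame.loc[variable, "evpi"])


def evpi_report(result, decision: str, bins: int = 20) -> EVPIReport:
    """EVPI of every variable entering a decision, from paired MC draws."""
    X = result.decision_inputs(decision)
    y = result.outcome(decision)
    values = {
        str(c): evpi_for_variable(X[c].to_numpy(), y, bins=bins) for c in X.columns
    }
    frame = pd.DataFrame(
        {"evpi": pd.Series(values)},
    )
    frame.index.name = "variable"
    return EVPIReport(
        frame=frame, decision=decision, emv=max(0.0, float(np.mean(y))), bins=bins
    )
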