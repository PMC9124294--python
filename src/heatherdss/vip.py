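"""PLS sensitivity analysis with Variable Importance in the Projection.

Outcome draws are regressed on the input draws with partial least
squares (NIPALS, via scikit-learn, inputs and outcome standardized).
The importance of input ``j`` over ``A`` components is

    VIP_j = sqrt( K * sum_a(w_aj^2 * SSY_a) / sum_a(SSY_a) )

where ``K`` is the number of inputs, ``w_aj`` the (unit-norm) PLS weight
of input j on component a and ``SSY_a`` the outcome sum of squares
explained by component a.  Squared VIP scores average to one, so VIP > 1
flags an input as influential.  The sign of the final PLS regression
coefficient gives the direction of influence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = ["PLSModel", "VIPReport", "pls_fit", "vip_scores", "vip_for_decision"]


@dataclass
class PLSModel:
    """A fitted PLS decomposition plus the pieces VIP needs."""

    estimator: PLSRegression
    columns: tuple[str, ...]
    dropped: tuple[str, ...]
    weights: np.ndarray  # K x A, columns unit norm
    coefficients: np.ndarray  # K, on standardized scales
    ssy_components: np.ndarray  # A, outcome SS explained per component
    ssy_total: float  # total centered outcome SS

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def explained_y_ratio(self) -> np.ndarray:
        """Fraction of outcome variance explained per component."""
        if self.ssy_total == 0:
            return np.zeros_like(self.ssy_components)
        return self.ssy_components / self.ssy_total


@dataclass
class VIPReport:
    """Per-variable VIP scores with influence directions.

    ``frame`` has one row per variable with columns ``vip``, ``sign``
    and ``coefficient``; ``ranked()`` sorts by descending VIP and
    ``important`` lists the variables with VIP > 1.
    """

    frame: pd.DataFrame
    n_components: int
    decision: str | None = None

    @property
    def important(self) -> tuple[str, ...]:
        return tuple(self.frame.index[self.frame["vip"] > 1.0])

    @property
    def top(self) -> str:
        return str(self.frame["vip"].idxmax())

    def ranked(self) -> pd.DataFrame:
        return self.frame.sort_values("vip", ascending=False)

    def __getitem__(self, variable: str) -> float:
        return float(self.frame.loc[variable, "vip"])


def _as_frame(inputs) -> pd.DataFrame:
    if isinstance(inputs, pd.DataFrame):
        return inputs
    arr = np.asarray(inputs, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{i + 1}" for i in range(arr.shape[1])])


def pls_fit(inputs, outcome, n_components: int = 2) -> PLSModel:
    """Fit a PLS regression of ``outcome`` on ``inputs``.

    Constant columns carry no information on the standardized scale and
    are dropped with a warning; exact duplicates (up to affine rescaling)
    are consolidated.  Requesting more components than the rank of the
    remaining input matrix raises ``ValueError``.
    """
    X = _as_frame(inputs)
    y = np.asarray(outcome, dtype=float).ravel()
    if len(X) != len(y):
        raise ValueError("inputs and outcome must have the same length")
    if X.shape[1] < 1:
        raise ValueError("need at least one input variable")

    values = X.to_numpy(dtype=float)
    spread = np.ptp(values, axis=0)
    dropped = [c for c, s in zip(X.columns, spread) if s == 0.0]
    if dropped:
        warnings.warn(
            f"dropping constant input columns: {', '.join(map(str, dropped))}",
            RuntimeWarning,
            stacklevel=2,
        )
        X = X.drop(columns=dropped)
        values = X.to_numpy(dtype=float)

    # Consolidate columns identical after standardization (affine duplicates).
    standardized = (values - values.mean(axis=0)) / values.std(axis=0)
    keep: list[int] = []
    dup: list[str] = []
    for j in range(standardized.shape[1]):
        if any(np.allclose(standardized[:, j], standardized[:, k]) for k in keep):
            dup.append(str(X.columns[j]))
        else:
            keep.append(j)
    if dup:
        warnings.warn(
            f"consolidating duplicate input columns: {', '.join(dup)}",
            RuntimeWarning,
            stacklevel=2,
        )
        X = X.iloc[:, keep]
        standardized = standardized[:, keep]
        dropped += dup

    rank = np.linalg.matrix_rank(standardized)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the rank ({rank}) of the input matrix"
        )

    est = PLSRegression(n_components=n_components, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X.to_numpy(dtype=float), y)

    W = est.x_weights_
    norms = np.linalg.norm(W, axis=0, keepdims=True)
    W = W / np.where(norms == 0, 1.0, norms)
    T = est.x_scores_
    q = est.y_loadings_.ravel()
    ssy = q**2 * np.einsum("ia,ia->a", T, T)
    y_std = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    return PLSModel(
        estimator=est,
        columns=tuple(map(str, X.columns)),
        dropped=tuple(dropped),
        weights=W,
        coefficients=est.coef_.ravel(),
        ssy_components=ssy,
        ssy_total=float(y_std @ y_std),
    )


def vip_scores(model: PLSModel, decision: str | None = None) -> VIPReport:
    """Compute VIP scores and influence signs from a fitted PLS model."""
    K = len(model.columns)
    ssy = model.ssy_components
    total = ssy.sum()
    if total == 0:
        warnings.warn(
            "PLS model explains no outcome variance; VIP scores are all zero",
            RuntimeWarning,
            stacklevel=2,
        )
        vip = np.zeros(K)
    else:
        vip = np.sqrt(K * (model.weights**2 @ ssy) / total)
    signs = np.where(model.coefficients >= 0, "+", "-")
    frame = pd.DataFrame(
        {"vip": vip, "sign": signs, "coefficient": model.coefficients},
        index=pd.Index(model.columns, name="variable"),
    )
    return VIPReport(frame=frame, n_components=model.n_components, decision=decision)


def vip_for_decision(result, decision: str, n_components: int = 2) -> VIPReport:
    """VIP report of a decision outcome against the variables entering it."""
    X = result.decision_inputs(decision)
    y = result.outcome(decision)
    model = pls_fit(X, y, n_components=n_components)
    return vip_scores(model, decision=decision)
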