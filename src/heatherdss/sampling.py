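"""Calibrated sampling from elicited 90% confidence intervals.

Each expert estimate is an interval (5th, 95th percentile).  Calibration
turns it into a concrete distribution whose *truncated* quantiles match
the elicited bounds:

* ``posnorm`` -> normal truncated below at 0,
* ``tnorm``   -> normal truncated to [0, 100] (percent scale),
* ``const``   -> point mass.

The location and scale are solved by quantile matching on the truncated
distribution (two-parameter root finding).  When the truncation removes a
negligible probability mass (< 1e-6) the closed form of the untruncated
normal is used directly: location (L+U)/2, scale (U-L)/(2 * z_0.95).

Reproducibility uses one global seed with per-variable substreams derived
from (seed, key), so adding or removing a variable never perturbs the
draws of another.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .estimates import VariableEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "Z90",
    "CalibrationError",
    "CalibratedDistribution",
    "RandomPlan",
    "derive_rng",
    "calibrate",
    "draw",
    "value_varier",
]

#: Standard-normal 95th percentile; a 90% CI spans 2 * Z90 standard deviations.
Z90 = 1.6448536269514722

#: Truncation mass below which the closed-form (untruncated) solution is used.
_NEGLIGIBLE_MASS = 1e-6


class CalibrationError(RuntimeError):
    """The quantile-matching solver failed for a variable."""


@dataclass(frozen=True)
class CalibratedDistribution:
    """A sampling distribution fitted to an elicited 90% interval.

    ``mu`` and ``sigma`` are the parameters of the parent normal before
    truncation to ``(lower, upper)``; for a point mass ``sigma`` is 0 and
    ``mu`` is the value.
    """

    family: str  # "posnorm" | "tnorm" | "const"
    mu: float
    sigma: float
    lower: float = 0.0
    upper: float = math.inf

    @property
    def is_point_mass(self) -> bool:
        return self.sigma == 0.0

    def _frozen(self):
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def ppf(self, q):
        if self.is_point_mass:
            return np.full_like(np.asarray(q, dtype=float), self.mu)
        return self._frozen().ppf(q)

    def cdf(self, x):
        if self.is_point_mass:
            return np.where(np.asarray(x, dtype=float) >= self.mu, 1.0, 0.0)
        return self._frozen().cdf(x)

    def mean(self) -> float:
        if self.is_point_mass:
            return self.mu
        return float(self._frozen().mean())

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values inside the truncation interval."""
        if self.is_point_mass:
            return np.full(n, self.mu)
        return self._frozen().rvs(size=n, random_state=rng)


def _truncation(estimate: VariableEstimate) -> tuple[float, float]:
    if estimate.distribution == "posnorm":
        return 0.0, math.inf
    if estimate.distribution == "tnorm":
        return 0.0, 100.0
    raise ValueError(f"no truncation interval for {estimate.distribution!r}")


def calibrate(estimate: VariableEstimate, tol: float = 1e-3) -> CalibratedDistribution:
    """Fit a :class:`CalibratedDistribution` to an estimate's 90% interval.

    For non-degenerate intervals the fitted distribution's 5th and 95th
    percentiles reproduce ``(lower, upper)`` to relative tolerance ``tol``
    (relative to the interval scale); otherwise :class:`CalibrationError`
    is raised naming the variable.
    """
    lo, hi = estimate.lower, estimate.upper
    if estimate.is_constant or lo == hi:
        return CalibratedDistribution("const", mu=lo, sigma=0.0, lower=lo, upper=lo)

    a, b = _truncation(estimate)
    mu0 = 0.5 * (lo + hi)
    sigma0 = (hi - lo) / (2.0 * Z90)

    # Mass the truncation would remove under the closed-form parameters.
    mass = stats.norm.cdf(a, mu0, sigma0) + stats.norm.sf(b, mu0, sigma0)
    if mass < _NEGLIGIBLE_MASS:
        mu, sigma = mu0, sigma0
    else:
        width = hi - lo

        def residuals(params):
            m, log_s = params
            s = math.exp(log_s)
            sa, sb = (a - m) / s, (b - m) / s
            q = stats.truncnorm.ppf([0.05, 0.95], sa, sb, loc=m, scale=s)
            return (q - [lo, hi]) / width

        sol = optimize.least_squares(
            residuals, x0=[mu0, math.log(sigma0)], xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        mu, sigma = sol.x[0], math.exp(sol.x[1])

    dist = CalibratedDistribution(estimate.distribution, mu=mu, sigma=sigma,
                                  lower=a, upper=b)
    scale = max(abs(lo), abs(hi), hi - lo)
    q05, q95 = dist.ppf([0.05, 0.95])
    if abs(q05 - lo) > tol * scale or abs(q95 - hi) > tol * scale:
        raise CalibrationError(
            f"{estimate.name}: calibrated quantiles ({q05:g}, {q95:g}) do not "
            f"reproduce the elicited bounds ({lo:g}, {hi:g}) within tolerance {tol:g}"
        )
    return dist


# --- reproducible random plans --------------------------------------------


def _substream_entropy(key: str) -> int:
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def derive_rng(seed: int, key: str) -> np.random.Generator:
    """A generator deterministically derived from a global seed and a key."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _substream_entropy(key)])
    )


@dataclass(frozen=True)
class RandomPlan:
    """Seed, iteration count and draw-order manifest of a simulation.

    A fixed (seed, manifest) pair yields bit-identical draw sequences;
    substreams are keyed by variable name so the draws of one variable do
    not depend on which other variables exist.
    """

    seed: int = 42
    iterations: int = 10_000
    manifest: tuple[str, ...] = field(default_factory=tuple)

    def rng(self, *key: str) -> np.random.Generator:
        return derive_rng(self.seed, "/".join(key))


def draw(
    dist: CalibratedDistribution,
    plan: RandomPlan,
    n: int | None = None,
    *,
    name: str = "",
) -> np.ndarray:
    """Draw ``n`` samples (default ``plan.iterations``) for variable ``name``."""
    if n is None:
        n = plan.iterations
    return dist.rvs(n, plan.rng("var", name or dist.family))


# --- interannual value variation ------------------------------------------


def _vv_matrix(
    annual_mean: np.ndarray,
    cv_fraction: np.ndarray,
    n_years: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Yearly values: normal(mean, mean * cv), clamped below at 0.

    ``annual_mean`` and ``cv_fraction`` broadcast; one trailing year axis
    is appended.
    """
    mean = np.asarray(annual_mean, dtype=float)
    cv = np.asarray(cv_fraction, dtype=float)
    z = rng.standard_normal(np.broadcast_shapes(mean.shape, cv.shape) + (n_years,))
    return np.clip(mean[..., None] * (1.0 + cv[..., None] * z), 0.0, None)


def value_varier(
    annual_mean: float,
    cv_percent: float,
    n_years: int,
    plan: RandomPlan | np.random.Generator,
    *,
    key: str = "value_varier",
) -> np.ndarray:
    """Perturb a yearly mean with interannual variation.

    Each year is drawn from a normal with mean ``annual_mean`` and standard
    deviation ``annual_mean * cv_percent / 100``, kept non-negative (costs,
    benefits and plant counts cannot go below zero).
    """
    if cv_percent < 0:
        raise ValueError(f"coefficient of variation must be >= 0, got {cv_percent}")
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    rng = plan.rng(key) if isinstance(plan, RandomPlan) else plan
    return _vv_matrix(np.float64(annual_mean), np.float64(cv_percent) / 100.0,
                      n_years, rng)
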