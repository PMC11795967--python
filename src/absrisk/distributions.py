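"""Sampling distributions fitted from user-facing effect summaries.

A baseline risk (BR) given as point + 95% CI is converted to a beta
distribution; a relative effect (RR/OR/HR) given as point + 95% CI is
converted to a lognormal distribution on the ratio scale.  These are the
two marginals the microsimulation draws from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

#: two-sided 95% normal quantile (1.959964 to printed precision) used for
#: all CI <-> SE conversions; full precision keeps quantile round-trips exact
Z95 = 1.9599639845400545

_MEASURES = ("RR", "OR", "HR")


@dataclass(frozen=True)
class BaselineRisk:
    """Control-group event probability with a 95% CI (or plain range).

    A ``range`` interval is treated identically to a 95% CI: the tool
    accepts a range only as a stand-in when no CI is available, and no
    separate calibration for it is defined.
    """

    point: float
    lower: float
    upper: float
    interval_kind: str = "ci95"  # "ci95" or "range"

    def __post_init__(self) -> None:
        if self.interval_kind not in ("ci95", "range"):
            raise ValueError(f"unknown interval_kind {self.interval_kind!r}")
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError(
                "baseline risk must satisfy 0 <= lower <= point <= upper <= 1, "
                f"got ({self.lower}, {self.point}, {self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class BetaParams:
    """Beta shape parameters, or a point mass when the CI has zero width."""

    alpha: float = float("nan")
    beta: float = float("nan")
    degenerate_at: Optional[float] = None

    def __post_init__(self) -> None:
        if self.degenerate_at is None and not (self.alpha > 0 and self.beta > 0):
            raise ValueError("beta shapes must be positive unless degenerate")

    @property
    def mean(self) -> float:
        if self.degenerate_at is not None:
            return self.degenerate_at
        return self.alpha / (self.alpha + self.beta)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.degenerate_at is not None:
            return np.full(n, self.degenerate_at)
        return rng.beta(self.alpha, self.beta, size=n)

    def quantile(self, q) -> np.ndarray:
        if self.degenerate_at is not None:
            return np.full_like(np.asarray(q, dtype=float), self.degenerate_at)
        return stats.beta.ppf(q, self.alpha, self.beta)


@dataclass(frozen=True)
class RelativeEffect:
    """Pooled relative effect (RR, OR or HR) with its 95% CI."""

    measure: str
    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        measure = self.measure.upper()
        object.__setattr__(self, "measure", measure)
        if measure not in _MEASURES:
            raise ValueError(f"measure must be one of {_MEASURES}, got {measure!r}")
        if not (0.0 < self.lower <= self.point <= self.upper):
            raise ValueError(
                "relative effect must satisfy 0 < lower <= point <= upper, "
                f"got ({self.lower}, {self.point}, {self.upper})"
            )


@dataclass(frozen=True)
class LognormalParams:
    """Parameters of the log-effect normal distribution."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0.0:
            return np.full(n, math.exp(self.mu))
        return rng.lognormal(self.mu, self.sigma, size=n)

    def quantile(self, q) -> np.ndarray:
        if self.sigma == 0.0:
            return np.full_like(np.asarray(q, dtype=float), math.exp(self.mu))
        return np.exp(stats.norm.ppf(q, loc=self.mu, scale=self.sigma))


def fit_beta(br: BaselineRisk, method: str = "moment") -> BetaParams:
    """Fit a beta distribution to a baseline risk and its 95% CI.

    The default is moment matching: the mean is set to ``br.point`` and the
    variance to ``((upper - lower) / (2 * 1.959964))**2``.  A zero-width
    interval yields a point mass.  When the implied variance is infeasible
    for a beta with that mean (var >= p(1-p)), the fit falls back to
    matching the 2.5%/97.5% quantiles to the CI bounds.  ``method="quantile"``
    forces quantile matching.
    """
    if method not in ("moment", "quantile"):
        raise ValueError(f"unknown fitting method {method!r}")
    p = br.point
    se = br.width / (2.0 * Z95)
    if se == 0.0:
        return BetaParams(degenerate_at=p)
    if p <= 0.0 or p >= 1.0:
        raise ValueError(
            "a baseline risk of exactly 0 or 1 with a nonzero CI width cannot "
            "be represented by a beta mean on the boundary; supply a zero-width "
            "interval or shape parameters directly"
        )
    var = se * se
    if method == "quantile" or var >= p * (1.0 - p):
        return _fit_beta_quantiles(br)
    nu = p * (1.0 - p) / var - 1.0
    return BetaParams(alpha=p * nu, beta=(1.0 - p) * nu)


def _fit_beta_quantiles(br: BaselineRisk) -> BetaParams:
    """Solve for (alpha, beta) whose 2.5%/97.5% quantiles hit the CI bounds."""
    lo, hi = br.lower, br.upper
    if lo <= 0.0:
        lo = min(1e-6, hi / 10.0)
    if hi >= 1.0:
        hi = max(1.0 - 1e-6, 1.0 - (1.0 - lo) / 10.0)

    target = np.log([lo, hi])

    def residual(logab):
        a, b = np.exp(logab)
        q = stats.beta.ppf([0.025, 0.975], a, b)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(q, 1e-300)) - target

    # moment-matched start at a feasible variance, then neutral fallbacks
    p = br.point
    var = min((br.width / (2 * Z95)) ** 2, 0.5 * p * (1 - p))
    nu = max(p * (1 - p) / var - 1.0, 0.1)
    starts = [(p * nu, (1 - p) * nu), (0.5, 5.0), (2.0, 2.0), (5.0, 0.5)]
    for start in starts:
        sol = optimize.least_squares(residual, np.log(start),
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15)
        a, b = np.exp(sol.x)
        q = stats.beta.ppf([0.025, 0.975], a, b)
        if np.max(np.abs(q - [lo, hi])) < 1e-8:
            return BetaParams(alpha=float(a), beta=float(b))
    raise RuntimeError(
        f"quantile-matching beta fit failed for bounds ({br.lower}, {br.upper})"
    )


def fit_lognormal(eff: RelativeEffect) -> LognormalParams:
    """Fit the log-effect normal from a ratio-scale point and 95% CI.

    mu = ln(point); sigma = (ln(upper) - ln(lower)) / (2 * 1.959964).
    The fit is exact on the log scale: the 2.5%/97.5% lognormal quantiles
    reproduce a log-symmetric input CI to machine precision.
    """
    mu = math.log(eff.point)
    sigma = (math.log(eff.upper) - math.log(eff.lower)) / (2.0 * Z95)
    return LognormalParams(mu=mu, sigma=sigma)
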