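"""Pooling 2x2 study counts into a log relative risk, and BR surrogates.

Implements inverse-variance common-effect pooling, the DerSimonian-Laird
moment estimator of between-study variance, and an iterative REML
estimator, all on the log-RR scale.  Control-arm event rates provide the
baseline-risk surrogates (largest study, or all studies aggregated), with
Wilson score intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .distributions import Z95, BaselineRisk

logger = logging.getLogger(__name__)

POOLING_MODELS = ("common", "dl", "reml")


@dataclass(frozen=True)
class StudyRecord:
    """One randomized study: 2x2 binary-outcome counts and labels."""

    review_id: str
    ma_id: str
    study_id: str
    events_t: int
    n_t: int
    events_c: int
    n_c: int
    comparator: str = "other"  # "placebo" or "other"

    def __post_init__(self) -> None:
        for ev, n, arm in ((self.events_t, self.n_t, "treatment"),
                           (self.events_c, self.n_c, "control")):
            if n < 1:
                raise ValueError(f"{arm} arm of {self.study_id}: n must be >= 1")
            if not (0 <= ev <= n):
                raise ValueError(
                    f"{arm} arm of {self.study_id}: events must be in [0, n]"
                )

    @property
    def total_n(self) -> int:
        return self.n_t + self.n_c

    @property
    def double_zero(self) -> bool:
        return self.events_t == 0 and self.events_c == 0


@dataclass(frozen=True)
class MetaAnalysis:
    """Studies pooled together under one meta-analysis id."""

    studies: Tuple[StudyRecord, ...]

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("a meta-analysis needs at least one study")
        object.__setattr__(self, "studies", tuple(self.studies))

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def ma_id(self) -> str:
        return self.studies[0].ma_id

    @property
    def review_id(self) -> str:
        return self.studies[0].review_id

    @property
    def all_placebo(self) -> bool:
        return all(s.comparator == "placebo" for s in self.studies)


@dataclass(frozen=True)
class PooledEffect:
    """Pooled log-RR with its SE, tau^2 and the back-transformed RR CI."""

    log_rr: float
    se_log_rr: float
    tau2: float
    model: str
    k: int

    @property
    def rr(self) -> float:
        return math.exp(self.log_rr)

    @property
    def rr_ci(self) -> Tuple[float, float]:
        return (
            math.exp(self.log_rr - Z95 * self.se_log_rr),
            math.exp(self.log_rr + Z95 * self.se_log_rr),
        )


def study_log_rr(s: StudyRecord) -> Tuple[float, float]:
    """Log relative risk and its delta-method variance for one study.

    If any cell (events or non-events in either arm) is zero, 0.5 is added
    to the event count and to the sample size of both arms.  Double-zero
    studies carry no RR information and must be filtered out upstream.

    A study in which *both* arms have events equal to n is returned with
    zero variance; ``pool`` excludes such degenerate studies.
    """
    if s.double_zero:
        raise ValueError(
            f"study {s.study_id} has zero events in both arms; "
            "double-zero studies must be excluded before pooling"
        )
    et, nt, ec, nc = float(s.events_t), float(s.n_t), float(s.events_c), float(s.n_c)
    if 0.0 in (et, ec, nt - et, nc - ec):
        et, ec = et + 0.5, ec + 0.5
        nt, nc = nt + 0.5, nc + 0.5
    y = math.log((et / nt) / (ec / nc))
    v = 1.0 / et - 1.0 / nt + 1.0 / ec - 1.0 / nc
    return y, v


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(y)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (k - 1)) / denom)


def _reml_tau2(y: np.ndarray, v: np.ndarray,
               tol: float = 1e-8, max_iter: int = 200) -> float:
    """Fixed-point REML iteration for tau^2; DL fallback on non-convergence."""
    tau2 = _dl_tau2(y, v)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        new = np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        new = max(0.0, float(new))
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    logger.warning("REML tau^2 did not converge in %d iterations; "
                   "falling back to DerSimonian-Laird", max_iter)
    return _dl_tau2(y, v)


def pool(ma: MetaAnalysis, model: str = "dl") -> PooledEffect:
    """Pool a meta-analysis on the log-RR scale under the requested model."""
    if model not in POOLING_MODELS:
        raise ValueError(f"model must be one of {POOLING_MODELS}, got {model!r}")
    usable = [s for s in ma.studies if not s.double_zero]
    yv = [study_log_rr(s) for s in usable]
    degenerate = [s.study_id for s, (_, v_i) in zip(usable, yv) if v_i <= 0.0]
    if degenerate:
        logger.warning("meta-analysis %s: excluding zero-variance studies %s "
                       "(all participants had the event in both arms)",
                       ma.ma_id, degenerate)
        yv = [pair for pair in yv if pair[1] > 0.0]
    if len(yv) < 2:
        raise ValueError(
            f"meta-analysis {ma.ma_id}: need at least 2 usable studies, "
            f"got {len(yv)}"
        )
    arr = np.array(yv)
    y, v = arr[:, 0], arr[:, 1]
    if model == "common":
        tau2 = 0.0
    elif model == "dl":
        tau2 = _dl_tau2(y, v)
    else:
        tau2 = _reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return PooledEffect(log_rr=mu, se_log_rr=se, tau2=tau2, model=model,
                        k=len(usable))


def wilson_interval(events: int, n: int) -> Tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(events, n, alpha=0.05, method="wilson")
    # the closed form can dip a few ulp outside [0,1] at the boundaries
    return float(min(max(lo, 0.0), 1.0)), float(min(max(hi, 0.0), 1.0))


def br_largest_study(ma: MetaAnalysis) -> BaselineRisk:
    """Control-arm event rate of the largest study as the BR surrogate.

    "Largest" means largest total randomized sample (both arms); ties go to
    the first study in input order.
    """
    largest = max(ma.studies, key=lambda s: s.total_n)  # max keeps first tie
    point = largest.events_c / largest.n_c
    lo, hi = wilson_interval(largest.events_c, largest.n_c)
    return BaselineRisk(point=point, lower=min(lo, point), upper=max(hi, point))


def br_all_studies(ma: MetaAnalysis) -> BaselineRisk:
    """Pooled control-arm rate: sum of events over sum of control sizes."""
    events = sum(s.events_c for s in ma.studies)
    n = sum(s.n_c for s in ma.studies)
    point = events / n
    lo, hi = wilson_interval(events, n)
    return BaselineRisk(point=point, lower=min(lo, point), upper=max(hi, point))
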