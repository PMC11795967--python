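"""Synthetic Cochrane-like corpus generator with known ground truth.

The real corpus behind the empirical evaluation (thousands of binary-outcome
meta-analyses from systematic reviews) is not redistributable, so this
module fabricates corpora with the same gross shape: a handful to dozens of
studies per meta-analysis, per-arm sample sizes spanning tens to thousands
(log-uniform), control-arm risks spread over (0, 1) with a median near 0.2,
and normally distributed between-study heterogeneity on the log-RR scale.
Every generated meta-analysis carries its true baseline risk, true RR and
true risk difference, so parameter-recovery and coverage properties are
testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .absolute import risk_under_treatment
from .pooling import StudyRecord

#: control-risk beta shapes calibrated so the corpus-level distribution of
#: baseline risks has median ~0.20 and IQR ~(0.07, 0.41)
BR_ALPHA_DEFAULT = 0.686
BR_BETA_DEFAULT = 1.905


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus; one meta-analysis per review.

    ``studies_per_ma`` is ``studies_min`` plus a Poisson(``studies_mean_extra``)
    count, giving a mean of ~8.6 studies per meta-analysis by default (the
    per-review study load typical of large review collections).  ``tau`` is
    the between-study SD of the log-RR; true per-MA log-RRs are normal with
    SD ``log_rr_sd`` around ``log_rr_mean``.
    """

    n_reviews: int = 500
    studies_min: int = 3
    studies_mean_extra: float = 5.6
    n_per_arm_min: int = 20
    n_per_arm_max: int = 2000
    br_alpha: float = BR_ALPHA_DEFAULT
    br_beta: float = BR_BETA_DEFAULT
    br_fixed: Optional[float] = None  # degenerate BR spec for tests
    log_rr_mean: float = 0.0
    log_rr_sd: float = 0.5
    tau: float = 0.25
    placebo_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reviews < 1:
            raise ValueError("n_reviews must be positive")
        if self.studies_min < 1 or self.studies_mean_extra < 0:
            raise ValueError("invalid studies-per-MA specification")
        if not (1 <= self.n_per_arm_min <= self.n_per_arm_max):
            raise ValueError("invalid per-arm sample-size range")
        if self.br_fixed is None and not (self.br_alpha > 0 and self.br_beta > 0):
            raise ValueError("beta shapes for the BR distribution must be positive")
        if self.br_fixed is not None and not (0.0 < self.br_fixed < 1.0):
            raise ValueError("br_fixed must lie strictly inside (0, 1)")
        if self.log_rr_sd < 0 or self.tau < 0:
            raise ValueError("spread parameters must be non-negative")
        if not (0.0 <= self.placebo_fraction <= 1.0):
            raise ValueError("placebo_fraction must be a probability")


def generate(spec: CorpusSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a corpus of study records plus a per-MA ground-truth table.

    Per meta-analysis: a true control risk and true log-RR are drawn; each
    study gets its own log-RR (normal around the truth with SD ``tau``), a
    control risk jittered on the logit scale so control arms differ between
    studies, and binomial event counts in both arms.  The treatment-arm
    risk is ``min(control_risk * study_RR, 1)`` — the same truncation rule
    as the microsimulation.

    Returns ``(corpus, truth)``: the corpus in the tabular study-record
    layout (one row per study), and the truth table with the true BR, RR
    and RD per 1,000 for every meta-analysis.
    """
    rng = np.random.default_rng(spec.seed)
    rows: List[dict] = []
    truth_rows: List[dict] = []
    for i in range(spec.n_reviews):
        review_id = f"R{i:05d}"
        ma_id = f"{review_id}.1"
        if spec.br_fixed is not None:
            true_br = spec.br_fixed
        else:
            true_br = float(rng.beta(spec.br_alpha, spec.br_beta))
            true_br = min(max(true_br, 1e-4), 1.0 - 1e-4)
        true_log_rr = float(rng.normal(spec.log_rr_mean, spec.log_rr_sd))
        comparator = "placebo" if rng.random() < spec.placebo_fraction else "other"
        k = spec.studies_min + int(rng.poisson(spec.studies_mean_extra))
        n_arms = np.exp(
            rng.uniform(math.log(spec.n_per_arm_min),
                        math.log(spec.n_per_arm_max), size=(k, 2))
        ).astype(int)
        study_log_rr = rng.normal(true_log_rr, spec.tau, size=k)
        # mild logit-scale jitter so control risks vary between studies
        logit = math.log(true_br / (1.0 - true_br))
        pc = 1.0 / (1.0 + np.exp(-rng.normal(logit, 0.15, size=k)))
        pt = np.minimum(pc * np.exp(study_log_rr), 1.0)
        ev_c = rng.binomial(n_arms[:, 1], pc)
        ev_t = rng.binomial(n_arms[:, 0], pt)
        for j in range(k):
            rows.append(dict(
                review_id=review_id, ma_id=ma_id, study_id=f"{ma_id}.s{j:03d}",
                events_t=int(ev_t[j]), n_t=int(n_arms[j, 0]),
                events_c=int(ev_c[j]), n_c=int(n_arms[j, 1]),
                comparator=comparator,
            ))
        true_rr = math.exp(true_log_rr)
        true_rd = risk_under_treatment(true_br, true_rr, "RR") - true_br
        truth_rows.append(dict(
            ma_id=ma_id, review_id=review_id, true_br=true_br,
            true_log_rr=true_log_rr, true_rr=true_rr,
            true_rd=true_rd, true_rd_per1000=true_rd * 1000.0,
            k=k, comparator=comparator,
        ))
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def records_from_frame(corpus: pd.DataFrame) -> List[StudyRecord]:
    """Convert the tabular corpus layout into StudyRecord objects."""
    return [
        StudyRecord(
            review_id=str(r.review_id), ma_id=str(r.ma_id),
            study_id=str(r.study_id),
            events_t=int(r.events_t), n_t=int(r.n_t),
            events_c=int(r.events_c), n_c=int(r.n_c),
            comparator=str(r.comparator),
        )
        for r in corpus.itertuples(index=False)
    ]
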