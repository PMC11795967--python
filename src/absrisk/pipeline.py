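"""Corpus-scale evaluation: filter, pool, derive BR, measure CI expansion.

Mirrors the empirical-evaluation design: studies with zero events in both
arms are dropped, meta-analyses with fewer than three remaining studies are
dropped, one meta-analysis is kept per review (the one with the most
studies, first encountered on a tie).  Each surviving meta-analysis is
pooled on the log-RR scale, a baseline-risk surrogate with a Wilson CI is
taken from its control arms, and the risk-difference CI is computed twice —
substitution and microsimulation — to quantify how much the interval
expands once baseline-risk uncertainty is included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .absolute import compute_absolute_effect
from .distributions import RelativeEffect
from .pooling import (
    MetaAnalysis,
    StudyRecord,
    br_all_studies,
    br_largest_study,
    pool,
)

logger = logging.getLogger(__name__)

#: Baseline-risk strata used for the stratified expansion summary.  The
#: first bin is closed at 0; every other bin is left-open/right-closed.
BR_BIN_EDGES = [0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.20, 0.30, 1.0]
BR_BIN_LABELS = ["0-0.02", "0.02-0.04", "0.04-0.06", "0.06-0.08",
                 "0.08-0.10", "0.10-0.20", "0.20-0.30", ">0.30"]

CORPUS_COLUMNS = ["review_id", "ma_id", "study_id", "events_t", "n_t",
                  "events_c", "n_c", "comparator"]


@dataclass(frozen=True)
class PipelineConfig:
    """One configuration axis of the corpus evaluation."""

    model: str = "dl"               # common | dl | reml
    br_source: str = "largest"      # largest | all
    placebo_only: bool = False
    n_draws: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.br_source not in ("largest", "all"):
            raise ValueError("br_source must be 'largest' or 'all'")


@dataclass
class FilterReport:
    """Audit trail of the corpus filters."""

    n_rows_in: int = 0
    n_malformed: int = 0
    n_double_zero_studies: int = 0
    n_mas_in: int = 0
    n_mas_k_lt_3: int = 0
    n_mas_dropped_duplicate_review: int = 0
    n_mas_out: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def read_corpus_csv(path) -> pd.DataFrame:
    """Read a corpus CSV with the tabular study-record layout."""
    df = pd.read_csv(path)
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"corpus CSV is missing required columns: {missing}")
    return df[CORPUS_COLUMNS]


def _records_from_rows(df: pd.DataFrame, report: FilterReport) -> List[StudyRecord]:
    records = []
    for row in df.itertuples(index=False):
        try:
            records.append(StudyRecord(
                review_id=str(row.review_id), ma_id=str(row.ma_id),
                study_id=str(row.study_id),
                events_t=int(row.events_t), n_t=int(row.n_t),
                events_c=int(row.events_c), n_c=int(row.n_c),
                comparator=str(row.comparator),
            ))
        except (ValueError, TypeError) as exc:
            report.n_malformed += 1
            logger.warning("skipping malformed corpus row %r: %s", row, exc)
    return records


def filter_corpus(
    raw: Iterable[StudyRecord] | pd.DataFrame,
    report: Optional[FilterReport] = None,
) -> List[MetaAnalysis]:
    """Apply the corpus inclusion rules and group studies into meta-analyses.

    Order of operations matters: double-zero studies are removed first, the
    k >= 3 rule is applied to the counts that remain, and review-level
    deduplication (keep the meta-analysis with the largest k, first
    encountered on ties) runs last.
    """
    if report is None:
        report = FilterReport()
    if isinstance(raw, pd.DataFrame):
        report.n_rows_in = len(raw)
        records = _records_from_rows(raw, report)
    else:
        records = list(raw)
        report.n_rows_in = len(records)

    by_ma: Dict[str, List[StudyRecord]] = {}
    for rec in records:
        if rec.double_zero:
            report.n_double_zero_studies += 1
            continue
        by_ma.setdefault(rec.ma_id, []).append(rec)
    report.n_mas_in = len(by_ma)

    best_per_review: Dict[str, MetaAnalysis] = {}
    for ma_id, studies in by_ma.items():  # dict preserves input order
        if len(studies) < 3:
            report.n_mas_k_lt_3 += 1
            continue
        ma = MetaAnalysis(studies=tuple(studies))
        held = best_per_review.get(ma.review_id)
        if held is None:
            best_per_review[ma.review_id] = ma
        elif ma.k > held.k:
            best_per_review[ma.review_id] = ma
            report.n_mas_dropped_duplicate_review += 1
        else:
            report.n_mas_dropped_duplicate_review += 1
    out = list(best_per_review.values())
    report.n_mas_out = len(out)
    return out


def _child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-MA seed, independent of parallelisation order."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    corpus: Sequence[MetaAnalysis],
    config: PipelineConfig,
) -> Tuple[pd.DataFrame, dict]:
    """Evaluate every meta-analysis under one configuration.

    Returns the per-MA expansion records as a DataFrame plus a manifest with
    the configuration and skip accounting.  A failure in one meta-analysis
    (for example no usable studies after degeneracy checks) is logged and
    recorded, never fatal for the run.
    """
    rows = []
    skipped: List[dict] = []
    mas = list(corpus)
    if config.placebo_only:
        mas = [ma for ma in mas if ma.all_placebo]
    for idx, ma in enumerate(mas):
        try:
            pooled = pool(ma, model=config.model)
            br = br_largest_study(ma) if config.br_source == "largest" \
                else br_all_studies(ma)
            if not (0.0 < br.point < 1.0) and br.width > 0:
                # boundary control rate with a nonzero CI cannot seed a beta
                skipped.append(dict(ma_id=ma.ma_id,
                                    reason="baseline risk on [0,1] boundary"))
                continue
            lo, hi = pooled.rr_ci
            eff = RelativeEffect(measure="RR", point=pooled.rr, lower=lo, upper=hi)
            result = compute_absolute_effect(
                br, eff, n_draws=config.n_draws,
                seed=_child_seed(config.seed, idx),
            )
            rows.append(dict(
                ma_id=ma.ma_id, review_id=ma.review_id, k=ma.k,
                model=config.model, br_source=config.br_source,
                placebo_only=config.placebo_only,
                br_point=br.point, br_lower=br.lower, br_upper=br.upper,
                br_ci_width=br.width,
                rr=pooled.rr, rr_lower=lo, rr_upper=hi, tau2=pooled.tau2,
                rd_point_per1000=result.rd_point_per1000,
                subst_width_per1000=result.subst_width_per1000,
                micro_width_per1000=result.micro_width_per1000,
                expansion_per1000=result.expansion_per1000,
                truncated_frac=result.truncated_frac,
                seed=result.seed, n_draws=result.n_draws,
            ))
        except (ValueError, RuntimeError) as exc:
            logger.warning("meta-analysis %s skipped: %s", ma.ma_id, exc)
            skipped.append(dict(ma_id=ma.ma_id, reason=str(exc)))
    records = pd.DataFrame(rows)
    manifest = dict(
        config=dict(model=config.model, br_source=config.br_source,
                    placebo_only=config.placebo_only,
                    n_draws=config.n_draws, seed=config.seed),
        n_meta_analyses_in=len(mas),
        n_evaluated=len(rows),
        n_skipped=len(skipped),
        skipped=skipped,
    )
    return records, manifest


def summarize(records: pd.DataFrame) -> dict:
    """Overall and BR-stratified medians of the CI expansion.

    Returns overall median and IQR of the per-1,000 expansion, the per-bin
    medians over the baseline-risk strata (empty bins are reported as
    missing, not zero), and the scatter columns used for expansion-vs-BR
    plots.
    """
    if records.empty:
        raise ValueError("cannot summarize an empty record table")
    exp = records["expansion_per1000"].to_numpy(dtype=float)
    q25, q50, q75 = np.percentile(exp, [25, 50, 75])
    bins = pd.cut(records["br_point"], bins=BR_BIN_EDGES,
                  labels=BR_BIN_LABELS, include_lowest=True, right=True)
    by_bin = records.groupby(bins, observed=False)["expansion_per1000"]
    stratified = pd.DataFrame({
        "br_bin": BR_BIN_LABELS,
        "n": by_bin.size().reindex(BR_BIN_LABELS).fillna(0).astype(int).values,
        "median_expansion_per1000":
            by_bin.median().reindex(BR_BIN_LABELS).values,
    })
    scatter = records[["ma_id", "br_point", "br_ci_width",
                       "expansion_per1000"]].copy()
    return dict(
        n=len(records),
        median_expansion_per1000=float(q50),
        iqr_expansion_per1000=(float(q25), float(q75)),
        median_br_ci_width=float(records["br_ci_width"].median()),
        stratified=stratified,
        scatter=scatter,
    )
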