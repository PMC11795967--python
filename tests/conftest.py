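import numpy as np
import pytest

from absrisk import MetaAnalysis, StudyRecord


def make_study(review="R1", ma="R1.1", sid="s1", et=10, nt=100, ec=10, nc=100,
               comparator="other"):
    return StudyRecord(review_id=review, ma_id=ma, study_id=sid,
                       events_t=et, n_t=nt, events_c=ec, n_c=nc,
                       comparator=comparator)


@pytest.fixture
def toy_filter_corpus():
    """Four-review corpus exercising every inclusion rule.

    Review A: two meta-analyses (k=5 and k=3) -> only the k=5 one survives.
    Review B: k=3 but one double-zero study -> k drops to 2 -> excluded.
    Review C: k=4 with one double-zero -> k drops to 3 -> survives.
    Review D: two meta-analyses tied at k=3 -> first encountered survives.
    Expected surviving ma_ids: {A.1, C.1, D.1}.
    """
    rows = []
    for j in range(5):
        rows.append(make_study("A", "A.1", f"A1.s{j}", et=5 + j, ec=4))
    for j in range(3):
        rows.append(make_study("A", "A.2", f"A2.s{j}", et=6, ec=5))
    rows.append(make_study("B", "B.1", "B1.s0", et=3, ec=2))
    rows.append(make_study("B", "B.1", "B1.s1", et=0, ec=0))  # double zero
    rows.append(make_study("B", "B.1", "B1.s2", et=4, ec=6))
    for j in range(3):
        rows.append(make_study("C", "C.1", f"C1.s{j}", et=7, ec=5))
    rows.append(make_study("C", "C.1", "C1.s3", et=0, ec=0))  # double zero
    for j in range(3):
        rows.append(make_study("D", "D.1", f"D1.s{j}", et=8, ec=6))
    for j in range(3):
        rows.append(make_study("D", "D.2", f"D2.s{j}", et=9, ec=7))
    return rows


def random_meta_analysis(rng, k=None, ma="M", review="R"):
    """Small random meta-analysis with informative 2x2 counts."""
    k = k or int(rng.integers(3, 9))
    base_pc = float(rng.uniform(0.05, 0.5))
    studies = []
    for j in range(k):
        n = int(rng.integers(30, 400))
        pc = min(base_pc * float(rng.lognormal(0.0, 0.15)), 0.9)
        pt = min(pc * float(rng.lognormal(0.0, 0.4)), 0.95)
        ec = int(rng.binomial(n, pc))
        et = int(rng.binomial(n, pt))
        if ec == 0 and et == 0:
            ec = 1
        studies.append(make_study(review, ma, f"{ma}.s{j}",
                                  et=et, nt=n, ec=ec, nc=n))
    return MetaAnalysis(studies=tuple(studies))
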