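# absrisk

Absolute treatment effects from meta-analysis, with baseline-risk
uncertainty propagated into the confidence interval.

## The problem

Evidence summaries (GRADE summary-of-findings tables, Cochrane reviews)
present the absolute effect of a treatment as a risk difference (RD) per
1,000 patients, derived by applying a pooled relative effect — a relative
risk (RR), odds ratio (OR) or hazard ratio (HR) with its 95% CI — to a
baseline risk (BR), the event probability in untreated patients.  The
conventional *substitution* method applies the fixed BR to the bounds of
the relative effect's CI:

    RD = BR·(RR − 1),   CI(RD) = [BR·(RR_lo − 1), BR·(RR_hi − 1)]

(with the analogous transforms for OR and HR).  The BR, however, is itself
an estimate — often the control-arm event rate of a single study — and the
substitution interval silently treats it as known.  `absrisk` quantifies
what that omission hides: it propagates BR uncertainty by Monte-Carlo
microsimulation, sampling

    BR_i ~ Beta(α, β)          (moment-matched to the BR and its 95% CI)
    RR_i ~ Lognormal(μ, σ)     (μ = ln RR, σ from the CI on the log scale)

independently, computing RD_i per draw, and taking the empirical
2.5%/97.5% quantiles.  The headline metric is the **CI expansion**: the
microsimulation CI width minus the substitution CI width, per 1,000
patients.

The package is for systematic reviewers, guideline developers and
methodologists: it provides the single-calculation tool, plus the
machinery to study expansion at corpus scale — 2×2-count pooling
(common-effect, DerSimonian–Laird, REML on log-RR), BR surrogates from
control arms (largest study, or all studies pooled) with Wilson score
intervals, corpus inclusion rules, stratified summaries, and a synthetic
corpus generator with known ground truth.

## Worked example

```python
from absrisk import BaselineRisk, RelativeEffect, compute_absolute_effect

br  = BaselineRisk(point=0.20, lower=0.15, upper=0.25)
eff = RelativeEffect(measure="RR", point=1.5, lower=1.25, upper=1.80)
res = compute_absolute_effect(br, eff, n_draws=1_000_000, seed=7)
```

Running `python examples/single_effect.py` (the same computation) prints:

```
risk difference: 100 per 1,000
substitution CI:  50 to 160 per 1,000 (width 110)
microsim CI:      48 to 170 per 1,000 (width 122)
CI expansion:     12 per 1,000
```

The treatment raises the event rate from 200 to 300 per 1,000 at the point
estimates.  Ignoring BR uncertainty the CI spans 110 per 1,000; once the
BR's own CI (15%–25%) is propagated it spans 122 — an expansion of 12 per
1,000 that the substitution method never shows.  Per-1,000 figures are
rounded away from zero (to the next whole patient); raw probability-scale
values are kept on the result object.

The same calculation is available from the shell:

```bash
absrisk effect --measure rr --est 1.5 --lo 1.25 --hi 1.8 \
               --br 0.2 --br-lo 0.15 --br-hi 0.25 --seed 7
```

`examples/corpus_evaluation.py` runs the corpus-scale pipeline on a
synthetic collection (see also `absrisk simulate` and `absrisk corpus`),
and `examples/coverage_check.py` verifies the frequentist calibration of
the two intervals.  `docs/methods.md` describes the model, its
assumptions and the numerical choices.

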