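# Methods

## Model

A binary-outcome treatment effect is summarised by a relative effect
(RR, OR or HR) with a 95% CI and a baseline risk (BR) with a 95% CI (a
plain range is accepted and treated as a 95% CI — no separate calibration
for ranges is defined, and users should read it as such).  The absolute
effect is the risk difference

    RD = r(BR, E) − BR

where `r` maps control risk and relative effect to the treated risk:
`min(BR·E, 1)` for RR, `E·BR / (1 − BR + E·BR)` for OR, and
`1 − (1 − BR)^E` for HR.  All three are monotone increasing in `E`, which
keeps CI bounds ordered under either interval construction.

Two intervals for RD are reported:

* **Substitution** — the fixed BR applied to the effect CI bounds.  This
  is the convention in GRADE/Cochrane software; it ignores BR uncertainty.
* **Microsimulation** — BR and effect are drawn independently from
  distributions fitted to their summaries, RD is computed per draw, and
  the 2.5%/97.5% empirical quantiles (linear interpolation between order
  statistics) form the interval.  Quantile-definition differences are far
  below Monte-Carlo noise at the draw counts used.

The **expansion** is the microsimulation width minus the substitution
width, per 1,000 patients.  It is non-negative up to Monte-Carlo noise
whenever the effect CI is log-symmetric, and grows with BR imprecision.

## Distribution fitting

All CI ↔ SE conversions use the two-sided 95% normal quantile
z = 1.959964 (full precision internally, so quantile round-trips are
exact where the model permits).

* **Effect → lognormal:** μ = ln(point), σ = (ln upper − ln lower)/(2z).
  For a log-symmetric CI — the shape every inverse-variance pooled effect
  has — the fitted quantiles reproduce the input CI to machine precision.
  An asymmetric user-entered CI is accepted; only its width informs σ, so
  its quantiles are reproduced only approximately.  This matters for the
  degenerate-BR limit: the microsimulation converges to the substitution
  interval exactly when the effect CI is log-symmetric, and only then.
* **BR → beta:** moment matching by default — mean = point,
  variance = ((upper − lower)/(2z))².  A zero-width interval yields a
  point mass.  A point of exactly 0 or 1 with a nonzero width is rejected
  (a beta mean cannot sit on the boundary); corpus runs skip such
  meta-analyses and record the reason.  When the implied variance is
  infeasible (var ≥ p(1−p)), or on request (`method="quantile"`), the fit
  instead solves for the shapes whose 2.5%/97.5% quantiles equal the CI
  bounds (least-squares on log-quantiles, multi-start, residual < 1e-8;
  a zero lower bound is clamped to 1e-6 since every beta quantile is
  positive).
* Moment-fit round-trip accuracy: because a beta with an off-centre mean
  is skewed, its central 95% interval reproduces a symmetric input CI
  within 0.01 only for widths up to ~0.12 (which covers typical
  control-arm CIs) or near-symmetric risks; at wide, skewed corners
  (e.g. point 0.2, width 0.3) the deviation reaches ~0.024.  This is a
  property of the beta family, not of the solver; the quantile fit is the
  remedy when exact CI reproduction matters.

The point estimate of RD is the plug-in value at the input points, not
the Monte-Carlo median, so the headline RD is identical under both
approaches and only the interval changes; the MC median is retained on
the raw record.  Draws of BR and effect are independent — the marginals
are fitted separately and no dependence information is available in the
inputs.  RR draws that would push the treated risk above 1 are truncated
at 1 and their frequency is reported (`truncated_frac`).

Per-1,000 presentation rounds away from zero to the next whole patient,
applied identically to point and bounds; integer widths are differences
of rounded bounds.  A 1e-9 guard absorbs binary-float artefacts
(0.16·1000 must print 160).  Raw values are always retained — rounding is
cosmetic, not analytic.

## Pooling and BR surrogates

Corpus mode pools 2×2 counts on the log-RR scale with the delta-method
variance.  If any cell (events or non-events, either arm) is zero, 0.5 is
added to the event count and to the sample size of both arms; studies
with zero events in both arms are excluded by the corpus filter (they
carry no RR information), and the rare study in which *all* participants
in both arms had the event (zero variance after correction) is excluded
at pooling time with a logged warning.

Three pooling models: common-effect (inverse variance), DerSimonian–Laird
(moment estimator of τ², truncated at 0), and REML (standard fixed-point
iteration, |Δτ²| < 1e-8, max 200 iterations, DL fallback with a logged
warning on non-convergence).  CIs use normal quantiles.  With few studies
z-based random-effects intervals undercover (~0.89 at ~9 studies per
meta-analysis) — a well-known property of the estimator, visible in the
calibration tests, which therefore check near-nominal coverage in a
many-studies regime (~28 studies/MA) where the asymptotics hold.

BR surrogates come from control arms: the largest study (by total
randomized sample, ties to input order) or all studies pooled
(Σ events / Σ n, the GRADEPro default).  Both use the 95% Wilson score
interval, chosen for its behaviour near 0 and 1 where corpus risks
concentrate.  The aggregated source is almost always far more precise,
hence produces much less expansion — pooling control arms assumes BR
homogeneity across studies, which is exactly what it cannot verify.

## Corpus rules and summaries

Inclusion: drop double-zero studies; drop meta-analyses with fewer than
three remaining studies; keep one meta-analysis per review — the one with
the most studies, first encountered on ties.  Filter counts are reported
in a manifest so corpus arithmetic is auditable.  Per-meta-analysis
microsimulation uses 10⁶ draws by default in corpus mode (expansion
medians are integer-scale and insensitive beyond that; the
single-calculation default is 10⁷); a master seed spawns per-MA child
seeds deterministically, so results are independent of evaluation order.

Summaries: overall median and IQR of expansion; medians stratified by BR
bin — [0, 0.02], then left-open bins (0.02, 0.04], (0.04, 0.06],
(0.06, 0.08], (0.08, 0.10], (0.10, 0.20], (0.20, 0.30], (0.30, 1] (the
shared-endpoint convention must be fixed somewhere; this one is
documented rather than implicit) — and a scatter table of expansion
against BR and BR CI width.  Empty bins are reported as missing, never
zero.  The placebo-only sensitivity analysis restricts to meta-analyses
in which every study's comparator is placebo.

## Synthetic corpus

Real review collections of this kind are not redistributable, so the
generator fabricates them: per meta-analysis a true control risk
BR* ~ Beta(0.686, 1.905) — calibrated once so the corpus-level BR
distribution has median ≈ 0.20 and IQR ≈ (0.07, 0.41) — and a true
log-RR ~ Normal(0, 0.5); per study a log-RR ~ Normal(true, τ = 0.25),
a control risk jittered around BR* on the logit scale (SD 0.15), per-arm
sizes log-uniform on 20–2,000 (mean ≈ 430/arm, matching the
participants-per-study scale of large review collections), and binomial
event counts with the treated risk `min(pc·RR_study, 1)` — the same
truncation rule as the microsimulation.  Study counts per meta-analysis
are 3 + Poisson(5.6) (mean ≈ 8.6).  Comparator labels (placebo/other)
are assigned per meta-analysis so the placebo-only restriction selects
clean subsets.  A ground-truth table (true BR, RR, RD per MA) accompanies
every corpus.

What the generator does *not* emulate: the extreme right-skew of real
trial-size distributions (its largest-study BR CIs are therefore narrower
than real corpora show, and absolute expansion medians smaller — the
qualitative structure, not the magnitudes, is the testable content),
selective reporting, risk-of-bias correlations, non-portable
(BR-dependent) relative effects, and time-to-event outcomes.  Passing
tests demonstrate the machinery is correct and calibrated under the
stated data model, not that real corpora will show any particular
expansion magnitude.

## Calibration experiment

`coverage_experiment` checks frequentist coverage with the generating
model matched to the fitted one: true BR uniform on [0.15, 0.35], true RR
log-uniform on [1.2, 2.0] (effects away from the null, so BR error
materially enters the RD), BR estimate normal around the truth (truncated
so its CI stays inside (0,1) — binding on ~1% of replicates at the widest
SE), log-RR estimate normal.  Under this match the microsimulation
interval holds near-nominal coverage (~0.94) while the substitution
interval decays from ~0.96 toward ~0.88 as the BR SE grows from 0.005 to
0.04.  With near-null effects the substitution interval is essentially
immune to BR error — the coverage cost of ignoring BR uncertainty is a
property of effects of material size.

## Problem sizes

Defaults used by the test suite and the reproduction script: corpus runs
of 500 synthetic meta-analyses at 10⁵ draws each; coverage at 1,000
replicates × 2×10⁴ draws; the single-calculation regression fixture at
10⁷ draws.  These sizes put Monte-Carlo noise well below every asserted
tolerance (quantile SE < 10⁻³ at 10⁶ draws for the intervals involved).

## Known limitations

* OR and HR inputs must already be pooled; corpus mode pools RR only.
* Independence of BR and effect draws is an assumption, not a finding;
  when BR and effect are estimated from the same studies (as in the
  corpus evaluation's largest-study surrogate) it is knowingly violated.
* The substitution/microsimulation comparison inherits the portability
  assumption — that the relative effect is constant across baseline
  risks.  Where portability fails, conditional-effect models are needed;
  they are out of scope here.
* Asymmetric BR CIs contribute only their width to the moment fit; the
  asymmetry is discarded.
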