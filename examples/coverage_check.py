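"""Frequentist calibration of the substitution vs microsimulation CIs.

Simulates repeated estimation with known truth: true RD = BR*(RR - 1);
noisy BR and log-RR estimates feed both interval constructions.  The
microsimulation interval should cover the true RD at close to its nominal
95%; the substitution interval, which ignores BR noise, should undercover,
and more so the wider the BR interval.
"""

from absrisk import coverage_experiment

for br_se in (0.01, 0.03, 0.04):
    res = coverage_experiment(n_replicates=500, br_se=br_se,
                              n_draws=20_000, seed=5)
    width_pct = 2 * 1.96 * br_se * 100
    print(f"BR CI width ~{width_pct:4.1f}%:  microsim coverage "
          f"{res.micro_coverage:.3f}   substitution coverage "
          f"{res.subst_coverage:.3f}")
# Both intervals target 95%.  The substitution column should fall away
# from 0.95 as the BR interval widens; the microsim column should not.
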