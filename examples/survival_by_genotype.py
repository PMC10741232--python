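"""Kaplan-Meier curves of cases stratified by genotype, with a log-rank test.

Cases carry exponential event times whose rate triples with each minor
allele at one SNP; follow-up is capped at 60 months.  The log-rank test
should detect a per-allele hazard ratio of 3 at this sample size.
"""

import candigene as cg

blocks = [cg.HaplotypeBlock(("S",), ("C", "T"), (0.6, 0.4))]
panel, _ = cg.simulate_cohort(
    cg.SimulationConfig(blocks=blocks, n_cases=120, n_controls=95,
                        missing_rate=0.0, seed=8)
)
panel = cg.simulate_survival(
    panel, {"S": {0: 0.004, 1: 0.012, 2: 0.036}}, censor_time=60.0, seed=8
)

res = cg.survival_by_genotype(panel, "S", censor_cap=60.0)
for label, curve in res.curves.items():
    events = int(curve.n_events.sum())
    s60 = curve.survival_at(60.0)
    print(f"genotype {label}: n={curve.n}, {events} deaths, S(60) = {s60:.3f}")
if res.test:
    print(f"log-rank: chi2 {res.test.chi2:.3f} (df {res.test.df}), "
          f"p = {res.test.p:.4f}")
print("(lower S(60) for minor-allele carriers reflects the per-allele hazard)")
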