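"""Stepwise covariate search on a cohort with one real effect.

Simulates a cohort in which lymphodepleting-antibody conditioning cuts the
initial CD4 concentration by 80%, then runs the forward/backward
likelihood-ratio search over several candidate covariate-parameter pairs.
Only the real effect should survive.
"""

import cd4recon as c
from cd4recon.defaults import table_defaults

pop = table_defaults()
spec = c.CohortSpec(n_subjects=40, horizon_days=1095.0)
skeletons = c.sample_demographics(spec, seed=13)
schedules = c.sample_schedule(spec, len(skeletons), seed=13)
dataset, _ = c.simulate_dataset(
    pop, [c.CovariateEffect("alemtuzumab", "x0", -0.8)],
    skeletons, schedules, seed=13)

candidates = [("alemtuzumab", "x0"), ("gvhd", "x0"),
              ("leukemia", "lambda0"), ("fludarabine", "d0")]
result = c.scm(dataset, candidates, pop,
               settings=c.FitSettings(n_samples=100, max_iter=12, streak=2),
               eval_samples=400, seed=13)

print(result.step_table().to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}"))
print("\nfinal model:")
for e in result.effects:
    print(f"  {e.covariate} on {e.parameter}: {e.value:+.2f} "
          f"({(1 + e.value):.2f}x the typical value)")
# Forward steps need P < 0.01 to enter, backward steps P < 0.005 to stay;
# the simulated -0.80 effect on the initial concentration should be the
# lone survivor, estimated near its true size.
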