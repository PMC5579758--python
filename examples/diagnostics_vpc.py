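"""Goodness-of-fit diagnostics on a well-specified cohort.

With data simulated from the model itself, conditional weighted residuals
should be approximately standard normal and the observed percentiles should
sit inside their simulated visual-predictive-check bands.
"""

import numpy as np

import cd4recon as c
from cd4recon.defaults import table_defaults

pop = table_defaults()
spec = c.CohortSpec(n_subjects=50, horizon_days=1825.0)
skeletons = c.sample_demographics(spec, seed=17)
schedules = c.sample_schedule(spec, len(skeletons), seed=17)
dataset, _ = c.simulate_dataset(pop, [], skeletons, schedules, seed=17)

res = c.cwres(dataset, pop)
print(f"CWRES over {len(res)} observations: "
      f"mean {res.mean():+.3f}, variance {res.var():.3f}")

check = c.vpc(dataset, pop, n_replicates=300, seed=17)
table = check.to_frame()
inside = ((table["obs_median"] >= table["sim_lo_median"])
          & (table["obs_median"] <= table["sim_hi_median"]))
print(f"VPC: observed median inside its simulated band in "
      f"{inside.sum()}/{len(table)} time bins")
print(table[["bin_mid", "obs_median", "sim_lo_median", "sim_hi_median"]]
      .to_string(index=False, float_format=lambda v: f"{v:.0f}"))
# CWRES mean near 0 and variance near 1 say the residual model is right;
# the VPC bins compare observed percentiles with what the fitted model
# simulates at the same ages and sampling times.
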