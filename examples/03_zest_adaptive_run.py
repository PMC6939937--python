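"""One ZEST run with the recommended fixed assumed spread.

ZEST keeps a posterior over the threshold, places every trial at the
posterior mean, and reports the posterior mean as the estimate.  The
assumed spread is fixed at the population-optimal 1.5 log10 arcsec (4AFC)
even though this observer's true spread is 1 - the recommended operating
point.
"""

import numpy as np

from stereozest import (
    SimulatedObserver,
    TASK_4AFC,
    run_procedure,
    standard_procedure_config,
)

observer = SimulatedObserver.standard(TASK_4AFC)
config = standard_procedure_config("zest_fixed_sigma", TASK_4AFC,
                                   n_trials=30)
trace = run_procedure(observer, config, rng=np.random.default_rng(3))

print("trial  stimulus  response  estimate (log10 arcsec)")
for t in (1, 2, 3, 5, 10, 20, 30):
    print(f"{t:5d}  {trace.stimulus[t-1]:8.2f}  "
          f"{'correct' if trace.response[t-1] else 'wrong  '}  "
          f"{trace.theta_hat[t-1]:.3f}")
print(f"\nfinal estimate: {trace.final_theta:.3f} log10 arcsec "
      f"({10**trace.final_theta:.1f} arcsec); true threshold 1.500 "
      f"(31.6 arcsec)")
print("the estimate settles near the truth within ~20 trials; single runs "
      "carry ~0.1 log10 arcsec of sampling error.")
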