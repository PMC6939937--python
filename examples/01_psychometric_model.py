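"""The logistic psychometric function and its parameterizations.

Builds the standard 2AFC and 4AFC stereoacuity observers (threshold 1.5
log10 arcsec = 31.6 arcsec, spread 1 log10 arcsec) and prints the derived
slope, logistic location, and response probabilities.
"""

import numpy as np

from stereozest import (
    SimulatedObserver,
    TASK_2AFC,
    TASK_4AFC,
    lapse_from_lapse_star,
    response_probability,
    spread_to_slope,
)

print("spread -> slope (beta = 2 ln 39 / sigma):")
for sigma in (1.0, 1.5, 1.7):
    print(f"  sigma = {sigma:.1f} log10 arcsec  ->  "
          f"beta = {float(spread_to_slope(sigma)):.3f} /log10 arcsec")

for task in (TASK_2AFC, TASK_4AFC):
    obs = SimulatedObserver.standard(task)
    m = obs.model
    lam_star = 0.04
    print(f"\n{task.n_alternatives}AFC standard observer "
          f"(guess {m.guess}, lapse* {lam_star} -> lapse "
          f"{float(lapse_from_lapse_star(lam_star, m.guess)):.3f}):")
    print(f"  logistic location alpha = {m.location:.4f} log10 arcsec")
    for x in (0.5, 1.5, 2.5):
        print(f"  P(correct | disparity 10^{x:.1f} arcsec) = "
              f"{response_probability(x, m):.4f}")
    print(f"  at the threshold (1.5): "
          f"{response_probability(1.5, m):.4f}  (the criterion pi = 0.75)")
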