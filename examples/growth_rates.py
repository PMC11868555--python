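"""Estimate specific growth rates and compare two conditions.

mu(t) = d/dt log OD is estimated by a penalised spline on log OD (a
Gaussian-process smoother is available via SmootherConfig(method="gp")).
The exponential window, mid-log rate and lag are read off mu(t); groups
of rates are compared with a Welch t-test.
"""

import numpy as np

from maldiauxie import (
    GrowthCurve,
    compare_growth_rates,
    estimate_growth_rate,
    find_exponential_phase,
)

t = np.linspace(0.0, 10.0, 61)
curve = GrowthCurve("demo", t, 0.05 * np.exp(0.3 * t))
est = estimate_growth_rate(curve)
phase = find_exponential_phase(est, curve)
print(f"mid-log growth rate: {phase.mu_midlog:.3f} per hour (true 0.300)")
print(f"exponential window: {phase.window[0]:.1f}-{phase.window[1]:.1f} h, lag {phase.lag:.1f} h")

galactose = [0.28, 0.30, 0.29, 0.31, 0.30]
palatinose = [0.11, 0.13, 0.12, 0.12, 0.14]
res = compare_growth_rates(galactose, palatinose)
print(
    f"\ngalactose {res.mean_a:.3f} +/- {res.sd_a:.3f} vs "
    f"palatinose {res.mean_b:.3f} +/- {res.sd_b:.3f} per hour"
)
print(f"Welch t-test: t = {res.statistic:.2f}, p = {res.p_value:.2e}")
print("-> galactose supports significantly faster growth than palatinose")
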