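"""Carried-state hysteresis of the regulon along a K_T path.

K_T is swept up (galactose appearing) and back down (galactose exhausted),
with the regulon state carried between steps.  Inside the bistable band
the state depends on history: the OFF transition on the way up happens at
a strictly larger K_T than the ON transition on the way down.
"""

import numpy as np

from maldiauxie import DEFAULT_PARAMS, hysteresis_sweep

params = DEFAULT_PARAMS.replace(u_I_max=3.3)  # a ratio crossing the bistable band
res = hysteresis_sweep(params, np.linspace(1.1, 4.5, 60))

print(f"forward sweep (K_T rising):  switches OFF at K_T = {res.forward_off_KT:.2f}")
print(f"backward sweep (K_T falling): switches ON  at K_T = {res.backward_on_KT:.2f}")
print(f"hysteresis gap: {res.gap:.2f} in units of K_I")
print(
    "-> cells entering the bistable band from low palatinose stay OFF; "
    "only when K_T falls below the backward transition does the positive "
    "feedback re-engage"
)
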