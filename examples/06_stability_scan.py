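"""Stability of the coexistence equilibrium across antibiotic doses.

The daily map behaves like a logistic-style one-dimensional map: at high
dose the fixed point is approached monotonically, at intermediate dose
with damped oscillations, and at low dose it loses stability
(|lambda| > 1) and a small limit cycle appears.  Also shown: the time to
saturation is minimized at an interior resistant fraction.
"""

import numpy as np

from coopres import (ModelParams, PassageProtocol, oscillation_scan,
                     saturation_time_profile)

params = ModelParams()
protocol = PassageProtocol(D=100.0)

scan = oscillation_scan(params, protocol,
                        [200.0, 150.0, 100.0, 50.0, 25.0, 12.0, 6.0])
print(scan.to_string(index=False,
                     formatters={"f_star": "{:.4f}".format,
                                 "lam": "{:+.3f}".format,
                                 "amplitude": "{:.4f}".format}))
print("\nlambda falls through -1 as the dose drops: weaker selection for")
print("degraders makes the overshoot relatively stronger, destabilizing")
print("the equilibrium into a small persistent oscillation.")

prof = saturation_time_profile(params, PassageProtocol(A_i=100.0),
                               np.linspace(0.05, 1.0, 39))
print(f"\ntime-to-saturation at 100 ug/ml: fastest composition is "
      f"f = {prof.f_min:.3f} ({prof.t_min:.2f} h), vs {prof.t_sat[-1]:.2f} h "
      f"for a fully resistant culture —")
print("a mixed culture clears the drug fast AND grows fast afterwards.")
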