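"""A beta-lactamase inhibitor (tazobactam) selects FOR resistance.

Competitive inhibition raises the effective Michaelis constant to
K_eff = K_M (1 + I/K_I), slowing degradation: more resistant cells are
needed to clear the same dose, so the equilibrium resistant fraction
rises linearly with inhibitor concentration until the population is
fully resistant.
"""

import numpy as np

from coopres import (DesignPoint, ModelParams, NoiseModel, PassageProtocol,
                     effective_km, find_equilibrium, fit_ki,
                     gen_equilibrium_dataset)

params = ModelParams()
proto = PassageProtocol(A_i=20.0, D=100.0)

print("tazobactam (ng/ml)   K_eff (ug/ml)   equilibrium f*")
levels = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
for I in levels:
    eq = find_equilibrium(params, proto.replace(I=I))
    keff = effective_km(params.K_M, I, params.K_I)
    label = f"{eq.f_star:.3f}" if eq.interior else "1.000 (fully resistant)"
    print(f"   {I:8.0f}          {keff:7.1f}         {label}")

# recover K_I from a noiseless synthetic inhibitor series
design = [DesignPoint(A_i=20.0, I=i) for i in (0.0, 10.0, 20.0, 30.0, 40.0)]
obs = gen_equilibrium_dataset(params, design,
                              NoiseModel(n_events=None, day_effect_sd=0.0),
                              n_reps=1).observations
fit = fit_ki(obs, params)
print(f"\nK_I fitted from the equilibrium series: "
      f"{fit.estimates['K_I']:.2f} ng/ml (generator truth 4.60)")
print("the linear rise means a drug meant to defeat resistance enriches")
print("the resistant fraction whenever it fails to clear the population.")
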