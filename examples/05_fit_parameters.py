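"""Estimating (MIC, V_max, K_M) from noisy equilibrium fractions.

Generates a synthetic dose-by-dilution design with flow-cytometry
counting noise (1e4 events/sample, 3 replicates), then fits the three
degradation parameters by bounded Nelder-Mead least squares on the
equilibrium fractions.
"""

from coopres import (ModelParams, NoiseModel, fit_core,
                     gen_equilibrium_dataset, preset_design)

truth = ModelParams()
noise = NoiseModel(n_events=10_000, day_effect_sd=0.0, seed=42)
ds = gen_equilibrium_dataset(truth, preset_design("fig3"), noise, n_reps=3)
print(f"design: {len(ds.design)} dose x dilution conditions, "
      f"3 replicates, binomial counting noise")

res = fit_core(ds.observations, truth, n_starts=2, seed=42)
print(f"\nconverged: {res.converged}  (loss {res.loss:.3g}, "
      f"{res.n_evals} model evaluations)")
print("parameter        truth      estimate   rel. error")
for name, t in (("MIC (ug/ml)", 1.1), ("V_max (molec/CFU/s)", 1e6),
                ("K_M (ug/ml)", 6.7)):
    key = name.split()[0].replace("V_max", "V_max_raw")
    est = res.estimates[key]
    print(f"  {name:20s} {t:8.3g}  {est:9.4g}   {abs(est - t) / t:6.1%}")
print("\nV_max is pinned tightly by the overall scale of the equilibria;")
print("MIC and K_M sit on a shallower valley and carry more uncertainty.")
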