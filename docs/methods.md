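# Methods

## Model and assumptions

`coopres` models daily serial-dilution co-culture of a β-lactamase-
carrying (resistant) strain and an isogenic plasmid-free (sensitive)
strain in a β-lactam antibiotic.  Within a cycle the state is
`(N_R, N_S, A)`: resistant and sensitive densities (cells/µl) and the
extracellular antibiotic concentration (µg/ml).  Assumptions:

- **Sharp MIC threshold.**  Sensitive cells grow at `γ_S` for `A < MIC`
  and die at `γ_D` for `A ≥ MIC` (boundary inclusive, making the
  MIC-crossing time τ_b a strict down-crossing).  Sub-MIC partial growth
  inhibition is out of scope.  In bacteriostatic mode the above-MIC rate
  is 0 instead of `−γ_D`.
- **Resistant cells are unaffected by the drug** in the concentration
  range modelled and grow at `γ_R < γ_S`; the difference
  `γ_S − γ_R ≈ 0.165/h` is the cost of plasmid carriage.
- **Lag phase.**  For `t < t_lag` neither strain divides or dies, but
  degradation is active (cells are enzymatically competent on transfer).
- **Bulk Michaelis–Menten degradation.**
  `dA/dt = −V_max N_R A/(K_eff + A)` treats hydrolysis as a single
  well-mixed pool; `K_M` is phenomenological (hydrolysis is partly
  periplasmic) and no periplasmic partitioning is modelled.  A
  competitive inhibitor raises `K_eff = K_M (1 + I/K_I)`.
- **Saturation.**  Growth stops when `N_R + N_S` reaches `N_sat`
  (resource exhaustion).  Saturation is treated as absorbing for the
  growth terms: if sensitive death later reduces the total below
  `N_sat`, growth does not resume (this avoids event chattering and
  matches the resource-exhaustion interpretation).  Death and
  degradation continue after saturation; post-saturation degradation
  never affects the map because the antibiotic is reset at dilution.
- **Deterministic densities**, no extinction floor within a day.  A
  multi-day run flags extinction when the diluted inoculum falls below
  10⁻⁶ cells/µl.
- **Daily reset.**  Dilution divides both densities by `D` and resets
  the antibiotic to `A_i`; carry-over of residual antibiotic (≤ A/D,
  with A already near 0 at transfer) is neglected.

## Numerical scheme

Between events (lag end, MIC down-crossing, saturation, end of day) all
per-capita rates are constant, so `N_R`, `N_S` are exponentials and the
antibiotic obeys the separable implicit solution

    A + K_eff ln A = A₀ + K_eff ln A₀ − C(τ),

where `C(τ) = V_max N_R₀ (e^{r_R τ} − 1)/r_R` is the degradation
capacity spent.  The simulator therefore advances analytically from
event to event: the MIC-crossing time solves
`C(τ) = (A₀ − MIC) + K_eff ln(A₀/MIC)` in closed form, the saturation
time is a bracketed Brent root of a two-exponential, and `A(τ)` is a
bracketed Brent root of the implicit relation (absolute tolerance
10⁻¹³; events are located to ~10⁻⁸ h).  Final fractions are therefore
reproducible to ≳10 significant digits, which makes the central
finite-difference map derivative (step 10⁻⁴ in f) safe.  An independent
`scipy.integrate.solve_ivp` (LSODA, terminal events) integration of the
same equations serves as a cross-check oracle in the test suite; the
two routes agree to ≲10⁻⁷ in the final fraction.

Degenerate inputs: a day starting at or below the MIC has `τ_b = 0` by
convention and no death phase; `f = 0` and `f = 1` are absorbing
endpoints of the map, exactly.

## Fixed points, stability, scans

`find_equilibrium` scans a 200-point grid of `g(f) − f` for sign
changes and refines each bracket with Brent (|g(f*) − f*| < 10⁻⁶), then
classifies the fixed point by the multiplier λ = g′(f*): stable-monotone
(0 ≤ λ < 1), stable-oscillatory (−1 < λ < 0), unstable (|λ| ≥ 1).  When
no interior crossing exists the boundary attractor (0 or 1) is
reported.  A `quick` bracket-expansion path seeded by the closed-form
equilibrium (or the previous iterate) skips the scan inside fitting
loops; it is exact for maps with at most one interior crossing, which
holds throughout this model's regime.  The closed-form `f*` above is
not an approximation for this map — the equal-fold-growth and
antibiotic-budget conditions it encodes are exact at the fixed point
whenever the culture saturates daily and `A_i > MIC` — and the test
suite checks agreement to a conservative 10 % (observed: ~10⁻⁹
relative).

The oscillation scan reports, per dose, λ and the amplitude
(max − min) of the last 20 iterates of a 200-iterate orbit started at
`f* + 0.01`; orbit and tail lengths are fixed constants chosen for
desk-scale determinism.  With the default (printed, one-significant-
figure) parameters the equilibrium loses stability below roughly
A_i ≈ 70 µg/ml at D = 100, with period-2 amplitudes up to ≈0.2 — larger
than the experimentally reported invisibility of oscillations, a known
consequence of the rounded parameter set (the sharp-MIC model also
lacks the sub-MIC growth attenuation that softens the real map).

Parameter sensitivity: the closed form gives elasticities of `f*` of
−0.84 (t_lag), +0.12 (γ_D) and −0.17 (cost) at the reference condition
— all below 1 in magnitude, i.e. first-order insensitive; γ_D and the
cost also tolerate ±50 % finite changes with <10 % movement in `f*`,
while t_lag does not (f* ∝ 1/(t_lag + 0.19 h)).

## Data collapse

`collapse_check` pools interior equilibria across dilution factors and
fits `N_R,eq` vs `A_i` by least squares.  Boundary (fully-resistant)
conditions are excluded — they carry no scaling information — and the
dose span must be ≥7× (the canonical dose designs span 7.4–16× once
boundary conditions drop out).  Doses below `4 K_eff` flag the fit
out-of-regime (Michaelis–Menten curvature).  At the default parameters
the pooled max relative residual is ≈5.3 % for A_i ∈ [27, 200],
D ∈ [100, 800]: the exposure term varies ≈7.5 % across that dilution
range and the `K_eff ln A_i` term bends the low-dose end, so the
collapse is near- but not sub-5 %-linear.

## Fitting

The observables are equilibrium resistant fractions per condition
(dose, inhibitor, dilution, inoculum).  The objective is unweighted
least squares on fractions (1/se² weighting behind a flag); model
equilibria come from the numeric fixed-point finder, not the closed
form, to avoid approximation bias — the closed form only seeds the
optimizer.  `fit_core` estimates (MIC, V_max, K_M) by bounded
Nelder–Mead over linear MIC and log₁₀(V_max, K_M), with bounds
MIC ∈ [0.1, 10] µg/ml, V_max ∈ [10⁴, 10⁸] molecules/(CFU·s),
K_M ∈ [0.5, 100] µg/ml, K_I ∈ [0.1, 1000] ng/ml (about a decade around
the defaults, configurable).  Multi-start: the first start is a cheap
Nelder–Mead fit of the closed-form model, the rest are seeded uniform
draws in the (log-scaled) box; results are bit-reproducible given the
seed.  `fit_ki` is a 1-D bounded minimization on log₁₀ K_I with all
other parameters fixed; an estimate pinned at the upper bound (no
inhibitor effect in the data) is flagged non-converged.

Identifiability: the model obeys an exact symmetry — scaling `A_i`,
`MIC`, `K_M` by c while scaling `V_max N_i` by c leaves all equilibria
unchanged — so with doses fixed by the design the scale is pinned, but
(MIC, K_M) sit on a shallow ridge.  With counting noise alone
(10⁴ events, 3 replicates) the 10-seed median recovery errors are
≈4 % (MIC), ≈0.3 % (V_max), ≈2 % (K_M).  Adding the 5 % day effect on
`N_sat` inflates MIC/K_M errors to ≈50 %/33 % median while V_max stays
≈5 % — a real identifiability limit of equilibrium-only data under
multiplicative day-to-day variability, not an optimizer artifact.
K_I is recovered from a noiseless inhibitor series to <10⁻⁶ relative;
note that at 20 µg/ml ampicillin and 100× dilution the equilibrium
reaches 1 near I ≈ 50 ng/ml with the default parameters, so an
informative series must sample below that.

## Synthetic data

The generator emulates the study design: dose × dilution equilibrium
panels ("fig3" preset: {12.5, 25, 50, 100, 200} µg/ml ×
{100, 200, 400, 800}×; an approximation — the experimental condition
set is only shown graphically) and an inhibitor series at 20 µg/ml
("fig4" preset), 24-point difference maps, 3 replicates.  Noise has two
knobs: binomial flow-cytometry counting noise (default 10⁴ events per
sample, sd ≈ 0.005 at f = 0.5, matching "smaller than symbol size"
measurement error) and a multiplicative lognormal day effect on `N_sat`
(default sd 0.05) standing in for media/day variability — the simplest
single-knob replicate effect; growth-rate variability is not modelled.
Map datasets draw the realized inoculum fraction binomially around its
target (mixing error) and add counting noise to the final fraction.
Datasets are byte-reproducible from (design, truth, seed).  What
passing tests on such data do *not* show: robustness to sub-MIC growth
inhibition, enzyme release by lysis, density-dependent lag, or any
misspecification between model and organism — the generator is the
model itself.

## Problem sizes

Defaults keep everything desk-scale: one day integrates in ~0.1 ms, a
24-point map in ~2 ms, a full equilibrium scan in ~20 ms; a 3-parameter
fit takes seconds to tens of seconds depending on starts, and the
10-seed recovery study a couple of minutes.

## Known limitations

- The printed one-significant-figure parameters over-predict the
  reference equilibrium (~0.52 at 100 µg/ml, 100× vs the ~0.25
  observed experimentally); the model output scales as 1/V_max and
  1/N_sat, both printed to one digit, so this is expected and the
  experimental value is deliberately not hard-coded anywhere.
- Stochastic birth–death, spatial structure, persistence, and
  piperacillin-style enzyme release are out of scope.
- The sharp MIC threshold exaggerates the overshoot and the low-dose
  instability relative to a soft dose–response.
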