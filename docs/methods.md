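# Methods

## Model

The package implements a closed-cell model of IP₃-mediated Ca²⁺ signaling
forced by intracellular amyloid-β oligomers. Cytosolic Ca²⁺ exchanges only
with the ER: release through IP₃ receptors with Li–Rinzel open-probability
kinetics plus a passive leak, reuptake through a degree-2 Hill SERCA pump.
Closed-cell conservation `c + c_e/γ = c_t` eliminates ER Ca²⁺ as a dynamic
variable; buffering is implicit in the effective fluxes. IP₃ is produced
by active PLC with Ca²⁺ feedback (half-activation `K_PLC`) and removed by a
3-kinase/5-phosphatase pair whose rates define the turnover time
`τ_p = 1/(k_3k + k_5p)` and kinase fraction `η = k_3k/(k_3k + k_5p)`.
PLC is activated by G-protein, G-protein by the amyloid-β drive
`q(t) = a e^{−r(t−t₁)}·H(t−t₁)` through `ρ = V_R q/(K_R + q)`; the drive
also raises the maximal IP₃ production rate through a Hill-2 term
`V_Q q²/(K_Q² + q²)`.

Assumptions worth keeping in mind: plasma-membrane fluxes are neglected
(valid for oocytes bathed in Ca²⁺-free medium, questionable for neurons),
receptor populations are mean-field (no stochastic puffs or spatial waves),
and amyloid-β acts only at the two upstream sites above.

All computation is in seconds; every rate in the packaged parameter sets is
per second. The injection time defaults to t₁ = 2 s and the decay rate to
r = 0.001 s⁻¹ (responses persist for tens of minutes). The redundant
Heaviside factor in the drive's exponent is implemented as the equivalent
piecewise form. The SERCA symbols that appear twice in the source
formulation under different names are a single pair (V_s, K_s).

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with LSODA, rtol 1e−8 / atol
  1e−10 by default; the run is split at t₁ so the stepper never straddles
  the drive discontinuity. Ensemble work (UQ, PRCC, fitting) uses rtol
  1e−6 / atol 1e−9 — halving tolerances moves peak values by far less than
  the 0.1% refinement-stability bound asserted in the tests.
* Steady states: PLC and G have closed-form equilibria; the remaining
  (c, y, p) components are Newton-solved from a low-calcium seed
  (c, y, p) = (0.05, 0.5, 0.1), with a 5000 s relaxation fallback. An
  equilibrium is accepted at residual norm < 1e−10. Inside an oscillatory
  window the returned fixed point is the unstable one; `with_stability`
  reports the Jacobian verdict.
* Continuation: natural-parameter continuation with a damped Newton
  (backtracking line search), re-seeded from the previous grid point, with
  adaptive step halving between grid points — the subsystem equilibrium
  moves rapidly at small PLC and a single grid step can exceed Newton's
  basin. Roots with negative concentrations or y outside [0, 1] are
  rejected as non-physical.
* Jacobians: central finite differences with relative step 1e−7.
  Eigenvalues from `numpy.linalg.eigvals`.
* Hopf detection: sign changes of the real part of the leading
  complex-conjugate pair between grid points, refined by bisection to
  |Re| < 1e−8. A pair that collapses to real eigenvalues on one flank is
  treated as the stable side so the crossing is still bracketed;
  real-eigenvalue (saddle-node) crossings never register. On the Hopf
  normal form the detector recovers the bifurcation to 1e−8.
* Oscillation classification: attractor envelope width of c above 1e−3 µM
  after a 500 s transient, measured over a 500 s window.
* The two-Hopf "bubble" interval in K_s is obtained by bisecting K_s
  (tolerance 1e−4) on the predicate "exactly two Hopf points in the PLC
  scan window [10⁻⁵, 0.02]". The lower edge of that interval depends
  mildly on the window choice, because the upper Hopf point leaves the
  window before the bubble itself disappears; the upper edge is
  window-independent (the two Hopf points merge).

## Scaling and calibration

Scaled output `c_s = (c − c₀)/K_D` uses each run's own resting Ca²⁺ as c₀,
mirroring how Δf/f₀ recordings are referenced to their own baseline; the
indicator constants default to K_D = 0.3 µM, R_f = 100, f_m = 40 and
resting c₀ = 0.05 µM for fluorescence conversion. Samples at or beyond the
saturation level δf_max are rejected rather than clipped — a saturated
sample carries no concentration information.

The calibration objective is the sum of squared differences between the
scaled data and the model solution linearly interpolated at the data
times, summed over doses sharing one parameter set. The search is a random
sampling of an admissible space with an accept-if-better multiplicative
random walk (step scale 5% per parameter by default) around any draw below
an error threshold. The published per-parameter sampling distributions are
not recoverable, so the default space is a declared stand-in: log-uniform
over [baseline/5, baseline×5] for rates and affinities, uniform ±50% for
dimensionless fractions; fully overridable. No global-optimality claim is
made or needed.

A structural identifiability limit matters here: active G-protein stays
far from saturation (k_c(ρ+δ) ≪ k_d), so G* ≈ k_c(ρ+δ)/k_d and the PLC
equation sees only the product k_a·k_c. Dose–response traces therefore pin
down V_Q and k_a·k_c but not k_a and k_c separately; fits recover the
product to a few percent while the individual rates wander along the flat
valley. One acceptance test documents this by asserting individual
recovery and failing.

## Sensitivity analysis

PRCC: parameters are drawn independently and uniformly within ±pct of
baseline (the 26 kinetic constants; the fixed totals c_t, PLC_tot, G_tot
and the protocol constants are excluded). Each member is simulated from
the **baseline** zero-dose steady state — the ensemble represents kinetic
uncertainty about one prepared resting cell, so initial conditions are not
re-equilibrated per sample (re-equilibrating them folds the shift of the
resting state into the outcome and, for example, reverses the apparent
sign of the SERCA half-activation's effect on the peak). Outcomes are the
post-injection peak of c and its time. Ranks use average tie-handling;
each parameter's PRCC is the correlation of rank residuals after linear
regression on all other rank-transformed parameters, with significance
from the standard t-approximation (dof = n − 2 − 25). Independent uniform
sampling is used rather than Latin hypercube to match the stated design;
ensembles of n = 2000 are used where the original analysis used 100,000 —
the leading coefficients are stable to well under 0.05 between n = 2000
and n = 10,000.

UQ envelopes are the pointwise mean ± SD of the scaled trace over the same
kind of ensemble; failed integrations are dropped and counted, with more
than 5% failures an error.

## Synthetic data

The generator emulates the unavailable oocyte recordings: per-dose model
runs from the zero-dose steady state, scaled relative to rest, optionally
mapped to Δf/f₀ through the inverse indicator relation, with i.i.d.
additive Gaussian noise (the real recordings are 4–5-cell averages with no
stated noise model). Cadence 1 s, duration 600 s, matching the latency
scales under study. What passing tests show is therefore internal
consistency of the machinery under the model's own phenomenology — single
peaks growing and accelerating with dose, and the small-dose oscillatory
regimes in K_s — not robustness to imaging artifacts, cell-to-cell
heterogeneity or spatial wave structure, which the generator does not
emulate.

## Problem sizes

Default analysis sizes: 60–90-point grids for one-parameter Hopf scans,
K_s bisection to 1e−4, PRCC ensembles of n = 2000 per dose, 5-seed
calibration experiments with 30-draw searches and 120-step walks. These
were chosen as the smallest sizes at which the reported quantities are
stable (grid-halving and n-doubling change them by less than their
comparison tolerances).

## Known limitations

The multi-Hopf/limit-point structure near K_s ≈ 0.09 is excluded by
design, as are unstable periodic-orbit branches (the scan-then-bisect
approach tracks equilibria, not orbits, so subcritical branches are
invisible). Open-cell fluxes, RyR channels, membrane amyloid-β pores and
explicit buffering are out of scope. The zero-dose steady state is assumed
unique along the scanned branches; no claim is made outside the scanned
windows.
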