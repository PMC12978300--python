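# Methods

This note documents the models implemented in `naquad`, their assumptions,
the defaults that matter, and what the synthetic-data round trips do and do
not demonstrate.

## Three-site exchange model

Na⁺ counterions occupy three environments: bulk water (fraction `P_b`),
pentamer clusters (`X_c P_a`) and micelles (`X_m P_a`), with
`P_a + P_b = 1`, `X_m + X_c = 1`. Exchange among the sites is assumed fast
relative to relaxation, so observed rates, spectral densities and diffusion
coefficients are population-weighted means, and cross-correlations between
site motions are neglected. The micelle share of the aggregate-bound
surfactant is fixed by mass action, `X_m = (C − CMC)/C`, clamped to zero
below the CMC (default CMC 100 mM), and counterion partitioning between
micelles and clusters is taken proportional to the surfactant partitioning.

### Rate convention

Spin-3/2 relaxation in the single-exponential approximation is used
throughout (the experiments this models show monoexponential decays):

    R1 = (π²/10) χ² [2 J(ω₀) + 8 J(2ω₀)]
    R2 = (π²/10) χ² [3 J(0) + 5 J(ω₀) + 2 J(2ω₀)]
    J(ω) = 2τ / (1 + ω²τ²)

In extreme narrowing both rates reduce to `2π²χ²τ`. The effective coupling χ
absorbs the field-gradient asymmetry factor; with χ ≈ 117 kHz and the
sub-nanosecond correlation times of this system, the convention reproduces
the measured 24–86 s⁻¹ rate span of aqueous sodium decanoate, which is the
property the unit tests pin (R1 = R2 in extreme narrowing, exact χ² scaling,
affinity in `P_a`). Any overall constant absorbed into χ² would rescale the
fitted coupling but not the site fractions.

### Bulk site

No bulk correlation time is introduced. The bulk contribution enters as the
*measured* reference rates of dilute (10 mM) NaCl, which is equivalent to
back-computing the bulk spectral densities under the shared coupling
(`J1 = J2` near extreme narrowing, `J0` absorbing the small measured
R1/R2 difference). Defaults: (22.1, 22.8) s⁻¹ at 295 K and (30.4, 31.0) s⁻¹
at 283 K; the 275 K pair (38.2, 38.6 s⁻¹) is a two-point Arrhenius
extrapolation because no low-temperature bulk measurement exists. Datasets
may override any of these per temperature.

Temperatures are treated as verbatim labels. The defaults are keyed at
275/283/295 K, matching the cluster correlation times; no remapping between
nominal sample temperatures is attempted.

### Diffusion

`D_eff = P_a (X_m D_m + X_c D_c) + P_b D_b`. Aggregate coefficients are
Stokes–Einstein spheres, `kT/(6πηR)` with R = 27.0 Å (micelle) and 6.4 Å
(cluster), multiplied by the spherical-cell obstruction factor
`1/(1 + φ/2)`; the volume fraction is `φ = v̄ (C − CMC)₊` with a partial
molar volume default of 0.19 L/mol. Both the obstruction law and the φ rule
are module-level functions that can be swapped. The D₂O viscosity table
(2.18/1.65/1.18 mPa·s at 275/283/295 K) is a documented literature default;
only the 295 K value enters the fits because diffusion is measured at one
temperature. `D_b` defaults to the measured 10.7×10⁻¹⁰ m²/s.

### Micelle correlation time

Two parameterizations:

* **model 1**: `τ_m(T) = [A_m exp(−E_m/RT)]⁻¹`, two adjustable parameters;
* **model 2**: `τ_m(T) = R_m²/(6 D_s(T))` — diffusion on a spherical
  interface — with `D_s` fixed at the MD estimates
  (7.4/9.1/10.6 ×10⁻¹⁰ m²/s at 275/283/295 K) and the radius `R_m` shared
  across conditions.

Cluster correlation times are fixed inputs (0.42/0.34/0.29 ns at
275/283/295 K, MD-derived). Micelle residence can optionally shorten τ_m via
`τ_eff⁻¹ = τ_m⁻¹ + τ_res⁻¹`; with residence times of tens of nanoseconds the
correction is < 4% and it is off (τ_res = ∞) by default.

## Decay-curve reduction

Inversion recovery is fitted as `S∞(1 − 2f e^{−R1 t})` with the inversion
efficiency `f ∈ (0.5, 1]` free, because real 180° pulses are imperfect and
fixing `f = 1` biases R1 whenever the truth is not exactly on that boundary.
CPMG uses `S₀ e^{−R2 t}` with t = echo count × 0.49 ms; pulsed-gradient
stimulated echo uses the Stejskal–Tanner exponent
`b = γ²g²δ²(Δ − δ/3)`. Fits are unweighted least squares unless per-point σ
are provided; initial values come from a deterministic log-linear pre-fit,
so reductions are reproducible. Ramps attenuating the echo by less than 20%
raise a warning rather than an error, mirroring how an operator would treat
an under-attenuated acquisition.

## Trajectory estimators

`com_frame` re-expresses ion coordinates relative to the aggregate centre of
mass, unwrapping periodic images by minimum-image continuity first.
Aggregate rotation is deliberately **not** removed: for a small micelle the
relaxing motion is a mixture of reorientation and surface diffusion, and the
estimator measures that mixture. (A rotation-removal mode can be composed by
the caller but is not part of the default path.)

The MSD is time- and ion-averaged with averaging origins restricted to ions
within a boundary radius (default 35 Å) of the centre at the origin frame.
`D_s` is the slope/4 of a straight line fitted over lags up to the window
(default 100 ps) — the quasi-two-dimensional convention for interface
diffusion. The line carries a free intercept that absorbs uncorrelated
radial jitter; the window is deliberately short because at longer lags the
MSD of motion on a sphere saturates (the exact curve is
`2R²(1 − e^{−2Dt/R²})`), which biases the slope low by ~5% at 100 ps for
R = 14.5 Å. The window is a required, logged parameter, not a hidden choice.

Residence events are contiguous within-boundary intervals of at least a
minimum duration (default 100 ps); intervals truncated by the trajectory
edges are kept at their observed length and full-trajectory occupancies
count as single full-length events. This estimator is therefore biased low
relative to the true mean dwell when dwellings are comparable to the
trajectory length; `censored_mean_estimate` quantifies that bias by
simulating the dwell process alone (for a 12 ns dwell observed over 50 ns
the expected observed mean is ≈ 9.7 ns, a −20% censoring bias).

## Inference

Gaussian likelihood over all R1/R2/D rows with equal relative weighting:
the default σ is 2% of each observed value (overridable per row), consistent
with the percent-level uncertainties this class of measurement supports.
D rows participate only where measured (295 K). Priors are uniform:
A_m ∈ [10¹⁰, 10¹⁶] s⁻¹, E_m ∈ [5, 60] kJ/mol, P_a ∈ [0, 1],
R_m ∈ [5, 27] Å, and χ ∈ [99, 119] kHz (the literature window for sodium at
surfactant headgroups).

The sampler is a single componentwise Metropolis–Hastings chain
(numba-compiled), 2×10⁵ sweeps, 20% burn-in, proposal scales adapted every
500 sweeps during burn-in toward ~30% acceptance, started from a
deterministic bounded least-squares solution. Chains are bit-reproducible
under the mandatory seed. Summaries are posterior means with central 99%
quantile intervals; diagnostics are per-component acceptance rates
(warned outside [0.05, 0.7]), a split-chain R̂ over four segments (warned
above 1.1), and a boundary-proximity measure (distance of each posterior
mean to its prior bound in posterior standard deviations) that flags
posteriors piled on a bound — relevant for χ, whose 117 kHz sits about two
posterior standard deviations below the 119 kHz prior edge.

Known sampler limitation: A_m and E_m individually mix slowly (R̂ up to
~1.5) because the data constrain mainly the combination
`ln τ_m = E_m/RT − ln A_m`, a narrow curved ridge for componentwise
proposals. The physically meaningful combinations — τ_m(T), the site
fractions and χ — mix cleanly (R̂ ≈ 1.00).

## Synthetic data

The generators encode the study conditions: R1/R2 at {50, 300, 700} mM ×
{275, 283, 295} K plus D at 295 K, 2% relative Gaussian noise, reference
parameters A_m = 1.6×10¹³ s⁻¹, E_m = 20.9 kJ/mol or R_m = 14.5 Å, χ =
117 kHz, and bulk fractions 0.97/0.62/0.41 (0.97/0.63/0.43 for the
surface-diffusion parameterization). Decay curves use the experimental
acquisition grids (8 log-spaced recovery delays over 1 ms–0.5 s; echo counts
2–400 at 0.49 ms spacing; 16 gradient steps to 0.70 T/m) with a 0.95
inversion efficiency. Sphere-walk trajectories default to 50 ions × 5 ns at
1 ps spacing on a 14.5 Å sphere with D_s = 10.6×10⁻¹⁰ m²/s and a 1 Å RMS
radial tether (AR(1), 5 ps memory) — the tether model is a generator choice,
exposed as a parameter, since the simulations being emulated do not define
one. Exchange trajectories default to 100 ions × 50 ns with 12 ns mean
dwells, straddling the regime where censoring matters.

What passing round trips show: the estimators are unbiased and the fit
recovers its generating parameters *under the stated noise model and
acquisition design*. What they do not show: robustness to non-Gaussian or
correlated noise, aggregate polydispersity (a single micelle size and a
single cluster size are assumed), temperature-dependent cluster sizes,
multi-Lorentzian spectral densities, or force-field accuracy of the MD
inputs. Deviations of real data from the model (e.g. diffusion at high
concentration where larger aggregates exist) are outside what the synthetic
tests can certify.

## Numerical choices

* SI units internally; couplings in kHz, radii in Å and concentrations in mM
  only at interfaces, converted once.
* Degenerate inputs raise: non-positive times/rates, volume fractions ≥ 1,
  harmonics outside {0, 1, 2}, decay curves with < 4 points or
  non-increasing abscissae, stationary trajectories (no positive MSD slope).
* Ties/edge rules: `X_m` clamps to 0 at C ≤ CMC; residence runs touching the
  trajectory edges are kept; parameters proposed outside their prior bounds
  are rejected by setting the log-posterior to −∞ rather than raising.
* Problem sizes in the test suite (20-repetition recovery campaigns at
  2×10⁵ sweeps, 50-ion × 5 ns and 100-ion × 50 ns trajectories, 200-replicate
  decay Monte Carlo) were chosen so the statistical tolerances quoted above
  are resolvable with comfortable margins.
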