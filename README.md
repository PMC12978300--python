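# naquad

Quadrupolar ²³Na NMR relaxation modelling of counterion binding in aqueous
surfactant solutions.

## The problem

Ionic surfactants such as sodium decanoate release Na⁺ counterions that
distribute between free ions in bulk water, ions following small pre-micellar
clusters, and — above the critical micelle concentration (CMC) — ions bound to
micelles. How many counterions sit where controls the water activity of the
solution, which matters anywhere surfactant-laden droplets form (e.g.
atmospheric aerosols). ²³Na is a spin-3/2 nucleus whose relaxation is
dominated by the quadrupolar interaction, so measured relaxation and diffusion
rates carry quantitative information about the populations and mobility of
those sites. `naquad` turns tables of ²³Na *R*₁, *R*₂ and diffusion
coefficients into site fractions with credible intervals.

## The model

Exchange between the three sites is fast on the NMR timescale, so observed
rates are population-weighted. With the single-exponential spin-3/2
expressions

```
R1 = (π²/10) χ² [2 J(ω₀) + 8 J(2ω₀)]
R2 = (π²/10) χ² [3 J(0) + 5 J(ω₀) + 2 J(2ω₀)]
J(ω) = 2τ / (1 + ω²τ²)
```

the spectral densities are weighted over sites,

```
jₙ = P_a [X_m J(τ_m) + X_c J(τ_c)] + P_b j_b ,
```

where `P_a` (aggregate-bound fraction, `P_b = 1 − P_a`) and the micelle share
`X_m = (C − CMC)/C` do the bookkeeping, `τ_m`, `τ_c` are the micelle and
cluster correlation times, and the bulk term is anchored to rates measured on
dilute NaCl. Translational diffusion averages the same way,
`D_eff = P_a D_a + P_b D_b`, with Stokes–Einstein aggregate coefficients and a
geometric obstruction correction.

Two parameterizations of the micelle dynamics are fitted globally to the
(concentration × temperature) grid by componentwise Metropolis–Hastings MCMC:

* **model 1** — Arrhenius law `τ_m⁻¹ = A_m exp(−E_m/RT)` (6 free parameters);
* **model 2** — surface diffusion `τ_m = R_m²/(6 D_s(T))` with MD-derived
  `D_s(T)` fixed and one shared radius `R_m` (5 free parameters).

The MD estimators that parameterize the model are included: a COM-frame MSD
initial-slope estimate of the surface diffusion coefficient (`MSD = 4 D_s t`)
and a residence-time analysis of ions within a boundary radius of the
aggregate. Because no raw data are distributed, a synthetic-data module
generates every input — noisy relaxation grids, raw inversion-recovery /
CPMG / pulsed-field-gradient decay curves, and ion trajectories — from known
ground truth, so the whole pipeline is testable end to end.

## Worked example

Generate a synthetic dataset at the model-2 reference parameters
(R_m = 14.5 Å, χ = 117 kHz, 2% noise) and fit it back:

```python
from naquad.inference import MCMCSettings, mcmc_fit, site_fraction_table
from naquad.synthetic import default_model2_truth, generate_dataset

dataset = generate_dataset(default_model2_truth(seed=1))
posterior = mcmc_fit(dataset, 2, MCMCSettings(seed=1))

rm, (lo, hi) = posterior.means["R_m"], posterior.ci99["R_m"]
print(f"R_m = {rm * 1e10:.2f} A   99% CI [{lo * 1e10:.2f}, {hi * 1e10:.2f}]")
print(f"chi = {posterior.means['chi'] / 1e3:.1f} kHz")
print(posterior.tau_m_summary().round(3).to_string(index=False))
print(site_fraction_table(posterior, dataset)[
    ["concentration_mM", "micelle", "cluster", "bulk"]]
    .round(3).to_string(index=False))
```

prints (posterior means with 99% credible intervals)

```
R_m = 14.54 A   99% CI [13.82, 15.47]
chi = 116.6 kHz
 temperature_K  tau_m_ns  ci99_lo_ns  ci99_hi_ns
         275.0     0.476        0.43       0.539
         283.0     0.387        0.35       0.438
         295.0     0.333        0.30       0.376
 concentration_mM  micelle  cluster  bulk
             50.0    0.000    0.034 0.966
            300.0    0.250    0.125 0.625
            700.0    0.488    0.081 0.430
```

i.e. the fit recovers the generating radius and coupling, the sub-nanosecond
micelle correlation times decreasing with temperature, and the site
populations: ~97% of Na⁺ free below the CMC, a majority bound to micelles or
clusters at 700 mM. The same pipeline runs from the shell:

```sh
naquad simulate --model 2 --seed 1 --out run/
naquad fit run/dataset.csv --model 2 --seed 1 --out run/fit/
naquad report run/fit/posterior.json
```

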