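# nmrdfit

Multi-model analysis of ¹H spin-lattice relaxation dispersion (NMRD)
profiles of concentrated protein–water mixtures.

Fast-field-cycling NMR relaxometry measures the spin-lattice relaxation
rate R₁ as a function of the ¹H Larmor frequency ν (here 10 kHz–20 MHz),
probing water motion over time scales from ~10⁻⁸ to ~10⁻⁴ s in a single
experiment. In crowded protein solutions (the worked examples use
bovine serum albumin, BSA, at 20 and 40 mass-%), several relaxation
pathways overlap, and deciding the *mechanism* of water motion — free 3D
diffusion versus surface-confined 2D diffusion, with or without transient
adsorption — requires confronting the same dispersion curves with several
model families. `nmrdfit` implements that workflow for people who analyze
relaxometry data: model evaluation and decomposition, single-profile and
global multi-temperature fitting, model ranking, and a synthetic-data
generator that emulates the acquisition protocol.

## Models

All families share the dipolar skeleton R₁(ω) = C[J(ω) + 4J(2ω)] + A,
ω = 2πν, with A a frequency-independent term from very fast (bulk-like)
motion:

* **Lorentzian decomposition** — up to three exponential-correlation
  contributions Cᵏ[τₖ/(1+(ωτₖ)²) + 4τₖ/(1+(2ωτₖ)²)] labelled slow /
  intermediate / fast by their correlation time.
* **3D translational diffusion** (force-free hard spheres): the
  Hwang–Freed spectral density, an integral over the dimensionless
  variable u with weight u⁴/(81+9u²−2u⁴+u⁶), prefactor
  (3/2)(μ₀γ²ℏ/4π)²·N_H/d³, with τ_trans = d²/2D.
* **2D surface diffusion**: J₂D(ω) = τ_trans·ln[(1+(ωτ)²)/((τ/τ_res)²+(ωτ)²)],
  logarithmic in frequency; τ_res is the mean adsorption residence
  lifetime on the protein surface (τ_res → ∞ gives the long-residence
  limit).
* **¹H–¹⁴N quadrupole relaxation enhancement (QRE)**: six Lorentzians of
  width 1/τ_Q centred at the ¹⁴N quadrupole transition frequencies
  ν∓ = a_Q(1∓η/3), ν₀ = ν₊−ν₋, with orientation-dependent weights that
  sum to 2 — the frequency-specific R₁ peaks seen in frozen samples.

Fitting is weighted nonlinear least squares (weights 1/σ², or relative
1/R₁² when no uncertainties are recorded), multi-start from a seeded
Latin hypercube in log-parameter space, with box bounds. Global
temperature-series fits share amplitude constants across temperatures
while correlation times and offsets stay per-temperature, mirroring how
such results are tabulated.

## Worked example

```python
import nmrdfit as nf

# simulate one dispersion profile from a published parameter preset
# (residence-lifetime 2D-diffusion model, 20%wt BSA at 268 K)
prof = nf.simulate_profile(nf.SyntheticScenario(
    preset="table4_20wt_268K", noise_cv=0.02, seed=1))

spec, _, _, _ = nf.get_preset("table4_20wt_268K")
res = nf.fit_profile(prof, spec, n_starts=12, seed=1234)
print(res.summary())
```

```
Model family: surface2d_res (1 Lorentzian term(s))
Sample: BSA_20wt  T = 268 K  n = 60 points
Weighted SS = 43.4374   reduced chi2 = 0.804396   AICc = -5.79651
nfev = 963   gradient optimality = 0.000631   seed = 1234, best start #12/13
----------------------------------------------------------
parameter             estimate      std. error
----------------------------------------------------------
C1                  5.6565e+07       1.697e+07
tau1                5.6836e-09       1.112e-09
C_trans             8.0972e+06        2.44e+05
tau_trans           5.0927e-08       3.723e-09
tau_res_ratio           9.5944           1.303
A                       1.8552          0.2341
tau_res             4.8861e-07        3.37e-08
D_trans             7.1573e-13              --
```

The recovered translational correlation time τ_trans ≈ 5.09×10⁻⁸ s and
residence lifetime τ_res ≈ 4.89×10⁻⁷ s sit within one standard error of
the generating values (5.17×10⁻⁸ s and 4.81×10⁻⁷ s); `D_trans` is the
equivalent diffusion coefficient d²/(2τ_trans) with d = 2.7 Å, and the
reduced χ² near 1 confirms the noise model. `res.decompose()` returns the labelled
per-contribution curves; `nf.dominant_range` reports, per contribution,
the frequency interval where it exceeds all others — the width of that
interval (in decades) is the practical criterion for whether a diffusion
mechanism is identifiable from the data.

A command-line interface covers the same workflow
(`nmrdfit simulate | fit | decompose | arrhenius | ratio | convert`), e.g.

```bash
nmrdfit convert --tau 5.17e-8 --d-angstrom 2.7
# D_trans = 7.05e-13 m^2/s
```

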