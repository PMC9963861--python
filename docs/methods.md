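# Methods

## Relaxation models

¹H spin-lattice relaxation in water–protein mixtures is dominated by
magnetic dipole–dipole couplings whose fluctuations are driven by
molecular motion. Every model family in `nmrdfit` is a sum of
contributions of the form C·[J(ω) + 4J(2ω)] — the standard dipolar
combination of the spectral density at the Larmor frequency and at twice
the Larmor frequency — plus a frequency-independent offset A that
represents motion fast enough that ωτ ≪ 1 across the whole acquisition
window (bulk-like water). Public interfaces take ν in Hz; ω = 2πν is
applied at a single point in `models.py`.

**Lorentzian decomposition.** One to three exponential-correlation
contributions with amplitudes Cₖ (s⁻², conventionally quoted as Hz²) and
correlation times τₖ. The sum is permutation-symmetric, so components
are labelled slow / intermediate / fast by sorting τ descending; the
zero-frequency plateau is exactly Σ 5Cₖτₖ + A. This family is a
parametrization — it fixes time scales but says nothing about the
mechanism of motion.

**3D translational diffusion (force-free hard spheres).** Relative
translational diffusion of spin-bearing hard spheres with closest
approach d; the spectral density is

J₃D(ω) = (72/5) τ ∫₀^∞ u⁴/(81+9u²−2u⁴+u⁶) · 1/(u⁴+(ωτ)²) du,

τ_trans = d²/(2D), and the rate carries the prefactor
(3/2)(μ₀γ_H²ℏ/4π)²·N_H/d³, linear in the hydrogen number density N_H of
the diffusing fraction. The 72/5 normalization belongs to the standard
Hwang–Freed spectral density; dropping it makes the translational
contribution ~14× too small to ever dominate the dispersion and breaks
the consistency between this family's low-frequency plateau and the
Lorentzian decomposition of the same data, so it is included. The
kernel with u⁴ in the diffusive denominator is used throughout (the
form actually fitted in this family).

**2D surface diffusion.** Translational motion confined near the
macromolecular surface gives a logarithmic spectral density
J₂D(ω) = τ_trans ln[(1+(ωτ)²)/((τ/τ_res)²+(ωτ)²)]. The residence
lifetime τ_res — the mean time a water molecule stays adsorbed —
truncates the correlation function and caps the otherwise logarithmic
divergence at ω → 0; τ_res = ∞ selects the long-residence limit
τ ln(1+(ωτ)⁻²), which diverges at ω = 0 (a domain error). A finite
τ_res must exceed τ_trans.

**¹H–¹⁴N quadrupole relaxation enhancement.** When protein motion is
slow, the ¹⁴N level structure is set by the quadrupole coupling a_Q
(Hz) and asymmetry η; at fields where the ¹H Larmor frequency matches a
¹⁴N transition frequency — ν∓ = a_Q(1∓η/3), ν₀ = ν₊−ν₋ — magnetization
transfers to ¹⁴N and R₁ shows peaks. The rate is six Lorentzians of
width 1/τ_Q centred at ±ω₋, ±ω₊, ±ω₀ with orientation weights
(⅓+sin²θcos²φ), (⅓+sin²θsin²φ), (⅓+cos²θ) that sum to 2 identically.
Angles are stored in degrees at the interface. a_Q is treated as a
frequency (Hz), consistent with the ν∓ definitions. The dipolar
amplitude may be derived from the H–N distance as
C = (2/3)(μ₀γ_Hγ_Nℏ/4πr³)².

## Numerical evaluation of the FFHS integral

The reduced integral I(x) = ∫ u⁴/(81+9u²−2u⁴+u⁶)/(u⁴+x²) du depends on
ω and τ only through x = ωτ. The reference path is adaptive quadrature
(relative tolerance 10⁻⁸, upper cutoff 2×10³ chosen so the ~u⁻⁶ tail
contributes < 10⁻¹⁰ relative, non-convergence raised as an error, values
memoized on x). Because fitting evaluates I at thousands of
continuously varying x, the model-evaluation path interpolates a cubic
spline of log I versus log x through quadrature values at 2500 knots on
x ∈ [10⁻⁷, 10⁶] — covering any profile fit the parameter bounds allow —
with the √x leading correction below the table and direct quadrature
above it. The spline agrees with quadrature to ~5×10⁻¹² relative and
with an independent trapezoid-plus-Richardson oracle to better than
10⁻⁶ (tested). The low-frequency behaviour of J₃D is pinned numerically
by that oracle; no linear-in-ω small-x expansion is asserted (the true
leading correction is √ω-like).

## Fitting

Weighted least squares with weights 1/σ per point when uncertainties are
recorded, else 1/R₁ (relative weighting — profiles span ~2 decades in
R₁ and no instrument error bars are assumed). Scale parameters
(amplitudes, correlation times, N_H, A) are optimized as log₁₀ values in
box bounds (τ-type 10⁻¹²–10⁻⁴ s, C-type 10⁴–10¹⁰ s⁻², A 10⁻³–10³ s⁻¹,
N_H 10²⁴–10³⁰ m⁻³); η and the angles stay linear in [0,1] and [0°,90°].
The residence lifetime is parametrized internally as the ratio
τ_res/τ_trans (log₁₀, bounds ~[1.05, 10⁵]) so every iterate honours
τ_res > τ_trans; the reported parameter is τ_res with a delta-method
uncertainty.

Single-profile fits run `scipy.optimize.least_squares` (trf) from a
midpoint start, an optional user start, and a seeded Latin-hypercube of
16 further starts (the richer families are multi-modal); the best-cost
converged solution wins. A fit is refused when fewer than twice as many
points as free parameters are available. Uncertainties come from the
local quadratic approximation at the optimum — cov = (JᵀJ)⁻¹ · χ²_red in
transformed space, mapped back by the delta method; no bootstrap by
default. AICc (small-sample corrected) is attached for model ranking.

Global multi-temperature fits accept a sharing layout per parameter:
shared across temperatures, free per temperature, or fixed. The joint
objective is warm-started from independent per-profile fits; because a
single profile stuck in a swapped-component local minimum can poison a
naively assembled start, each per-profile result acts in turn as a
donor of the shared constants, the other profiles are re-fitted with
those constants fixed (pulling them into the donor's mode), and the
best joint refinement is kept. With a fully free layout the joint
objective is block-diagonal and reproduces the independent fits.

Model comparison ranks candidate fits of the same profile by AICc and
reports, separately, the width in decades of the interval where each
model's non-Lorentzian contribution strictly dominates the total — the
physically meaningful discriminator (a diffusion mechanism is only
identifiable when its contribution dominates over a broad frequency
range); the two are never merged into one score. Ties keep input order.

The quadrupole family can be fitted jointly (default) or staged:
background Lorentzians first on off-peak points (outside 1.8–4.2 MHz),
then the quadrupole block with the background fixed.

Arrhenius analysis regresses ln τ on 1/T (activation energy = slope × R);
profile ratios interpolate the second profile log-log onto the first
profile's grid over the overlap; magnetization decays are fitted as
M(t) = M_∞ + (M₀−M_∞)e^(−R₁t) with a log-linear initial guess, either
recovery direction, and a flag for data flat within noise.

## Synthetic data

The generator emulates the acquisition protocol of the study
conditions: 60 log-spaced frequencies from 10 kHz to 20 MHz, optionally
densified with 40 extra log-spaced points in the 1.8–3.3 MHz window
where the ¹⁴N peaks sit, and 32 log-spaced magnetization samples per
decay (span 5/R₁ by default). Parameter presets transcribe the
published fitted values for the 20%wt and 40%wt samples verbatim
(`data/table_presets.json`, guarded by a checksum test), including the
3D-diffusion rows whose printed (τ_trans, D_trans) pairs satisfy
τ = d²/D rather than the caption relation τ = d²/(2D) — the
transcription stores both numbers and flags the inconsistency instead
of silently correcting it; all conversions in the package use
D = d²/(2τ). d defaults to 2.7 Å, the diameter of a water molecule.

Noise is multiplicative Gaussian, R₁_obs = R₁_model(1+ε) with
ε ~ N(0, cv), truncated at ±5 cv, default cv = 0.02 (typical
relaxometer performance; no error bars are published), independent
across points and profiles; σ = cv·R₁_model is recorded so the fitting
weights match the noise model exactly. What the generator does *not*
emulate: freezing hysteresis, magnet-switching transients,
temperature-dependent sample composition, or any frequency-correlated
instrument drift — so passing recovery tests demonstrates estimator
correctness under the assumed noise model, not robustness to real
instrument systematics.

## Problem sizes and estimator choices

Recovery studies use 25 noisy replicates per single-profile target and
report the median (robust to occasional wrong-mode fits). For the
shared dipolar constant of the joint 4-temperature fit, a single series
yields a ~20–30% sampling spread: the Lorentzian correlation time of a
few ns puts its dispersion just beyond the 20 MHz acquisition ceiling,
leaving C_DD constrained only through a soft ridge against τ_c. The
reported quantity is therefore the median over 15 replicate series,
matching the median-over-replicates protocol of the other recovery
targets; the per-series curvature uncertainty (~23%) is reported by the
fit itself.

## Known limitations

* C_DD–τ_c degeneracy for components dispersing above the frequency
  window (above); joint multi-temperature data mitigate but do not
  remove it.
* The 2D-diffusion amplitude C_trans is phenomenological; no attempt is
  made to derive it from a surface hydration geometry.
* Uncertainties are local (curvature-based); strongly non-quadratic
  ridges (e.g. C_DD–τ_c) are better explored with the seeded bootstrap
  option or replicate simulations.
* No exchange-averaged two-site models, stretched spectral densities,
  cross-relaxation networks, or rotational/model-free spectral
  densities.
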