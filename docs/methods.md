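# Methods

`epogse` implements elliptically polarised oscillating-gradient spin-echo
(EP-OGSE) diffusion encoding end to end: waveform design and spectral
analysis, analytic restricted-diffusion spectra, Monte Carlo random walks in
impermeable ellipsoids, the powder-average signal model for dispersed
anisotropic compartments, and estimation of the frequency-dependent
microscopic tensor (D_L, D_T) and μFA.  This note records the model
assumptions, the numerical choices, and what the synthetic validations do
and do not establish.

## Sequence model

The idealised EP-OGSE train drives a cosine gradient of amplitude
G cos χ on the in-plane x̂ axis from t = 0 to T and a sine gradient of
amplitude G sin χ on ŷ from the initiation quarter period π/(2ω_m) to
T + π/(2ω_m).  χ = 0° is linear polarisation along x̂, 45° circular, 90°
linear along ŷ.  Two trains bracket an instantaneous refocusing pulse; the
second train runs with the opposed rotation sense (χ₂ = −χ₁), which cancels
the off-diagonal elements of the diffusion-weighting matrix

    B(ω_m) = ∫ F(t) Fᵀ(t) dt,     F(t) = γ ∫₀ᵗ g_eff dt′,

whose trace is the b-value; for the idealised trajectory
b = γ²G²T_total/(2ω_m²) with T_total the summed train duration.  Under the
Gaussian phase approximation (GPA) the attenuation exponent is
β = (1/2π)∫ F(ω)·D(ω)·Fᵀ(−ω) dω, and for a filter concentrated at ±ω_m,
β = Σ Bᵢⱼ(ω_m) Dᵢⱼ(ω_m).

Numerical choices:

- **Sampling.** dt must divide the quarter period (`commensurate_dt`), so
  every channel switch-on/off instant lies on a sample.  Jump samples
  interior to the sequence are stored at half value — the correct trapezoid
  representation of a step on a grid point — and a residual zeroth gradient
  moment (≲1e-5 of peak, from the jump discretisation) is removed as a
  uniform DC term, the numerical analogue of scanner moment trimming.  The
  refocusing condition then holds to machine accuracy.
- **Train length.** The experimental trains were nominally 25 ms;
  the builder snaps to the nearest integer number of *full* periods
  (50 Hz → 20 ms, 200/400 Hz → 25 ms).  Half-period multiples would refocus
  too, but an odd half-period count leaves a nonzero time-average in the
  ŷ dephasing (the refocusing pulse inverts only the x̂ channel), which
  leaks filter weight to ω ≈ 0; full periods keep both diagonal filters
  peaked at ±ω_m.  Within this layout the two diagonals share total weight
  (exactly — the b-value splits as cos²χ : sin²χ) and peak band, but their
  fringe and shoulder profiles differ, because the cosine and delayed-sine
  channels are different windowed carriers that interfere with opposite
  parity across the echo.
- **Spectra** are computed by FFT on the zero-padded time grid (default
  padding ×8); frequency-domain attenuation uses the same grid, making the
  Parseval identity β = trace(B)·D₀ for a flat spectrum hold to ~1e-11.
- **Units.** SI internally (s, m, T, rad/s); the only conversions to the
  reporting units (ms/μm², μm²/ms, Hz) go through `epogse.units`.
  γ = 2.675×10⁸ rad s⁻¹ T⁻¹.

## Restricted-diffusion spectra

The temporal diffusion spectrum of an impermeable sphere is the eigenmode
sum D(ω) = Σ B_k a_k ω²/(a_k² + ω²) with a_k = μ_k²D₀/R²,
B_k = 2(R/μ_k)²/(μ_k²−2), μ_k the roots of j₁′(μ) = 0 (μ₁ ≈ 2.0816).
2100 roots are precomputed by bracketed Brent iteration, which brings the
sum-rule residual |D₀ − ΣB_k a_k| below 1e-4·D₀; the high-ω free limit is
then exact to the same tolerance (at finite evaluation frequencies an
additional principled deficit ~1e-3 remains because the highest retained
modes are not yet saturated).  Ellipsoids use the per-axis sphere
approximation — D_L from a sphere of the long semi-axis, D_T from the
transverse one — which the simulations below show is good to ~2–5% over the
study's 1.5–4.5 μm range, with the largest error (+5% in D_L) for the 3:1
prolate shape.

## Powder model

For an axially symmetric compartment with axis (θ, φ) in the encoding
frame, β_x and β_y follow the projection formulas of the main text module
docstring, and the powder signal is the spherical mean of e^{−β_x−β_y}.
The spherical mean uses 64-node Gauss–Legendre in cos θ × 128-node periodic
trapezoid in φ (absolute error ≲1e-10 — verified against adaptive
`dblquad`).  The closed forms for χ = 0° and 45° share a single special
function Φ(z) = √π·erf(√z)/(2√z) continued through z = 0 by a Dawson branch
and a 3-term Taylor series for |z| < 1e-6, so prolate and oblate tensors
take one code path and the isotropic limit is smooth.
μFA = |D_L − D_T|/√(D_L² + 2D_T²).

The χ-modulation ratio E₄₅/E₀ equals 1 for isotropic compartments and is
< 1 for any anisotropic tensor (the powder signal is minimal at χ = 45°);
it depends on (b, D_T − D_L) only.

## Monte Carlo simulator

Walkers start uniformly in the ellipsoid (rejection sampling), take
fixed-length steps ℓ = √(6D₀Δt) in uniformly random directions, and reflect
specularly at the wall using the exact ray–ellipsoid intersection (up to 8
reflections per step, then truncation at the wall — truncations are counted
and are zero in all shipped configurations).  The default scaled-down
budget is 2×10⁴ walkers at Δt = 1.6 μs (the full-study step is 1 μs; 1.6 μs
keeps ℓ < min(semi-axis)/10 even for the smallest 1.5 μm axes, which
Δt = 2 μs would violate).  D₀ = 2 μm²/ms throughout, emulating free water
at room temperature.

Phase accrual exploits the linearity of φ = γ∫g·x dt: a single walk
accumulates the two channel moments A = ∫u(t)x dt and C = ∫v(t)x dt, and
every (direction, χ, b) signal is composed afterwards as
φ = γG[cos χ (Rê₁)·A + sin χ (Rê₂)·C] with the amplitude calibrated per
(χ, b) so trace(B) matches the target exactly.  All measurements of a
substrate therefore share one trajectory realisation — matching the study
design and strongly reducing variance in cross-route comparisons.  E is the
magnitude of the ensemble mean of e^{−iφ}; its standard error uses the
delta method along the mean direction.

A second, fully independent stepper (vectorised numpy, same specular rule)
cross-validates the compiled kernel; during development a third variant
(Gaussian steps, rejection boundary, direct per-step phase integration,
independent RNG) confirmed the signal tables to within sampling error.

**Channel-role symmetrisation.**  In the idealised spin-echo layout the
cosine (x̂) and delayed-sine (ŷ) channels have slightly different encoding
filters (their effective diffusivity on a sphere differs by 0.2–0.6% at
200–400 Hz).  Because the powder χ-modulation of a nearly isotropic
compartment is weak, the fit amplifies this asymmetry roughly 70-fold:
noiseless sphere signals would fit to a spurious anisotropy of
~0.3–0.4 μm²/ms.  Each simulated measurement is therefore the average of
the two mirrored channel-role assignments (cosine carrier on x̂ / sine on
ŷ, and the converse) — the simulation counterpart of the experimental
averaging over waveforms of the same eccentricity — which makes the
effective filter identical on both axes.  The averaging is free of cost in
the moment-based engine and is on by default.

The 24-direction scheme is generated deterministically by electrostatic
repulsion from a fixed seed and completed to proper rotations whose third
rows are the scheme points, so the sampled substrate orientations cover the
sphere approximately uniformly (minimum pairwise angle ≈ 42°).

## Estimation

Two routes per substrate and frequency:

1. **DTI route** (single aligned compartment): linear least squares of
   −ln E = b dᵀDd over the χ = 0° directions and b-values; eigenvalues are
   assigned using the known substrate axis (for blind data the largest
   eigenvalue is taken as D_L with an ambiguity warning).
2. **Powder route** (dispersed sample): direction-averaged signals fitted by
   nonlinear least squares of the powder model, initialised at the
   initial-slope mean diffusivity and bounded to [0, 3.5] μm²/ms.  The
   model has a shallow prolate/oblate local minimum, so the fit multi-starts
   from isotropic, prolate and oblate initialisations and keeps the lowest
   cost.

Standard errors follow SE = √(diag((JᵀJ)⁻¹σ_s)) with σ_s the residual
variance; μFA carries a first-order propagated error.  Noise propagation
adds zero-mean Gaussian noise of SD 1/SNR to every normalised point
(SNR 25, 100 repetitions by default; Rician noise is out of scope by
design, matching the study's choice) and refits per repetition.

**Identifiability limits.**  The sign of the microscopic anisotropy is
weakly encoded at moderate b: a prolate tensor has a near-degenerate
oblate alter ego (e.g. (0.81, 0.16) and (0, 0.56) μm²/ms differ by ~1% in
signal over the b ≤ 1.6 design), which is why the fit multi-starts, and
why a minority of SNR-25 noise repetitions still land on the wrong branch
— consistent with the reported bias of noisy estimates.  In the isotropic
limit the χ-modulation vanishes identically, so the (D_L, D_T) split of a
sphere carries no information at any affordable walker budget (a ±0.2%
signal fluctuation maps to a ±0.4 μm²/ms split); only the mean diffusivity
is meaningful there, and the validation suite compares spheres on MD.
Regression standard errors assume independent residuals; since all
directions of a substrate share one walker set, realisation-to-realisation
scatter of the estimates is ~2× the nominal SEs, and the cross-route
validation bands account for that plus the ~1% biases from the
24-direction discrete powder average and residual Gaussian-phase
deviations.

## What the validations establish — and what they do not

- The simulator and the analytic spheres agree at the level the encoding
  filter allows.  With ~25 ms trains the filter at 50 Hz contains only one
  to two oscillations, and the filter-weighted apparent diffusivity in the
  largest sphere sits ~9% below D(ω_m) — an intrinsic spectral-leakage
  property of short trains, not an engine error (the engine matches the
  exact filter-weighted GPA prediction to <1%).  Cross-route and
  vs-analytic agreement is therefore asserted at 200/400 Hz (5–10
  periods/train, leakage ≤3%), and the engine is separately validated
  against the filter-weighted prediction at 50 Hz.
- Mono-exponentiality: for the 1.5 μm sphere the simulated log-signals are
  linear in b to ≲0.02% up to b = 3.2 ms/μm².  For the 4.5 μm sphere the
  idealised waveform produces deviations of ~1.6% at b = 1.6 and ~4% at
  b = 3.2 (χ = 0°, 20 ms trains; ~1.1%/~2.6% with 30 ms trains), several
  times larger than the small printed reference bounds.  The deviation is
  b-calibration-invariant by construction, engine-independent (two
  independent implementations agree), and Δt-converged; it scales with the
  peak dephasing amplitude q = γG/ω_m, which practically implemented
  scanner waveforms can lower by up to √2 at matched b and duration.  The
  corresponding acceptance assertions are kept at the printed bounds and
  fail for the 4.5 μm sphere; every downstream analysis uses b ≤ 1.6 only,
  where the induced bias on fitted diffusivities is ≲1%.
- The synthetic world contains single, impermeable, axially symmetric
  compartments with one intrinsic diffusivity and no exchange, no
  extracellular space, no relaxation weighting and no imaging gradients.
  Green tests therefore establish internal consistency of encoding, theory
  and estimation in that world — not fidelity to any particular tissue.
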