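# epogse

Elliptically polarised oscillating-gradient spin-echo (EP-OGSE) diffusion
MRI: waveform design, temporal diffusion spectra, Monte Carlo simulation of
restricted diffusion, and estimation of the frequency-dependent microscopic
diffusion tensor.

## The problem

A diffusion-weighted MRI voxel averages over many microscopic tissue
compartments of different sizes, shapes and orientations, so conventional
diffusion tensor metrics confound microscopic anisotropy with orientational
dispersion, and time-dependent diffusion with compartment-size
heterogeneity.  EP-OGSE disentangles them in a single family of
measurements: two orthogonal oscillating gradients, a cosine on x̂ scaled by
cos χ and a quarter-period-delayed sine on ŷ scaled by sin χ, trace an
elliptical gradient trajectory whose ellipticity angle χ sweeps from linear
(0°) through circular (45°) polarisation.  The oscillation frequency ω_m
selects which part of the temporal diffusion spectrum D(ω) is probed, while
the χ-modulation of the direction-averaged (powder) signal is produced only
by microscopically anisotropic compartments — mixtures of isotropic
diffusivities leave it flat.

For an axially symmetric compartment with frequency-specific longitudinal
and transverse diffusivities D_L(ω_m), D_T(ω_m), the powder-average signal
has closed forms at linear and circular polarisation,

    E_lin  = e^{−b·D_T}            Φ(b (D_L − D_T)),
    E_circ = e^{−b (D_L+D_T)/2}    Φ(b (D_T − D_L)/2),
    Φ(z)   = √π · erf(√z) / (2√z)   (Dawson branch for z < 0),

and the microscopic fractional anisotropy is
μFA = |D_L − D_T| / √(D_L² + 2 D_T²) — insensitive to orientational
dispersion by construction.

The package covers the full pipeline: idealised EP-OGSE waveforms and their
dephasing spectra and B-matrices (`epogse.waveforms`), analytic sphere and
ellipsoid diffusion spectra (`epogse.spectra`), the powder model
(`epogse.powder`), a compiled random-walk simulator in impermeable
ellipsoids (`epogse.montecarlo`), powder/DTI estimation with error
propagation (`epogse.estimation`), and a CLI (`epogse`).

## Worked example

```python
import math, numpy as np
from epogse import EPOGSEParams, CompartmentTensor, b_matrix_ideal, mu_fa
from epogse.waveforms import commensurate_dt
from epogse.powder import modulation_ratio, powder_signal
from epogse.estimation import PowderDataset, fit_powder_model

# microscopic anisotropy of the reference tissue tensors (um^2/ms)
for name, (dl, dt) in {"gray matter 50 Hz": (0.73, 0.28),
                       "white matter 50 Hz": (0.81, 0.16)}.items():
    ct = CompartmentTensor(dl, dt)
    print(f"{name}: muFA = {mu_fa(ct):.3f}, "
          f"E45/E0 at b=0.8 = {float(modulation_ratio(ct, 0.8)):.4f}")

# diffusion weighting available from two 40 ms trains at 100 Hz
w = 2 * math.pi * 100
for G in (0.08, 0.30):
    p = EPOGSEParams(G_max=G, omega_m=w, chi_deg=45, T_train=0.04,
                     dt=commensurate_dt(w, 5e-5))
    print(f"G = {G*1e3:.0f} mT/m: b = {b_matrix_ideal(p, n_trains=2).b_ms_um2:.3f} ms/um^2")

# recover the tensor from a powder chi-sweep (b = 0.8, 19 steps 0-90 deg)
chis = np.linspace(0, 90, 19)
E = np.array([powder_signal(CompartmentTensor(0.81, 0.16), 0.8, c) for c in chis])
fit = fit_powder_model(PowderDataset(b=np.full(19, 0.8), chi_deg=chis, E=E))
print(f"fit: D_L = {fit.D_L:.3f}, D_T = {fit.D_T:.3f}, muFA = {fit.mu_fa:.3f}")
```

prints

```
gray matter 50 Hz: muFA = 0.542, E45/E0 at b=0.8 = 0.9958
white matter 50 Hz: muFA = 0.773, E45/E0 at b=0.8 = 0.9915
G = 80 mT/m: b = 0.046 ms/um^2
G = 300 mT/m: b = 0.653 ms/um^2
fit: D_L = 0.810, D_T = 0.160, muFA = 0.773
```

The μFA values say gray matter at 50 Hz is moderately anisotropic at the
microscopic scale while white matter is strongly so; the modulation ratios
are the corresponding depths of the χ-modulation at b = 0.8 ms/μm² (a
~0.4–0.9% signal dip at circular polarisation).  The b-values show that a
clinical 80 mT/m system reaches only b ≈ 0.05 ms/μm² at 100 Hz whereas a
300 mT/m research system reaches b ≈ 0.65, approaching the 0.8 used
ex vivo.  The fit recovers the generating tensor from the χ-sweep alone.

The same estimation applies to simulated dispersed substrates:

```sh
epogse simulate --radii 2.5 --freqs-hz 200 --walkers 20000 --out runs/sphere.tsv
epogse fit runs/sphere.tsv --out runs/sphere_fit.json
```

See `docs/methods.md` for the model assumptions, numerical choices and the
known limits of validity (encoding-filter leakage at low oscillation
counts, Gaussian-phase breakdown for the largest restrictions at b = 3.2).

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline numbers from
scratch: the two 50 Hz tissue μFA values from the reported diffusivities,
and the maximum relative deviation of simulated sphere log-signals from
mono-exponentiality at b = 3.2 ms/μm² (Monte Carlo at a scaled-down walker
budget, ~4 minutes).  Run from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
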