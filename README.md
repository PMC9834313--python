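# irispec

Reference-free reconstruction of the complex refractive index
`η(ν̃) = n(ν̃) + i k(ν̃)` of homogeneous and two-layer dielectric
microspheres from their infrared extinction-efficiency spectra
`Q_ext(ν̃)` — or from raw apparent-absorbance spectra, with simultaneous
correction of baseline shift, tilt, curvature and scaling distortions and
optional recovery of the sphere and core radii.

## Who this is for

Single-cell and microparticle IR spectroscopists: when the particle size is
comparable to the wavelength, Mie scattering dominates the measured spectrum
and buries the chemistry.  Standard scatter-correction methods need a
reference spectrum or a numerical Kramers–Kronig transform over a spectral
window that is never wide enough.  This package needs neither.

## The model

The imaginary index of each voxel (whole sphere, or core and shell) is a sum
of *M* anti-symmetrized Lorentzians,

```
k_j(ν̃) = Σ_m [ h_m / (1 + ((ν̃ − ν̃_m)/Γ_m)²) − h_m / (1 + ((ν̃ + ν̃_m)/Γ_m)²) ],
```

odd in ν̃ as causality requires.  Its Kramers–Kronig partner is closed-form:

```
n_j(ν̃) = n_∞ − Σ_m [ h_m u_m⁻/(1 + (u_m⁻)²) − h_m u_m⁺/(1 + (u_m⁺)²) ],   u_m^± = (ν̃ ± ν̃_m)/Γ_m,
```

so every candidate index is Kramers–Kronig-consistent by construction.  A
Lorenz–Mie forward model (Aden–Kerker for two layers) maps the candidate
index and geometry to `Q_ext^(model)`, and a bounded multi-start
trust-region least-squares fit minimizes

```
S = Σ_l [ Q_ext^(model)(ν̃_l) − Q_ext^(given)(ν̃_l) ]²
```

over band centers ν̃_m, heights h_m, widths Γ_m, the baseline index n_∞ per
voxel, and optionally the distortion parameters and radii.  Reconstructions
are scored against a reference index with R² = 1 − S_res/S_tot, separately
for the real and imaginary parts.

## Worked example

Simulate a noisy extinction spectrum of a 10 µm sphere with three absorption
bands, then reconstruct the index from that spectrum alone:

```python
import numpy as np
from irispec import (FitConfig, SphereGeometry, WavenumberGrid, fit,
                     make_observation, random_dispersion)

truth = random_dispersion(n_bands=3, seed=7)
geometry = SphereGeometry(outer_radius=10.0)          # micrometres
grid = WavenumberGrid.regular(500.0, 4000.0, 8.0)     # cm^-1
bundle = make_observation(truth, geometry, grid, noise_fraction=0.02, seed=7)

config = FitConfig(bands_per_voxel=3, seed=0, n_starts=3)
results = fit(bundle.observed, geometry, config,
              reference=[truth.complex_index(grid)])
print(results.summary())
```

prints

```
Refractive-index reconstruction
================================================
objective S          3.743780e-01
converged            True
starts (best #2)    1.041e+01, 1.041e+01, 3.744e-01
outer radius [um]    10.0000
-- voxel: sphere (n_inf = 1.5003)
   center[cm-1]   height     width[cm-1]
       615.29    0.18785       22.53
      2978.54    0.27107       25.34
      3070.81    0.23400       53.72
R^2 (sphere)        real=0.9623 imag=0.9602
```

The generating truth had bands at (615.8, 2991.2, 3063.7) cm⁻¹ with heights
(0.195, 0.271, 0.237) and `n_∞ = 1.5`: from a single noisy real-valued
`Q_ext` curve the fit recovered both parts of the complex index to
R² ≈ 0.96, the band centers to a few cm⁻¹, and the baseline index to 3·10⁻⁴.
Two of the three random starts landed in a secondary minimum (S ≈ 10.4); the
third found the global one — that is what the multi-start is for.

The same machinery handles two-layer spheres (`fit_layered`, one dispersion
per voxel through the coated-sphere forward model), free radii
(`fit_outer_radius` / `fit_core_radius`), and raw absorbance input with
distortion unfolding (`fit_distortion=True`, `g_ratio=...`).

A command-line interface wraps the library for shell use:

```
irispec simulate --seed 1 --out bundle/
irispec reconstruct bundle/observed.csv --kind qext --outer-radius 10 \
        --bands 6 --out run/
irispec score ref_nk.csv --reconstruction run/reconstructed_index_sphere.csv
```

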