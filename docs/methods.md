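# Methods

## The inverse problem

A micrometre-sized dielectric sphere illuminated by mid-IR radiation removes
energy from the forward beam by absorption *and* scattering.  A single-element
detector therefore reports an apparent absorbance that mixes chemistry
(absorption bands) with morphology (Mie interference and resonance
structure).  The measured quantity, after the G/g conversion
(`spectra_io.absorbance_to_qext`), is the extinction efficiency
`Q_ext(v)`; the quantity of scientific interest is the complex refractive
index `eta(v) = n(v) + i k(v)` inside the particle — per layer, for a
stratified particle.  Recovering `eta` from `Q_ext` is an inverse scattering
problem: one real curve in, two (or four) real curves out, made solvable by a
physically constrained parameterization.

## Dispersion model

The imaginary index of each voxel (the homogeneous sphere, or core and shell)
is a sum of M anti-symmetrized Lorentzians,

    k_j(v) = sum_m [ h_m / (1 + ((v - v_m)/G_m)^2) - h_m / (1 + ((v + v_m)/G_m)^2) ],

which is odd in `v` as causality requires, and whose Kramers-Kronig partner
is analytic:

    n_j(v) = n_inf - sum_m [ h_m u_m^- / (1 + (u_m^-)^2) - h_m u_m^+ / (1 + (u_m^+)^2) ],

`u_m^± = (v ± v_m)/G_m`.  No numerical Hilbert transform is ever needed — the
decisive practical advantage, since measured windows (~500-4000 cm^-1) are
far too narrow for an accurate numerical transform.  `n_inf >= 1` absorbs the
real-index contribution of resonances outside the window.  Heights are
constrained non-negative (passive media); the constraint can be lifted by
passing explicit `height_bounds`.  A numerical principal-value transform
(`kk_numeric_transform`) exists purely as a test oracle for the closed form.

## Forward model

`mie_forward` evaluates the Lorenz-Mie partial-wave series for homogeneous
spheres and the Aden-Kerker solution for two concentric layers, in the
`m = n + ik, k >= 0` absorbing convention with a vacuum/air host.  Numerical
choices:

- series truncated at the Wiscombe order `N = ceil(x + 4 x^(1/3) + 2)`,
  clamped to `N >= 3`, per wavenumber point;
- logarithmic derivatives `D_n = psi_n'/psi_n` by downward recurrence seeded
  at `max(N, |z|) + 15` — the start order must exceed `|z|` or the recurrence
  has not converged onto the true ratio when it reaches the orders in use;
- `psi_n` from the `D_n` ratio chain anchored at `psi_0 = sin z` *or*
  `psi_1`, whichever is larger in magnitude.  Anchoring at `psi_0` alone
  loses all relative accuracy when the size parameter sits near a multiple of
  pi — which happens at exact grid endpoints for round radii (x = pi at
  500 cm^-1 for a 10 um sphere);
- the irregular `chi_n` by upward recurrence (its stable direction);
- coated-sphere shell algebra in ratio-stabilized form: the admixture of the
  irregular shell solution enters only through products such as
  `(psi_n(m2 x) chi_n(m2 y)) / (psi_n(m2 y) chi_n(m2 x))` whose exponential
  factors cancel for absorbing shells, so nothing overflows at mid-IR size
  parameters;
- coated efficiencies are referenced to the **outer** geometric cross
  section, which is what makes them comparable to the measured `Q_ext`.

The series run in JIT-compiled scalar kernels (`_mie_kernels`); a fit
evaluates the forward model tens of thousands of times, and the kernel
evaluation cost sets the total runtime.  Correctness is pinned by tests against an independent oracle
(direct series from scipy's AMOS complex Bessel functions), the Rayleigh
closed form, the extinction paradox, energy conservation
`Q_ext = Q_sca + Q_abs`, and the three degeneracy limits of the coated model.

## Estimation

`reconstruct.RefractiveIndexModel` minimizes the sum of squared residuals

    S = sum_l [ Q_ext_model(v_l) - Q_ext_given(v_l) ]^2

over all band parameters, `n_inf` per voxel, optionally the four distortion
parameters and the sphere radii, using bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF, finite-difference Jacobian,
`x_scale='jac'`, step/residual tolerances 1e-10, 400 evaluations per solve).
When the data are apparent absorbance, the *model* is converted through the
G/g relation and the distortion is applied to the model's absorbance before
comparison — algebraically equivalent to unfolding the data, but it keeps the
data untouched.

Design choices where the problem left the design open:

- **Initialization.**  Band centers start equi-spaced at mid-bin positions
  (`v_min + (m - 1/2) span / M`): wherever a true band lies, some start band
  is nearby.  Heights start uniform in [0.001, 0.1], widths in [5, 50] cm^-1,
  `n_inf` at 1.5, distortion at identity, radii at the user's geometry.
- **Multi-start.**  `n_starts = 3` seeded starts (independent height/width
  draws); best final S wins, ties to the lowest start index.
- **Basin hops.**  After each start converges, up to 4 seeded perturbations
  are tried and kept when they lower S: plain parameter jitter; splitting the
  strongest band while recycling the weakest (escapes a merged close pair
  plus a band wasted on noise); and, for layered spheres, exchanging a band
  between core and shell (escapes wrong-voxel assignment).  Hops are skipped
  once S reaches the numerical floor of the data.  These moves target the
  empirically observed failure modes of the plain solver.
- **Free radii.**  S is violently multi-modal in a radius (the fringe phase
  shifts with it), and the band parameters partially compensate for a wrong
  radius, so neither a plain radius sweep at the random initial bands (flat,
  uninformative landscape) nor a local joint fit (locks onto the wrong
  fringe) finds the right basin.  Each start therefore minimizes a coarse
  *profile* objective: a short (15-iteration) band fit at each of 13 frozen
  candidate radii across the bounds, refined locally around the winner, then
  a deep band fit at the chosen radius, then a joint refinement with the
  radius released.
- **Bounds.**  Centers are confined to the measured window: a band outside it
  is seen only through its dispersive tail and degenerates into a nuisance
  mode nearly collinear with `n_inf` (in early experiments such bands pegged
  their height and width bounds while a real band went missing).  Heights
  [0, 1], widths [2, 400] cm^-1, `n_inf` [1, 2], radii ±50% of the start
  unless overridden.
- **Identifiability guard.**  Fits require 10 data points per parameter
  (`min_points_per_parameter`, settable to 0).  G/g and the fitted scale `s`
  are not jointly identifiable; G/g must be supplied and `s` absorbs its
  error.
- **Band count.**  M is user-set; there is no automatic model selection.

Reconstructions are scored against a reference index with the coefficient of
determination, separately for the real and imaginary parts
(`quality.r_squared`): `R^2 = 1 - S_res/S_tot`, with `S_tot` about the scalar
mean of the reference part.  `R^2` is not clamped and is undefined for a
constant reference part.

## Synthetic data

`synthetic_data` emulates the study conditions end to end: multi-band random
dispersions (defaults: 6 bands, centers 600-3600 cm^-1 with pairwise gaps of
at least 1.5x the mean width, heights 0.02-0.3, widths 10-60 cm^-1,
`n_inf = 1.5`), spheres of 10 um radius (core 8 um in the layered case), a
500-4000 cm^-1 grid at 2 cm^-1 spacing (4 cm^-1 in the recovery experiments,
which keeps a full study under ten minutes on one core while leaving ~35
points per parameter), bounded uniform multiplicative noise (`up to f` means
exactly that: eps ~ U(-f, f)), and scale/shift/tilt/curvature distortions
applied on the absorbance representation.  Every bundle is bit-reproducible
from its seed.

What the generator does *not* emulate: instrument line-shape convolution,
detector nonlinearity, correlated (non-white) baselines, non-spherical or
more-than-two-layer particles, and refractive indexes outside the Lorentzian
family.  Passing recovery tests therefore demonstrate the correctness and
robustness of the inversion machinery under the model's own assumptions, not
performance on arbitrary real cells.

## Known limitations

- Recovery from noisy data depends on the interplay of band configuration
  and noise realization.  When bands are closely spaced or weak, the S
  minimizer under 10% multiplicative noise can sit far from the generating
  truth — refitting *from the truth itself* then drifts away, i.e. the
  information is genuinely absent from the data, and no optimizer of S can
  restore it.  Expect the noisy-recovery R^2 to vary substantially between
  seeds.
- The layered fit assumes known outer radius; only the core radius is
  routinely treated as free.  J > 2 layers and non-concentric geometries are
  out of scope.
- Uncertainty quantification (confidence intervals on band parameters or
  radii) is not implemented.
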