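# Methods

This note documents the models, numerical choices and limitations of
`eapsim` in the package's own terms.  Everything quantitative asserted here
is computed by the test suite or by `scripts/acceptance.py`.

## Propagator models

The Ensemble Average Propagator (EAP) `P(R; tau)` is the density of a water
molecule's net displacement `R` (mm) over the effective diffusion time
`tau = Delta - delta/3` (s).  All propagators here are antipodally
symmetric, `P(R) = P(-R)`, so their characteristic functions are real.

**Gaussian / diffusion tensor.**
`P(R) = (4 pi tau)^(-3/2) |D|^(-1/2) exp(-R^T D^-1 R / 4 tau)` with `D` a
symmetric positive-semidefinite 3x3 tensor in mm^2/s; the covariance is
`2 tau D`.  `DiffusionTensorModel` fixes a deterministic eigenframe: the
spectrum is sorted descending, the first two eigenvectors get their
largest-magnitude component made positive, and the third is their cross
product (det U = +1).  This makes frames reproducible across runs and
platforms, including for degenerate spectra.

**MAP-MRI.**  A truncated expansion in products of normalized 1D Hermite
functions evaluated in the tensor frame `R' = U^T R` with scales
`s_i = sqrt(2 tau lambda_i)`:

```
P(R') = sum_{N even} sum_{n1+n2+n3=N} a_{n1 n2 n3}
        H_n1(x'; s_x) H_n2(y'; s_y) H_n3(z'; s_z)
H_n(t; s) = [2^(n+1) pi n!]^(-1/2) s^-1 exp(-t^2/2s^2) Hn(t/s)
```

with `Hn` the physicists' Hermite polynomials.  The normalization is fixed
so that `H_0(.; s)` is exactly the `N(0, s^2)` PDF; consequently an
expansion with only `a_000 = 1` reproduces the Gaussian propagator exactly
(verified to 1e-9 relative).  Only even total orders appear (antipodal
symmetry); for `Nmax = 6` there are 50 coefficients.  Truncated expansions
may dip slightly below zero; evaluation reports the signed value and the
sampler crops it (below).

**Spherical convolution (SC).**  A mixture of axisymmetric Gaussian kernels
over fiber orientations: `P(R) = \int_S Phi(v) kappa(R; v) dv`, where
`kappa` is the Gaussian propagator of the tensor with principal axis `v`
and spectrum `(lambda_par, lambda_perp, lambda_perp)`.  The fODF `Phi` is
expanded in real, even-degree spherical harmonics

```
Y_lm = sqrt((2l+1)/(2 pi) (l-|m|)!/(l+|m|)!) P_l^|m|(cos theta) T(m phi)
```

with `T` = sin (m>0), cos (m<0), `2^-1/2` (m=0).  The Condon–Shortley
phase is excluded and `|m|` is used in the Legendre function and factorial
ratio; the convention is pinned down by the quadrature Gram test
(orthonormality to better than 1e-8), which is the only property the rest
of the package relies on.  Unit fODF mass is equivalent to
`phi_00 = 1/sqrt(4 pi)`.

## Rejection sampling

Displacements are drawn by the plain rejection method: proposals `u` from a
wrapper density `f_U`, a uniform height `v ~ U(0, c f_U(u))`, acceptance
when `v <= f_X(u)`.  Negative target values (a truncation artifact) can
never be accepted because heights are non-negative — the sampler draws
exactly from `max(f_X, 0)` renormalized.

**MAP-MRI.**  Sampling happens in normalized coordinates `t_i = x'_i/s_i`,
where the target is scale-free (the Jacobian `prod s_i` cancels the scale
dependence of the Hermite factors).  The wrapper is a product of three
`N(0, nu^2)` densities; a Gaussian with `nu > 1` decays slower than any
Hermite function, so a finite bound exists.  For each `nu` in
{1.1, 1.2, 1.3, 1.4, 1.5}, `c(nu)` is the maximum of target/wrapper over
the lattice `[-5, 5)^3` with step 0.1 (10^6 points, evaluated separably),
and the `nu` minimizing `c` is kept.  For the pure Gaussian target the
ratio is `nu^3 exp(-(1 - nu^-2)||t||^2/2)`, maximal at the origin, so the
search returns `nu = 1.1`, `c = 1.331`.  Because a finite lattice can
under-bound the supremum, the bound used for sampling is inflated by a
5% safety factor (reported separately from the raw grid maximum).
Accepted samples are scaled per axis by `s_i` and rotated back by `U`.

**SC.**  Orientations are proposed uniformly on the sphere
(`cos theta ~ U(-1,1)`, `phi ~ U(0, 2 pi)`) and accepted against the fODF
*per unit solid angle* (ratio `Phi / (1/4 pi)`); `c` is the maximum of that
ratio over a 1-degree lattice `[0, pi) x [0, 2 pi)`, again with the 5%
safety factor.  From the accepted orientation the frame
`u1 = (sin t cos p, sin t sin p, cos t)`, `u2 = (-sin p, cos p, 0)`,
`u3 = u1 x u2` is assembled (at the poles `u2` falls back to `(0,1,0)` by
convention), and the displacement is `R = sqrt(2 tau) D^(1/2) S` with `S`
three standard normal deviates.  The `sqrt(2 tau)` factor is required for
consistency with the Gaussian propagator's covariance `2 tau D`; it is
verified by the covariance and characteristic-function tests.

For unit-mass targets the acceptance probability is `1/c`; the tests check
the empirical rate to within three binomial standard errors.  Each distinct
EAP gets its wrapper built once and cached for a whole phantom simulation.

## PGSE simulation

A PGSE acquisition is parameterized by `delta` (pulse duration), `Delta`
(inter-pulse lapse), amplitude `G` (mT/mm), direction `g`, `TE`, `TR`, and
`gamma = 2.6752e5 rad s^-1 mT^-1`.  Derived quantities:
`q = gamma delta G g` (rad/mm), `b = |q|^2 tau` (s/mm^2).  Units are s, mm
and mT/mm throughout, which makes b-values come out in s/mm^2 with no
conversion factors.  Defaults follow a realistic ex-vivo cardiac protocol:
`Delta/delta = 55.7/16.6 ms` (so `tau = 50.17 ms`), `TE = 113.725 ms`,
`TR = 50.033 s`, six shells at 300–3600 s/mm^2 and 192 directions.

**Motion convention.**  Each spin moves at constant velocity `R/Delta`
from the onset of the first diffusion pulse through the end of the second,
reaching displacement `R` after the lapse `Delta`.  Under this convention
the piecewise closed-form phase integral collapses to `phi = -q.R`
independent of the start position, so the expected voxel signal is exactly
the EAP's characteristic function at `q` — the property every validation
oracle builds on, with no finite-pulse correction.  The alternative (motion
confined to the `Delta` window only) would introduce a `1 - delta/(2 Delta)`
factor and break that identity.

**Signal model.**  Ideal spin echo: each spin contributes
`PD (1 - e^(-TR/T1)) e^(-TE/T2) e^(i phi)`; no relaxation during readout,
no off-resonance, no coil model.  Displacements are redrawn independently
per gradient by default (each DWI is an independent diffusion experiment);
a flag freezes one draw across the table for variance studies.  An
idealized Cartesian k-space encoder (`encode_kspace_ideal`) is provided as
the only imaging layer; it agrees with the direct per-voxel sum up to
discretization and is not a model of EPI readout timing.

## Validation metrics

* **NMSE** per pixel and shell: `sum_j (S_sim - S_ref)^2 / sum_j S_ref^2`
  over the shell's gradients; a single global least-squares intensity
  factor `alpha = sum(S_sim S_ref)/sum(S_sim^2)` is applied beforehand
  (scale calibration, not per-pixel).
* **Correlation maps**: per pixel and shell, Pearson r across the shell's
  gradients; Fisher `z = atanh(r)` with standard error `1/sqrt(N-3)`.  A
  level `rho_0` in {0.5..0.9} is *accepted* when H0: `rho >= rho_0` is not
  rejected against `rho < rho_0` at `alpha = 0.05` (configurable; the
  stricter reject-`rho <= rho_0` reading is available behind a flag).
  Accepted levels are downward closed; pixels failing 0.5 render black,
  the rest follow the blue/green/yellow/red/purple temperature code.
* **DTI fits**: unweighted log-linear least squares of
  `ln S = ln S0 - b g^T D g`, by default on shells up to 1200 s/mm^2
  (configurable, since high-b magnitudes are noise-biased); eigenvalues
  clipped at zero before FA.  Exact on noise-free mono-exponential data.
  Orientation maps are FA-weighted |e1| with red=x, green=y, blue=z.
* **Proton density**: `rho = S / ((1 - e^(-TR/T1)) e^(-TE/T2))`, with
  pixels flagged unstable when the relaxation factor underflows.

Where the package's own tests need a slope from noisy log-attenuations
(Stejskal–Tanner recovery), they use the inverse-variance weighted
log-linear fit — the variance of `ln(atten)` scales like `1/atten^2`, so
unweighted fits are dominated by the noisiest high-b shell.

## Synthetic phantoms and what they do (not) show

The generator emulates the study conditions: 2D slices of ~1700 grid
positions, 2000 spins per position, tissue tuple `(T1, T2, PD) =
(1 s, 50 ms, 1)`, six shells.  Presets: `uniform` (one tensor),
`circular_myocardium` (annulus with principal eigenvector tangent to
concentric circles, the in-plane organization of a mid-ventricular wall),
and `crossing` (SC voxels with two-peak fODFs in an overlap band).  fODF
fixtures are antipodally symmetrized von Mises–Fisher peaks (default
concentration kappa = 5) projected to degree L = 6 and renormalized to unit
mass; kernel defaults `lambda_par = 2e-3`, `lambda_perp = 0.5e-3 mm^2/s`
are physiologically plausible white-matter/myocardium values.  The
non-Gaussian MAP-MRI fixture perturbs `a000 = 1` with small positive
even-order terms (`a200 = 0.25`, `a020 = 0.12`, `a400 = 0.05`,
`a220 = 0.04`, then renormalized to unit mass), chosen so the density is
non-negative on the sampling lattice while the signal departs from
mono-exponential by ~15% at b = 3600 s/mm^2 — including a zero crossing of
the characteristic function near b = 2000 along the principal axis.

Passing tests on these phantoms demonstrate the *mechanics* — exact
sampling, the Fourier identity between propagator and signal, metric
correctness — not fidelity to any real acquisition: the phantoms have no
noise floor, no partial volume, no susceptibility or motion effects, and
their EAPs are known rather than estimated from data.

## Numerical choices

* Spherical quadrature: product Gauss–Legendre in `cos theta` x trapezoid
  in `phi`; exact for band-limited integrands when the rule resolves
  degree 2L (SH projection refuses lower orders).
* MAP-MRI characteristic functions: 3D Gauss–Legendre Fourier quadrature
  on a +/-8-scale box (72 nodes per axis); cross-checked against the
  Gaussian closed form to 1e-6.
* Hermite normalization constants are computed in the log domain
  (`gammaln`), so large orders cannot overflow.
* SC negative fODF lobes (projection truncation artifacts) are cropped at
  the quadrature nodes and the weights renormalized wherever a computation
  must match what the sampler draws from (`clip_negative` flags); the raw
  signed mixture remains the default for density evaluation.
* Kernel matrices in SC evaluation are chunked (8192 points at a time) to
  bound memory.
* Rejection proposal chunks are sized `1.3 c n` and capped at 2e6.
* Degenerate inputs: singular tensors raise on Gaussian-density evaluation
  (`D = 0` still samples as all-zero displacements); zero-variance pixels
  give undefined correlations flagged black; zero reference energy gives
  NaN NMSE; empty voxels warn and return zero signal.

## Problem sizes

The test suite and the acceptance script use 1e5 samples for KS and moment
checks, 2e4 spins for attenuation oracles, 1e4 replicates for the Fisher
calibration, and three 58x58 ring slices (~1670 voxels each) x 49 volumes
x 2000 spins for the end-to-end run — sizes at which Monte-Carlo standard
errors are far below every tolerance used, while the whole pipeline runs
in about a minute on one CPU.

## Known limitations

* No fitting of MAP-MRI or SC representations from measured DWIs — inputs
  are coefficient files or synthetic fixtures.
* The imaging layer is an ideal Cartesian encoder: no EPI trajectory,
  SENSE/multicoil, off-resonance, or relaxation during readout.
* A simulation is only valid at the diffusion time of the EAP it samples
  (a mismatch triggers a warning): the propagator carries no microstructure
  to extrapolate across diffusion times.
* The rejection bound uses a finite lattice plus a fixed 5% safety margin;
  a pathological target peaking between lattice points sharper than the
  lattice step could still exceed it.
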