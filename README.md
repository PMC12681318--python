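# eapsim

Exact sampling of diffusion-MRI Ensemble Average Propagators (EAPs) and
spin-level simulation of pulsed-gradient spin-echo (PGSE) acquisitions.

## The problem

Diffusion MRI probes tissue microstructure through the random displacement of
water molecules.  Over the effective diffusion time `tau = Delta - delta/3`
of a PGSE sequence, the net displacement `R` of a molecule is distributed
according to the EAP `P(R; tau)`.  Classical simulators assume Gaussian
diffusion (the diffusion-tensor model), but real tissue — crossing muscle
fibers, restricted compartments — produces non-Gaussian propagators.

`eapsim` simulates dMRI at the level of individual spins for *any* EAP a
signal representation can describe:

1. **Exact displacement sampling** by the rejection method.  Given a target
   density `f_X` and an auxiliary wrapper density `f_U` with a bound
   `f_X <= c f_U`, proposals `u ~ f_U` are accepted when a uniform height
   `v ~ U(0, c f_U(u))` falls below `f_X(u)`.  Two concrete targets:
   * **MAP-MRI** — the EAP as a truncated expansion in products of 1D
     Hermite functions `H_n(x'; s_x) H_m(y'; s_y) H_k(z'; s_z)` in a
     tensor-adapted rotated/scaled frame.  The wrapper is a product of
     `N(0, nu^2)` densities in normalized coordinates, with `nu` searched
     over {1.1, ..., 1.5} to minimize `c` (grid maximum of the ratio over
     `[-5, 5)^3`).
   * **Spherical convolution (SC)** — the EAP as a mixture of axisymmetric
     Gaussian kernels `(lambda_par, lambda_perp, lambda_perp)` over
     orientations weighted by a fiber ODF in even-degree real spherical
     harmonics.  An orientation is drawn from the fODF against a
     uniform-sphere wrapper, then a Gaussian kernel step
     `R = sqrt(2 tau) D(v)^(1/2) S` is taken.
2. **Spin-level PGSE simulation.**  Each voxel holds 2000 spins (by
   default) sharing one EAP and one `(T1, T2, PD)` tuple; each spin moves
   along a linear path at constant velocity `R/Delta` spanning both
   diffusion pulses, so its accrued phase is exactly `-q.R` with
   `q = gamma delta G g` and the expected signal is the EAP's
   characteristic function at `q` — the Fourier relation that makes the
   simulation checkable against independent quadrature oracles.
3. **Validation metrics** — shell-wise NMSE, pixelwise Pearson correlation
   maps with Fisher-transformed unilateral level tests, log-linear DTI fits
   with FA-weighted RGB orientation maps, and ideal-spin-echo proton-density
   estimation.
4. **Synthetic phantoms** — uniform, concentric-ring ("myocardium-like")
   and crossing-fiber fields, multi-shell Fibonacci gradient tables, and
   analytic reference signals, so the whole pipeline is testable without
   any acquisition.

## Worked example

Sample a non-Gaussian MAP-MRI propagator and compare the simulated PGSE
attenuation with its characteristic function:

```python
import numpy as np
from eapsim import (SequenceTiming, PGSESequence, build_mapmri_wrapper,
                    sample_mapmri, pgse_phase, analytic_signal)
from eapsim.phantom import nongaussian_mapmri

timing = SequenceTiming()          # delta=16.6 ms, Delta=55.7 ms -> tau=50.17 ms
eap = nongaussian_mapmri(tau=timing.tau)

wrapper = build_mapmri_wrapper(eap)
print(f"wrapper: nu={wrapper.nu}, c={wrapper.c:.3f} (grid max {wrapper.c_grid:.3f})")

rng = np.random.default_rng(0)
batch = sample_mapmri(eap, 100_000, rng, wrapper=wrapper)
print(f"acceptance rate: {batch.acceptance_rate:.3f} (1/c = {1/wrapper.c:.3f})")

seq = PGSESequence.from_bvalue(2000.0, eap.U[:, 0], timing)
atten = np.exp(1j * pgse_phase(None, batch.displacements, seq)).mean().real
print(f"simulated attenuation at b=2000: {atten:+.4f}")
print(f"characteristic-function oracle:  {analytic_signal(eap, seq.q).real:+.4f}")
```

prints

```
wrapper: nu=1.3, c=1.760 (grid max 1.676)
acceptance rate: 0.569 (1/c = 0.568)
simulated attenuation at b=2000: -0.0095
characteristic-function oracle:  -0.0079
```

The wrapper search selected `nu = 1.3` with bound `c = 1.76`; the observed
acceptance rate matches `1/c` because the target has unit mass.  At
`b = 2000 s/mm^2` along the principal axis this propagator's attenuation is
*negative* (its characteristic function crosses zero) — a signature no
mono-exponential tensor model can produce (the Gaussian value here would be
`+0.033`) — and the Monte-Carlo simulation reproduces the oracle within
sampling noise.

## Command line

```sh
eapsim phantom  --preset circular_myocardium --grid 40 40 --seed 1 --out ph/
eapsim sample   --eap eap.json -n 10000 --seed 1 --out displacements.csv
eapsim simulate --phantom ph/phantom.json --bvals ph/bvals --bvecs ph/bvecs \
                --seed 1 --out sim/
eapsim validate --sim sim/ --ref ref/ --out report/
```

Every stage writes a JSON manifest with the configuration, seeds, wrapper
constants (`nu`, `c`) and acceptance rates needed to reproduce it.
Gradient tables use the FSL bvals/bvecs dialect; stacks are written as
plain-text CSV + manifest or as NIfTI.  Run configuration (spins per voxel,
wrapper grids, sequence timing) is a small YAML file; the defaults are
2000 spins/voxel, `nu` in {1.1..1.5}, a `[-5, 5)^3` wrapper lattice at step
0.1, a 180x360 spherical lattice, and PGSE timing
`Delta/delta = 55.7/16.6 ms`, `TE = 113.725 ms`, `TR = 50.033 s`.

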