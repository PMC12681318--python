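"""Spin-level simulation of pulsed-gradient spin-echo (PGSE) diffusion MRI.

Each voxel holds an ensemble of spins sharing one EAP and one tissue tuple
(T1, T2, PD).  Every spin receives an independent end-to-end displacement
``R`` drawn from the voxel's EAP and moves along a linear path at constant
velocity ``R / Delta`` spanning both diffusion pulses.  Under that
convention the accrued PGSE phase is exactly ``-q . R`` with
``q = gamma delta G g_hat``, so the expected signal equals the EAP's
characteristic function at ``q`` — the Fourier relation all validation in
:mod:`eapsim.metrics` builds on.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

log = logging.getLogger(__name__)

from .eap import GYROMAGNETIC_RATIO, DiffusionTensorModel, MapMriEAP, ScEAP
from .gradients import GradientTable
from .sampling import (
    SampleBatch,
    build_fodf_wrapper,
    build_mapmri_wrapper,
    sample_gaussian,
    sample_mapmri,
    sample_sc,
)

DEFAULT_SPINS_PER_VOXEL = 2000


@dataclasses.dataclass(frozen=True)
class SequenceTiming:
    """PGSE timing shared across a whole acquisition (seconds)."""

    delta: float = 0.0166    # gradient pulse duration
    Delta: float = 0.0557    # inter-pulse lapse
    TE: float = 0.113725
    TR: float = 50.033
    gamma: float = GYROMAGNETIC_RATIO  # rad s^-1 mT^-1

    def __post_init__(self):
        if not (0 < self.delta <= self.Delta):
            raise ValueError("require 0 < delta <= Delta")
        if self.TE <= 0 or self.TR <= 0 or self.gamma <= 0:
            raise ValueError("TE, TR and gamma must be positive")

    @property
    def tau(self) -> float:
        """Effective diffusion time ``Delta - delta / 3``."""
        return self.Delta - self.delta / 3.0


@dataclasses.dataclass(frozen=True)
class PGSESequence:
    """One PGSE acquisition: timing plus gradient amplitude and direction."""

    G: float                         # mT/mm
    g_dir: np.ndarray                # unit 3-vector (zero for b = 0)
    timing: SequenceTiming = SequenceTiming()

    def __post_init__(self):
        g = np.asarray(self.g_dir, dtype=float).ravel()
        if g.shape != (3,):
            raise ValueError("g_dir must be a 3-vector")
        nrm = np.linalg.norm(g)
        if nrm > 1e-12:
            g = g / nrm
        elif self.G > 0:
            raise ValueError("zero direction with non-zero amplitude")
        object.__setattr__(self, "g_dir", g)

    @property
    def tau(self) -> float:
        return self.timing.tau

    @property
    def q(self) -> np.ndarray:
        """q-vector ``gamma delta G g_hat`` in rad/mm."""
        return self.timing.gamma * self.timing.delta * self.G * self.g_dir

    @property
    def b(self) -> float:
        """b-value ``gamma^2 delta^2 G^2 (Delta - delta/3)`` in s/mm^2."""
        return float((self.timing.gamma * self.timing.delta * self.G) ** 2 * self.tau)

    @classmethod
    def from_bvalue(cls, b: float, g_dir, timing: SequenceTiming | None = None
                    ) -> "PGSESequence":
        """Solve the gradient amplitude from a b-value at fixed timing."""
        timing = timing or SequenceTiming()
        if b < 0:
            raise ValueError("b must be non-negative")
        G = np.sqrt(b / timing.tau) / (timing.gamma * timing.delta) if b > 0 else 0.0
        return cls(G=G, g_dir=g_dir if b > 0 else np.zeros(3), timing=timing)


def linear_path(r0, R, t, seq: PGSESequence, t_start: float = 0.0):
    """Spin position along the constant-velocity diffusion path.

    The spin sits at ``r0`` before the motion window, then moves at constant
    velocity ``R / Delta`` from the onset of the first diffusion pulse
    through the end of the second, reaching ``r0 + R`` after the lapse
    ``Delta``.
    """
    r0 = np.asarray(r0, dtype=float)
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    Delta, delta = seq.timing.Delta, seq.timing.delta
    frac = np.clip((t - t_start) / Delta, 0.0, (Delta + delta) / Delta)
    return r0 + frac[..., None] * R


def pgse_phase(r0, R, seq: PGSESequence):
    """Net PGSE phase of a spin with end-to-end displacement ``R`` (rad).

    For the constant-velocity path the piecewise closed-form integral of
    ``gamma G(t) . r(t)`` over the two pulses (with the refocusing sign
    flip) collapses to ``-q . R``, independent of the starting position
    ``r0``.
    """
    R = np.asarray(R, dtype=float)
    return -(R @ seq.q)


def voxel_signal(displacements, seq: PGSESequence, T1: float, T2: float,
                 PD=1.0) -> complex:
    """Complex voxel signal from an ensemble of spin displacements.

    ``S = sum_spins PD (1 - exp(-TR/T1)) exp(-TE/T2) exp(i phi)`` — an ideal
    spin echo with relaxation applied as a scalar weight at TE.
    """
    R = np.asarray(displacements, dtype=float)
    if R.size == 0:
        warnings.warn("empty voxel: returning zero signal", stacklevel=2)
        return 0.0 + 0.0j
    w = relaxation_weight(T1, T2, seq.timing.TE, seq.timing.TR, PD)
    phase = pgse_phase(None, R, seq)
    return complex(np.sum(w * np.exp(1j * phase)))


def relaxation_weight(T1, T2, TE: float, TR: float, PD=1.0):
    """Steady-state ideal spin-echo weight ``PD (1 - e^(-TR/T1)) e^(-TE/T2)``."""
    T1 = np.asarray(T1, dtype=float)
    T2 = np.asarray(T2, dtype=float)
    return PD * (1.0 - np.exp(-TR / T1)) * np.exp(-TE / T2)


# ---------------------------------------------------------------------------
# Whole-stack simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DwiStack:
    """Per-voxel complex signals for every gradient-table entry.

    ``data`` has axis order (x, y, gradient); voxels outside ``mask`` hold
    zeros.
    """

    data: np.ndarray          # (nx, ny, nvol) complex
    bvals: np.ndarray         # (nvol,)
    bvecs: np.ndarray         # (nvol, 3)
    mask: np.ndarray          # (nx, ny) bool
    meta: dict = dataclasses.field(default_factory=dict)

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def baseline(self) -> np.ndarray:
        """Mean magnitude over the b = 0 entries."""
        b0 = self.bvals <= 1e-6
        if not np.any(b0):
            raise ValueError("stack has no b = 0 entry")
        return np.abs(self.data[..., b0]).mean(axis=-1)


def _draw_displacements(eap, n: int, rng: np.random.Generator, tau: float,
                        wrapper_cache: dict) -> SampleBatch:
    if isinstance(eap, DiffusionTensorModel):
        return sample_gaussian(eap, tau, n, rng)
    key = id(eap)
    if isinstance(eap, MapMriEAP):
        if key not in wrapper_cache:
            wrapper_cache[key] = build_mapmri_wrapper(eap)
            w = wrapper_cache[key]
            log.debug("MAP-MRI wrapper: nu=%.2f c_grid=%.4f c=%.4f", w.nu,
                      w.c_grid, w.c)
        return sample_mapmri(eap, n, rng, wrapper=wrapper_cache[key])
    if isinstance(eap, ScEAP):
        if key not in wrapper_cache:
            wrapper_cache[key] = build_fodf_wrapper(eap.fodf)
            w = wrapper_cache[key]
            log.debug("fODF wrapper: c_grid=%.4f c=%.4f", w.c_grid, w.c)
        return sample_sc(eap, n, rng, wrapper=wrapper_cache[key])
    raise TypeError(f"unsupported EAP type {type(eap).__name__}")


def simulate_dwi_stack(phantom, table: GradientTable,
                       timing: SequenceTiming | None = None,
                       spins_per_voxel: int = DEFAULT_SPINS_PER_VOXEL,
                       rng: np.random.Generator | None = None,
                       redraw_per_gradient: bool = True) -> DwiStack:
    """Monte-Carlo PGSE simulation of a phantom over a gradient table.

    Displacements are redrawn independently for every gradient by default
    (each DWI is an independent diffusion experiment); with
    ``redraw_per_gradient=False`` one draw per spin is reused across the
    whole table, which is useful for variance studies.
    """
    timing = timing or SequenceTiming()
    rng = rng or np.random.default_rng()
    nvol = len(table)
    seqs = [PGSESequence.from_bvalue(b, g, timing) for b, g in table]
    qs = np.stack([s.q for s in seqs])                       # (nvol, 3)
    nx, ny = phantom.grid_shape
    data = np.zeros((nx, ny, nvol), dtype=complex)
    mask = np.zeros((nx, ny), dtype=bool)
    wrapper_cache: dict = {}
    acc_rates = []
    for vox in phantom.voxels:
        eap = vox.eap
        eap_tau = getattr(eap, "tau", None)
        if eap_tau is not None and abs(eap_tau - timing.tau) > 1e-9 + 1e-4 * timing.tau:
            warnings.warn(
                f"EAP diffusion time {eap_tau:.6g}s differs from the sequence's "
                f"{timing.tau:.6g}s; the simulation is only valid at the EAP's tau",
                stacklevel=2,
            )
        n_draw = spins_per_voxel * nvol if redraw_per_gradient else spins_per_voxel
        batch = _draw_displacements(eap, n_draw, rng, timing.tau, wrapper_cache)
        acc_rates.append(batch.acceptance_rate)
        if redraw_per_gradient:
            R = batch.displacements.reshape(nvol, spins_per_voxel, 3)
            phases = -np.einsum("vj,vsj->vs", qs, R)
        else:
            phases = -batch.displacements @ qs.T             # (spins, nvol)
            phases = phases.T
        w = relaxation_weight(vox.t1, vox.t2, timing.TE, timing.TR, vox.pd)
        i, j = vox.index
        data[i, j, :] = w * np.exp(1j * phases).sum(axis=1)
        mask[i, j] = True
    if acc_rates:
        log.info("simulated %d voxels x %d volumes; acceptance rate "
                 "mean %.3f min %.3f", len(acc_rates), nvol,
                 float(np.mean(acc_rates)), float(np.min(acc_rates)))
    meta = {
        "spins_per_voxel": spins_per_voxel,
        "redraw_per_gradient": redraw_per_gradient,
        "timing": dataclasses.asdict(timing),
        "acceptance_rate_mean": float(np.mean(acc_rates)) if acc_rates else None,
        "acceptance_rate_min": float(np.min(acc_rates)) if acc_rates else None,
        "wrappers": [
            {"nu": w.nu, "c": w.c, "c_grid": w.c_grid, "family": w.family}
            for w in wrapper_cache.values()
        ],
    }
    return DwiStack(data, table.bvals.copy(), table.bvecs.copy(), mask, meta)


# ---------------------------------------------------------------------------
# Idealized Cartesian encoding
# ---------------------------------------------------------------------------

def encode_kspace_ideal(positions, weights, phases, matrix_size, fov: float):
    """Ideal Cartesian k-space encoding and reconstruction of spin signals.

    Samples ``S(k) = sum_s w_s e^{i phi_s} e^{-i 2 pi k . r_s}`` on an
    ``nx x ny`` Cartesian lattice with spacing ``1 / fov`` (cycles/mm) and
    returns the inverse-DFT image on pixel centers.  This is a simplified
    imaging layer: no EPI trajectory timing, relaxation during readout or
    coil model.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] < 2:
        raise ValueError("positions must be (n, >=2)")
    x, y = pos[:, 0], pos[:, 1]
    if np.any(np.abs(x) > fov / 2) or np.any(np.abs(y) > fov / 2):
        warnings.warn("spins outside the FOV will alias", stacklevel=2)
    nx, ny = matrix_size
    c = np.asarray(weights, dtype=float) * np.exp(1j * np.asarray(phases, dtype=float))
    kx = (np.arange(nx) - nx // 2) / fov
    ky = (np.arange(ny) - ny // 2) / fov
    Ax = np.exp(-2j * np.pi * np.outer(kx, x))     # (nx, n)
    Ay = np.exp(-2j * np.pi * np.outer(ky, y))     # (ny, n)
    K = (Ax * c) @ Ay.T                            # (nx, ny)
    xp = (np.arange(nx) - nx // 2) * (fov / nx)
    yp = (np.arange(ny) - ny // 2) * (fov / ny)
    Ex = np.exp(2j * np.pi * np.outer(xp, kx))     # (nx, nx)
    Ey = np.exp(2j * np.pi * np.outer(yp, ky))
    return Ex @ K @ Ey.T / (nx * ny)
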