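"""Synthetic ground-truth phantoms, gradient tables and analytic references.

Everything the simulator and the metrics need can be generated here without
any acquisition: fiber fields with known orientation structure (uniform,
concentric "myocardium-like" rings, crossing fibers), deterministic
multi-shell gradient tables, band-limited fODF fixtures, and analytic /
quadrature reference signals that serve as independent oracles for the
Monte-Carlo simulator.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .eap import (
    DiffusionTensorModel,
    MapMriEAP,
    ScEAP,
    ShCoefficients,
    mapmri_index_set,
    sh_basis_matrix,
    sh_index_set,
    sphere_nodes,
    sphere_quadrature,
)
from .gradients import GradientTable

#: default tissue tuple: ex-vivo myocardium-like T1/T2 (s) and unit PD
DEFAULT_TISSUE = (1.0, 0.05, 1.0)

#: default axisymmetric kernel eigenvalues (mm^2/s)
DEFAULT_LAMBDA_PAR = 2.0e-3
DEFAULT_LAMBDA_PERP = 0.5e-3


@dataclasses.dataclass(frozen=True)
class VoxelSpec:
    """One grid position: an EAP plus the tissue tuple its spins share."""

    index: tuple       # (i, j)
    eap: object        # DiffusionTensorModel | MapMriEAP | ScEAP
    t1: float
    t2: float
    pd: float


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """A 2D grid of voxels, each carrying an EAP and tissue parameters."""

    grid_shape: tuple
    spacing: float      # mm
    voxels: tuple       # of VoxelSpec
    name: str = ""
    seed: int | None = None


# ---------------------------------------------------------------------------
# Spherical-harmonic fixtures
# ---------------------------------------------------------------------------

def project_to_sh(f, L: int, n_theta: int | None = None,
                  n_phi: int | None = None) -> ShCoefficients:
    """Project a function on the sphere onto the even real SH basis.

    Exact for integrands band-limited to degree L.  The quadrature must
    resolve degree 2L (the product f * Y_lm); orders below that are refused.
    """
    if L < 0 or L % 2:
        raise ValueError("L must be even and non-negative")
    n_theta = n_theta if n_theta is not None else 2 * L + 2
    n_phi = n_phi if n_phi is not None else 4 * L + 4
    if 2 * n_theta - 1 < 2 * L + 1 or n_phi < 2 * (2 * L) + 1:
        raise ValueError(
            f"quadrature order too low for L={L}: need Gauss-Legendre degree "
            f">= {2 * L + 1} and >= {4 * L + 1} azimuthal nodes")
    theta, phi, w = sphere_quadrature(n_theta, n_phi)
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    vals = np.asarray(f(TH, PH), dtype=float)
    B = sh_basis_matrix(L, TH, PH)              # (ncoef, ntheta, nphi)
    coeffs = np.einsum("i,kij->k", w, B * vals[None])
    return ShCoefficients(coeffs, L)


def symmetric_peak_fodf(directions, weights=None, kappa: float = 5.0,
                        L: int = 6) -> ShCoefficients:
    """Antipodally symmetrized von Mises–Fisher mixture projected to degree L.

    A smooth, band-limit-friendly stand-in for deconvolved fODFs; the
    projection is rescaled to unit spherical mass.
    """
    mus = np.asarray(directions, dtype=float)
    if mus.ndim == 1:
        mus = mus[None]
    mus = mus / np.linalg.norm(mus, axis=1, keepdims=True)
    if weights is None:
        weights = np.full(len(mus), 1.0 / len(mus))
    weights = np.asarray(weights, dtype=float)
    norm = kappa / (4.0 * np.pi * np.sinh(kappa))

    def f(theta, phi):
        v = np.stack([np.sin(theta) * np.cos(phi),
                      np.sin(theta) * np.sin(phi),
                      np.cos(theta)], axis=-1)
        out = np.zeros(theta.shape)
        for w, mu in zip(weights, mus):
            d = v @ mu
            out += w * norm * 0.5 * (np.exp(kappa * d) + np.exp(-kappa * d))
        return out

    coeffs = project_to_sh(f, L, n_theta=2 * L + 8, n_phi=4 * L + 16)
    # renormalize the truncated series to unit mass
    mass = coeffs.values[0] * np.sqrt(4.0 * np.pi)
    return ShCoefficients(coeffs.values / mass, L)


def uniform_fodf(L: int = 0) -> ShCoefficients:
    values = np.zeros(len(sh_index_set(L)))
    values[0] = 1.0 / np.sqrt(4.0 * np.pi)
    return ShCoefficients(values, L)


# ---------------------------------------------------------------------------
# Non-Gaussian MAP-MRI fixture
# ---------------------------------------------------------------------------

def nongaussian_mapmri(model: DiffusionTensorModel | None = None,
                       tau: float = 0.050167) -> MapMriEAP:
    """A positivity-checked non-Gaussian MAP-MRI fixture.

    The Gaussian term a000 = 1 is perturbed with small even-order
    coefficients (kept positive on the sampling lattice and normalized to
    unit mass); its signal departs from mono-exponential by well over 5% at
    b = 3600 s/mm^2, giving the simulator a genuinely non-Gaussian case.
    """
    if model is None:
        model = DiffusionTensorModel(np.diag([1.7e-3, 0.45e-3, 0.35e-3]))
    base = MapMriEAP.from_tensor(model, tau)
    idx = mapmri_index_set(6)
    coeffs = np.zeros(len(idx))
    values = {(0, 0, 0): 1.0, (2, 0, 0): 0.25, (0, 2, 0): 0.12,
              (4, 0, 0): 0.05, (2, 2, 0): 0.04}
    for k, triple in enumerate(map(tuple, idx)):
        coeffs[k] = values.get(triple, 0.0)
    eap = MapMriEAP(coeffs, idx, base.scales, base.U, tau).normalized()
    t = np.linspace(-6.0, 6.0, 41)
    grid_min = eap.grid_eval_normalized(t, t, t).min()
    if grid_min < -1e-12:
        raise ValueError(f"fixture density dips to {grid_min:g}; adjust coefficients")
    return eap


# ---------------------------------------------------------------------------
# Fiber-field presets
# ---------------------------------------------------------------------------

def _tensor_from_frame(e1, e2, e3, eigenvalues) -> DiffusionTensorModel:
    U = np.column_stack([e1, e2, e3])
    lam = np.asarray(eigenvalues, dtype=float)
    return DiffusionTensorModel(U @ np.diag(lam) @ U.T)


def make_fiber_field(preset: str, grid_shape=(40, 40), spacing: float = 1.0,
                     seed: int = 0, tau: float = 0.050167,
                     tissue=DEFAULT_TISSUE, **kwargs) -> PhantomSpec:
    """Generate a ground-truth phantom from a named geometry preset.

    Presets
    -------
    ``uniform``
        One tensor everywhere (default diag(2, 1, 0.5) x 10^-3 mm^2/s).
    ``circular_myocardium``
        Annulus with the principal eigenvector tangent to concentric
        circles, mimicking the in-plane organization of the myocardial
        wall.
    ``crossing``
        Spherical-convolution voxels: single-fiber fODFs in two flanks and
        a two-orientation fODF in the overlap band.

    Deterministic for a given ``(preset, grid_shape, seed)``.
    """
    nx, ny = grid_shape
    t1, t2, pd = tissue
    voxels = []
    if preset == "uniform":
        D = kwargs.get("D")
        model = DiffusionTensorModel(np.diag([2e-3, 1e-3, 0.5e-3]) if D is None
                                     else np.asarray(D, dtype=float))
        for i in range(nx):
            for j in range(ny):
                voxels.append(VoxelSpec((i, j), model, t1, t2, pd))
    elif preset == "circular_myocardium":
        eigenvalues = kwargs.get("eigenvalues", (2.0e-3, 0.5e-3, 0.5e-3))
        r_in = kwargs.get("r_inner", 0.25 * min(nx, ny) * spacing)
        r_out = kwargs.get("r_outer", 0.45 * min(nx, ny) * spacing)
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        for i in range(nx):
            for j in range(ny):
                x, y = (i - cx) * spacing, (j - cy) * spacing
                r = np.hypot(x, y)
                if not (r_in <= r <= r_out):
                    continue
                radial = np.array([x / r, y / r, 0.0])
                tangent = np.array([-y / r, x / r, 0.0])
                model = _tensor_from_frame(tangent, radial, [0, 0, 1.0], eigenvalues)
                voxels.append(VoxelSpec((i, j), model, t1, t2, pd))
    elif preset == "crossing":
        lam_par = kwargs.get("lambda_par", DEFAULT_LAMBDA_PAR)
        lam_perp = kwargs.get("lambda_perp", DEFAULT_LAMBDA_PERP)
        kappa = kwargs.get("kappa", 5.0)
        L = kwargs.get("L", 6)
        d1 = np.array([1.0, 0.0, 0.0])
        d2 = np.array([0.5, np.sqrt(3.0) / 2.0, 0.0])
        f1 = symmetric_peak_fodf(d1, kappa=kappa, L=L)
        f2 = symmetric_peak_fodf(d2, kappa=kappa, L=L)
        f12 = symmetric_peak_fodf([d1, d2], kappa=kappa, L=L)
        band = max(nx // 4, 1)
        lo, hi = nx // 2 - band // 2, nx // 2 + (band + 1) // 2
        for i in range(nx):
            fodf = f1 if i < lo else (f12 if i < hi else f2)
            for j in range(ny):
                voxels.append(VoxelSpec(
                    (i, j), ScEAP(fodf, lam_par, lam_perp, tau), t1, t2, pd))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return PhantomSpec((nx, ny), spacing, tuple(voxels), name=preset, seed=seed)


# ---------------------------------------------------------------------------
# Analytic / quadrature reference signals
# ---------------------------------------------------------------------------

def analytic_signal(eap, q, tau: float | None = None, n_nodes: int = 72,
                    extent_scales: float = 8.0, clip_negative: bool = True):
    """Expected complex attenuation E[e^(i q.R)] for an EAP at q (rad/mm).

    * Gaussian tensor: closed form ``exp(-tau q^T D q)`` (equal to
      ``exp(-b g^T D g)`` with ``b = |q|^2 tau``).
    * Spherical convolution: spherical quadrature of the fODF-weighted
      kernel characteristic functions (negative fODF lobes cropped by
      default, matching what the sampler draws from).
    * MAP-MRI: 3D Gauss–Legendre Fourier quadrature of the density on a
      ``+/- extent_scales`` box in normalized coordinates.

    This routine is the universal independent oracle for the spin
    simulator: under the constant-velocity path convention the simulated
    attenuation must converge to it.
    """
    q = np.asarray(q, dtype=float)
    qs = q.reshape(-1, 3)
    if isinstance(eap, DiffusionTensorModel):
        if tau is None:
            raise ValueError("tau is required for a tensor EAP")
        vals = np.exp(-tau * np.einsum("ki,ij,kj->k", qs, eap.D, qs)).astype(complex)
    elif isinstance(eap, ScEAP):
        v, W, TH, PH = sphere_nodes(48, 96)
        from .eap import fodf_eval
        f = fodf_eval(eap.fodf, TH, PH)
        if clip_negative:
            f = np.clip(f, 0.0, None)
            f = f / np.sum(W * f)
        dots = qs @ v.T
        q2 = np.sum(qs * qs, axis=-1)[:, None]
        expo = eap.lambda_perp * (q2 - dots ** 2) + eap.lambda_par * dots ** 2
        vals = (np.exp(-eap.tau * expo) @ (W * f)).astype(complex)
    elif isinstance(eap, MapMriEAP):
        t1d, w1d = np.polynomial.legendre.leggauss(n_nodes)
        t1d = t1d * extent_scales
        w1d = w1d * extent_scales
        P = eap.grid_eval_normalized(t1d, t1d, t1d)
        qp = qs @ eap.U * eap.scales                # omega_i = (U^T q)_i s_i
        vals = np.empty(qs.shape[0], dtype=complex)
        for k in range(qs.shape[0]):
            ex = w1d * np.exp(1j * qp[k, 0] * t1d)
            ey = w1d * np.exp(1j * qp[k, 1] * t1d)
            ez = w1d * np.exp(1j * qp[k, 2] * t1d)
            vals[k] = np.einsum("ijk,i,j,k->", P, ex, ey, ez)
    else:
        raise TypeError(f"unsupported EAP type {type(eap).__name__}")
    return vals.reshape(q.shape[:-1]) if q.ndim > 1 else vals[0]


# ---------------------------------------------------------------------------
# Gradient-table generation
# ---------------------------------------------------------------------------

DEFAULT_SHELLS = (300.0, 600.0, 900.0, 1200.0, 2000.0, 3600.0)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, well-spread unit directions via the spherical Fibonacci lattice."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.standard_normal(4)
    w, x, y, z = quat / np.linalg.norm(quat)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_gradient_table(shells=DEFAULT_SHELLS, n_dirs: int = 32,
                        n_b0: int = 1, seed: int = 0) -> GradientTable:
    """Multi-shell table: Fibonacci-lattice directions, one rotation per shell.

    The default six shells with 32 directions each give 192 DWIs plus the
    baseline entries (placed first, with zero direction vectors).
    """
    if n_dirs < 1:
        raise ValueError("need at least one direction per shell")
    rng = np.random.default_rng(seed)
    base = fibonacci_sphere(n_dirs)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b in shells:
        rot = _random_rotation(rng)
        for v in base @ rot.T:
            bvals.append(float(b))
            bvecs.append(v)
    return GradientTable(np.array(bvals), np.array(bvecs))
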