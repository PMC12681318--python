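"""Ensemble Average Propagator (EAP) models.

The EAP is the probability density of a water molecule's net 3D displacement
``R`` (in mm) over the effective diffusion time ``tau`` (in s).  Three
representations are provided:

* :class:`DiffusionTensorModel` — the Gaussian propagator of classical DTI,
  with covariance ``2 * tau * D``;
* :class:`MapMriEAP` — a truncated expansion in products of 1D Hermite
  functions evaluated in a tensor-adapted rotated and scaled frame
  (the MAP-MRI representation);
* :class:`ScEAP` — a spherical-convolution mixture: an axisymmetric Gaussian
  kernel with eigenvalues ``(lambda_par, lambda_perp, lambda_perp)`` mixed
  over orientations weighted by a fiber Orientation Distribution Function
  (fODF) expanded in even-degree real spherical harmonics.

Units are seconds, millimeters and mm^2/s throughout; the proton
gyromagnetic ratio is expressed in rad s^-1 mT^-1 so that b-values emerge in
s/mm^2.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import special

#: Proton gyromagnetic ratio, rad s^-1 mT^-1.
GYROMAGNETIC_RATIO = 2.6752e5


class SingularModelError(ValueError):
    """Raised when a Gaussian propagator is requested from a singular tensor."""


class InvalidTensorError(ValueError):
    """Raised for tensors that are not symmetric positive semidefinite."""


class InvalidKernelError(ValueError):
    """Raised for non-positive spherical-convolution kernel eigenvalues."""


# ---------------------------------------------------------------------------
# Diffusion tensor / Gaussian propagator
# ---------------------------------------------------------------------------

def _fix_eigenframe(eigvals: np.ndarray, eigvecs: np.ndarray):
    """Order a spectrum descending and fix a deterministic right-handed frame.

    The sign of the first two eigenvectors is fixed so that their
    largest-magnitude component is positive; the third is their cross
    product, which enforces det(U) = +1.
    """
    order = np.argsort(eigvals)[::-1]
    lam = eigvals[order]
    U = eigvecs[:, order].copy()
    for k in range(2):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    U[:, 2] = np.cross(U[:, 0], U[:, 1])
    return lam, U


@dataclasses.dataclass(frozen=True)
class DiffusionTensorModel:
    """A 3x3 symmetric positive-semidefinite diffusion tensor (mm^2/s).

    Attributes
    ----------
    D : (3, 3) ndarray
        The tensor itself.
    eigenvalues : (3,) ndarray
        Spectrum sorted descending, ``lambda_x >= lambda_y >= lambda_z``.
    U : (3, 3) ndarray
        Eigenvector matrix (columns ordered like the eigenvalues) with a
        deterministic sign convention and det(U) = +1.
    """

    D: np.ndarray
    eigenvalues: np.ndarray = dataclasses.field(init=False)
    U: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (3, 3):
            raise InvalidTensorError(f"expected a 3x3 tensor, got shape {D.shape}")
        if not np.allclose(D, D.T, atol=1e-12 * max(1.0, float(np.abs(D).max()))):
            raise InvalidTensorError("tensor is not symmetric")
        D = 0.5 * (D + D.T)
        lam, vec = np.linalg.eigh(D)
        scale = max(1.0, float(lam.max(initial=0.0)))
        if lam.min() < -1e-10 * scale:
            raise InvalidTensorError(f"negative eigenvalue {lam.min():g}")
        lam = np.clip(lam, 0.0, None)
        lam, U = _fix_eigenframe(lam, vec)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "eigenvalues", lam)
        object.__setattr__(self, "U", U)

    @classmethod
    def from_eigensystem(cls, eigenvalues, U=None) -> "DiffusionTensorModel":
        lam = np.asarray(eigenvalues, dtype=float)
        U = np.eye(3) if U is None else np.asarray(U, dtype=float)
        return cls(U @ np.diag(lam) @ U.T)

    @property
    def sqrtm(self) -> np.ndarray:
        """Symmetric square root ``D^(1/2) = U diag(sqrt(lam)) U^T``."""
        return self.U @ np.diag(np.sqrt(self.eigenvalues)) @ self.U.T

    def pdf(self, R, tau: float):
        return gaussian_eap_pdf(R, self, tau)


def gaussian_eap_pdf(R, model: DiffusionTensorModel, tau: float):
    """Gaussian EAP density ``(4 pi tau)^(-3/2) |D|^(-1/2) exp(-R^T D^-1 R / 4 tau)``.

    Parameters
    ----------
    R : (..., 3) array_like
        Displacements in mm.
    model : DiffusionTensorModel
        Positive-definite tensor.
    tau : float
        Effective diffusion time in s.

    Returns
    -------
    ndarray
        Density in mm^-3, broadcast over the leading axes of ``R``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    lam = model.eigenvalues
    if np.any(lam <= 0):
        raise SingularModelError(
            "singular diffusion tensor: the Gaussian propagator is undefined "
            f"(eigenvalues {lam})"
        )
    R = np.asarray(R, dtype=float)
    Rp = R @ model.U  # coordinates in the eigenframe, (U^T R)_i
    quad = np.sum(Rp * Rp / lam, axis=-1)
    norm = (4.0 * np.pi * tau) ** 1.5 * np.sqrt(np.prod(lam))
    return np.exp(-quad / (4.0 * tau)) / norm


def dt_spectrum_to_frame(model: DiffusionTensorModel, tau: float):
    """Tensor eigenframe and MAP-MRI scale factors ``s_i = sqrt(2 tau lam_i)``.

    Returns ``(U, sx, sy, sz)`` with ``sx >= sy >= sz`` matching the
    descending eigenvalue order.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    lam = model.eigenvalues
    if np.any(lam < 0):  # pragma: no cover - guarded in the constructor
        raise InvalidTensorError("negative eigenvalue")
    s = np.sqrt(2.0 * tau * lam)
    return model.U, s[0], s[1], s[2]


# ---------------------------------------------------------------------------
# MAP-MRI Hermite basis
# ---------------------------------------------------------------------------

def hermite_basis_1d(n: int, t, s: float = 1.0):
    """Normalized 1D Hermite function ``H_n(t; s)``.

    ``H_n(t; s) = [2^(n+1) pi n!]^(-1/2) s^-1 exp(-t^2 / 2 s^2) Hn(t / s)``
    with ``Hn`` the physicists' Hermite polynomial.  ``H_0(.; s)`` is exactly
    the zero-mean Gaussian PDF with standard deviation ``s``; the constants
    are evaluated in the log domain so large orders cannot overflow.
    """
    if n < 0:
        raise ValueError("order must be non-negative")
    t = np.asarray(t, dtype=float)
    u = t / s
    log_norm = -0.5 * ((n + 1) * np.log(2.0) + np.log(np.pi) + special.gammaln(n + 1))
    return np.exp(log_norm - 0.5 * u * u) * special.eval_hermite(n, u) / s


def mapmri_index_set(nmax: int) -> np.ndarray:
    """All (n1, n2, n3) with even total order N = n1+n2+n3 <= nmax.

    Ordered by N ascending, then n1 descending, then n2 descending; for
    ``nmax = 6`` this yields the canonical 50 triplets (1 + 6 + 15 + 28).
    """
    if nmax < 0 or nmax % 2:
        raise ValueError("nmax must be a non-negative even integer")
    idx = []
    for N in range(0, nmax + 1, 2):
        for n1 in range(N, -1, -1):
            for n2 in range(N - n1, -1, -1):
                idx.append((n1, n2, N - n1 - n2))
    return np.asarray(idx, dtype=int)


def _basis_matrix(t: np.ndarray, max_order: int) -> np.ndarray:
    """Rows ``H_n(t; 1)`` for n = 0..max_order; shape (max_order+1, t.size)."""
    return np.stack([hermite_basis_1d(n, t) for n in range(max_order + 1)])


@dataclasses.dataclass(frozen=True)
class MapMriEAP:
    """MAP-MRI propagator: Hermite-function expansion in a tensor frame.

    The density at a point ``R`` in the measurement frame is evaluated in the
    rotated frame ``R' = U^T R`` as::

        P(R') = sum_{n1+n2+n3 even} a_{n1 n2 n3}
                H_{n1}(x'; sx) H_{n2}(y'; sy) H_{n3}(z'; sz)

    Truncated expansions may dip slightly below zero; callers that sample
    must tolerate this (the rejection sampler crops negative lobes).
    """

    coefficients: np.ndarray  # (m,)
    indices: np.ndarray       # (m, 3) non-negative ints, even total order
    scales: np.ndarray        # (3,) mm, strictly positive
    U: np.ndarray             # (3, 3) rotation
    tau: float                # s

    def __post_init__(self):
        coeff = np.asarray(self.coefficients, dtype=float).ravel()
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] != coeff.size:
            raise ValueError("indices must be (m, 3) matching the coefficients")
        if np.any(idx < 0):
            raise ValueError("negative Hermite orders")
        if np.any(idx.sum(axis=1) % 2):
            raise ValueError("only even total orders are allowed (antipodal symmetry)")
        scales = np.asarray(self.scales, dtype=float).ravel()
        if scales.shape != (3,) or np.any(scales <= 0):
            raise ValueError("scales must be three strictly positive lengths")
        U = np.asarray(self.U, dtype=float)
        if U.shape != (3, 3) or not np.allclose(U @ U.T, np.eye(3), atol=1e-10):
            raise ValueError("U must be a 3x3 rotation matrix")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        object.__setattr__(self, "coefficients", coeff)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "U", U)

    @property
    def nmax(self) -> int:
        return int(self.indices.sum(axis=1).max(initial=0))

    @classmethod
    def from_tensor(cls, model: DiffusionTensorModel, tau: float,
                    coefficients=None, indices=None) -> "MapMriEAP":
        """Build an EAP in the frame/scales of a tensor (Gaussian if a000 = 1 only)."""
        U, sx, sy, sz = dt_spectrum_to_frame(model, tau)
        if np.any(np.array([sx, sy, sz]) <= 0):
            raise InvalidTensorError("tensor must be positive definite")
        if coefficients is None:
            coefficients = np.array([1.0])
            indices = np.array([[0, 0, 0]])
        return cls(coefficients, indices, np.array([sx, sy, sz]), U, tau)

    # -- evaluation --------------------------------------------------------

    def pdf_normalized(self, t):
        """Density in normalized coordinates ``t_i = x'_i / s_i`` (unit scales).

        This is the scale-free target used by the rejection sampler; the
        density in the rotated frame is ``pdf_normalized(R'/s) / prod(s)``.
        """
        t = np.asarray(t, dtype=float)
        pts = t.reshape(-1, 3)
        B = [_basis_matrix(pts[:, ax], self.nmax) for ax in range(3)]
        out = np.zeros(pts.shape[0])
        for a, (n1, n2, n3) in zip(self.coefficients, self.indices):
            out += a * B[0][n1] * B[1][n2] * B[2][n3]
        return out.reshape(t.shape[:-1])

    def pdf_rotated(self, Rp):
        Rp = np.asarray(Rp, dtype=float)
        return self.pdf_normalized(Rp / self.scales) / np.prod(self.scales)

    def pdf(self, R):
        """Density at displacements ``R`` (mm) in the measurement frame."""
        R = np.asarray(R, dtype=float)
        return self.pdf_rotated(R @ self.U)  # R' = U^T R

    def grid_eval_normalized(self, tx, ty, tz) -> np.ndarray:
        """Evaluate the normalized density on a product grid (separable, fast)."""
        Bx = _basis_matrix(np.asarray(tx, float), self.nmax)
        By = _basis_matrix(np.asarray(ty, float), self.nmax)
        Bz = _basis_matrix(np.asarray(tz, float), self.nmax)
        out = np.zeros((Bx.shape[1], By.shape[1], Bz.shape[1]))
        for a, (n1, n2, n3) in zip(self.coefficients, self.indices):
            out += a * Bx[n1][:, None, None] * By[n2][None, :, None] * Bz[n3][None, None, :]
        return out

    def mass(self, extent: float = 12.0, step: float = 0.01) -> float:
        """Total probability mass by 1D quadrature of each Hermite factor."""
        t = np.arange(-extent, extent + step, step)
        ints = np.array([np.trapezoid(hermite_basis_1d(n, t), t)
                         for n in range(self.nmax + 1)])
        m = 0.0
        for a, (n1, n2, n3) in zip(self.coefficients, self.indices):
            m += a * ints[n1] * ints[n2] * ints[n3]
        return float(m)

    def normalized(self) -> "MapMriEAP":
        """Return a copy rescaled to unit total mass."""
        m = self.mass()
        if m <= 0:
            raise ValueError("non-positive total mass; cannot normalize")
        return dataclasses.replace(self, coefficients=self.coefficients / m)


# ---------------------------------------------------------------------------
# Real symmetric spherical harmonics and the fODF
# ---------------------------------------------------------------------------

def sh_index_set(L: int):
    """(l, m) pairs for even l <= L, m = -l..l; 28 pairs for L = 6."""
    if L < 0 or L % 2:
        raise ValueError("L must be a non-negative even integer")
    return [(l, m) for l in range(0, L + 1, 2) for m in range(-l, l + 1)]


def sh_basis(l: int, m: int, theta, phi):
    """Real symmetric spherical-harmonic basis function.

    ``Y_lm = sqrt((2l+1)/(2 pi) (l-|m|)!/(l+|m|)!) P_l^{|m|}(cos theta) T(m phi)``
    where ``T`` is sin for m > 0, cos for m < 0 and 2^-1/2 for m = 0.  The
    Condon–Shortley phase is excluded; the basis is orthonormal under the
    sphere measure ``sin(theta) dtheta dphi``.
    """
    if l < 0 or l % 2:
        raise ValueError("degree l must be even and non-negative")
    if abs(m) > l:
        raise ValueError("|m| must not exceed l")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    am = abs(m)
    log_ratio = special.gammaln(l - am + 1) - special.gammaln(l + am + 1)
    norm = np.sqrt((2 * l + 1) / (2.0 * np.pi) * np.exp(log_ratio))
    # scipy's lpmv includes the Condon-Shortley phase; remove it
    P = special.lpmv(am, l, np.cos(theta)) * ((-1.0) ** am)
    if m > 0:
        T = np.sin(m * phi)
    elif m < 0:
        T = np.cos(m * phi)
    else:
        T = np.broadcast_to(1.0 / np.sqrt(2.0), np.broadcast(theta, phi).shape)
    return norm * P * T


def sh_basis_matrix(L: int, theta, phi) -> np.ndarray:
    """Stacked basis values, shape ``(n_coeff,) + broadcast(theta, phi).shape``."""
    return np.stack([sh_basis(l, m, theta, phi) for l, m in sh_index_set(L)])


@dataclasses.dataclass(frozen=True)
class ShCoefficients:
    """fODF coefficients in (l ascending, m = -l..l) order for even l <= L."""

    values: np.ndarray
    L: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        n = len(sh_index_set(self.L))
        if values.size != n:
            raise ValueError(f"expected {n} coefficients for L={self.L}, got {values.size}")
        object.__setattr__(self, "values", values)

    def __call__(self, theta, phi):
        return fodf_eval(self, theta, phi)

    def mass(self) -> float:
        """Total spherical mass; equals ``phi_00 * sqrt(4 pi)`` by orthogonality."""
        return float(self.values[0] * np.sqrt(4.0 * np.pi))


def fodf_eval(coeffs: ShCoefficients, theta, phi):
    """Evaluate the fODF (antipodally symmetric since only even l are present)."""
    B = sh_basis_matrix(coeffs.L, theta, phi)
    return np.tensordot(coeffs.values, B, axes=1)


def sphere_quadrature(n_theta: int, n_phi: int):
    """Gauss–Legendre (theta) x trapezoid (phi) product rule on the sphere.

    Returns ``(theta, phi, w_theta)``; the integral of f over the sphere is
    ``sum_i sum_j w_theta[i] * f(theta[i], phi[j])`` (the phi weight
    ``2 pi / n_phi`` is folded into ``w_theta``).  Exact for integrands
    band-limited to degree ``2 n_theta - 1`` in cos(theta) and harmonic
    order ``< n_phi / 2`` in phi.
    """
    u, wu = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(u)
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    return theta, phi, wu * (2.0 * np.pi / n_phi)


def sphere_nodes(n_theta: int, n_phi: int):
    """Flattened quadrature nodes: unit vectors (n, 3), weights (n,), angles."""
    theta, phi, w = sphere_quadrature(n_theta, n_phi)
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    v = np.stack([np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH)], axis=-1)
    W = np.repeat(w, n_phi)
    return v.reshape(-1, 3), W, TH.ravel(), PH.ravel()


# ---------------------------------------------------------------------------
# Spherical convolution EAP
# ---------------------------------------------------------------------------

def sc_kernel_tensor(v, lambda_par: float, lambda_perp: float) -> np.ndarray:
    """Axisymmetric kernel tensor ``D(v) = lam_perp I + (lam_par - lam_perp) v v^T``."""
    v = np.asarray(v, dtype=float)
    return lambda_perp * np.eye(3) + (lambda_par - lambda_perp) * np.outer(v, v)


@dataclasses.dataclass(frozen=True)
class ScEAP:
    """Spherical-convolution EAP: fODF-weighted mixture of Gaussian kernels."""

    fodf: ShCoefficients
    lambda_par: float   # mm^2/s
    lambda_perp: float  # mm^2/s
    tau: float          # s

    def __post_init__(self):
        if not (self.lambda_par >= self.lambda_perp > 0):
            raise InvalidKernelError(
                f"kernel eigenvalues must satisfy lambda_par >= lambda_perp > 0, "
                f"got ({self.lambda_par}, {self.lambda_perp})"
            )
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if abs(self.fodf.mass() - 1.0) > 1e-6:
            warnings.warn(
                f"fODF mass is {self.fodf.mass():.6g}, not 1; the density will "
                "not integrate to 1", stacklevel=2,
            )

    def pdf(self, R, n_theta: int = 48, n_phi: int = 96,
            clip_negative: bool = False):
        """Density by spherical quadrature of fODF x Gaussian kernel.

        With ``clip_negative`` the (truncation-artifact) negative fODF lobes
        are cropped at the quadrature nodes and the weights renormalized to
        unit mass — this is the distribution the orientation sampler
        actually draws from.
        """
        R = np.asarray(R, dtype=float)
        pts = R.reshape(-1, 3)
        v, W, TH, PH = sphere_nodes(n_theta, n_phi)
        f = fodf_eval(self.fodf, TH, PH)
        if clip_negative:
            f = np.clip(f, 0.0, None)
            f = f / np.sum(W * f)
        weights = W * f
        norm = (4.0 * np.pi * self.tau) ** 1.5 * np.sqrt(
            self.lambda_par * self.lambda_perp ** 2)
        out = np.empty(pts.shape[0])
        chunk = 8192  # bound the (points x nodes) kernel matrix
        for lo in range(0, pts.shape[0], chunk):
            p = pts[lo:lo + chunk]
            dots = p @ v.T                        # (chunk, m)
            r2 = np.sum(p * p, axis=-1)[:, None]
            quad = (r2 - dots ** 2) / self.lambda_perp + dots ** 2 / self.lambda_par
            out[lo:lo + chunk] = np.exp(-quad / (4.0 * self.tau)) @ weights / norm
        return out.reshape(R.shape[:-1])


def sc_eap_pdf(R, eap: ScEAP, **kwargs):
    """Functional form of :meth:`ScEAP.pdf` (quadrature density oracle)."""
    return eap.pdf(R, **kwargs)


def mapmri_eap_pdf(Rprime, eap: MapMriEAP):
    """MAP-MRI density at points given in the rotated (eigen) frame."""
    return eap.pdf_rotated(Rprime)
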