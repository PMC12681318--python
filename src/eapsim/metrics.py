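"""Validation metrics for simulated diffusion-weighted images.

Three-fold quality assessment: (i) DTI color-orientation maps fitted per
simulation, (ii) pixelwise Pearson correlation maps with Fisher-transformed
unilateral level tests, and (iii) shell-wise normalized mean squared error
(NMSE).  Also provides the ideal-spin-echo proton-density estimate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .eap import DiffusionTensorModel, InvalidTensorError


# ---------------------------------------------------------------------------
# Shell grouping
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ShellGrouping:
    """Maps each non-baseline gradient to exactly one shell."""

    b_values: np.ndarray            # (n_shell,) representative b per shell
    indices: tuple                  # tuple of index arrays into the volume axis

    @classmethod
    def from_bvals(cls, bvals, b0_threshold: float = 10.0,
                   rtol: float = 0.05) -> "ShellGrouping":
        bvals = np.asarray(bvals, dtype=float).ravel()
        remaining = np.nonzero(bvals > b0_threshold)[0]
        shells = []
        used = np.zeros(bvals.size, dtype=bool)
        for i in remaining:
            if used[i]:
                continue
            members = remaining[np.abs(bvals[remaining] - bvals[i])
                                <= rtol * bvals[i]]
            used[members] = True
            shells.append((float(np.mean(bvals[members])), members))
        shells.sort(key=lambda t: t[0])
        return cls(np.array([b for b, _ in shells]),
                   tuple(idx for _, idx in shells))

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(ix) for ix in self.indices])

    def __len__(self) -> int:
        return len(self.b_values)


# ---------------------------------------------------------------------------
# NMSE and scale normalization
# ---------------------------------------------------------------------------

def nmse(S_sim, S_ref, shells: ShellGrouping) -> np.ndarray:
    """Per-pixel, per-shell normalized mean squared error.

    ``NMSE = sum_j (S_sim - S_ref)^2 / sum_j S_ref^2`` over the gradients of
    each shell; pixels with zero reference energy get NaN.
    """
    S_sim = np.asarray(S_sim, dtype=float)
    S_ref = np.asarray(S_ref, dtype=float)
    if S_sim.shape != S_ref.shape:
        raise ValueError("simulated and reference stacks must share a shape")
    out = np.empty(S_sim.shape[:-1] + (len(shells),))
    for k, idx in enumerate(shells.indices):
        num = np.sum((S_sim[..., idx] - S_ref[..., idx]) ** 2, axis=-1)
        den = np.sum(S_ref[..., idx] ** 2, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[..., k] = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def normalize_scale(S_sim, S_ref):
    """Global least-squares intensity calibration of a simulated stack.

    Returns ``(alpha * S_sim, alpha)`` with ``alpha = sum(S_sim S_ref) /
    sum(S_sim^2)`` minimizing ``sum (alpha S_sim - S_ref)^2``.  A single
    factor is applied to the whole stack.
    """
    S_sim = np.asarray(S_sim, dtype=float)
    S_ref = np.asarray(S_ref, dtype=float)
    denom = float(np.sum(S_sim ** 2))
    if denom == 0.0:
        raise ValueError("all-zero simulated stack cannot be scale-normalized")
    alpha = float(np.sum(S_sim * S_ref)) / denom
    return alpha * S_sim, alpha


# ---------------------------------------------------------------------------
# Pearson / Fisher correlation maps
# ---------------------------------------------------------------------------

DEFAULT_LEVELS = (0.5, 0.6, 0.7, 0.8, 0.9)

#: color-temperature bins for accepted levels [0.5,0.6) ... [0.9,1]
LEVEL_COLORS = {
    0.5: (0.0, 0.0, 1.0),   # blue
    0.6: (0.0, 0.8, 0.0),   # green
    0.7: (1.0, 1.0, 0.0),   # yellow
    0.8: (1.0, 0.0, 0.0),   # red
    0.9: (0.6, 0.0, 0.8),   # purple
}


@dataclasses.dataclass
class CorrelationMap:
    """Per-pixel Pearson r and maximum accepted correlation level per shell.

    ``accepted`` holds the largest tested level passing the unilateral
    Fisher test (0 where even the smallest level fails — rendered black);
    ``undefined`` flags zero-variance pixels.
    """

    r: np.ndarray           # (..., n_shell)
    accepted: np.ndarray    # (..., n_shell)
    undefined: np.ndarray   # (..., n_shell) bool
    levels: tuple
    alpha: float

    def colors(self, shell: int) -> np.ndarray:
        """RGB rendering of one shell's accepted-level map (black = none)."""
        acc = self.accepted[..., shell]
        rgb = np.zeros(acc.shape + (3,))
        for level, color in LEVEL_COLORS.items():
            rgb[np.isclose(acc, level)] = color
        return rgb


def fisher_accepted_levels(r, n_per_shell, levels=DEFAULT_LEVELS,
                           alpha: float = 0.05,
                           direction: str = "accept_high"):
    """Largest correlation level accepted by the unilateral Fisher test.

    With ``direction='accept_high'`` (default) a level ``rho0`` is accepted
    when H0: rho >= rho0 is *not rejected* against rho < rho0, i.e. when
    ``atanh(r) >= atanh(rho0) + Phi^-1(alpha) / sqrt(n - 3)``.  With
    ``direction='reject_low'`` the level is accepted when H0: rho <= rho0
    is rejected in favor of rho > rho0.  Either rule is downward closed in
    ``rho0``.
    """
    r = np.asarray(r, dtype=float)
    levels = tuple(sorted(levels))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    z = np.where(r >= 1.0, np.inf, z)
    se = 1.0 / np.sqrt(np.asarray(n_per_shell, dtype=float) - 3.0)
    accepted = np.zeros(r.shape)
    for rho0 in levels:
        if direction == "accept_high":
            ok = z >= np.arctanh(rho0) + stats.norm.ppf(alpha) * se
        elif direction == "reject_low":
            ok = z > np.arctanh(rho0) + stats.norm.ppf(1.0 - alpha) * se
        else:
            raise ValueError(f"unknown direction {direction!r}")
        accepted = np.where(ok & np.isfinite(r), rho0, accepted)
    accepted = np.where(np.isnan(r), 0.0, accepted)
    return accepted


def correlation_map(S_sim, S_ref, shells: ShellGrouping,
                    levels=DEFAULT_LEVELS, alpha: float = 0.05,
                    direction: str = "accept_high") -> CorrelationMap:
    """Pixelwise Pearson correlation across each shell's gradients.

    For every pixel the vector of DWI values across the shell's gradients in
    the simulation is correlated with the reference; the Fisher-transformed
    unilateral test assigns the largest accepted level in ``levels``.
    """
    S_sim = np.asarray(S_sim, dtype=float)
    S_ref = np.asarray(S_ref, dtype=float)
    if S_sim.shape != S_ref.shape:
        raise ValueError("stacks must share a shape")
    if np.any(shells.counts < 4):
        raise ValueError("each shell needs at least 4 gradients for the Fisher test")
    shape = S_sim.shape[:-1]
    r = np.empty(shape + (len(shells),))
    undefined = np.zeros(shape + (len(shells),), dtype=bool)
    for k, idx in enumerate(shells.indices):
        a = S_sim[..., idx]
        b = S_ref[..., idx]
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean(axis=-1, keepdims=True)
        va = np.sum(a * a, axis=-1)
        vb = np.sum(b * b, axis=-1)
        bad = (va <= 0) | (vb <= 0)
        undefined[..., k] = bad
        with np.errstate(divide="ignore", invalid="ignore"):
            rk = np.sum(a * b, axis=-1) / np.sqrt(va * vb)
        r[..., k] = np.where(bad, np.nan, np.clip(rk, -1.0, 1.0))
    accepted = np.empty_like(r)
    for k, idx in enumerate(shells.indices):
        accepted[..., k] = fisher_accepted_levels(
            r[..., k], len(idx), levels=levels, alpha=alpha, direction=direction)
    return CorrelationMap(r, accepted, undefined, tuple(sorted(levels)), alpha)


# ---------------------------------------------------------------------------
# DTI fitting and orientation color maps
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DtiFit:
    """Log-linear least-squares tensor fit per pixel."""

    tensors: np.ndarray     # (..., 3, 3)
    fa: np.ndarray          # (...,)
    md: np.ndarray          # (...,)
    principal: np.ndarray   # (..., 3) principal eigenvector
    s0: np.ndarray          # (...,) fitted baseline
    valid: np.ndarray       # (...,) bool; False where signals were unusable


def _dti_design(bvals, bvecs):
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)
    X = np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2.0 * b * g[:, 0] * g[:, 1],
        -2.0 * b * g[:, 0] * g[:, 2],
        -2.0 * b * g[:, 1] * g[:, 2],
    ])
    return X


def fit_dti(signals, bvals, bvecs, b_max: float | None = None,
            b_min: float = 0.0) -> DtiFit:
    """Unweighted log-linear least-squares DTI fit.

    ``ln S = ln S0 - b g^T D g`` is solved per pixel over all entries with
    ``b <= b_max`` (plus baselines); exact on noise-free mono-exponential
    data.  Pixels with any non-positive selected signal are excluded
    (``valid = False``, NaN outputs).  Eigenvalues are clipped at zero
    before computing FA.
    """
    S = np.asarray(signals, dtype=float)
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    sel = np.ones(bvals.size, dtype=bool)
    if b_max is not None:
        sel &= (bvals <= b_max) | (bvals <= 1e-6)
    sel &= (bvals >= b_min) | (bvals <= 1e-6)
    if np.count_nonzero(sel & (bvals > 1e-6)) < 6:
        raise ValueError("need at least 6 diffusion-weighted entries to fit a tensor")
    X = _dti_design(bvals[sel], bvecs[sel])
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("gradient scheme is rank deficient (collinear directions)")
    shape = S.shape[:-1]
    Y = S[..., sel].reshape(-1, int(sel.sum()))
    valid = np.all(Y > 0, axis=-1)
    beta = np.full((Y.shape[0], 7), np.nan)
    if np.any(valid):
        sol, *_ = np.linalg.lstsq(X, np.log(Y[valid]).T, rcond=None)
        beta[valid] = sol.T
    tensors = np.full((Y.shape[0], 3, 3), np.nan)
    fa = np.full(Y.shape[0], np.nan)
    md = np.full(Y.shape[0], np.nan)
    principal = np.full((Y.shape[0], 3), np.nan)
    s0 = np.full(Y.shape[0], np.nan)
    for i in np.nonzero(valid)[0]:
        d = beta[i, 1:]
        Dm = np.array([[d[0], d[3], d[4]],
                       [d[3], d[1], d[5]],
                       [d[4], d[5], d[2]]])
        lam, vec = np.linalg.eigh(Dm)
        lam = np.clip(lam, 0.0, None)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        tensors[i] = vec @ np.diag(lam) @ vec.T
        md[i] = lam.mean()
        denom = np.sqrt(np.sum(lam ** 2))
        fa[i] = (np.sqrt(1.5 * np.sum((lam - lam.mean()) ** 2)) / denom
                 if denom > 0 else 0.0)
        principal[i] = vec[:, 0]
        s0[i] = np.exp(beta[i, 0])
    return DtiFit(
        tensors.reshape(shape + (3, 3)), fa.reshape(shape), md.reshape(shape),
        principal.reshape(shape + (3,)), s0.reshape(shape), valid.reshape(shape),
    )


def color_orientation_map(fit: DtiFit) -> np.ndarray:
    """FA-weighted RGB map of the principal eigenvector.

    Red maps to |e1_x| (right-left), green to |e1_y| (anterior-posterior)
    and blue to |e1_z| (inferior-superior); e1 and -e1 give the same color.
    """
    rgb = np.abs(fit.principal) * fit.fa[..., None]
    rgb = np.where(np.isfinite(rgb), rgb, 0.0)
    return np.clip(rgb, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Proton-density estimation
# ---------------------------------------------------------------------------

def estimate_pd(S, T1, T2, TE: float, TR: float, floor: float = 1e-12):
    """Ideal-spin-echo proton density ``rho = S / ((1 - e^(-TR/T1)) e^(-TE/T2))``.

    Returns ``(rho, stable)``; pixels whose relaxation factor falls below
    ``floor`` are flagged unstable and set to NaN.
    """
    S = np.asarray(S, dtype=float)
    if np.any(np.asarray(T1, dtype=float) <= 0) or np.any(np.asarray(T2, dtype=float) <= 0):
        raise ValueError("T1 and T2 must be positive")
    denom = (1.0 - np.exp(-TR / np.asarray(T1, dtype=float))) * \
        np.exp(-TE / np.asarray(T2, dtype=float))
    denom = np.broadcast_to(denom, S.shape)
    stable = denom > floor
    rho = np.where(stable, S / np.where(stable, denom, 1.0), np.nan)
    return rho, stable
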