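"""Shared fixtures: canonical EAPs and independent distribution oracles.

The marginal-CDF builders here are deliberately independent of the sampling
code paths they are used to check: MAP-MRI marginals come from 1D
quadratures of the Hermite factors, spherical-convolution marginals from
the kernel-mixture structure evaluated on a dense spherical quadrature.
"""

import numpy as np
import pytest
from scipy import stats

from eapsim import (
    DiffusionTensorModel,
    MapMriEAP,
    ScEAP,
    SequenceTiming,
)
from eapsim.eap import fodf_eval, hermite_basis_1d, sphere_nodes
from eapsim.phantom import nongaussian_mapmri, symmetric_peak_fodf

TAU = SequenceTiming().tau  # 0.0557 - 0.0166/3 s


@pytest.fixture(scope="session")
def timing():
    return SequenceTiming()


@pytest.fixture(scope="session")
def tau():
    return TAU


@pytest.fixture(scope="session")
def iso_tensor():
    return DiffusionTensorModel(1e-3 * np.eye(3))


@pytest.fixture(scope="session")
def prolate_tensor():
    return DiffusionTensorModel(np.diag([2.0e-3, 0.5e-3, 0.5e-3]))


@pytest.fixture(scope="session")
def oblate_tensor():
    return DiffusionTensorModel(np.diag([1.5e-3, 1.5e-3, 0.3e-3]))


@pytest.fixture(scope="session")
def anisotropic_tensor():
    return DiffusionTensorModel(np.diag([2.0e-3, 1.0e-3, 0.5e-3]))


@pytest.fixture(scope="session")
def nongaussian_eap():
    return nongaussian_mapmri(tau=TAU)


@pytest.fixture(scope="session")
def two_fiber_sc():
    fodf = symmetric_peak_fodf(
        [[1.0, 0.0, 0.0], [0.5, np.sqrt(3.0) / 2.0, 0.0]], kappa=5.0, L=6)
    return ScEAP(fodf, 2.0e-3, 0.5e-3, TAU)


# ---------------------------------------------------------------------------
# Independent marginal-CDF oracles
# ---------------------------------------------------------------------------

def mapmri_marginal_cdf(eap: MapMriEAP, axis: int, extent: float = 10.0,
                        n_grid: int = 4001):
    """CDF of one normalized coordinate of a MAP-MRI EAP.

    Marginalizes the triple Hermite product semi-analytically: the two
    integrated axes reduce to 1D quadratures of single Hermite factors.
    """
    tq = np.linspace(-14.0, 14.0, 14001)
    ints = np.array([np.trapezoid(hermite_basis_1d(n, tq), tq)
                     for n in range(eap.nmax + 1)])
    t = np.linspace(-extent, extent, n_grid)
    pdf = np.zeros_like(t)
    other = [a for a in range(3) if a != axis]
    for a, idx in zip(eap.coefficients, eap.indices):
        pdf += (a * ints[idx[other[0]]] * ints[idx[other[1]]]
                * hermite_basis_1d(idx[axis], t))
    pdf = np.clip(pdf, 0.0, None)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(t))])
    cdf /= cdf[-1]

    def F(x):
        return np.interp(x, t, cdf)

    return F


def sc_marginal_cdf(eap: ScEAP, axis: int, n_theta: int = 32, n_phi: int = 64):
    """CDF of one lab-frame displacement component of an SC EAP.

    Uses the mixture structure: conditional on orientation v the component
    is N(0, 2 tau (lam_perp + (lam_par - lam_perp)(v.e)^2)); fODF weights
    are cropped at zero like the sampler does.
    """
    v, W, TH, PH = sphere_nodes(n_theta, n_phi)
    f = np.clip(fodf_eval(eap.fodf, TH, PH), 0.0, None)
    w = W * f
    w /= w.sum()
    var = 2.0 * eap.tau * (eap.lambda_perp
                           + (eap.lambda_par - eap.lambda_perp) * v[:, axis] ** 2)
    sig = np.sqrt(var)
    # tabulate the smooth mixture CDF once and interpolate
    from scipy.special import ndtr
    xg = np.linspace(-10 * sig.max(), 10 * sig.max(), 8001)
    cdf = ndtr(xg[:, None] / sig[None, :]) @ w

    def F(x):
        return np.interp(np.asarray(x, dtype=float), xg, cdf)

    return F


def gaussian_marginal_cdf(model: DiffusionTensorModel, tau: float, axis: int):
    """CDF of one lab-frame component of the Gaussian propagator."""
    sig = np.sqrt(2.0 * tau * model.D[axis, axis])
    return lambda x: stats.norm.cdf(np.asarray(x, dtype=float) / sig)
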