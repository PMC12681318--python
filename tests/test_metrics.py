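"""Validation metrics: NMSE, scale calibration, Fisher maps, DTI, PD."""

import numpy as np
import pytest
from scipy import stats

from eapsim import (
    ShellGrouping,
    color_orientation_map,
    correlation_map,
    estimate_pd,
    fit_dti,
    nmse,
    normalize_scale,
)
from eapsim.metrics import DtiFit, fisher_accepted_levels
from eapsim.phantom import make_gradient_table


@pytest.fixture(scope="module")
def toy_shells():
    bvals = np.array([0.0, 600, 600, 600, 600, 600, 2000, 2000, 2000, 2000, 2000])
    return bvals, ShellGrouping.from_bvals(bvals)


def brute_force_nmse(S_sim, S_ref, shell_indices):
    out = np.empty(S_sim.shape[:-1] + (len(shell_indices),))
    it = np.ndindex(S_sim.shape[:-1])
    for pix in it:
        for k, idx in enumerate(shell_indices):
            num = sum((S_sim[pix][j] - S_ref[pix][j]) ** 2 for j in idx)
            den = sum(S_ref[pix][j] ** 2 for j in idx)
            out[pix + (k,)] = num / den
    return out


def brute_force_pearson(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = np.sqrt(sum((x - ma) ** 2 for x in a))
    db = np.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


class TestShellGrouping:
    def test_every_gradient_in_exactly_one_shell(self, toy_shells):
        bvals, shells = toy_shells
        all_idx = np.concatenate(shells.indices)
        assert sorted(all_idx) == list(range(1, 11))  # b=0 excluded
        assert list(shells.b_values) == [600.0, 2000.0]
        assert list(shells.counts) == [5, 5]


class TestNmse:
    def test_identical_stacks_zero(self, toy_shells):
        bvals, shells = toy_shells
        S = np.random.default_rng(0).uniform(1, 2, (3, 4, 11))
        assert np.all(nmse(S, S, shells) == 0.0)

    def test_doubled_signal_unit_error(self, toy_shells):
        bvals, shells = toy_shells
        S = np.random.default_rng(1).uniform(1, 2, (2, 2, 11))
        np.testing.assert_allclose(nmse(2 * S, S, shells), 1.0, rtol=1e-12)

    def test_single_gradient_shell_arithmetic(self):
        shells = ShellGrouping.from_bvals(np.array([0.0, 1000.0]))
        S_ref = np.array([[3.0, 2.0]])
        S_sim = np.array([[3.0, 2.5]])
        assert nmse(S_sim, S_ref, shells)[0, 0] == pytest.approx(0.25 / 4.0, rel=1e-14)

    def test_matches_bruteforce_to_machine_precision(self, toy_shells):
        bvals, shells = toy_shells
        rng = np.random.default_rng(2)
        S_sim = rng.uniform(0.5, 2.0, (4, 3, 11))
        S_ref = rng.uniform(0.5, 2.0, (4, 3, 11))
        fast = nmse(S_sim, S_ref, shells)
        slow = brute_force_nmse(S_sim, S_ref, shells.indices)
        np.testing.assert_allclose(fast, slow, rtol=1e-12)

    def test_zero_reference_energy_is_nan(self):
        shells = ShellGrouping.from_bvals(np.array([1000.0]))
        out = nmse(np.array([[1.0]]), np.array([[0.0]]), shells)
        assert np.isnan(out[0, 0])


class TestNormalizeScale:
    def test_recovers_proportionality(self):
        rng = np.random.default_rng(3)
        S_ref = rng.uniform(1, 2, (5, 7))
        scaled, alpha = normalize_scale(S_ref / 3.0, S_ref)
        assert alpha == pytest.approx(3.0, rel=1e-12)
        np.testing.assert_allclose(scaled, S_ref, rtol=1e-12)

    def test_already_matched_unit_factor(self):
        S = np.random.default_rng(4).uniform(1, 2, (4, 4))
        _, alpha = normalize_scale(S, S)
        assert alpha == pytest.approx(1.0, rel=1e-12)

    def test_orthogonal_inputs_zero_factor(self):
        S_sim = np.array([1.0, 0.0])
        S_ref = np.array([0.0, 1.0])
        _, alpha = normalize_scale(S_sim, S_ref)
        assert alpha == 0.0

    def test_all_zero_simulation_raises(self):
        with pytest.raises(ValueError):
            normalize_scale(np.zeros(5), np.ones(5))


class TestCorrelationMap:
    def test_proportional_signals_accept_highest_level(self, toy_shells):
        bvals, shells = toy_shells
        rng = np.random.default_rng(5)
        S_ref = rng.uniform(1, 2, (2, 2, 11))
        cmap = correlation_map(1.7 * S_ref, S_ref, shells)
        np.testing.assert_allclose(cmap.r, 1.0)
        assert np.all(cmap.accepted == 0.9)

    def test_anticorrelated_pixels_black(self, toy_shells):
        bvals, shells = toy_shells
        rng = np.random.default_rng(6)
        S_ref = rng.uniform(1, 2, (1, 1, 11))
        cmap = correlation_map(-S_ref, S_ref, shells)
        assert np.all(cmap.r < 0)
        assert np.all(cmap.accepted == 0.0)

    def test_accepted_levels_downward_closed(self, toy_shells):
        bvals, shells = toy_shells
        rng = np.random.default_rng(7)
        S_sim = rng.uniform(1, 2, (6, 6, 11))
        S_ref = 0.5 * S_sim + 0.5 * rng.uniform(1, 2, (6, 6, 11))
        cmap = correlation_map(S_sim, S_ref, shells)
        for rho0 in cmap.levels:
            acc_r = fisher_accepted_levels(cmap.r[..., 0], shells.counts[0],
                                           levels=(rho0,))
            # wherever rho0 itself is accepted, the map's level is >= rho0
            assert np.all(cmap.accepted[..., 0][acc_r == rho0] >= rho0)

    def test_pearson_matches_bruteforce(self, toy_shells):
        bvals, shells = toy_shells
        rng = np.random.default_rng(8)
        S_sim = rng.uniform(1, 2, (3, 2, 11))
        S_ref = rng.uniform(1, 2, (3, 2, 11))
        cmap = correlation_map(S_sim, S_ref, shells)
        for i in range(3):
            for j in range(2):
                for k, idx in enumerate(shells.indices):
                    ref = brute_force_pearson(list(S_sim[i, j, idx]),
                                              list(S_ref[i, j, idx]))
                    assert cmap.r[i, j, k] == pytest.approx(ref, rel=1e-12)

    def test_zero_variance_flagged_undefined(self, toy_shells):
        bvals, shells = toy_shells
        S_ref = np.ones((1, 1, 11))
        S_sim = np.random.default_rng(9).uniform(1, 2, (1, 1, 11))
        cmap = correlation_map(S_sim, S_ref, shells)
        assert np.all(cmap.undefined)
        assert np.all(cmap.accepted == 0.0)

    def test_fisher_type_one_error_calibrated(self):
        """At true rho = rho0 the unilateral test rejects ~alpha of the time."""
        rho0, alpha, n, reps = 0.5, 0.05, 100, 10000
        rng = np.random.default_rng(10)
        x = rng.standard_normal((reps, n))
        y = rho0 * x + np.sqrt(1 - rho0 ** 2) * rng.standard_normal((reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc ** 2).sum(axis=1)
                                            * (yc ** 2).sum(axis=1))
        accepted = fisher_accepted_levels(r, n, levels=(rho0,), alpha=alpha)
        reject_rate = np.mean(accepted < rho0)
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(reject_rate - alpha) < 3 * se

    def test_reject_low_direction_is_stricter(self):
        r = np.array([0.52, 0.75, 0.95])
        n = 50
        acc_hi = fisher_accepted_levels(r, n, direction="accept_high")
        acc_lo = fisher_accepted_levels(r, n, direction="reject_low")
        assert np.all(acc_lo <= acc_hi)


@pytest.fixture(scope="module")
def scheme():
    table = make_gradient_table(shells=(600.0, 1000.0), n_dirs=15, seed=11)
    return table.bvals, table.bvecs


class TestDtiFit:
    def test_noise_free_recovery_machine_precision(self, scheme):
        bvals, bvecs = scheme
        D = np.array([[1.8, 0.2, 0.1], [0.2, 1.0, -0.05], [0.1, -0.05, 0.6]]) * 1e-3
        S0 = 420.0
        S = S0 * np.exp(-bvals * np.einsum("ni,ij,nj->n", bvecs, D, bvecs))
        fit = fit_dti(S[None, :], bvals, bvecs)
        np.testing.assert_allclose(fit.tensors[0], D, atol=1e-16, rtol=1e-10)
        assert fit.s0[0] == pytest.approx(S0, rel=1e-12)

    def test_isotropic_signals_zero_fa(self, scheme):
        bvals, bvecs = scheme
        S = 100.0 * np.exp(-bvals * 1e-3)
        fit = fit_dti(S[None, :], bvals, bvecs)
        assert fit.fa[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.md[0] == pytest.approx(1e-3, rel=1e-10)

    def test_gradient_permutation_invariance(self, scheme):
        bvals, bvecs = scheme
        D = np.diag([2.0, 1.0, 0.5]) * 1e-3
        S = 50.0 * np.exp(-bvals * np.einsum("ni,ij,nj->n", bvecs, D, bvecs))
        perm = np.random.default_rng(12).permutation(len(bvals))
        a = fit_dti(S[None, :], bvals, bvecs)
        b = fit_dti(S[None, perm], bvals[perm], bvecs[perm])
        np.testing.assert_allclose(a.tensors, b.tensors, rtol=1e-9, atol=1e-15)

    def test_nonpositive_signals_excluded(self, scheme):
        bvals, bvecs = scheme
        S = np.ones((2, len(bvals)))
        S[1, 3] = 0.0
        fit = fit_dti(S, bvals, bvecs)
        assert fit.valid[0] and not fit.valid[1]
        assert np.all(np.isnan(fit.tensors[1]))

    def test_too_few_gradients_rejected(self):
        bvals = np.array([0.0, 1000, 1000, 1000])
        bvecs = np.vstack([np.zeros(3), np.eye(3)])
        with pytest.raises(ValueError):
            fit_dti(np.ones((1, 4)), bvals, bvecs)


class TestColorOrientationMap:
    def test_pure_red_for_x_fiber(self):
        fit = DtiFit(np.zeros((1, 3, 3)), np.array([1.0]), np.array([1e-3]),
                     np.array([[1.0, 0.0, 0.0]]), np.array([1.0]),
                     np.array([True]))
        np.testing.assert_allclose(color_orientation_map(fit)[0], [1, 0, 0])

    def test_zero_fa_black(self):
        fit = DtiFit(np.zeros((1, 3, 3)), np.array([0.0]), np.array([1e-3]),
                     np.array([[0.6, 0.8, 0.0]]), np.array([1.0]),
                     np.array([True]))
        np.testing.assert_allclose(color_orientation_map(fit)[0], [0, 0, 0])

    def test_sign_flip_invariant(self):
        e = np.array([[0.6, -0.8, 0.0]])
        a = DtiFit(np.zeros((1, 3, 3)), np.array([0.7]), np.array([1e-3]),
                   e, np.array([1.0]), np.array([True]))
        b = DtiFit(np.zeros((1, 3, 3)), np.array([0.7]), np.array([1e-3]),
                   -e, np.array([1.0]), np.array([True]))
        np.testing.assert_allclose(color_orientation_map(a),
                                   color_orientation_map(b))


class TestEstimatePd:
    def test_ideal_limits(self):
        rho, stable = estimate_pd(np.array([42.0]), T1=1.0, T2=0.05,
                                  TE=1e-9, TR=1e3)
        assert stable[0]
        assert rho[0] == pytest.approx(42.0, rel=1e-6)

    def test_printed_sequence_values(self):
        # S=100 with the default sequence timing (TR=50.033 s, TE=113.725 ms)
        rho, stable = estimate_pd(np.array([100.0]), T1=1.0, T2=0.05,
                                  TE=0.113725, TR=50.033)
        assert stable[0]
        assert rho[0] == pytest.approx(972.31, rel=1e-3)

    def test_monotone_in_te(self):
        tes = np.linspace(0.01, 0.2, 8)
        rhos = [estimate_pd(np.array([100.0]), 1.0, 0.05, te, 50.0)[0][0]
                for te in tes]
        assert np.all(np.diff(rhos) > 0)

    def test_unstable_pixels_flagged(self):
        rho, stable = estimate_pd(np.array([1.0]), T1=100.0, T2=0.001,
                                  TE=0.5, TR=0.001)
        assert not stable[0]
        assert np.isnan(rho[0])

    def test_nonpositive_relaxation_times_rejected(self):
        with pytest.raises(ValueError):
            estimate_pd(np.array([1.0]), T1=-1.0, T2=0.05, TE=0.1, TR=1.0)
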