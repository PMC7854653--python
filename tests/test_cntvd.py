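"""Constrained tensor-variate Gaussian: sampling, density, moments."""

import numpy as np
import pytest

from dtdmc.cntvd import (
    CNTVDParams,
    TensorEnsemble,
    empirical_moments,
    log_density,
    psd_mask,
    sample_cntvd,
)
from dtdmc.symmetry import isotropic_omega
from dtdmc.tensor_algebra import d6_to_matrix

MEAN_ISO = 0.8 * np.array([1, 1, 1, 0, 0, 0.0])


def test_params_validation():
    with pytest.raises(ValueError, match="positive semi-definite"):
        CNTVDParams(mean_d6=[1, 1, -0.5, 0, 0, 0], omega=np.zeros((6, 6)))
    with pytest.raises(ValueError, match="symmetric"):
        CNTVDParams(mean_d6=MEAN_ISO, omega=np.triu(np.ones((6, 6))))


def test_psd_mask_matches_eigenvalues(rng):
    d6 = rng.normal(scale=0.7, size=(2000, 6))
    mask = psd_mask(d6)
    eig = np.linalg.eigvalsh(d6_to_matrix(d6)).min(axis=1)
    np.testing.assert_array_equal(mask, eig >= -1e-9)


class TestSampling:
    def test_zero_covariance_degenerate(self):
        ens = sample_cntvd(CNTVDParams(MEAN_ISO, np.zeros((6, 6))), n=500, seed=0)
        assert ens.acceptance == 1.0
        np.testing.assert_array_equal(ens.d6, np.tile(MEAN_ISO, (500, 1)))

    def test_rank_one_trace_direction(self):
        """lambda-only isotropic covariance only moves the trace."""
        params = CNTVDParams(MEAN_ISO, isotropic_omega(0.01, 0.0))
        ens = sample_cntvd(params, n=2000, seed=1)
        dev = ens.d6 - MEAN_ISO
        # deviation is a multiple of the identity: off-diagonals zero, diagonals equal
        assert np.abs(dev[:, 3:]).max() < 1e-8
        assert np.abs(dev[:, :3] - dev[:, [0]]).max() < 1e-6

    def test_acceptance_against_bruteforce_oracle(self):
        # covariance strong enough that the cone boundary truncates real mass
        params = CNTVDParams(0.3 * MEAN_ISO, isotropic_omega(0.02, 0.01))
        big = sample_cntvd(params, n=1_000_000, seed=42)
        p_hat = big.acceptance
        se = np.sqrt(p_hat * (1 - p_hat) / 1_000_000)
        ens = sample_cntvd(params, n=50_000, seed=7)
        se_small = np.sqrt(p_hat * (1 - p_hat) / 50_000)
        assert abs(ens.acceptance - p_hat) < 3 * (se + se_small)

    def test_deterministic_for_fixed_seed(self):
        params = CNTVDParams(MEAN_ISO, isotropic_omega(0.02, 0.01))
        a = sample_cntvd(params, n=5000, seed=3)
        b = sample_cntvd(params, n=5000, seed=3)
        np.testing.assert_array_equal(a.d6, b.d6)
        assert a.n_proposed == b.n_proposed == 5000

    def test_all_samples_physical(self):
        params = CNTVDParams(MEAN_ISO, isotropic_omega(0.05, 0.03))
        ens = sample_cntvd(params, n=20_000, seed=9)
        lam = ens.eigenvalues()
        assert lam.min() >= -1e-9
        assert (ens.d6[:, :3].sum(axis=1) >= 0).all()

    def test_mass_outside_cone_errors(self):
        # support concentrated on tensors with one strictly negative eigenvalue
        u = np.array([1.0, -1.0, 0, 0, 0, 0])
        params = CNTVDParams(np.zeros(6), np.outer(u, u))
        with pytest.raises(RuntimeError, match="outside the PSD cone"):
            sample_cntvd(params, n=5000, seed=0)

    def test_low_acceptance_warns(self):
        params = CNTVDParams(0.05 * MEAN_ISO, isotropic_omega(0.0, 0.05))
        with pytest.warns(RuntimeWarning, match="low PSD acceptance"):
            sample_cntvd(params, n=20_000, seed=0)


class TestLogDensity:
    def test_nonphysical_is_minus_inf(self):
        params = CNTVDParams(MEAN_ISO, isotropic_omega(0.01, 0.01))
        assert log_density(params, [1, 1, -0.2, 0, 0, 0]) == -np.inf

    def test_mode_value_without_truncation(self):
        """Far from the cone boundary the density is the plain Gaussian."""
        omega = 1e-6 * np.eye(6)
        params = CNTVDParams(MEAN_ISO, omega)
        expected = -0.5 * np.log((2 * np.pi) ** 6 * np.linalg.det(omega))
        assert np.isclose(log_density(params, MEAN_ISO, seed=0), expected, rtol=1e-6)

    def test_density_integrates_to_one_over_cone(self):
        """MC integration with an independent Gaussian proposal stream."""
        params = CNTVDParams(0.3 * MEAN_ISO, 0.02 * np.eye(6))
        logp = lambda d: log_density(params, d, n_norm=1_000_000, seed=11)
        rng = np.random.default_rng(99)
        from dtdmc.tensor_algebra import sym_sqrt_psd

        root = sym_sqrt_psd(params.omega)
        draws = params.mean_d6 + rng.standard_normal((1_000_000, 6)) @ root.T
        mask = psd_mask(draws)
        # integral of p over the cone = E_gaussian[1_cone * p/q]; p/q = 1/p_acc
        p_acc_indep = mask.mean()
        quad_norm = np.exp(logp(params.mean_d6)) / np.exp(
            -0.5 * np.log((2 * np.pi) ** 6 * np.linalg.det(params.omega))
        )
        integral = p_acc_indep * quad_norm
        assert abs(integral - 1.0) < 0.01

    def test_singular_needs_flag(self):
        params = CNTVDParams(MEAN_ISO, isotropic_omega(0.01, 0.0))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            log_density(params, MEAN_ISO)
        val = log_density(params, MEAN_ISO, allow_singular=True, seed=0)
        assert np.isfinite(val)
        # off-support point has zero density
        off = MEAN_ISO + np.array([0.05, -0.05, 0, 0, 0, 0])
        assert log_density(params, off, allow_singular=True, seed=0) == -np.inf


class TestEmpiricalMoments:
    def test_identical_tensors_zero_covariance(self):
        ens = TensorEnsemble(np.tile(MEAN_ISO, (50, 1)), n_proposed=50)
        mean, omega = empirical_moments(ens)
        np.testing.assert_allclose(mean, MEAN_ISO)
        assert np.abs(omega).max() < 1e-30

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match="single sample"):
            empirical_moments(TensorEnsemble(MEAN_ISO[None, :], n_proposed=1))

    def test_recovers_sampling_distribution(self):
        """Negligible truncation: moments approach (mean, omega) at large n."""
        omega = isotropic_omega(0.01, 0.0)
        params = CNTVDParams(MEAN_ISO, omega)
        ens = sample_cntvd(params, n=200_000, seed=21)
        mean_hat, omega_hat = empirical_moments(ens)
        n = len(ens)
        se_mean = np.sqrt(np.diag(omega) / n)
        assert np.all(np.abs(mean_hat - MEAN_ISO) < 5 * se_mean + 1e-12)
        se_cov = (np.sqrt(np.outer(np.diag(omega), np.diag(omega))) + np.abs(omega)) / np.sqrt(n)
        assert np.all(np.abs(omega_hat - omega) < 5 * se_cov + 1e-9)

    def test_two_point_mixture_closed_form(self):
        """90-degree crossing: covariance is the dyad of the half-difference."""
        from dtdmc.phantoms import MotifSpec, make_motif

        ens, params = make_motif(MotifSpec(kind="crossing_90", n=10_000, seed=0))
        d1 = np.array([1.7, 0.2, 0.2, 0, 0, 0])
        d2 = np.array([0.2, 1.7, 0.2, 0, 0, 0])
        np.testing.assert_allclose(params.mean_d6, (d1 + d2) / 2, atol=1e-12)
        delta = (d1 - d2) / 2
        expected = np.outer(delta, delta) * 10_000 / 9_999  # n/(n-1) from ddof=1
        np.testing.assert_allclose(params.omega, expected, atol=1e-12)
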