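"""Forward signal models: MC, DTI, cumulant, kurtosis, Rician noise."""

import numpy as np
import pytest
from scipy import integrate, stats

from dtdmc.cntvd import CNTVDParams, sample_cntvd
from dtdmc.phantoms import MotifSpec, make_motif
from dtdmc.signal import (
    SignalDataset,
    add_noise,
    cumulant_signal,
    dti_signal,
    kurtosis_from_covariance,
    kurtosis_signal,
    mc_signal,
)
from dtdmc.symmetry import isotropic_omega
from dtdmc.tensor_algebra import omega_to_fourth_order

MEAN = np.array([0.9, 0.7, 0.5, 0.05, 0.02, 0.01])
OMEGA = isotropic_omega(0.02, 0.01)


@pytest.fixture(scope="module")
def params():
    return CNTVDParams(mean_d6=MEAN, omega=OMEGA, s0=1.0)


class TestMCSignal:
    def test_zero_covariance_equals_dti(self, small_design):
        p = CNTVDParams(MEAN, np.zeros((6, 6)), s0=0.9)
        s_mc = mc_signal(p, small_design, n=2000, seed=0)
        s_dti = dti_signal(MEAN, 0.9, small_design)
        np.testing.assert_allclose(s_mc, s_dti, atol=1e-12)

    def test_b0_returns_s0(self, params, small_design):
        s = mc_signal(params, small_design, n=5000, seed=0)
        assert np.isclose(s[0], params.s0)  # first design entry is the b=0 anchor

    def test_bounds(self, params, small_design):
        s = mc_signal(params, small_design, n=20_000, seed=1)
        assert (s >= 0).all() and (s <= params.s0 + 1e-12).all()

    def test_monotone_under_b_scaling(self, params, small_design):
        ens = sample_cntvd(params, n=20_000, seed=2)
        b6 = small_design.b6
        prev = None
        for c in [0.0, 0.5, 1.0, 2.0, 4.0]:
            s = np.exp(-(ens.d6 @ (c * b6).T)).mean(axis=0)
            if prev is not None:
                assert (s <= prev + 1e-12).all()
            prev = s

    def test_iso_emulsion_matches_quadrature(self, full_design):
        """1-D oracle: trace-distributed isotropic tensors by adaptive quadrature."""
        _, params = make_motif(MotifSpec(kind="iso_emulsion", n=150_000, seed=8))
        s_mc = mc_signal(params, full_design, n=200_000, seed=3)
        d_mean = params.mean_d6[0]
        d_sd = np.sqrt(params.omega[0, 0])
        traces = full_design.traces

        def signal_1d(btrace):
            f = lambda d: stats.norm.pdf(d, d_mean, d_sd) * np.exp(-btrace * d)
            num, _ = integrate.quad(f, 0, d_mean + 10 * d_sd)
            den = stats.norm.sf(0, d_mean, d_sd)
            return num / den

        s_quad = np.array([signal_1d(t) for t in traces])
        rel = np.abs(s_mc - s_quad) / s_quad
        assert rel.max() < 0.005


class TestDTISignal:
    def test_isotropic_depends_on_trace_only(self, small_design):
        d = 0.7
        s = dti_signal(d * np.array([1, 1, 1, 0, 0, 0.0]), 1.0, small_design)
        np.testing.assert_allclose(s, np.exp(-small_design.traces * d), atol=1e-12)

    def test_monotone_in_trace(self, small_design):
        base = np.array([1, 1, 1, 0, 0, 0.0])
        s1 = dti_signal(0.5 * base, 1.0, small_design)
        s2 = dti_signal(0.8 * base, 1.0, small_design)
        assert (s2 <= s1 + 1e-15).all()


class TestCumulantSignal:
    def test_zero_covariance_is_dti(self, small_design):
        p = CNTVDParams(MEAN, np.zeros((6, 6)))
        np.testing.assert_allclose(cumulant_signal(p, small_design), dti_signal(MEAN, 1.0, small_design))

    def test_small_b_third_order_agreement(self, params):
        """Relative deviation from the MC model shrinks as O(b^3)."""
        from dtdmc.acquisition import BMatrix, BMatrixDesign

        direction = np.diag([1.0, 0.0, 0.0])
        devs = []
        for b in (0.01, 0.02, 0.04):
            design = BMatrixDesign([BMatrix(b * direction, rank=1)], b_range=(0, 1), rank_mix=1.0)
            s_mc = mc_signal(params, design, n=400_000, seed=4)
            s_cu = cumulant_signal(params, design)
            devs.append(abs(s_mc[0] - s_cu[0]) / s_mc[0])
        # O(b^3): doubling b should multiply the deviation by ~8 (allow MC slop)
        assert devs[2] / max(devs[0], 1e-14) > 4

    def test_unphysical_increase_at_large_b(self, params):
        from dtdmc.acquisition import BMatrix, BMatrixDesign

        bmats = [BMatrix(b * np.diag([1.0, 0, 0]), rank=1) for b in (0.0, 20.0, 60.0)]
        design = BMatrixDesign(bmats, b_range=(0, 60), rank_mix=1.0)
        s = cumulant_signal(params, design)
        assert s[2] > s[0]  # eventually exceeds s0


class TestKurtosis:
    def test_zero_covariance_zero_kurtosis(self, small_design):
        p = CNTVDParams(MEAN, np.zeros((6, 6)))
        assert np.abs(kurtosis_from_covariance(p)).max() == 0.0

    def test_matches_bruteforce_symmetrization(self, params):
        k = kurtosis_from_covariance(params)
        c = omega_to_fourth_order(params.omega)
        tr = params.mean_d6[:3].sum()
        brute = np.zeros((3, 3, 3, 3))
        for i in range(3):
            for j in range(3):
                for kk in range(3):
                    for l in range(3):
                        brute[i, j, kk, l] = (c[i, j, kk, l] + c[i, kk, j, l] + c[i, l, j, kk]) / tr**2
        np.testing.assert_allclose(k, brute, atol=1e-12)

    def test_full_permutation_symmetry(self, rng):
        a = rng.normal(size=(6, 6))
        p = CNTVDParams(MEAN, a @ a.T * 0.01)
        k = kurtosis_from_covariance(p)
        import itertools

        for perm in itertools.permutations(range(4)):
            np.testing.assert_allclose(k, k.transpose(perm), atol=1e-12)

    def test_zero_trace_rejected(self, small_design):
        p = CNTVDParams(np.zeros(6), np.zeros((6, 6)))
        with pytest.raises(ValueError, match="trace"):
            kurtosis_from_covariance(p)

    def test_kurtosis_signal_exceeds_s0_at_large_b(self, params):
        from dtdmc.acquisition import BMatrix, BMatrixDesign

        bmats = [BMatrix(b * np.diag([1.0, 0, 0]), rank=1) for b in (0.0, 60.0)]
        design = BMatrixDesign(bmats, b_range=(0, 60), rank_mix=1.0)
        s = kurtosis_signal(params, design)
        assert s[1] > params.s0


def test_projection_identity(full_design):
    """b^T Omega b equals the variance of b . d over untruncated draws."""
    rng = np.random.default_rng(17)
    from dtdmc.tensor_algebra import sym_sqrt_psd

    root = sym_sqrt_psd(OMEGA)
    draws = MEAN + rng.standard_normal((200_000, 6)) @ root.T
    b6 = full_design.b6[1:]
    proj = draws @ b6.T
    var_hat = proj.var(axis=0, ddof=1)
    var_theory = np.einsum("ki,ij,kj->k", b6, OMEGA, b6)
    se = var_theory * np.sqrt(2.0 / 200_000)  # SE of a normal variance estimate
    assert np.all(np.abs(var_hat - var_theory) < 5 * se + 1e-12)


class TestNoise:
    def test_infinite_snr_identity(self, params, small_design):
        ds = SignalDataset(design=small_design, signal=dti_signal(MEAN, 1.0, small_design))
        out = add_noise(ds, np.inf, seed=0)
        np.testing.assert_array_equal(out.signal, ds.signal)

    def test_sigma_definition(self, small_design):
        sig = np.linspace(1.0, 0.1, len(small_design))
        ds = SignalDataset(design=small_design, signal=sig)
        out = add_noise(ds, 10.0, seed=1)
        traces = small_design.traces
        ref = sig[traces >= np.quantile(traces, 0.95)].mean()
        assert np.isclose(out.noise_sigma, ref / 10.0)

    def test_rayleigh_mean_at_zero_signal(self, small_design):
        rng_draws = 100_000
        sigma = 0.3
        rng = np.random.default_rng(5)
        mags = np.hypot(rng.normal(0, sigma, rng_draws), rng.normal(0, sigma, rng_draws))
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((2 - np.pi / 2) / rng_draws)
        assert abs(mags.mean() - expected) < 3 * se

    def test_rician_distribution(self):
        """KS test of the magnitude distribution at S = 5 sigma."""
        sigma, s_true, n = 0.1, 0.5, 100_000
        rng = np.random.default_rng(6)
        mags = np.hypot(s_true + rng.normal(0, sigma, n), rng.normal(0, sigma, n))
        p = stats.kstest(mags, stats.rice(b=s_true / sigma, scale=sigma).cdf).pvalue
        assert p > 0.01

    def test_invalid_snr(self, small_design):
        ds = SignalDataset(design=small_design, signal=np.ones(len(small_design)))
        with pytest.raises(ValueError, match="positive"):
            add_noise(ds, -3.0)
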