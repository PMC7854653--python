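"""Forward MR signal models and the Rician noise channel.

The reference forward model evaluates the tensor-distribution signal

    S(b) = S0 * E[ exp(-b6 . d6) ]

by Monte Carlo over CNTVD draws restricted to the PSD cone (one shared
ensemble across all b-matrices).  Being an average of decaying
exponentials it is bounded by S0 and monotonically non-increasing along
any ray of b-matrices — unlike the second-order cumulant and kurtosis
comparators, which blow up once the quadratic term dominates.

Noise is added on the real and imaginary channels before taking the
magnitude, producing Rician-distributed data; the noise level is set by
the SNR at the largest b-values (mean noiseless signal over the top-5%
trace measurements divided by the channel sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .acquisition import BMatrixDesign
from .cntvd import CNTVDParams, TensorEnsemble, sample_cntvd
from .tensor_algebra import (
    fourth_order_to_omega,
    omega_to_fourth_order,
)

__all__ = [
    "SignalDataset",
    "mc_signal",
    "ensemble_signal",
    "dti_signal",
    "cumulant_signal",
    "kurtosis_from_covariance",
    "kurtosis_signal",
    "add_noise",
]


@dataclass
class SignalDataset:
    """A design with the magnitude signal it produced (the estimator input)."""

    design: BMatrixDesign
    signal: np.ndarray
    snr: float = np.inf
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float).reshape(-1)
        if len(self.signal) != len(self.design):
            raise ValueError("signal length must match design length")
        if np.any(self.signal < 0):
            raise ValueError("signal magnitudes must be non-negative")


def ensemble_signal(ensemble: TensorEnsemble | np.ndarray, design: BMatrixDesign, s0: float = 1.0) -> np.ndarray:
    """Signal of an explicit micro-tensor ensemble (mean of exponentials)."""
    d6 = ensemble.d6 if isinstance(ensemble, TensorEnsemble) else np.atleast_2d(ensemble)
    b6 = design.b6
    return s0 * np.exp(-(d6 @ b6.T)).mean(axis=0)


def mc_signal(
    params: CNTVDParams,
    design: BMatrixDesign,
    n: int = 200_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Monte Carlo CNTVD signal; S(0) = s0 exactly, 0 <= S <= s0 always."""
    ensemble = sample_cntvd(params, n=n, seed=seed)
    return ensemble_signal(ensemble, design, s0=params.s0)


def dti_signal(mean_d6: np.ndarray, s0: float, design: BMatrixDesign) -> np.ndarray:
    """Single-tensor (zero-covariance) closed form S = s0 exp(-b6 . d6)."""
    mean_d6 = np.asarray(mean_d6, dtype=float).reshape(6)
    return s0 * np.exp(-(design.b6 @ mean_d6))


def cumulant_signal(params: CNTVDParams, design: BMatrixDesign) -> np.ndarray:
    """Second-order cumulant expansion ln(S/s0) = -b.Dbar + 0.5 b^T Omega b."""
    b6 = design.b6
    lin = b6 @ params.mean_d6
    quad = np.einsum("ki,ij,kj->k", b6, params.omega, b6)
    return params.s0 * np.exp(-lin + 0.5 * quad)


def kurtosis_from_covariance(params: CNTVDParams) -> np.ndarray:
    """Dimensionless kurtosis tensor K_ijkl = (C_ijkl + C_ikjl + C_iljk) / tr(Dbar)^2.

    Full symmetrization over index permutations discards the
    antisymmetric information the covariance carries.
    """
    tr = float(params.mean_d6[:3].sum())
    if tr <= 0:
        raise ValueError("mean trace must be positive")
    c = omega_to_fourth_order(params.omega)
    # C_ikjl and C_iljk as axis permutations: result[i,j,k,l] = c[i,k,j,l] / c[i,l,j,k]
    k = c + c.transpose(0, 2, 1, 3) + c.transpose(0, 2, 3, 1)
    return k / tr**2


def kurtosis_signal(params: CNTVDParams, design: BMatrixDesign) -> np.ndarray:
    """Cumulant form with the covariance replaced by its fully symmetric part.

    The kurtosis tensor retains only sym(C); the signal model is therefore
    ln(S/s0) = -b.Dbar + 0.5 b^T sym(Omega) b with sym(Omega) rebuilt from
    K * tr(Dbar)^2 / 3.
    """
    tr = float(params.mean_d6[:3].sum())
    k = kurtosis_from_covariance(params)
    sym_c = k * tr**2 / 3.0
    sym_params = CNTVDParams.__new__(CNTVDParams)  # bypass PSD check: sym part may be indefinite
    sym_params.mean_d6 = params.mean_d6
    sym_params.omega = fourth_order_to_omega(sym_c)
    sym_params.s0 = params.s0
    sym_params.symmetry_class = None
    return cumulant_signal(sym_params, design)


def add_noise(
    dataset: SignalDataset,
    snr: float,
    seed: int | np.random.Generator | None = None,
) -> SignalDataset:
    """Rician-corrupt a dataset at the requested SNR (infinity = identity).

    sigma is the mean signal over the top-5%-trace b-matrices divided by
    ``snr``; independent N(0, sigma^2) noise is added on the real and
    imaginary channels and the magnitude taken.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return replace(dataset, snr=np.inf, noise_sigma=0.0)
    rng = np.random.default_rng(seed)
    traces = dataset.design.traces
    cutoff = np.quantile(traces, 0.95)
    ref = float(dataset.signal[traces >= cutoff].mean())
    sigma = ref / snr
    eps1 = rng.normal(0.0, sigma, size=len(dataset.signal))
    eps2 = rng.normal(0.0, sigma, size=len(dataset.signal))
    mag = np.hypot(dataset.signal + eps1, eps2)
    return SignalDataset(design=dataset.design, signal=mag, snr=snr, noise_sigma=sigma)
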