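"""The constrained normal tensor-variate distribution (CNTVD).

A diffusion tensor distribution (DTD) is modeled as a 6-D Gaussian over
tensor components, truncated to the cone of positive-semidefinite 3x3
tensors: draw ``d6 ~ N(mean, omega)`` and keep only draws whose 3x3 form
has no negative eigenvalue.  The reported parameters ``(mean, omega)``
are those of the *untruncated* Gaussian (the parameters appearing in the
density), not the moments of the truncated law; the two coincide as the
covariance shrinks or moves away from the cone boundary.

The PSD filter is evaluated through the characteristic-polynomial
invariants (trace, sum of principal 2x2 minors, determinant), which for
a symmetric 3x3 matrix are all non-negative exactly when the eigenvalues
are; this avoids a per-sample eigendecomposition in the Monte Carlo hot
path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tensor_algebra import d6_to_matrix, is_psd, sym_sqrt_psd

__all__ = ["CNTVDParams", "TensorEnsemble", "psd_mask", "sample_cntvd", "log_density", "empirical_moments"]


@dataclass
class CNTVDParams:
    """Mean 6-vector, 6x6 covariance and non-weighted amplitude of a CNTVD.

    ``mean_d6`` in um^2/ms, ``omega`` in (um^2/ms)^2 (plain-covariance
    convention), ``s0`` in arbitrary signal units.
    """

    mean_d6: np.ndarray
    omega: np.ndarray
    s0: float = 1.0
    symmetry_class: str | None = None

    def __post_init__(self):
        self.mean_d6 = np.asarray(self.mean_d6, dtype=float).reshape(6)
        self.omega = np.asarray(self.omega, dtype=float).reshape(6, 6)
        if np.abs(self.omega - self.omega.T).max() > 1e-10 * max(np.abs(self.omega).max(), 1.0):
            raise ValueError("omega must be symmetric")
        if not is_psd(d6_to_matrix(self.mean_d6), tol_scale=1e-10):
            raise ValueError("mean tensor must be positive semi-definite")
        if not is_psd(self.omega, tol_scale=1e-8):
            raise ValueError("omega must be positive semi-definite")

    @property
    def mean_matrix(self) -> np.ndarray:
        return d6_to_matrix(self.mean_d6)


@dataclass
class TensorEnsemble:
    """Accepted Monte Carlo draws from a DTD (one row per micro-tensor)."""

    d6: np.ndarray
    n_proposed: int
    seed: int | None = None
    n_rejected: int = field(init=False)

    def __post_init__(self):
        self.d6 = np.atleast_2d(np.asarray(self.d6, dtype=float))
        self.n_rejected = self.n_proposed - len(self.d6)

    def __len__(self) -> int:
        return len(self.d6)

    @property
    def acceptance(self) -> float:
        return len(self.d6) / self.n_proposed

    @property
    def matrices(self) -> np.ndarray:
        return d6_to_matrix(self.d6)

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of every member, sorted descending along axis 1."""
        return np.linalg.eigvalsh(self.matrices)[:, ::-1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["dxx", "dyy", "dzz", "dxy", "dxz", "dyz"]
        df = pd.DataFrame(self.d6, columns=cols)
        lam = self.eigenvalues()
        for i in range(3):
            df[f"lambda{i + 1}"] = lam[:, i]
        return df


def psd_mask(d6: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Boolean mask of rows whose 3x3 form has all eigenvalues >= -tol."""
    d = np.atleast_2d(d6)
    a, b, c, f, g, h = (d[:, k] for k in range(6))
    scale = np.maximum(np.abs(d).max(initial=0.0), 1.0)
    eps = tol * scale
    i1 = a + b + c
    i2 = a * b + a * c + b * c - f * f - g * g - h * h
    i3 = a * b * c + 2 * f * g * h - a * h * h - b * g * g - c * f * f
    return (i1 >= -3 * eps) & (i2 >= -3 * eps * scale) & (i3 >= -eps * scale**2)


def sample_cntvd(
    params: CNTVDParams,
    n: int,
    seed: int | np.random.Generator | None = None,
    z: np.ndarray | None = None,
) -> TensorEnsemble:
    """Draw ``n`` Gaussian proposals and keep those inside the PSD cone.

    ``z`` optionally supplies the standard-normal block (shape ``(n, 6)``)
    so that fitting can reuse common random numbers.  Deterministic for a
    fixed integer seed.  Works for singular covariances (eigenvalue-clipped
    symmetric square root).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if z is None:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, 6))
    elif z.shape != (n, 6):
        raise ValueError("z block must have shape (n, 6)")
    root = sym_sqrt_psd(params.omega)
    proposals = params.mean_d6[None, :] + z @ root.T
    mask = psd_mask(proposals)
    frac = mask.mean()
    if frac < 1e-4:
        raise RuntimeError(
            "distribution mass almost entirely outside the PSD cone "
            f"(acceptance {frac:.2e})"
        )
    if frac < 0.05:
        warnings.warn(f"low PSD acceptance fraction {frac:.3f}", RuntimeWarning)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return TensorEnsemble(proposals[mask], n_proposed=n, seed=seed_val)


def acceptance_probability(
    params: CNTVDParams, n: int = 100_000, seed: int | np.random.Generator | None = None
) -> float:
    """Monte Carlo estimate of the Gaussian mass inside the PSD cone."""
    rng = np.random.default_rng(seed)
    root = sym_sqrt_psd(params.omega)
    proposals = params.mean_d6[None, :] + rng.standard_normal((n, 6)) @ root.T
    return float(psd_mask(proposals).mean())


def log_density(
    params: CNTVDParams,
    d6: np.ndarray,
    n_norm: int = 100_000,
    seed: int | np.random.Generator | None = None,
    allow_singular: bool = False,
) -> float:
    """Log density of the CNTVD at one tensor (6-vector or 3x3).

    The truncation normalizer (Gaussian normalizer times the PSD-cone
    acceptance probability) is estimated by Monte Carlo with ``n_norm``
    proposals.  For singular covariances the density is evaluated on the
    support subspace (pseudo-inverse and pseudo-determinant) and must be
    requested explicitly with ``allow_singular``.
    """
    d6 = np.asarray(d6, dtype=float)
    if d6.shape == (3, 3):
        from .tensor_algebra import matrix_to_d6

        d6 = matrix_to_d6(d6)
    if not psd_mask(d6[None, :])[0]:
        return -np.inf
    dev = d6 - params.mean_d6
    w, v = np.linalg.eigh(params.omega)
    # variances far below the mean-tensor scale are numerical dust:
    # treat them as exact zeros (point-mass directions)
    tol = max(1e-10 * w.max(initial=0.0), 1e-12 * float(np.max(params.mean_d6**2)), 1e-300)
    support = w > tol
    rank = int(support.sum())
    if rank < 6 and not allow_singular:
        raise np.linalg.LinAlgError(
            "omega is singular; pass allow_singular=True for the subspace density"
        )
    if rank == 0:
        return 0.0 if np.allclose(dev, 0.0, atol=1e-10) else -np.inf
    coeff = v.T @ dev
    off = coeff[~support]
    if off.size and np.abs(off).max() > 1e-8 * max(np.abs(d6).max(), 1.0):
        return -np.inf  # outside the support subspace
    quad = float(np.sum(coeff[support] ** 2 / w[support]))
    log_pdet = float(np.sum(np.log(w[support])))
    p_acc = acceptance_probability(params, n=n_norm, seed=seed)
    return -0.5 * quad - 0.5 * (rank * np.log(2 * np.pi) + log_pdet) - np.log(p_acc)


def empirical_moments(ensemble: TensorEnsemble | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean 6-vector and sample covariance (denominator n-1)."""
    d6 = ensemble.d6 if isinstance(ensemble, TensorEnsemble) else np.atleast_2d(ensemble)
    if len(d6) == 0:
        raise ValueError("ensemble is empty")
    if len(d6) < 2:
        raise ValueError("covariance undefined for a single sample")
    mean = d6.mean(axis=0)
    omega = np.cov(d6, rowvar=False, ddof=1)
    return mean, np.atleast_2d(omega)
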