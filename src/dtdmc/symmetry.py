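"""Symmetry classes of the fourth-order covariance tensor.

The nested covariance submodels follow the classical symmetry classes of
fourth-order tensors (isotropic, cubic, hexagonal/transversely isotropic,
trigonal, tetragonal, orthorhombic, monoclinic, triclinic).  Each class is
the fixed-point space of a rotation group acting on symmetric 6x6
matrices; rather than transcribing the non-zero patterns, the class bases
are computed here as null spaces of the group-generator constraints.  The
parameter counts (2, 3, 5, 6/7, 6/7, 9, 13, 21) are asserted at build
time.

Everything in this module works in the Mandel (orthonormal) basis, where
rotations act orthogonally.  Two consequences are exploited heavily:

* a class is closed under matrix products, so its PSD cone is *exactly*
  ``{A @ A : A symmetric, A in class}`` — the estimator parameterizes the
  in-class symmetric square root ``A`` and positive-semidefiniteness is
  automatic;
* the orthogonal projection onto a class commutes with the congruence
  action, so projecting an empirical covariance onto a class and rotating
  it can be done in either order.

The symmetry axis of the axial classes (hexagonal, trigonal, tetragonal)
is the template x-axis (axis 1); templates are later rotated so that this
axis lands on the principal eigenvector of the mean tensor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import null_space

from .tensor_algebra import mandel_scale, rotation_operator_6

__all__ = [
    "COV_CLASSES",
    "MEAN_CLASSES",
    "SymmetryClass",
    "cov_class",
    "class_basis",
    "project_to_class",
    "omega_plain_to_mandel",
    "omega_mandel_to_plain",
    "isotropic_omega",
    "isotropic_params_from_omega",
]

_M = np.diag(mandel_scale)
_MINV = np.diag(1.0 / mandel_scale)


def omega_plain_to_mandel(omega: np.ndarray) -> np.ndarray:
    return _M @ omega @ _M


def omega_mandel_to_plain(omega_m: np.ndarray) -> np.ndarray:
    return _MINV @ omega_m @ _MINV


def _rot(axis: str, angle: float) -> np.ndarray:
    from .tensor_algebra import _axis_rotation

    return _axis_rotation(axis, angle)


# generators of the point groups (symmetry axis = x).  A C_n rotation with
# n >= 5 pins the same fixed space as the full axial rotation group for
# tensors of harmonic degree <= 4, hence the 2*pi/7 angles.
_GENERATORS: dict[str, list[np.ndarray]] = {
    "triclinic": [],
    "monoclinic": [_rot("X", np.pi)],
    "orthorhombic": [_rot("X", np.pi), _rot("Y", np.pi)],
    "trigonal7": [_rot("X", 2 * np.pi / 3)],
    "trigonal6": [_rot("X", 2 * np.pi / 3), _rot("Y", np.pi)],
    "tetragonal7": [_rot("X", np.pi / 2)],
    "tetragonal6": [_rot("X", np.pi / 2), _rot("Y", np.pi)],
    "hexagonal": [_rot("X", 2 * np.pi / 7)],
    "cubic": [_rot("X", np.pi / 2), _rot("Z", np.pi / 2)],
    "isotropic": [_rot("X", 2 * np.pi / 7), _rot("Z", 2 * np.pi / 7)],
}

_EXPECTED_DIM = {
    "none": 0,
    "isotropic": 2,
    "cubic": 3,
    "hexagonal": 5,
    "trigonal6": 6,
    "tetragonal6": 6,
    "trigonal7": 7,
    "tetragonal7": 7,
    "orthorhombic": 9,
    "monoclinic": 13,
    "triclinic": 21,
}

#: ladder order used for tie-breaking in model selection (fewest params first)
COV_CLASSES = tuple(_EXPECTED_DIM)

#: mean-tensor submodels with their total parameter count (including S0)
MEAN_CLASSES = {"noise": 1, "isotropic": 2, "prolate": 5, "oblate": 5, "general": 7}


def _sym_basis() -> np.ndarray:
    """Orthonormal basis of symmetric 6x6 matrices, shape (21, 6, 6)."""
    basis = []
    for i in range(6):
        for j in range(i, 6):
            e = np.zeros((6, 6))
            if i == j:
                e[i, i] = 1.0
            else:
                e[i, j] = e[j, i] = 1.0 / np.sqrt(2.0)
            basis.append(e)
    return np.array(basis)


def _mandel_rotation(r: np.ndarray) -> np.ndarray:
    """Orthogonal 6x6 representation of a rotation in the Mandel basis."""
    return _M @ rotation_operator_6(r) @ _MINV


@dataclass(frozen=True)
class SymmetryClass:
    """A covariance symmetry class with its orthonormal Mandel basis."""

    name: str
    basis: np.ndarray  # (k, 6, 6) symmetric Mandel matrices

    @property
    def n_params(self) -> int:
        return len(self.basis)

    def compose(self, coeffs: np.ndarray) -> np.ndarray:
        """Symmetric Mandel matrix from class coefficients."""
        return np.einsum("p,pij->ij", np.asarray(coeffs, dtype=float), self.basis)

    def coefficients(self, sym_m: np.ndarray) -> np.ndarray:
        """Projection coefficients of a symmetric Mandel matrix."""
        return np.einsum("pij,ij->p", self.basis, sym_m)


@lru_cache(maxsize=None)
def cov_class(name: str) -> SymmetryClass:
    if name not in _EXPECTED_DIM:
        raise ValueError(f"unknown covariance class {name!r}; choose from {COV_CLASSES}")
    if name == "none":
        return SymmetryClass("none", np.zeros((0, 6, 6)))
    sym = _sym_basis()
    if not _GENERATORS[name]:
        basis = sym
    else:
        rows = []
        for g in _GENERATORS[name]:
            t = _mandel_rotation(g)
            for e in sym:
                rows.append(((t @ e @ t.T) - e).ravel())
        # constraints expressed in symmetric-basis coordinates; the congruence
        # representation is orthogonal here, so fixed vectors of the operator
        # and of its transpose coincide and no transposition is needed
        coeff_rows = np.array(rows) @ sym.reshape(21, 36).T
        ns = null_space(coeff_rows, rcond=1e-10)
        basis = np.einsum("qp,qij->pij", ns, sym)
    sc = SymmetryClass(name, basis)
    if sc.n_params != _EXPECTED_DIM[name]:
        raise RuntimeError(
            f"class {name}: computed dimension {sc.n_params} != expected {_EXPECTED_DIM[name]}"
        )
    return sc


def class_basis(name: str) -> np.ndarray:
    return cov_class(name).basis


def project_to_class(omega_mandel: np.ndarray, name: str) -> np.ndarray:
    """Orthogonal (Frobenius) projection of a Mandel covariance onto a class."""
    sc = cov_class(name)
    if sc.n_params == 0:
        return np.zeros((6, 6))
    return sc.compose(sc.coefficients(0.5 * (omega_mandel + omega_mandel.T)))


def isotropic_omega(lam: float, mu: float) -> np.ndarray:
    """Plain-convention isotropic covariance C_ijkl = lam d_ij d_kl + mu (d_ik d_jl + d_il d_jk)."""
    omega = np.zeros((6, 6))
    omega[:3, :3] = lam
    omega[:3, :3] += 2 * mu * np.eye(3)
    omega[3:, 3:] = mu * np.eye(3)
    return omega


def isotropic_params_from_omega(omega_plain: np.ndarray) -> tuple[float, float]:
    """(lambda, mu) of the isotropic part of a plain-convention covariance."""
    m = omega_plain_to_mandel(omega_plain)
    proj = project_to_class(m, "isotropic")
    p = omega_mandel_to_plain(proj)
    mu = float(p[3:, 3:].trace() / 3.0)
    lam = float((p[:3, :3].sum() - 6 * mu) / 9.0)
    return lam, mu
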