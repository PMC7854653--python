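"""Conversions among diffusion-tensor representations and rotations.

A micro diffusion tensor is stored either as a symmetric 3x3 matrix
(units um^2/ms) or as the 6-vector of its independent components in the
fixed ordering ``(xx, yy, zz, xy, xz, yz)``.  Diffusion weighting is a
symmetric positive-semidefinite 3x3 b-matrix (units ms/um^2) whose
6-vector form carries a factor of two on the off-diagonal components so
that the Euclidean inner product ``b6 . d6`` equals the full double
contraction ``sum_ij B_ij D_ij``.

The second moment of a tensor distribution is a fourth-order covariance
tensor ``C_ijkl = Cov(D_ij, D_kl)`` with minor and major symmetries,
stored as a symmetric 6x6 matrix ``omega`` whose entries are the *raw*
covariances of the 6-vector components (no sqrt-2 Mandel scaling; the
factor-of-two bookkeeping lives entirely in the b-vector).  Helpers for
the Mandel (orthonormal) basis are provided because rotations act
orthogonally there.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "VOIGT_PAIRS",
    "d6_to_matrix",
    "matrix_to_d6",
    "bvec_from_bmatrix",
    "bmatrix_from_bvec",
    "omega_to_fourth_order",
    "fourth_order_to_omega",
    "euler_rotation",
    "rotation_operator_6",
    "rotate_fourth_order",
    "mandel_scale",
    "is_psd",
    "psd_eigenvalue_floor",
    "sym_sqrt_psd",
]

#: index pairs (i, j) of the 3x3 matrix backing each 6-vector slot
VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))

#: diagonal scaling taking plain 6-vectors to the Mandel orthonormal basis
mandel_scale = np.array([1.0, 1.0, 1.0, np.sqrt(2.0), np.sqrt(2.0), np.sqrt(2.0)])


def _check_symmetric(m: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - np.swapaxes(m, -1, -2)).max() > rtol * scale:
        raise ValueError("matrix is not symmetric")
    return m


def d6_to_matrix(d6: np.ndarray) -> np.ndarray:
    """Expand 6-vector(s) ``(xx,yy,zz,xy,xz,yz)`` into symmetric 3x3 form.

    Accepts shape ``(6,)`` or ``(n, 6)``.
    """
    d6 = np.asarray(d6, dtype=float)
    squeeze = d6.ndim == 1
    d6 = np.atleast_2d(d6)
    if d6.shape[-1] != 6:
        raise ValueError("expected 6 components")
    out = np.empty(d6.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(VOIGT_PAIRS):
        out[..., i, j] = d6[..., k]
        out[..., j, i] = d6[..., k]
    return out[0] if squeeze else out


def matrix_to_d6(m: np.ndarray) -> np.ndarray:
    """Collapse symmetric 3x3 matrix/matrices to the 6-vector form."""
    m = _check_symmetric(m)
    comps = [0.5 * (m[..., i, j] + m[..., j, i]) for i, j in VOIGT_PAIRS]
    return np.stack(comps, axis=-1)


def psd_eigenvalue_floor(eigvals: np.ndarray) -> float:
    """Tolerance below which an eigenvalue counts as genuinely negative."""
    return -1e-12 * max(float(np.abs(eigvals).max(initial=0.0)), 1.0)


def is_psd(m: np.ndarray, tol_scale: float = 1e-12) -> bool:
    m = np.asarray(m, dtype=float)
    w = np.linalg.eigvalsh(0.5 * (m + m.T))
    return bool(w.min() >= -tol_scale * max(float(np.abs(w).max()), 1.0))


def bvec_from_bmatrix(bmat: np.ndarray) -> np.ndarray:
    """6-vector ``(bxx,byy,bzz,2bxy,2bxz,2byz)`` of a symmetric PSD b-matrix.

    Raises if the matrix has a negative eigenvalue beyond numerical tolerance.
    """
    bmat = _check_symmetric(bmat)
    w = np.linalg.eigvalsh(bmat)
    if w.min() < psd_eigenvalue_floor(w):
        raise ValueError(f"b-matrix has negative eigenvalue {w.min():g}")
    b6 = matrix_to_d6(bmat)
    b6[..., 3:] *= 2.0
    return b6


def bmatrix_from_bvec(b6: np.ndarray) -> np.ndarray:
    """Inverse of :func:`bvec_from_bmatrix` (halves the off-diagonals)."""
    b6 = np.asarray(b6, dtype=float).copy()
    b6[..., 3:] *= 0.5
    return d6_to_matrix(b6)


def omega_to_fourth_order(omega: np.ndarray) -> np.ndarray:
    """Symmetric 6x6 covariance -> full 3x3x3x3 tensor C_ijkl = Cov(D_ij, D_kl)."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (6, 6):
        raise ValueError("omega must be 6x6")
    if np.abs(omega - omega.T).max() > 1e-10 * max(np.abs(omega).max(), 1.0):
        raise ValueError("omega must be symmetric")
    pair_index = np.empty((3, 3), dtype=int)
    for k, (i, j) in enumerate(VOIGT_PAIRS):
        pair_index[i, j] = k
        pair_index[j, i] = k
    c = np.empty((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    c[i, j, k, l] = omega[pair_index[i, j], pair_index[k, l]]
    return c


def fourth_order_to_omega(c: np.ndarray) -> np.ndarray:
    """Full fourth-order tensor (minor symmetries required) -> 6x6 matrix."""
    c = np.asarray(c, dtype=float)
    if c.shape != (3, 3, 3, 3):
        raise ValueError("C must be 3x3x3x3")
    scale = max(np.abs(c).max(), 1.0)
    if (
        np.abs(c - c.transpose(1, 0, 2, 3)).max() > 1e-10 * scale
        or np.abs(c - c.transpose(0, 1, 3, 2)).max() > 1e-10 * scale
    ):
        raise ValueError("C lacks minor symmetry")
    omega = np.empty((6, 6))
    for p, (i, j) in enumerate(VOIGT_PAIRS):
        for q, (k, l) in enumerate(VOIGT_PAIRS):
            omega[p, q] = c[i, j, k, l]
    return 0.5 * (omega + omega.T)


_AXES = {"X": 0, "Y": 1, "Z": 2}


def _axis_rotation(axis: str, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    r = np.eye(3)
    if axis == "X":
        r[1:, 1:] = [[c, -s], [s, c]]
    elif axis == "Y":
        r[0, 0], r[0, 2], r[2, 0], r[2, 2] = c, s, -s, c
    elif axis == "Z":
        r[:2, :2] = [[c, -s], [s, c]]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return r


def euler_rotation(alpha: float, beta: float, gamma: float, order: str = "XYZ") -> np.ndarray:
    """Proper rotation from Euler angles applied in the given axis order.

    ``order='XYZ'`` gives ``R = X(alpha) Y(beta) Z(gamma)``.
    """
    order = order.upper()
    if sorted(order) != ["X", "Y", "Z"]:
        raise ValueError("order must be a permutation of 'XYZ'")
    r = np.eye(3)
    for axis, angle in zip(order, (alpha, beta, gamma)):
        r = r @ _axis_rotation(axis, angle)
    return r


def rotation_operator_pair(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Bilinear building block of the 6x6 rotation operator.

    ``rotation_operator_6(R) == rotation_operator_pair(R, R)`` and the
    differential of the operator is ``pair(dR, R) + pair(R, dR)``.
    """
    t = np.empty((6, 6))
    for row, (a, b) in enumerate(VOIGT_PAIRS):
        for col, (i, j) in enumerate(VOIGT_PAIRS):
            if i == j:
                t[row, col] = p[a, i] * q[b, i]
            else:
                t[row, col] = p[a, i] * q[b, j] + p[a, j] * q[b, i]
    return t


def rotation_operator_6(r: np.ndarray) -> np.ndarray:
    """6x6 operator T with ``d6(R D R^T) = T @ d6(D)`` (plain convention)."""
    return rotation_operator_pair(r, r)


def rotate_fourth_order(c_or_omega: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Rotate a fourth-order covariance: ``C'_ijkl = R_ia R_jb R_kc R_ld C_abcd``.

    Accepts and returns either the 3x3x3x3 or the 6x6 representation.
    """
    r = np.asarray(r, dtype=float)
    arr = np.asarray(c_or_omega, dtype=float)
    if arr.shape == (6, 6):
        t = rotation_operator_6(r)
        return t @ arr @ t.T
    c = arr
    return np.einsum("ia,jb,kc,ld,abcd->ijkl", r, r, r, r, c)


def sym_sqrt_psd(m: np.ndarray, clip: bool = True) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition.

    Negative eigenvalues within tolerance are clipped to zero (supports
    singular covariances); genuinely indefinite input raises unless
    ``clip`` is set.
    """
    m = np.asarray(m, dtype=float)
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    floor = psd_eigenvalue_floor(w) * 100.0
    if not clip and w.min() < floor:
        raise ValueError(f"matrix not PSD (eigenvalue {w.min():g})")
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T
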