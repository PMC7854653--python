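"""Unconstrained parameterizations of the nested mean/covariance submodels.

Each model couples one mean-tensor class (noise/isotropic/prolate/oblate/
general, 1-7 parameters including S0) with one covariance symmetry class
(0-21 parameters).  A flat unconstrained vector theta maps to

* ``s0 = exp(theta_0)``,
* a physical mean tensor ``Dbar = F Lambda F^T`` with softplus-chained
  eigenvalues (ordering and non-negativity built in) and a frame ``F``
  whose columns are ordered by descending eigenvalue,
* a covariance factor ``A`` with ``Omega = A A^T``: the class template is
  parameterized by its *symmetric in-class square root* in the Mandel
  basis (symmetry classes are closed under products there, so this covers
  exactly the class's PSD cone) and rotated so that the template symmetry
  axis lands on the mean tensor's principal eigenvector ``F[:, 0]``.

Micro-tensor draws are ``d6 = Dbar6 + A z`` with z standard normal, so
the Jacobian of the Monte Carlo signal with respect to theta reduces to a
handful of matrix products; :meth:`ParamMap.jacobian_parts` returns the
per-parameter derivative pairs ``(dDbar6, dA)`` the fitter contracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cntvd import CNTVDParams
from .symmetry import (
    MEAN_CLASSES,
    SymmetryClass,
    cov_class,
    omega_plain_to_mandel,
    project_to_class,
)
from .tensor_algebra import (
    mandel_scale,
    matrix_to_d6,
    rotation_operator_pair,
    sym_sqrt_psd,
)

__all__ = ["ModelSpec", "ParamMap", "build_model"]

_MINV = np.diag(1.0 / mandel_scale)
_PERM_PROLATE = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softplus_inv(y):
    y = max(float(y), 1e-8)
    return y + np.log(-np.expm1(-y)) if y < 30 else y


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _drz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, -c, 0.0], [c, -s, 0.0], [0.0, 0.0, 0.0]])


def _dry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0.0, c], [0.0, 0.0, 0.0], [-c, 0.0, -s]])


@dataclass(frozen=True)
class ModelSpec:
    """A (mean class, covariance class) pair with its parameter count."""

    mean_class: str
    cov_class: str

    def __post_init__(self):
        if self.mean_class not in MEAN_CLASSES:
            raise ValueError(f"unknown mean class {self.mean_class!r}")
        cov_class(self.cov_class)  # validates

    @property
    def n_mean_params(self) -> int:
        return MEAN_CLASSES[self.mean_class]

    @property
    def n_cov_params(self) -> int:
        return cov_class(self.cov_class).n_params

    @property
    def n_params(self) -> int:
        return self.n_mean_params + self.n_cov_params

    def __str__(self) -> str:
        return f"{self.mean_class}+{self.cov_class}"


@dataclass
class ModelValue:
    """Evaluated model at one theta."""

    s0: float
    d6bar: np.ndarray
    a_factor: np.ndarray  # plain-convention factor, Omega = A A^T
    frame: np.ndarray

    @property
    def omega(self) -> np.ndarray:
        return self.a_factor @ self.a_factor.T

    def to_params(self, symmetry_class: str | None = None) -> CNTVDParams:
        return CNTVDParams(
            mean_d6=self.d6bar, omega=self.omega, s0=self.s0, symmetry_class=symmetry_class
        )


class ParamMap:
    """theta <-> (s0, mean tensor, covariance factor) for one ModelSpec."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.sym: SymmetryClass = cov_class(spec.cov_class)
        self.n_params = spec.n_params
        # pre-rotate nothing: class bases are in Mandel; factor basis in plain
        self._g_plain = np.array([_MINV @ g for g in self.sym.basis]) if self.sym.n_params else np.zeros((0, 6, 6))

    # mean-part layout after theta[0] = ln s0:
    #   isotropic: (xd,)
    #   prolate:   (x_trans, x_gap, theta, phi)        axis = principal
    #   oblate:    (x_axial, x_gap, theta, phi)        axis = minor
    #   general:   (x_l3, x_g2, x_g1, alpha, beta, gamma)

    def _mean_eval(self, tm: np.ndarray, want_jac: bool):
        cls = self.spec.mean_class
        eye = np.eye(3)
        jac: list[tuple[np.ndarray, np.ndarray | None]] = []  # (dLambda_frame, dF)
        if cls == "noise":
            return np.zeros(3), eye, []
        if cls == "isotropic":
            d = _softplus(tm[0])
            lam = np.array([d, d, d])
            if want_jac:
                sd = _sigmoid(tm[0])
                jac = [(np.array([sd, sd, sd]), None)]
            return lam, eye, jac
        if cls in ("prolate", "oblate"):
            x1, xg, th, ph = tm
            base = _softplus(x1)
            gap = _softplus(xg)
            r = _rz(ph) @ _ry(th)
            if cls == "prolate":
                lam = np.array([base + gap, base, base])
                f = r @ _PERM_PROLATE  # columns (Rz@Ry) @ (z, x, y): e1 = axis
                perm = _PERM_PROLATE
            else:
                lam = np.array([base + gap, base + gap, base])
                f = r  # e3 = axis = R z
                perm = eye
            if want_jac:
                s1, sg = _sigmoid(x1), _sigmoid(xg)
                if cls == "prolate":
                    dl1 = np.array([s1, s1, s1])
                    dlg = np.array([sg, 0.0, 0.0])
                else:
                    dl1 = np.array([s1, s1, s1])
                    dlg = np.array([sg, sg, 0.0])
                dth = (_rz(ph) @ _dry(th)) @ perm
                dph = (_drz(ph) @ _ry(th)) @ perm
                jac = [(dl1, None), (dlg, None), (None, dth), (None, dph)]
            return lam, f, jac
        if cls == "general":
            x3, g2, g1, al, be, ga = tm
            l3 = _softplus(x3)
            l2 = l3 + _softplus(g2)
            l1 = l2 + _softplus(g1)
            lam = np.array([l1, l2, l3])
            ra, rb, rg = _rz(al), _ry(be), _rz(ga)
            f = ra @ rb @ rg
            if want_jac:
                s3, sg2, sg1 = _sigmoid(x3), _sigmoid(g2), _sigmoid(g1)
                jac = [
                    (np.array([s3, s3, s3]), None),
                    (np.array([sg2, sg2, 0.0]), None),
                    (np.array([sg1, 0.0, 0.0]), None),
                    (None, _drz(al) @ rb @ rg),
                    (None, ra @ _dry(be) @ rg),
                    (None, ra @ rb @ _drz(ga)),
                ]
            return lam, f, jac
        raise ValueError(cls)

    def unpack(self, theta: np.ndarray) -> ModelValue:
        return self._eval(np.asarray(theta, dtype=float), want_jac=False)[0]

    def _eval(self, theta, want_jac: bool):
        tm = theta[1 : 1 + self.spec.n_mean_params - 1]
        tc = theta[1 + self.spec.n_mean_params - 1 :]
        s0 = float(np.exp(theta[0]))
        lam, f, mean_jac = self._mean_eval(tm, want_jac)
        d3 = (f * lam) @ f.T
        d6bar = matrix_to_d6(d3)
        if self.sym.n_params:
            a_t = np.einsum("p,pij->ij", tc, self._g_plain)  # Minv @ A_M
            tp = rotation_operator_pair(f, f)
            a = tp @ a_t
        else:
            a_t = np.zeros((6, 6))
            tp = None
            a = np.zeros((6, 6))
        value = ModelValue(s0=s0, d6bar=d6bar, a_factor=a, frame=f)
        if not want_jac:
            return value, None
        parts: list[tuple[np.ndarray | None, np.ndarray | None]] = []
        for dlam, df in mean_jac:
            dd6 = None
            da = None
            if dlam is not None:
                dd6 = matrix_to_d6((f * dlam) @ f.T)
            if df is not None:
                dd3 = (df * lam) @ f.T
                dd6 = matrix_to_d6(dd3 + dd3.T)
                if self.sym.n_params:
                    dtp = rotation_operator_pair(df, f) + rotation_operator_pair(f, df)
                    da = dtp @ a_t
            parts.append((dd6, da))
        for p in range(self.sym.n_params):
            parts.append((None, tp @ self._g_plain[p]))
        return value, parts

    def jacobian_parts(self, theta: np.ndarray):
        """(value, list of per-parameter (dDbar6, dA)) excluding the s0 slot."""
        return self._eval(np.asarray(theta, dtype=float), want_jac=True)

    # ---------------- initialization helpers ----------------

    def initial_theta(self, s0: float, mean_d6: np.ndarray, omega_plain: np.ndarray) -> np.ndarray:
        """Map rough (s0, mean, covariance) estimates into theta space."""
        from .tensor_algebra import d6_to_matrix

        theta = np.empty(self.n_params)
        theta[0] = np.log(max(float(s0), 1e-8))
        d3 = d6_to_matrix(np.asarray(mean_d6, dtype=float))
        w, v = np.linalg.eigh(d3)
        w = np.clip(w[::-1], 1e-6, None)  # descending
        v = v[:, ::-1]
        if np.linalg.det(v) < 0:
            v[:, 2] *= -1
        cls = self.spec.mean_class
        if cls == "isotropic":
            theta[1] = _softplus_inv(w.mean())
        elif cls == "prolate":
            trans = 0.5 * (w[1] + w[2])
            theta[1] = _softplus_inv(trans)
            theta[2] = _softplus_inv(max(w[0] - trans, 1e-6))
            axis = v[:, 0]
            theta[3] = np.arccos(np.clip(axis[2], -1, 1))
            theta[4] = np.arctan2(axis[1], axis[0])
        elif cls == "oblate":
            trans = 0.5 * (w[0] + w[1])
            theta[1] = _softplus_inv(w[2])
            theta[2] = _softplus_inv(max(trans - w[2], 1e-6))
            axis = v[:, 2]
            theta[3] = np.arccos(np.clip(axis[2], -1, 1))
            theta[4] = np.arctan2(axis[1], axis[0])
        elif cls == "general":
            theta[1] = _softplus_inv(w[2])
            theta[2] = _softplus_inv(max(w[1] - w[2], 1e-6))
            theta[3] = _softplus_inv(max(w[0] - w[1], 1e-6))
            be = np.arccos(np.clip(v[2, 2], -1, 1))
            if abs(v[2, 2]) < 1 - 1e-9:
                al = np.arctan2(v[1, 2], v[0, 2])
                ga = np.arctan2(v[2, 1], -v[2, 0])
            else:
                al = np.arctan2(v[1, 0], v[0, 0])
                ga = 0.0
            theta[4], theta[5], theta[6] = al, be, ga
        if self.sym.n_params:
            k0 = self.spec.n_mean_params
            value = self.unpack(np.concatenate([theta[:k0], np.zeros(self.sym.n_params)]))
            theta[k0:] = self.cov_coefficients_from_omega(omega_plain, value.frame)
        return theta

    def cov_coefficients_from_omega(self, omega_plain: np.ndarray, frame: np.ndarray) -> np.ndarray:
        """Class square-root coefficients approximating a plain covariance."""
        if self.sym.n_params == 0:
            return np.zeros(0)
        m_scale = np.diag(mandel_scale)
        t_m = m_scale @ rotation_operator_pair(frame, frame) @ _MINV
        om = omega_plain_to_mandel(np.asarray(omega_plain, dtype=float))
        om_frame = t_m.T @ om @ t_m  # t_m is orthogonal
        proj = project_to_class(om_frame, self.spec.cov_class)
        root = sym_sqrt_psd(proj, clip=True)
        return self.sym.coefficients(root)


def build_model(mean_class: str, cov_class_name: str) -> ParamMap:
    """Parameterization for one (mean class, covariance class) pair."""
    return ParamMap(ModelSpec(mean_class, cov_class_name))
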