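"""Microstructural stains and glyph surfaces derived from a DTD.

Stains are rotation-invariant scalars that separate the three modes of
intravoxel heterogeneity:

* ``v_size``   — standard deviation of the mean apparent diffusion
  coefficient (trace/3) across micro-tensors, obtained from the
  covariance by the scalar-projection identity with c = (1,1,1,0,0,0)/3
  (units um^2/ms);
* ``v_shape``  — root summed variance of the sorted-eigenvalue ratios
  lambda2/lambda1 and lambda3/lambda2 (dimensionless);
* ``v_orient`` — eigenvector dispersion: for each eigenvector family the
  mean dyadic (outer-product average) has eigenvalues beta1>beta2>beta3
  and the stain is the minimum over families of sqrt((beta2+beta3)/(2*beta1)),
  0 for coherent and 1 for uniformly random orientations;
* ``mu_fa``, entropy and ODF entropy — ensemble averages of per-tensor
  functions (micro-FA, negative log density, ODF entropy).

Glyphs are spherical surfaces: the covariance glyph radius is the
directional variance ``r_i r_j r_k r_l C_ijkl = Var(r^T D r)`` and the
macro/micro ODF glyphs use the single-tensor ODF
``1 / (4 pi sqrt(|D|) (r^T D^-1 r)^(3/2))`` and its ensemble average.

Sphere integrals use a Gauss-Legendre (cos theta) x uniform-phi product
grid, spectrally accurate for these smooth integrands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cntvd import CNTVDParams, TensorEnsemble, log_density
from .tensor_algebra import d6_to_matrix

__all__ = [
    "SphereGrid",
    "StainReport",
    "micro_average",
    "fa",
    "odf",
    "odf_entropy",
    "v_size",
    "v_shape",
    "v_orient",
    "covariance_glyph",
    "micro_odf",
    "macro_odf",
    "stain_report",
    "export_glyph_mesh",
]


@dataclass
class SphereGrid:
    """Unit directions with quadrature weights summing to 4*pi."""

    directions: np.ndarray  # (m, 3)
    weights: np.ndarray  # (m,)
    shape: tuple[int, int] | None = None  # (n_theta, n_phi) for meshable grids

    @classmethod
    def gauss_legendre(cls, n_theta: int = 48, n_phi: int = 96) -> "SphereGrid":
        x, w = np.polynomial.legendre.leggauss(n_theta)  # x = cos(theta)
        phi = 2 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
        ct = x[:, None] * np.ones(n_phi)[None, :]
        st = np.sqrt(1 - x**2)[:, None] * np.ones(n_phi)[None, :]
        dirs = np.stack(
            [st * np.cos(phi)[None, :], st * np.sin(phi)[None, :], ct], axis=-1
        ).reshape(-1, 3)
        weights = (w[:, None] * (2 * np.pi / n_phi) * np.ones(n_phi)[None, :]).reshape(-1)
        return cls(dirs, weights, shape=(n_theta, n_phi))

    @classmethod
    def latlong(cls, n_theta: int = 64, n_phi: int = 128) -> "SphereGrid":
        """Regular latitude-longitude grid (for mesh export; trapezoid weights)."""
        theta = np.pi * (np.arange(n_theta) + 0.5) / n_theta
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        dirs = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
        ).reshape(-1, 3)
        w = (np.sin(tt) * (np.pi / n_theta) * (2 * np.pi / n_phi)).reshape(-1)
        w *= 4 * np.pi / w.sum()
        return cls(dirs, w, shape=(n_theta, n_phi))

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if np.abs(norms - 1).max() > 1e-10:
            raise ValueError("directions must be unit vectors")
        if abs(self.weights.sum() - 4 * np.pi) > 1e-8:
            raise ValueError("weights must sum to 4*pi")


_DEFAULT_GRID: SphereGrid | None = None


def default_grid() -> SphereGrid:
    global _DEFAULT_GRID
    if _DEFAULT_GRID is None:
        _DEFAULT_GRID = SphereGrid.gauss_legendre()
    return _DEFAULT_GRID


def fa(d6_or_matrix: np.ndarray) -> float | np.ndarray:
    """Fractional anisotropy from the eigenvalues of the 3x3 form."""
    m = np.asarray(d6_or_matrix, dtype=float)
    if m.shape[-1] == 6:
        m = d6_to_matrix(m)
    lam = np.linalg.eigvalsh(m)
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    out = np.sqrt(1.5 * np.divide(num, den, out=np.zeros_like(num), where=den > 0))
    return float(out) if out.ndim == 0 else out


def odf(d: np.ndarray, grid: SphereGrid | None = None) -> np.ndarray:
    """Gaussian-diffusion ODF of one tensor on the grid (integrates to 1)."""
    grid = grid or default_grid()
    m = np.asarray(d, dtype=float)
    if m.shape == (6,):
        m = d6_to_matrix(m)
    det = np.linalg.det(m)
    if det <= 0:
        raise np.linalg.LinAlgError("ODF requires a positive-definite tensor")
    inv = np.linalg.inv(m)
    quad = np.einsum("ni,ij,nj->n", grid.directions, inv, grid.directions)
    return 1.0 / (4 * np.pi * np.sqrt(det) * quad**1.5)


def odf_entropy(d: np.ndarray, grid: SphereGrid | None = None) -> float:
    """Orientation disorder: -integral of ODF * ln(ODF) over the sphere."""
    grid = grid or default_grid()
    vals = odf(d, grid)
    return float(-np.sum(grid.weights * vals * np.log(vals)))


def micro_average(
    ensemble: TensorEnsemble | np.ndarray,
    f: str | callable,
    grid: SphereGrid | None = None,
    params: CNTVDParams | None = None,
    n_norm: int = 100_000,
    seed: int | None = 0,
) -> float | np.ndarray:
    """Ensemble average of a per-tensor function over accepted samples.

    ``f`` may be 'fa', 'odf', 'odf_entropy', 'neg_log_density' (requires
    ``params``) or any callable taking a 6-vector.
    """
    d6 = ensemble.d6 if isinstance(ensemble, TensorEnsemble) else np.atleast_2d(ensemble)
    if len(d6) == 0:
        raise ValueError("empty ensemble")
    if f == "fa":
        return float(np.mean(fa(d6)))
    if f == "odf":
        return micro_odf(d6, grid)
    if f == "odf_entropy":
        grid = grid or default_grid()
        vals = [odf_entropy(row, grid) for row in d6]
        return float(np.mean(vals))
    if f == "neg_log_density":
        if params is None:
            raise ValueError("params required for the entropy stain")
        from .cntvd import acceptance_probability
        import numpy.linalg as la

        w, v = la.eigh(params.omega)
        # variances far below the mean-tensor scale are numerical dust:
        # treat them as exact zeros (point-mass directions)
        tol = max(1e-10 * w.max(initial=0.0), 1e-12 * float(np.max(params.mean_d6**2)), 1e-300)
        support = w > tol
        rank = int(support.sum())
        if rank == 0:
            return -np.inf  # point mass: differential entropy diverges
        dev = d6 - params.mean_d6[None, :]
        coeff = dev @ v
        quad = (coeff[:, support] ** 2 / w[support][None, :]).sum(axis=1)
        log_pdet = float(np.sum(np.log(w[support])))
        p_acc = acceptance_probability(params, n=n_norm, seed=seed)
        logp = -0.5 * quad - 0.5 * (rank * np.log(2 * np.pi) + log_pdet) - np.log(p_acc)
        return float(-(logp).mean())
    if callable(f):
        return float(np.mean([f(row) for row in d6]))
    raise ValueError(f"unknown micro function {f!r}")


def v_size(omega: np.ndarray) -> float:
    """SD of the mean ADC: sqrt of the averaged upper 3x3 covariance block."""
    omega = np.asarray(omega, dtype=float)
    block = omega[:3, :3].sum() / 9.0
    if block < -1e-12 * max(np.abs(omega).max(), 1.0):
        raise ValueError("negative mADC variance: omega is not PSD")
    return float(np.sqrt(max(block, 0.0)))


def v_shape(ensemble: TensorEnsemble | np.ndarray) -> float:
    """Root summed variance of sorted-eigenvalue ratios across the ensemble.

    Degenerate members are treated as shape-identical: if lambda2 = 0 the
    ratio lambda3/lambda2 is defined as 1, and an all-zero tensor counts
    as spherical (both ratios 1).
    """
    d6 = ensemble.d6 if isinstance(ensemble, TensorEnsemble) else np.atleast_2d(ensemble)
    lam = np.linalg.eigvalsh(d6_to_matrix(d6))[:, ::-1]  # descending
    r1 = np.where(lam[:, 0] > 0, lam[:, 1] / np.where(lam[:, 0] > 0, lam[:, 0], 1.0), 1.0)
    r2 = np.where(lam[:, 1] > 0, lam[:, 2] / np.where(lam[:, 1] > 0, lam[:, 1], 1.0), 1.0)
    return float(np.sqrt(np.var(r1) + np.var(r2)))


def v_orient(ensemble: TensorEnsemble | np.ndarray, degeneracy_rtol: float = 1e-6) -> float:
    """Eigenvector dispersion, 0 (coherent) to 1 (uniformly random).

    The dyadic averaging removes the eigenvector sign ambiguity; exact
    eigenvalue degeneracies make eigenvector labels arbitrary, in which
    case the deterministic symmetric eigensolver ordering is used and a
    caveat is emitted.
    """
    d6 = ensemble.d6 if isinstance(ensemble, TensorEnsemble) else np.atleast_2d(ensemble)
    lam, vec = np.linalg.eigh(d6_to_matrix(d6))
    lam, vec = lam[:, ::-1], vec[:, :, ::-1]  # descending eigenvalues
    scale = np.abs(lam).max()
    if scale > 0:
        gaps = np.abs(np.diff(lam, axis=1)) / scale
        if (gaps < degeneracy_rtol).any():
            warnings.warn(
                "degenerate micro-tensor eigenvalues: eigenvector families are "
                "labelled by the eigensolver's deterministic ordering",
                RuntimeWarning,
            )
    values = []
    for i in range(3):
        e = vec[:, :, i]
        dyadic = np.einsum("na,nb->ab", e, e) / len(e)
        beta = np.sort(np.linalg.eigvalsh(dyadic))[::-1]
        values.append(np.sqrt(max(beta[1] + beta[2], 0.0) / (2 * beta[0])))
    return float(min(values))


def covariance_glyph(omega: np.ndarray, grid: SphereGrid | None = None) -> np.ndarray:
    """Directional variance radii r_i r_j r_k r_l C_ijkl = Var(r^T D r) >= 0."""
    grid = grid or default_grid()
    r = grid.directions
    c = np.stack(
        [r[:, 0] ** 2, r[:, 1] ** 2, r[:, 2] ** 2,
         2 * r[:, 0] * r[:, 1], 2 * r[:, 0] * r[:, 2], 2 * r[:, 1] * r[:, 2]],
        axis=1,
    )
    return np.einsum("ni,ij,nj->n", c, np.asarray(omega, dtype=float), c)


def macro_odf(mean_d6: np.ndarray, grid: SphereGrid | None = None) -> np.ndarray:
    """ODF of the mean tensor."""
    return odf(np.asarray(mean_d6, dtype=float), grid)


def micro_odf(ensemble: TensorEnsemble | np.ndarray, grid: SphereGrid | None = None) -> np.ndarray:
    """Sample mean of per-tensor ODFs (singular members skipped, counted)."""
    grid = grid or default_grid()
    d6 = ensemble.d6 if isinstance(ensemble, TensorEnsemble) else np.atleast_2d(ensemble)
    total = np.zeros(len(grid.directions))
    used = 0
    skipped = 0
    for row in d6:
        try:
            total += odf(row, grid)
            used += 1
        except np.linalg.LinAlgError:
            skipped += 1
    if used == 0:
        raise ValueError("all member tensors singular; micro ODF undefined")
    if skipped:
        warnings.warn(f"skipped {skipped} singular member tensors in micro ODF", RuntimeWarning)
    return total / used


@dataclass
class StainReport:
    """The stain panel for one DTD."""

    mu_fa: float
    fa_of_mean: float
    v_size: float
    v_shape: float
    v_orient: float
    entropy: float
    odf_entropy_micro: float

    def as_dict(self) -> dict:
        return {
            "mu_fa": self.mu_fa,
            "fa_of_mean": self.fa_of_mean,
            "v_size": self.v_size,
            "v_shape": self.v_shape,
            "v_orient": self.v_orient,
            "entropy": self.entropy,
            "odf_entropy_micro": self.odf_entropy_micro,
        }


def stain_report(
    ensemble: TensorEnsemble | np.ndarray,
    params: CNTVDParams | None = None,
    grid: SphereGrid | None = None,
    odf_subsample: int = 2000,
    seed: int = 0,
) -> StainReport:
    """All stains for one ensemble (ODF entropy on a subsample for speed)."""
    from .cntvd import empirical_moments

    d6 = ensemble.d6 if isinstance(ensemble, TensorEnsemble) else np.atleast_2d(ensemble)
    if params is None:
        mean, omega = empirical_moments(d6)
        params = CNTVDParams(mean_d6=mean, omega=omega)
    grid = grid or default_grid()
    rng = np.random.default_rng(seed)
    sub = d6 if len(d6) <= odf_subsample else d6[rng.choice(len(d6), odf_subsample, replace=False)]
    try:
        odf_ent = micro_average(sub, "odf_entropy", grid=grid)
    except np.linalg.LinAlgError:
        odf_ent = np.nan
    return StainReport(
        mu_fa=micro_average(d6, "fa"),
        fa_of_mean=fa(params.mean_d6),
        v_size=v_size(params.omega),
        v_shape=v_shape(d6),
        v_orient=v_orient(d6),
        entropy=micro_average(d6, "neg_log_density", params=params, seed=seed),
        odf_entropy_micro=odf_ent,
    )


def export_glyph_mesh(radii: np.ndarray, grid: SphereGrid, path) -> None:
    """Write the glyph surface (vertices radius * direction) as PLY or OBJ.

    Requires a grid with regular (n_theta, n_phi) topology.
    """
    import trimesh

    radii = np.asarray(radii, dtype=float).reshape(-1)
    if radii.min() < 0:
        raise ValueError("radii must be non-negative")
    if radii.max() <= 0:
        raise ValueError("all radii are zero; degenerate glyph mesh")
    if grid.shape is None:
        raise ValueError("mesh export needs a regular (n_theta, n_phi) grid")
    nt, np_ = grid.shape
    verts = radii[:, None] * grid.directions
    faces = []
    for i in range(nt - 1):
        for j in range(np_):
            j2 = (j + 1) % np_
            a, b = i * np_ + j, i * np_ + j2
            c, d = (i + 1) * np_ + j, (i + 1) * np_ + j2
            faces.append([a, b, d])
            faces.append([a, d, c])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    mesh.export(str(path))
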