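"""Synthetic DTD motifs emulating gray- and white-matter voxels.

Each motif is an ensemble of physical micro diffusion tensors built by
randomly varying eigenvalues and/or eigenvectors of a template tensor;
the empirical first two moments of the ensemble define the ground-truth
CNTVD parameters used for signal synthesis and estimator benchmarking.

Motifs (distinguished axis along x-hat):

``uniform``          one repeated tensor (zero covariance);
``iso_emulsion``     isotropic tensors, trace normally distributed
                     (truncated at zero by rejection) — size heterogeneity;
``shape_het``        equal-thirds mixture of prolate, oblate and spherical
                     tensors sharing one trace and one eigenframe;
``full_het``         random sizes, shapes and orientations;
``aniso_emulsion``   one prolate shape, random overall scale;
``transverse_size``  fixed longitudinal eigenvalue, jointly random
                     transverse eigenvalues (fiber-diameter spread);
``crossing_90``      two equal populations of identical prolate tensors
                     with principal axes 90 degrees apart (x and y);
``continuous_mix``   handled by :func:`continuous_mix`.

Default diffusivities are brain-plausible: mean diffusivity 0.8 um^2/ms,
prolate template eigenvalues (1.7, 0.2, 0.2) um^2/ms, coefficient of
variation 0.25 for the emulsions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cntvd import CNTVDParams, TensorEnsemble, empirical_moments
from .tensor_algebra import matrix_to_d6

__all__ = ["MOTIF_KINDS", "MotifSpec", "make_motif", "continuous_mix"]

MOTIF_KINDS = (
    "uniform",
    "iso_emulsion",
    "shape_het",
    "full_het",
    "aniso_emulsion",
    "transverse_size",
    "crossing_90",
)


@dataclass
class MotifSpec:
    """Recipe for one DTD motif."""

    kind: str = "uniform"
    base_eigenvalues: tuple[float, float, float] = (0.8, 0.8, 0.8)
    prolate_eigenvalues: tuple[float, float, float] = (1.7, 0.2, 0.2)
    trace_cv: float = 0.25
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    crossing_angle_deg: float = 90.0
    random_orientations: bool = False
    shape_mode: str = "triplet"  # 'triplet' (isotropic mean) or 'aspect' (coherent frame)
    aspect_range: tuple[float, float] = (0.25, 1.0)
    n: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MOTIF_KINDS:
            raise ValueError(f"unknown motif kind {self.kind!r}; choose from {MOTIF_KINDS}")
        if min(self.base_eigenvalues) < 0 or min(self.prolate_eigenvalues) < 0:
            raise ValueError("eigenvalues must be non-negative")
        if self.trace_cv < 0:
            raise ValueError("trace_cv must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9 or min(self.weights) < 0:
            raise ValueError("weights must be non-negative and sum to 1")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws rejected at zero, mirroring the 6-D PSD filter."""
    if sd == 0:
        return np.full(size, mean)
    out = np.empty(size)
    have = 0
    while have < size:
        block = rng.normal(mean, sd, size=2 * (size - have) + 16)
        block = block[block >= 0.0]
        take = min(len(block), size - have)
        out[have : have + take] = block[:take]
        have += take
    return out


#: transverse-to-mean-diffusivity ratio of the shape-het prolate member
_SHAPE_HET_Q = 0.6


def _shape_het_triplet(spec: MotifSpec) -> np.ndarray:
    """Prolate/oblate/sphere eigenvalue rows sharing one trace, axis on x.

    With equal mixing weights and a shared trace 3*md, an isotropic
    ensemble mean forces the oblate shape once the prolate one is chosen:
    writing the prolate transverse eigenvalue as q*md, the prolate is
    md*(3-2q, q, q) and the oblate md*(2q-1, 2-q, 2-q), q in (1/2, 1).
    """
    md = float(np.mean(spec.base_eigenvalues))
    q = _SHAPE_HET_Q
    p = md * np.array([3 - 2 * q, q, q])  # prolate: long axis on x
    ob = md * np.array([2 * q - 1, 2 - q, 2 - q])  # oblate: short axis on x
    sph = np.full(3, md)
    return np.vstack([p, ob, sph])


def _motif_d6(spec: MotifSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n
    kind = spec.kind
    if kind == "uniform":
        d6 = np.zeros((n, 6))
        d6[:, :3] = np.asarray(spec.base_eigenvalues, dtype=float)
    elif kind == "iso_emulsion":
        md = float(np.mean(spec.base_eigenvalues))
        d = _truncated_normal(rng, md, spec.trace_cv * md, n)
        d6 = np.zeros((n, 6))
        d6[:, :3] = d[:, None]
    elif kind == "shape_het":
        if spec.shape_mode == "aspect":
            # prolate aspect-ratio spread at fixed trace, coherent frame on x:
            # eigenvalues md*(3-2t, t, t) with t uniform; no eigenvalue crossing
            md = float(np.mean(spec.base_eigenvalues))
            t = md * rng.uniform(*spec.aspect_range, size=n)
            d6 = np.zeros((n, 6))
            d6[:, 0] = 3 * md - 2 * t
            d6[:, 1] = t
            d6[:, 2] = t
        elif spec.shape_mode == "triplet":
            rows = _shape_het_triplet(spec)
            counts = np.floor(np.asarray(spec.weights) * n).astype(int)
            counts[0] += n - counts.sum()
            d6 = np.zeros((n, 6))
            d6[:, :3] = np.repeat(rows, counts, axis=0)
            rng.shuffle(d6)
        else:
            raise ValueError(f"unknown shape_mode {spec.shape_mode!r}")
    elif kind == "full_het":
        md = float(np.mean(spec.base_eigenvalues))
        lam = _truncated_normal(rng, md, spec.trace_cv * md, 3 * n).reshape(n, 3)
        d6 = _randomly_rotate_eigs(lam, rng)
    elif kind == "aniso_emulsion":
        scale = _truncated_normal(rng, 1.0, spec.trace_cv, n)
        d6 = np.zeros((n, 6))
        d6[:, :3] = scale[:, None] * np.asarray(spec.prolate_eigenvalues, dtype=float)
    elif kind == "transverse_size":
        long_ax, trans = spec.prolate_eigenvalues[0], spec.prolate_eigenvalues[1]
        t = _truncated_normal(rng, trans, spec.trace_cv * trans, n)
        d6 = np.zeros((n, 6))
        d6[:, 0] = long_ax
        d6[:, 1] = t
        d6[:, 2] = t
    elif kind == "crossing_90":
        ang = np.deg2rad(spec.crossing_angle_deg)
        if abs(spec.crossing_angle_deg - 90.0) > 1e-9:
            warnings.warn(
                "crossing angles other than 90 degrees are outside CNTVD "
                "representability (mixture models required)",
                RuntimeWarning,
            )
        p = np.asarray(spec.prolate_eigenvalues, dtype=float)
        d_a = np.diag(p)  # fiber along x
        c, s = np.cos(ang), np.sin(ang)
        rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        d_b = rz @ d_a @ rz.T
        d6 = np.empty((n, 6))
        d6[0::2] = matrix_to_d6(d_a)
        d6[1::2] = matrix_to_d6(d_b)
    else:  # pragma: no cover - guarded by MotifSpec
        raise ValueError(kind)
    if spec.random_orientations:
        d6 = _apply_random_rotations(d6, rng)
    return d6


def _randomly_rotate_eigs(lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d6 = np.zeros((len(lam), 6))
    d6[:, :3] = lam
    return _apply_random_rotations(d6, rng)


def _apply_random_rotations(d6: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from .tensor_algebra import d6_to_matrix

    rots = Rotation.random(len(d6), random_state=rng).as_matrix()
    mats = d6_to_matrix(d6)
    rotated = np.einsum("nab,nbc,ndc->nad", rots, mats, rots)
    return matrix_to_d6(rotated)


def make_motif(spec: MotifSpec) -> tuple[TensorEnsemble, CNTVDParams]:
    """Build the motif ensemble and its empirical (mean, covariance) parameters."""
    rng = np.random.default_rng(spec.seed)
    d6 = _motif_d6(spec, rng)
    ensemble = TensorEnsemble(d6, n_proposed=spec.n, seed=spec.seed)
    mean, omega = empirical_moments(ensemble)
    params = CNTVDParams(mean_d6=mean, omega=omega)
    return ensemble, params


def continuous_mix(
    spec_a: MotifSpec, spec_b: MotifSpec, weight_grid
) -> list[tuple[TensorEnsemble, CNTVDParams]]:
    """Ensembles interpolating between two motifs by mixing fraction.

    Weight 0 reproduces motif A exactly, weight 1 motif B exactly; in
    between, a fraction of the samples is swapped for motif-B samples.
    """
    weights = np.asarray(list(weight_grid), dtype=float)
    if weights.size == 0:
        raise ValueError("weight grid is empty")
    if weights.min() < 0 or weights.max() > 1:
        raise ValueError("weights must lie in [0, 1]")
    ens_a, _ = make_motif(spec_a)
    ens_b, _ = make_motif(spec_b)
    n = min(len(ens_a), len(ens_b))
    out = []
    for w in weights:
        n_b = int(round(w * n))
        d6 = np.vstack([ens_a.d6[: n - n_b], ens_b.d6[:n_b]])
        ens = TensorEnsemble(d6, n_proposed=n)
        mean, omega = empirical_moments(ens)
        out.append((ens, CNTVDParams(mean_d6=mean, omega=omega)))
    return out
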