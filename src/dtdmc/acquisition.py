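"""Compressed-sensing-style random b-matrix designs.

The acquisition is a set of symmetric PSD b-matrices of rank 1 and 2
whose trace (total diffusion weighting) is uniform over the b-value
range, whose eigenvalue ratio is uniform (rank 2), and whose orientation
is randomized by drawing Euler angles and the rotation order at random.
A single b = 0 measurement is always prepended to anchor S0.

Mixing rank-1 and rank-2 matrices is essential: rank-1 designs only probe
the fully symmetric part of the fourth-order covariance (15 of 21
dimensions), while a mixed design spans all 21 — :func:`audit_design`
reports this rank along with the size/shape/orientation uniformity
summaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .tensor_algebra import bvec_from_bmatrix, euler_rotation

__all__ = ["BMatrix", "BMatrixDesign", "design_bmatrices", "audit_design", "covariance_design_rank"]

_ORDERS = ["".join(p) for p in itertools.permutations("XYZ")]


@dataclass
class BMatrix:
    """One symmetric PSD diffusion-weighting matrix (ms/um^2)."""

    matrix: np.ndarray
    rank: int
    eigenparams: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)

    @property
    def b6(self) -> np.ndarray:
        """(bxx, byy, bzz, 2bxy, 2bxz, 2byz) contraction vector."""
        return bvec_from_bmatrix(self.matrix)

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


@dataclass
class BMatrixDesign:
    """Ordered b-matrix set with its generation settings."""

    bmatrices: list[BMatrix]
    b_range: tuple[float, float]
    rank_mix: float
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.bmatrices)

    @property
    def b6(self) -> np.ndarray:
        """Stacked contraction vectors, shape (n, 6)."""
        return np.array([b.b6 for b in self.bmatrices])

    @property
    def traces(self) -> np.ndarray:
        return np.array([b.trace for b in self.bmatrices])

    @property
    def ranks(self) -> np.ndarray:
        return np.array([b.rank for b in self.bmatrices])


def design_bmatrices(
    n: int = 216,
    b_range: tuple[float, float] = (0.0, 5.0),
    rank_mix: float = 0.5,
    seed: int | None = None,
    haar_orientations: bool = False,
    n_params_intended: int = 28,
) -> BMatrixDesign:
    """Sample a mixed rank-1/rank-2 design of ``n`` b-matrices.

    Traces are uniform over ``b_range``; rank-2 eigenvalue ratios uniform
    on (0, 1]; orientations from uniform Euler angles with randomized
    rotation order (set ``haar_orientations`` for exactly uniform random
    rotations instead).  The first entry is the exact b = 0 anchor.
    """
    if n < 28:
        raise ValueError("need at least 28 b-matrices (most general model size)")
    b_min, b_max = b_range
    if not (b_max > b_min >= 0):
        raise ValueError("require b_max > b_min >= 0")
    if n < n_params_intended:
        warnings.warn("fewer b-matrices than model parameters", RuntimeWarning)
    rng = np.random.default_rng(seed)
    mats = [BMatrix(np.zeros((3, 3)), rank=0, eigenparams={"anchor": True})]
    n_rank1 = int(round((n - 1) * rank_mix))
    ranks = np.array([1] * n_rank1 + [2] * (n - 1 - n_rank1))
    rng.shuffle(ranks)
    for rank in ranks:
        trace = rng.uniform(b_min, b_max)
        if rank == 1:
            lam = np.array([trace, 0.0, 0.0])
        else:
            ratio = 1.0 - rng.uniform(0.0, 1.0)  # lam2/lam1 uniform on (0, 1]
            lam1 = trace / (1.0 + ratio)
            lam = np.array([lam1, ratio * lam1, 0.0])
        if haar_orientations:
            r = Rotation.random(random_state=rng).as_matrix()
            eig = {"lambdas": lam[:rank], "haar": True}
        else:
            angles = rng.uniform(0.0, 2 * np.pi, size=3)
            order = _ORDERS[rng.integers(len(_ORDERS))]
            r = euler_rotation(*angles, order=order)
            eig = {"lambdas": lam[:rank], "angles": angles, "order": order}
        mats.append(BMatrix(r @ np.diag(lam) @ r.T, rank=int(rank), eigenparams=eig))
    return BMatrixDesign(mats, b_range=b_range, rank_mix=rank_mix, seed=seed)


def covariance_design_rank(design: BMatrixDesign, rtol: float = 1e-10) -> int:
    """Rank of the map from 21-D covariance space to the quadratic signal terms.

    Row k holds the coefficients of each independent omega entry in
    ``b6_k^T Omega b6_k``; a full mixed rank-1/rank-2 design reaches 21.
    """
    b6 = design.b6
    cols = []
    for i in range(6):
        for j in range(i, 6):
            coef = b6[:, i] * b6[:, j]
            cols.append(coef if i == j else 2.0 * coef)
    a = np.column_stack(cols)
    return int(np.linalg.matrix_rank(a, tol=rtol * max(np.abs(a).max(), 1.0)))


def audit_design(design: BMatrixDesign, n_bins: int = 20) -> dict:
    """Uniformity and spanning report for a design (size/shape/orientation)."""
    if len(design) == 0:
        raise ValueError("empty design")
    nonzero = [b for b in design.bmatrices if b.trace > 1e-12]
    traces = np.array([b.trace for b in nonzero])
    ratios = []
    principals = []
    for b in nonzero:
        w, v = np.linalg.eigh(b.matrix)
        w = w[::-1]
        v = v[:, ::-1]
        principals.append(v[:, 0])
        if b.rank >= 2:
            ratios.append(w[1] / w[0])
    principals = np.array(principals)
    dyadic = np.einsum("ni,nj->ij", principals, principals) / len(principals)
    beta = np.sort(np.linalg.eigvalsh(dyadic))[::-1]
    dispersion = float(np.sqrt((beta[1] + beta[2]) / (2 * beta[0])))
    trace_hist = np.histogram(traces, bins=n_bins, range=design.b_range)
    ratio_hist = np.histogram(np.array(ratios), bins=n_bins, range=(0.0, 1.0))
    return {
        "n": len(design),
        "n_rank1": int((design.ranks == 1).sum()),
        "n_rank2": int((design.ranks == 2).sum()),
        "trace_hist": trace_hist,
        "ratio_hist": ratio_hist,
        "orientation_dispersion": dispersion,
        "covariance_space_rank": covariance_design_rank(design),
    }
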