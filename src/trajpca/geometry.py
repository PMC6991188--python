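"""Structural alignment, mass-weighting, distance representations, chirality.

All coordinate math operates on arrays of shape ``(n_atoms, 3)`` (a frame) or
``(n_frames, n_atoms, 3)`` (a trajectory).  Mass-weighted coordinates carry
units of Angstrom * amu**0.5; weighting always happens *after* alignment,
because rigid-motion removal is only meaningful on unweighted geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import Trajectory

__all__ = [
    "AlignedCoordinates",
    "ChiralityCenter",
    "kabsch_rotation",
    "align_frame",
    "align_trajectory",
    "mass_weight",
    "unmass_weight",
    "squared_distance_matrix",
    "squared_distance_vector",
    "flatten_upper",
    "unflatten",
    "chirality_sign",
]

#: |det| below this (coordinates in Angstrom) counts as coplanar -> sign 0
PLANARITY_TOL = 1e-6


@dataclass
class AlignedCoordinates:
    """Trajectory coordinates after centroid-centering and Kabsch alignment.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; ``reference_index`` is
    the frame everything was rotated onto (itself only centered).
    """

    coords: np.ndarray
    reference_index: int = 0
    mass_weighted: bool = False

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def flattened(self) -> np.ndarray:
        """(n_frames, 3 * n_atoms) view used as the PCA input matrix."""
        return self.coords.reshape(self.n_frames, -1)


@dataclass(frozen=True)
class ChiralityCenter:
    """Four 1-based atom indices surrounding a stereogenic center."""

    indices: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != 4:
            raise ValueError(f"chirality center needs four distinct atoms, got {idx}")
        if min(idx) < 1:
            raise ValueError("atom indices are 1-based")
        object.__setattr__(self, "indices", idx)

    def zero_based(self, n_atoms: int) -> np.ndarray:
        idx = np.asarray(self.indices) - 1
        if idx.max() >= n_atoms:
            raise ValueError(
                f"chirality atom index {idx.max() + 1} exceeds atom count {n_atoms}"
            )
        return idx


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R (3x3, det=+1) minimizing RMSD of R@P onto Q.

    Both point sets are centroid-centered internally, so the returned matrix
    is purely rotational; apply it to centered coordinates.  Coincident
    (fully degenerate) point sets yield the identity.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must share shape (N, 3), got {P.shape} vs {Q.shape}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    if not np.any(np.abs(H) > 1e-15):
        return np.eye(3)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    return Vt.T @ D @ U.T


def align_frame(frame: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Center ``frame`` and rotate it onto the centered ``reference``."""
    ref_c = reference - np.asarray(reference).mean(axis=0)
    frame_c = frame - np.asarray(frame).mean(axis=0)
    R = kabsch_rotation(frame_c, ref_c)
    return frame_c @ R.T


def align_trajectory(traj: Trajectory, reference: int = 0) -> AlignedCoordinates:
    """Remove rigid-body motion: center every frame and rotate onto the
    reference frame (first frame by default).  The reference itself is only
    translated to its centroid."""
    n = traj.n_frames
    if not (-n <= reference < n):
        raise IndexError(f"reference frame {reference} out of range for {n} frames")
    reference %= n
    ref = traj.coords[reference]
    out = np.empty_like(traj.coords)
    for k in range(n):
        out[k] = align_frame(traj.coords[k], ref)
    return AlignedCoordinates(out, reference_index=reference, mass_weighted=False)


def mass_weight(coords: AlignedCoordinates, masses: np.ndarray) -> AlignedCoordinates:
    """Scale each atom's coordinates by sqrt(mass). Refuses double weighting."""
    if coords.mass_weighted:
        raise ValueError("coordinates are already mass-weighted")
    w = np.sqrt(np.asarray(masses, dtype=float))
    if w.shape != (coords.n_atoms,):
        raise ValueError("need one mass per atom")
    return AlignedCoordinates(
        coords.coords * w[None, :, None],
        reference_index=coords.reference_index,
        mass_weighted=True,
    )


def unmass_weight(coords: AlignedCoordinates, masses: np.ndarray) -> AlignedCoordinates:
    """Exact inverse of :func:`mass_weight` (divide by sqrt(mass))."""
    if not coords.mass_weighted:
        raise ValueError("coordinates are not mass-weighted")
    w = np.sqrt(np.asarray(masses, dtype=float))
    return AlignedCoordinates(
        coords.coords / w[None, :, None],
        reference_index=coords.reference_index,
        mass_weighted=False,
    )


def squared_distance_matrix(frame: np.ndarray) -> np.ndarray:
    """N x N matrix of squared Euclidean interatomic distances.

    Rigid-motion invariant by construction; requires at least two atoms.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] < 2:
        raise ValueError("frame must be (N >= 2, 3)")
    return squareform(pdist(frame, metric="sqeuclidean"))


def squared_distance_vector(frame: np.ndarray) -> np.ndarray:
    """Flattened upper triangle (row-major, i<j) of the squared-distance
    matrix, length N(N-1)/2 — the per-frame 'Distances' feature vector."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] < 2:
        raise ValueError("frame must be (N >= 2, 3)")
    return pdist(frame, metric="sqeuclidean")


def flatten_upper(mat: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Row-major (i<j) upper-triangle flattening of a symmetric zero-diagonal
    matrix into a vector of length N(N-1)/2."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(mat, mat.T, atol=atol):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=atol):
        raise ValueError("matrix must have a zero diagonal")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def unflatten(vec: np.ndarray, n_atoms: int) -> np.ndarray:
    """Inverse of :func:`flatten_upper`.  Negative entries pass through
    unchanged — reduced-dimensional predistance vectors may contain them."""
    vec = np.asarray(vec, dtype=float)
    expected = n_atoms * (n_atoms - 1) // 2
    if vec.shape != (expected,):
        raise ValueError(
            f"vector length {vec.shape} does not match N(N-1)/2 = {expected} "
            f"for {n_atoms} atoms"
        )
    mat = np.zeros((n_atoms, n_atoms))
    iu = np.triu_indices(n_atoms, k=1)
    mat[iu] = vec
    return mat + mat.T


def chirality_sign(
    frame: np.ndarray, center: ChiralityCenter, tol: float = PLANARITY_TOL
) -> int:
    """Handedness of four atoms around a stereogenic center.

    Sign of the 4x4 determinant with rows (x_i, y_i, z_i, 1) over the four
    atoms; 0 when |det| < ``tol``, i.e. the quadruple is (numerically)
    coplanar.  Mirror reflection of the frame flips the sign.
    """
    frame = np.asarray(frame, dtype=float)
    idx = center.zero_based(frame.shape[0])
    m = np.ones((4, 4))
    m[:, :3] = frame[idx]
    det = np.linalg.det(m)
    if abs(det) < tol:
        return 0
    return 1 if det > 0 else -1
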