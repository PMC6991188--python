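"""Back-transformation of reduced paths into full-dimensional Cartesians.

The Cartesian branch is a plain linear back-projection (scores times weights
plus the mean structure).  The distances branch is harder: each
back-projected row is a flattened *predistance* matrix — symmetric, zero
diagonal, but not necessarily realizable by any 3-D point set once
dimensionality has been reduced.  Coordinates are recovered per frame by the
classical-MDS route: form the Gram matrix anchored on atom 1, eigendecompose
it, and embed with the top three eigenpairs (negative eigenvalues clamped to
zero).  The spectral mass beyond the top three eigenvalues is reported as a
per-frame diagnostic of how far the predistance matrix is from a true
distance matrix.

Distance matrices carry no handedness, so each recovered frame lands in an
arbitrary reflective configuration; when a stereogenic center is supplied,
frames whose chirality sign disagrees with the analogous source frame are
mirror-reflected.  Finally every frame is Kabsch-aligned onto the analogous
aligned source frame, which makes full-rank reconstructions reproduce the
aligned input exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import Trajectory
from .geometry import (
    ChiralityCenter,
    align_frame,
    align_trajectory,
    chirality_sign,
    unflatten,
)
from .model import PathPCAResults, ReducedPath

__all__ = [
    "GramDecomposition",
    "ReconstructionResult",
    "back_project",
    "gram_matrix",
    "gram_decomposition",
    "coords_from_gram",
    "fix_reflections",
    "reconstruct_trajectory",
]


@dataclass
class GramDecomposition:
    """Eigendecomposition of a Gram matrix built from a (pre)distance matrix.

    ``trailing_mass`` is the summed |eigenvalue| beyond the top three — zero
    (to rounding) iff the distance matrix is realizable in 3-D.
    """

    G: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def trailing_mass(self) -> float:
        return float(np.sum(np.abs(self.eigenvalues[3:])))


@dataclass
class ReconstructionResult:
    """Full-dimensional Cartesian paths recovered from selected components.

    ``per_pc`` maps a 1-based component index to the trajectory obtained
    from that component alone; ``combined`` uses all selected components at
    once.  ``trailing_mass`` holds the per-frame Gram trailing-spectrum mass
    of the combined reconstruction (all zeros on the Cartesian branch).
    """

    per_pc: dict[int, Trajectory]
    combined: Trajectory
    trailing_mass: np.ndarray


def back_project(
    results: PathPCAResults, path: ReducedPath, pcs: Iterable[int]
) -> np.ndarray:
    """Linear back-projection X~ = T W + mean restricted to components
    ``pcs`` (1-based).  An empty selection returns n copies of the mean
    structure (the documented degenerate case, not an error)."""
    pcs = sorted(set(int(i) for i in pcs))
    n_comp = results.components.shape[0]
    if any(i < 1 or i > n_comp for i in pcs):
        raise ValueError(f"component indices must lie in [1, {n_comp}], got {pcs}")
    if any(i > path.n_dim for i in pcs):
        raise ValueError(
            f"path holds only the top {path.n_dim} scores; cannot use PCs {pcs}"
        )
    out = np.tile(results.mean, (path.n_frames, 1))
    for i in pcs:
        out += np.outer(path.scores[:, i - 1], results.components[i - 1])
    return out


def gram_matrix(D: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Gram matrix G_ij = (D_i1 + D_j1 - D_ij)/2 anchored on atom 1.

    ``D`` must be symmetric with a zero diagonal; entries may be negative
    (predistance matrices).  The anchoring places atom 1 at the origin of
    the recovered coordinates.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > atol):
        raise ValueError("distance matrix must have a zero diagonal")
    d1 = D[:, 0]
    return 0.5 * (d1[:, None] + d1[None, :] - D)


def gram_decomposition(D: np.ndarray) -> GramDecomposition:
    """Gram matrix of ``D`` with its eigenpairs sorted by descending
    eigenvalue (ties broken by original index, for determinism)."""
    G = gram_matrix(D)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(-evals, kind="stable")
    return GramDecomposition(G=G, eigenvalues=evals[order], eigenvectors=evecs[:, order])


def coords_from_gram(decomp: GramDecomposition) -> np.ndarray:
    """Embed a Gram decomposition in 3-D: U_G[:, :3] * sqrt(lambda[:3]).

    Negative eigenvalues are clamped to zero before the square root (the
    standard classical-MDS resolution for predistance input), so the output
    is always real.  Atom 1 sits at the origin by the Gram anchoring.
    """
    lam = np.clip(decomp.eigenvalues[:3], 0.0, None)
    return decomp.eigenvectors[:, :3] * np.sqrt(lam)[None, :]


def fix_reflections(
    frames: Trajectory, center: ChiralityCenter, reference: Trajectory
) -> Trajectory:
    """Mirror-reflect frames whose chirality disagrees with the reference.

    Frame k is reflected (z negated) iff both its own sign and the
    reference frame k's sign are nonzero and they differ.  Frames at or
    near planarity (sign 0) on either side are left untouched.  The
    operation is idempotent.
    """
    if frames.n_frames != reference.n_frames or frames.n_atoms != reference.n_atoms:
        raise ValueError("frames and reference must agree in n_frames and n_atoms")
    coords = frames.coords.copy()
    for k in range(frames.n_frames):
        s = chirality_sign(coords[k], center)
        s_ref = chirality_sign(reference.coords[k], center)
        if s != 0 and s_ref != 0 and s != s_ref:
            coords[k, :, 2] *= -1.0
    return Trajectory(frames.elements, coords, list(frames.comments))


def reconstruct_trajectory(
    results: PathPCAResults,
    path: ReducedPath,
    source: Trajectory,
    center: ChiralityCenter | None = None,
    pcs: Iterable[int] | None = None,
) -> ReconstructionResult:
    """Recover Cartesian trajectories from selected principal components.

    Cartesian branch: back-project, reshape to (N, 3) frames, un-mass-weight
    if the model was mass-weighted, align each frame to the analogous
    aligned source frame.  Distances branch: back-project, unflatten each
    row into a predistance matrix, Gram-embed it, fix reflections against
    the source when a stereogenic ``center`` is given, un-mass-weight, then
    align likewise.

    Returns one trajectory per selected component and one combined
    trajectory using all of them.
    """
    if pcs is None:
        pcs = range(1, path.n_dim + 1)
    pcs = sorted(set(int(i) for i in pcs))
    if source.n_frames != path.n_frames:
        raise ValueError("source trajectory and reduced path disagree in n_frames")

    rep = results.rep_matrix
    if rep.representation == "distances" and center is None:
        warnings.warn(
            "no stereogenic center supplied: reconstructed frames keep the "
            "arbitrary reflective configuration of the Gram embedding",
            stacklevel=2,
        )

    # final alignment targets: the aligned, unweighted source frames
    aligned_src = align_trajectory(source, reference=0)
    aligned_ref = Trajectory(source.elements, aligned_src.coords, list(source.comments))

    masses = source.masses() if rep.mass_weighted else None
    # chirality is compared in the space the frames are recovered in: the
    # mass-weighted aligned source when the model was mass-weighted
    if masses is not None:
        chir_ref = Trajectory(
            source.elements,
            aligned_src.coords * np.sqrt(masses)[None, :, None],
            list(source.comments),
        )
    else:
        chir_ref = aligned_ref

    def _realize(flat_rows: np.ndarray) -> tuple[Trajectory, np.ndarray]:
        n = flat_rows.shape[0]
        frames = np.empty((n, rep.n_atoms, 3))
        trailing = np.zeros(n)
        if rep.representation == "cartesians":
            frames[:] = flat_rows.reshape(n, rep.n_atoms, 3)
        else:
            for k in range(n):
                D = unflatten(flat_rows[k], rep.n_atoms)
                dec = gram_decomposition(D)
                frames[k] = coords_from_gram(dec)
                trailing[k] = dec.trailing_mass
        traj = Trajectory(source.elements, frames, list(source.comments))
        if rep.representation == "distances" and center is not None:
            traj = fix_reflections(traj, center, chir_ref)
        if masses is not None:
            # the Gram embedding's arbitrary rotation must come off while the
            # frame is still mass-weighted: per-atom scaling does not commute
            # with rotation, so un-weighting a rotated frame would distort it
            if rep.representation == "distances":
                pre = np.empty_like(traj.coords)
                for k in range(n):
                    # re-add the reference centroid: dividing by sqrt(m) is
                    # only exact in the reference's own (uncentered)
                    # mass-weighted frame
                    pre[k] = align_frame(
                        traj.coords[k], chir_ref.coords[k]
                    ) + chir_ref.coords[k].mean(axis=0)
                traj = Trajectory(traj.elements, pre, list(traj.comments))
            traj = Trajectory(
                traj.elements,
                traj.coords / np.sqrt(masses)[None, :, None],
                list(traj.comments),
            )
        out = np.empty_like(traj.coords)
        for k in range(n):
            out[k] = align_frame(traj.coords[k], aligned_ref.coords[k])
        return Trajectory(traj.elements, out, list(traj.comments)), trailing

    per_pc: dict[int, Trajectory] = {}
    for i in pcs:
        traj_i, _ = _realize(back_project(results, path, [i]))
        per_pc[i] = traj_i
    combined, trailing = _realize(back_project(results, path, pcs))
    return ReconstructionResult(per_pc=per_pc, combined=combined, trailing_mass=trailing)
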