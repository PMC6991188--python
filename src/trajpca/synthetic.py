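"""Synthetic trajectories with known low-dimensional structure.

These generators build toy molecular paths whose geometry is controlled
exactly — a single stretching bond, a pure dihedral sweep, a bifurcating
pair of torsional branches, an oscillation about a base path, and rigid
rotation/translation contamination — so that every pipeline stage can be
exercised without any external data.  Atoms are unit-mass pseudo-atoms
("X") by default, keeping mass-weighting tests independent of geometry
tests; real element symbols can be substituted.

All generators are deterministic for a fixed seed and emit ordinary
:class:`~trajpca.io.Trajectory` objects that the full pipeline consumes
with no special casing.  They are geometric constructions only: no force
field, no energies, no thermal sampling.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .io import Trajectory

__all__ = [
    "make_stretch",
    "make_torsion",
    "make_bifurcating",
    "make_oscillating_path",
    "add_rigid_motion",
    "TORSION_CHIRALITY_ATOMS",
    "BIFURCATION_CHIRALITY_ATOMS",
]


def _rotation_about_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def make_stretch(
    n_frames: int = 40,
    n_atoms: int = 6,
    d_start: float = 1.2,
    d_end: float = 3.0,
    seed: int = 0,
) -> Trajectory:
    """One interatomic distance varies linearly; everything else is rigid.

    Atom 0 recedes from a rigid, randomly packed cluster (atoms 1..N-1)
    along +x, from ``d_start`` to ``d_end`` Angstrom — the minimal analog of
    a single-coordinate reaction path such as a bond dissociation.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    if not (d_start > 0 and d_end > 0):
        raise ValueError("separations must be positive")
    rng = np.random.default_rng(seed)
    # rejection-sample the rigid cluster so no two atoms sit closer than a
    # bond-like 0.9 A, whatever the seed
    anchor = rng.uniform(-0.3, 0.3, size=3)
    placed = [anchor]
    while len(placed) < n_atoms - 1:
        cand = rng.uniform(-1.2, 1.2, size=3)
        if min(np.linalg.norm(cand - p) for p in placed) < 0.9:
            continue
        # keep the +x dissociation channel of the departing atom clear
        rel = cand - anchor
        t = max(rel[0], 0.0)
        if np.linalg.norm(rel - np.array([t, 0.0, 0.0])) < 0.9:
            continue
        placed.append(cand)
    cluster = np.array(placed)
    cluster -= cluster.mean(axis=0)
    coords = np.empty((n_frames, n_atoms, 3))
    for k, d in enumerate(np.linspace(d_start, d_end, n_frames)):
        coords[k, 0] = cluster[0] + np.array([d, 0.0, 0.0])
        coords[k, 1:] = cluster
    return Trajectory(("X",) * n_atoms, coords,
                      [f"stretch frame {k}" for k in range(n_frames)])


# atoms forming a stereogenic quadruple in the torsion/bifurcation toys
# (1-based): pivot substituent, the two rotor atoms, and the far axis atom
TORSION_CHIRALITY_ATOMS = (3, 5, 6, 1)


def _torsion_frame(theta: float) -> np.ndarray:
    """Two rigid groups joined by an x-axis bond; the second group is
    rotated about that axis by ``theta``."""
    a = np.array([0.0, 0.0, 0.0])          # axis atom 1
    b = np.array([1.5, 0.0, 0.0])          # axis atom 2 (pivot)
    g1 = np.array(
        [
            [-0.7, 1.1, 0.0],              # substituents on atom 1 (static)
            [-0.7, -0.9, 0.4],
        ]
    )
    g2_local = np.array(
        [
            [2.2, 1.1, 0.0],               # substituents on atom 2 (rotor)
            [2.2, -0.8, 0.5],
        ]
    )
    R = _rotation_about_x(theta)
    g2 = (g2_local - b) @ R.T + b
    return np.vstack([a, b, g1, g2])


def make_torsion(n_frames: int = 37, angle_end: float = np.pi) -> Trajectory:
    """Pure dihedral sweep from 0 to ``angle_end`` (default 180 deg).

    Six atoms in two rigid groups rotate about the central bond; all bond
    lengths and within-group distances are constant, so the only structural
    change is torsional — the motion Cartesian PCA represents poorly and
    distance PCA captures in one component.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    coords = np.stack(
        [_torsion_frame(t) for t in np.linspace(0.0, angle_end, n_frames)]
    )
    return Trajectory(("X",) * 6, coords,
                      [f"torsion frame {k}" for k in range(n_frames)])


BIFURCATION_CHIRALITY_ATOMS = (3, 5, 6, 1)


def make_bifurcating(
    n_frames: int = 40,
    stem_fraction: float = 0.4,
    branch_angle: float = 2.0 * np.pi / 3.0,
) -> Trajectory:
    """A shared stem followed by two branches related by opposite torsions.

    The first half of the trajectory runs stem -> branch A (torsion to
    ``+branch_angle``), the second half stem -> branch B (torsion to
    ``-branch_angle``), with fixed atom numbering throughout.  The branch
    endpoints are mirror images related by a torsion, not by relabeling, so
    their interatomic distance matrices differ and their chirality signs
    (quadruple :data:`BIFURCATION_CHIRALITY_ATOMS`) are opposite — the toy
    analog of a post-transition-state bifurcation into enantiomeric
    products.
    """
    if n_frames < 4 or n_frames % 2:
        raise ValueError("need an even n_frames >= 4")
    if not 0.0 < stem_fraction < 1.0:
        raise ValueError("stem_fraction must lie in (0, 1)")
    half = n_frames // 2
    n_stem = max(1, int(round(stem_fraction * half)))
    n_branch = half - n_stem

    def _branch(sign: float) -> list[np.ndarray]:
        # stem: the rotor also spreads slightly (a non-torsional opening
        # coordinate) so the stem is not a single frozen geometry
        frames = []
        for f in np.linspace(0.0, 1.0, n_stem, endpoint=False):
            frame = _torsion_frame(0.0)
            frame[4:, 0] += 0.3 * f
            frames.append(frame)
        for t in np.linspace(0.0, sign * branch_angle, max(2, n_branch)):
            frame = _torsion_frame(t)
            frame[4:, 0] += 0.3
            frames.append(frame)
        return frames[: half]

    coords = np.stack(_branch(+1.0) + _branch(-1.0))
    return Trajectory(("X",) * 6, coords,
                      [f"bifurcation frame {k}" for k in range(n_frames)])


def make_oscillating_path(
    base: Trajectory,
    amplitude: float = 0.25,
    period: float = 8.0,
    atom: int = 0,
    direction=(1.0, 0.0, 0.0),
    min_separation: float = 0.3,
) -> Trajectory:
    """Base path plus a bounded sinusoidal displacement of one atom.

    Emulates a dynamical trajectory vibrating about a minimum-energy path:
    atom ``atom`` is displaced by ``amplitude * sin(2 pi k / period)`` along
    ``direction`` at frame k.  Raises if the perturbation drives any two
    atoms closer than ``min_separation`` Angstrom.
    """
    u = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("direction must be nonzero")
    u /= norm
    coords = base.coords.copy()
    k = np.arange(base.n_frames)
    disp = amplitude * np.sin(2.0 * np.pi * k / period)
    coords[:, atom] += disp[:, None] * u[None, :]
    def _min_sep(frame: np.ndarray) -> float:
        diff = frame[:, None, :] - frame[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return float(d.min())

    for f in range(base.n_frames):
        sep = _min_sep(coords[f])
        # complain only when the perturbation itself causes the contact,
        # not when the base path already carried a close pair
        if sep < min_separation and sep < _min_sep(base.coords[f]):
            raise ValueError(
                f"amplitude {amplitude} drives atoms within {sep:.3f} A "
                f"at frame {f}; reduce it"
            )
    return Trajectory(base.elements, coords,
                      [f"{c} +osc" for c in base.comments])


def add_rigid_motion(
    traj: Trajectory, seed: int = 0, max_translation: float = 5.0
) -> Trajectory:
    """Contaminate every frame with an independent random rigid motion.

    Rotations are drawn uniformly over SO(3) (normalized quaternions) and
    translations uniformly in a cube of half-width ``max_translation``
    Angstrom.  Internal geometry is untouched, so distance representations
    and post-alignment Cartesians must be unaffected.
    """
    rng = np.random.default_rng(seed)
    coords = np.empty_like(traj.coords)
    for k in range(traj.n_frames):
        q = rng.normal(size=4)
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        coords[k] = traj.coords[k] @ R.T + t
    return Trajectory(traj.elements, coords, list(traj.comments))
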