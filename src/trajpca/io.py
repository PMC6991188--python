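"""Multi-frame xyz input/output and atomic masses.

The xyz dialect accepted here is the plain XMOL one: an atom-count line, a
free-form comment line, then one ``element x y z`` line per atom, with frames
simply concatenated.  Coordinates are Angstrom.  Comment lines are carried
through verbatim and never interpreted; the analysis uses geometry only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "mass_of",
    "masses_for",
    "ATOMIC_MASSES",
]


class XYZParseError(ValueError):
    """Raised when an xyz file violates the format contract."""


# IUPAC standard atomic weights (conventional values for interval elements),
# amu.  "X" is a unit-mass pseudo-atom used by the synthetic generators.
ATOMIC_MASSES: dict[str, float] = {
    "X": 1.0,
    "H": 1.008, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815384, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Sc": 44.955908, "Ti": 47.867,
    "V": 50.9415, "Cr": 51.9961, "Mn": 54.938043, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.921595, "Se": 78.971,
    "Br": 79.904, "Kr": 83.798,
    "Rb": 85.4678, "Sr": 87.62, "Y": 88.90584, "Zr": 91.224,
    "Nb": 92.90637, "Mo": 95.95, "Ru": 101.07, "Rh": 102.90549,
    "Pd": 106.42, "Ag": 107.8682, "Cd": 112.414, "In": 114.818,
    "Sn": 118.710, "Sb": 121.760, "Te": 127.60, "I": 126.90447,
    "Xe": 131.293,
    "Cs": 132.90545196, "Ba": 137.327, "La": 138.90547, "Ce": 140.116,
    "Hf": 178.486, "Ta": 180.94788, "W": 183.84, "Re": 186.207,
    "Os": 190.23, "Ir": 192.217, "Pt": 195.084, "Au": 196.966570,
    "Hg": 200.592, "Tl": 204.38, "Pb": 207.2, "Bi": 208.98040,
}


def mass_of(element: str) -> float:
    """Atomic mass in amu for an element symbol; unknown symbols raise."""
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(f"unknown element symbol: {element!r}") from None


def masses_for(elements: Sequence[str]) -> np.ndarray:
    """Per-atom mass vector (amu) for a sequence of element symbols."""
    return np.array([mass_of(e) for e in elements], dtype=float)


@dataclass
class Trajectory:
    """An ordered series of molecular geometries sharing one atom list.

    Parameters
    ----------
    elements
        Per-atom element symbols, identical for every frame.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    comments
        One comment string per frame (kept verbatim, never parsed).
    """

    elements: tuple[str, ...]
    coords: np.ndarray
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.elements):
            raise ValueError(
                f"{len(self.elements)} element symbols but frames have "
                f"{self.coords.shape[1]} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.comments:
            self.comments = ["" for _ in range(self.n_frames)]
        if len(self.comments) != self.n_frames:
            raise ValueError("need one comment per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def masses(self) -> np.ndarray:
        return masses_for(self.elements)

    def __getitem__(self, key) -> "Trajectory":
        """Frame slicing; always returns a Trajectory (frames stay 3-D)."""
        coords = self.coords[key]
        if coords.ndim == 2:
            coords = coords[None]
            comments = [self.comments[key]]
        else:
            comments = list(np.asarray(self.comments, dtype=object)[key])
        return Trajectory(self.elements, coords.copy(), comments)


def read_xyz(path: str | Path) -> Trajectory:
    """Read a multi-frame xyz file.

    Raises
    ------
    XYZParseError
        On a malformed atom-count line, inconsistent atom count between
        frames, a non-numeric coordinate, or an unknown element symbol; the
        message names the offending line number.
    """
    path = Path(path)
    # splitlines() tolerates CRLF and a missing trailing newline alike
    lines = path.read_text().splitlines()

    frames: list[np.ndarray] = []
    comments: list[str] = []
    elements: tuple[str, ...] | None = None

    i = 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1  # blank trailing/separator lines are tolerated
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if n_atoms < 1:
            raise XYZParseError(f"{path}:{i + 1}: atom count must be >= 1")
        if i + 1 >= len(lines):
            raise XYZParseError(f"{path}:{i + 1}: truncated frame header")
        comments.append(lines[i + 1])

        frame_elems: list[str] = []
        frame_xyz = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            lineno = i + 2 + a
            if lineno >= len(lines):
                raise XYZParseError(
                    f"{path}:{lineno + 1}: frame truncated, expected {n_atoms} atoms"
                )
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}:{lineno + 1}: expected 'element x y z', got {lines[lineno]!r}"
                )
            symbol = parts[0]
            if symbol not in ATOMIC_MASSES:
                raise XYZParseError(
                    f"{path}:{lineno + 1}: unknown element symbol {symbol!r}"
                )
            frame_elems.append(symbol)
            try:
                frame_xyz[a] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"{path}:{lineno + 1}: non-numeric coordinate in {lines[lineno]!r}"
                ) from None

        if elements is None:
            elements = tuple(frame_elems)
        elif len(frame_elems) != len(elements):
            raise XYZParseError(
                f"{path}:{i + 1}: inconsistent atom count "
                f"({len(frame_elems)} vs {len(elements)} in first frame)"
            )
        elif tuple(frame_elems) != elements:
            raise XYZParseError(
                f"{path}:{i + 1}: element ordering differs from first frame"
            )
        frames.append(frame_xyz)
        i += 2 + n_atoms

    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    assert elements is not None
    return Trajectory(elements, np.stack(frames), comments)


def write_xyz(traj: Trajectory, path: str | Path) -> Path:
    """Write a Trajectory as plain multi-frame xyz (10 decimal places)."""
    path = Path(path)
    with path.open("w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{traj.comments[k]}\n")
            for sym, (x, y, z) in zip(traj.elements, traj.coords[k]):
                fh.write(f"{sym:<3s} {x: .10f} {y: .10f} {z: .10f}\n")
    return path
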