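"""PCA model of a molecular path and its fitted results.

The public surface follows the statsmodels convention: :class:`PathPCA` is
built from data (a :class:`~trajpca.io.Trajectory` plus representation
options), ``fit()`` returns a :class:`PathPCAResults` carrying the mean
structure, component weights, eigenvalues and variance fractions, and
projection / reconstruction / summary / serialization hang off the results
object.

Two structure representations are supported:

``"cartesians"``
    Each frame is the 3N-vector of its Kabsch-aligned (optionally
    mass-weighted) Cartesian coordinates.

``"distances"``
    Each frame is the flattened upper triangle (row-major, i<j) of its
    squared interatomic distance matrix, length N(N-1)/2 — rotationally and
    translationally invariant, which handles torsional motion far better
    than the Cartesian branch.

Mass-weighting, when requested, scales coordinates by sqrt(mass) after
alignment and before any distance computation, so a single weighting
definition covers both branches.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .io import Trajectory
from .geometry import (
    AlignedCoordinates,
    align_frame,
    align_trajectory,
    mass_weight,
    squared_distance_vector,
)

__all__ = [
    "RepresentationMatrix",
    "ReducedPath",
    "PathPCA",
    "PathPCAResults",
    "build_representation",
    "fit_pca",
]

#: eigenvalues below RANK_TOL * lambda_max are treated as numerical zeros
RANK_TOL = 1e-12

_REPRESENTATIONS = ("cartesians", "distances")
FLATTENING_ORDER = "row-major-upper(i<j)"


def _normalize_representation(representation: str) -> str:
    rep = str(representation).lower()
    if rep not in _REPRESENTATIONS:
        raise ValueError(
            f"representation must be one of {_REPRESENTATIONS} "
            f"(case-insensitive), got {representation!r}"
        )
    return rep


@dataclass
class RepresentationMatrix:
    """The n x p matrix fed to PCA plus the metadata needed to rebuild it.

    ``p`` is 3N for the Cartesian branch and N(N-1)/2 for the distances
    branch.  ``reference_frame`` stores the centroid-centered coordinates of
    the alignment reference so that *new* trajectories can be pushed through
    identical pre-processing later.
    """

    data: np.ndarray
    representation: str
    mass_weighted: bool
    n_atoms: int
    elements: tuple[str, ...]
    reference_frame: np.ndarray
    flattening_order: str = FLATTENING_ORDER

    def __post_init__(self) -> None:
        self.representation = _normalize_representation(self.representation)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("representation data must be 2-D (n_frames x p)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("representation data must be finite")
        if self.representation == "distances" and np.any(self.data < 0):
            raise ValueError("squared distances cannot be negative")
        expected_p = (
            3 * self.n_atoms
            if self.representation == "cartesians"
            else self.n_atoms * (self.n_atoms - 1) // 2
        )
        if self.data.shape[1] != expected_p:
            raise ValueError(
                f"expected p = {expected_p} columns for {self.representation} "
                f"with {self.n_atoms} atoms, got {self.data.shape[1]}"
            )
        self.elements = tuple(self.elements)
        self.reference_frame = np.asarray(self.reference_frame, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def metadata_matches(self, other: "RepresentationMatrix") -> bool:
        return (
            self.representation == other.representation
            and self.mass_weighted == other.mass_weighted
            and self.n_atoms == other.n_atoms
            and self.elements == other.elements
            and self.flattening_order == other.flattening_order
        )


@dataclass
class ReducedPath:
    """Per-frame scores in the reduced space (the object that gets plotted)."""

    scores: np.ndarray
    n_dim: int
    label: str = "path"

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[1] != self.n_dim:
            raise ValueError(
                f"scores have {self.scores.shape[1]} columns, n_dim = {self.n_dim}"
            )

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]


def _preprocess(
    traj: Trajectory,
    representation: str,
    mass_weighted: bool,
    reference: np.ndarray | None,
) -> tuple[np.ndarray, AlignedCoordinates, np.ndarray]:
    """Shared pre-processing for training and new data.

    Returns (feature matrix, aligned coordinates, centered reference frame).
    When ``reference`` is given, frames are aligned onto it (projection of
    new data into an existing space); otherwise the first frame is used.
    """
    rep = _normalize_representation(representation)
    if reference is None:
        aligned = align_trajectory(traj, reference=0)
        ref = traj.coords[0] - traj.coords[0].mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        out = np.empty_like(traj.coords)
        for k in range(traj.n_frames):
            out[k] = align_frame(traj.coords[k], ref)
        aligned = AlignedCoordinates(out, reference_index=0, mass_weighted=False)

    if mass_weighted:
        aligned = mass_weight(aligned, traj.masses())

    if rep == "cartesians":
        data = aligned.flattened()
    else:
        data = np.stack(
            [squared_distance_vector(aligned.coords[k]) for k in range(traj.n_frames)]
        )
    return data, aligned, ref


def build_representation(
    traj: Trajectory,
    representation: str = "distances",
    mass_weighted: bool = False,
) -> RepresentationMatrix:
    """Turn a trajectory into the matrix PCA consumes.

    Cartesian branch: Kabsch-align every frame onto the first, optionally
    mass-weight, flatten to 3N-vectors.  Distances branch: optionally align
    and mass-weight (weighted distances are only translation-invariant after
    alignment), then collect squared pairwise distances.
    """
    data, _, ref = _preprocess(traj, representation, mass_weighted, None)
    return RepresentationMatrix(
        data=data,
        representation=representation,
        mass_weighted=mass_weighted,
        n_atoms=traj.n_atoms,
        elements=traj.elements,
        reference_frame=ref,
    )


class PathPCA:
    """PCA model of a molecular path in a chosen structure representation.

    Parameters
    ----------
    trajectory
        The path (IRC, scan or trajectory) defining the reduced space.
    representation
        ``"cartesians"`` or ``"distances"`` (case-insensitive).
    mass_weighted
        Scale coordinates by sqrt(atomic mass) after alignment.  Emphasizes
        heavy-atom motion; leave off when hydrogen transfer matters.

    Examples
    --------
    >>> model = PathPCA(traj, representation="distances")
    >>> res = model.fit()
    >>> res.variance_fractions[:2]
    """

    def __init__(
        self,
        trajectory: Trajectory,
        representation: str = "distances",
        mass_weighted: bool = False,
    ) -> None:
        if trajectory.n_frames < 2:
            raise ValueError("PCA needs at least two frames")
        self.trajectory = trajectory
        self.representation = _normalize_representation(representation)
        self.mass_weighted = bool(mass_weighted)
        self.rep_matrix = build_representation(
            trajectory, self.representation, self.mass_weighted
        )

    @classmethod
    def from_xyz(
        cls,
        path: str | Path,
        representation: str = "distances",
        mass_weighted: bool = False,
    ) -> "PathPCA":
        from .io import read_xyz

        return cls(read_xyz(path), representation, mass_weighted)

    def fit(self) -> "PathPCAResults":
        return fit_pca(self.rep_matrix, model=self)


def _fix_component_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|.| entry of each
    component is made positive (eigenvectors are sign-ambiguous)."""
    out = components.copy()
    for row in out:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return out


def fit_pca(rep: RepresentationMatrix, model: "PathPCA | None" = None) -> "PathPCAResults":
    """Diagonalize the mean-centered covariance of a representation matrix.

    Implemented through the thin SVD of the centered data, which is the
    same spectrum as the p x p covariance eigendecomposition when p <= n and
    as the n x n inner-product decomposition when p > n, without forming
    either matrix.  Covariance normalization is 1/(n-1); variance fractions
    are unaffected by that choice.  Eigenvalues below ``RANK_TOL *
    lambda_max`` are zeroed so noise components do not pollute
    goodness-of-fit denominators.
    """
    X = rep.data
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two frames")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    if eigenvalues.size and eigenvalues[0] > 0:
        eigenvalues = np.where(eigenvalues < RANK_TOL * eigenvalues[0], 0.0, eigenvalues)
    components = _fix_component_signs(Vt)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PathPCAResults(
        model=model,
        rep_matrix=rep,
        mean=mean,
        components=components,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
    )


@dataclass
class PathPCAResults:
    """Fitted path-PCA: mean structure, component weights, spectrum.

    ``components`` rows are orthonormal weight vectors W_i (sorted by
    decreasing eigenvalue); ``variance_fractions`` is the spectrum
    normalized to sum to one.  Scores of the training path and of new
    trajectories are obtained with :meth:`transform` /
    :meth:`transform_new`; full-dimensional Cartesian paths with
    :meth:`reconstruct`.
    """

    model: PathPCA | None
    rep_matrix: RepresentationMatrix
    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    _training_scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def rank(self) -> int:
        return int(np.count_nonzero(self.eigenvalues))

    @property
    def n_frames(self) -> int:
        return self.rep_matrix.n_frames

    @property
    def representation(self) -> str:
        return self.rep_matrix.representation

    # ---- variance ----------------------------------------------------

    def goodness_of_fit(self, n_dim: int) -> float:
        """Fraction of total variance captured by the top ``n_dim``
        components (in [0, 1]; equals 1 at full rank)."""
        if not 1 <= n_dim <= self.rank:
            raise ValueError(f"n_dim must be in [1, {self.rank}], got {n_dim}")
        return float(self.variance_fractions[:n_dim].sum())

    # ---- projection --------------------------------------------------

    def transform(self, rep: RepresentationMatrix | None = None, n_dim: int = 2,
                  label: str = "path") -> ReducedPath:
        """Project a representation matrix (training data by default) onto
        the top ``n_dim`` components: scores = (X - mean) @ W^T."""
        if rep is None:
            rep = self.rep_matrix
        elif not self.rep_matrix.metadata_matches(rep):
            raise ValueError(
                "representation metadata mismatch: the matrix was not built "
                "with this model's representation/mass-weighting/atom layout"
            )
        if not 1 <= n_dim <= self.components.shape[0]:
            raise ValueError(f"n_dim out of range [1, {self.components.shape[0]}]")
        scores = (rep.data - self.mean) @ self.components[:n_dim].T
        return ReducedPath(scores, n_dim, label)

    def transform_new(self, new_traj: Trajectory, n_dim: int = 2,
                      label: str = "new") -> ReducedPath:
        """Project a new trajectory into the fitted space.

        The new frames are pushed through exactly the pre-processing the
        model recorded: alignment onto the model's reference frame, the same
        mass-weighting, the same flattening order.
        """
        if new_traj.elements != self.rep_matrix.elements:
            raise ValueError(
                "new trajectory atom list does not match the fitted model "
                f"({new_traj.n_atoms} atoms vs {self.rep_matrix.n_atoms})"
            )
        data, _, _ = _preprocess(
            new_traj,
            self.representation,
            self.rep_matrix.mass_weighted,
            reference=self.rep_matrix.reference_frame,
        )
        rep = RepresentationMatrix(
            data=data,
            representation=self.representation,
            mass_weighted=self.rep_matrix.mass_weighted,
            n_atoms=new_traj.n_atoms,
            elements=new_traj.elements,
            reference_frame=self.rep_matrix.reference_frame,
        )
        return self.transform(rep, n_dim=n_dim, label=label)

    # ---- reconstruction ----------------------------------------------

    def reconstruct(self, n_dim: int, center=None) -> "ReconstructionResult":
        """Back-project the top ``n_dim`` components to full-dimensional
        Cartesian trajectories (per-PC and combined).  See
        :mod:`trajpca.reconstruction`."""
        from .reconstruction import reconstruct_trajectory

        source = self.model.trajectory if self.model is not None else None
        if source is None:
            raise ValueError(
                "reconstruction needs the source trajectory; results loaded "
                "from disk support projection only"
            )
        path = self.transform(n_dim=n_dim, label="training")
        return reconstruct_trajectory(self, path, source, center=center,
                                      pcs=range(1, n_dim + 1))

    # ---- reporting ---------------------------------------------------

    def summary(self, n_components: int = 10) -> str:
        """Plain-text summary table of the fitted spectrum."""
        k = min(n_components, len(self.eigenvalues))
        buf = _io.StringIO()
        rep = self.representation
        mw = "yes" if self.rep_matrix.mass_weighted else "no"
        buf.write("Path PCA Results\n")
        buf.write("=" * 58 + "\n")
        buf.write(f"Representation:    {rep:<12s}  Mass-weighted: {mw}\n")
        buf.write(
            f"Frames: {self.n_frames:<6d} Atoms: {self.rep_matrix.n_atoms:<6d} "
            f"Features: {self.rep_matrix.data.shape[1]:<6d} Rank: {self.rank}\n"
        )
        buf.write("-" * 58 + "\n")
        buf.write(f"{'PC':>4s} {'eigenvalue':>14s} {'% variance':>12s} {'cumulative %':>13s}\n")
        cum = 0.0
        for i in range(k):
            pct = 100.0 * self.variance_fractions[i]
            cum += pct
            buf.write(f"{i + 1:>4d} {self.eigenvalues[i]:>14.6g} {pct:>12.1f} {cum:>13.1f}\n")
        buf.write("=" * 58 + "\n")
        return buf.getvalue()

    def variance_table(self) -> "pandas.DataFrame":  # noqa: F821
        """Spectrum as a DataFrame (percentages rounded to one decimal).

        The rounded column is largest-remainder corrected so it sums to
        exactly 100.0 despite per-row rounding.
        """
        import pandas as pd

        pct = np.round(100.0 * self.variance_fractions, 1)
        residual = np.round(100.0 - pct.sum(), 1)
        if residual != 0 and len(pct):
            pct[int(np.argmax(pct))] = np.round(pct.max() + residual, 1)
        return pd.DataFrame(
            {
                "pc": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "percent_variance": pct,
                "cumulative_percent": np.round(
                    100.0 * np.cumsum(self.variance_fractions), 1
                ),
            }
        )

    # ---- serialization -----------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Serialize to a NumPy ``.npz`` key-value archive (bit-exact
        round-trip of mean, components, eigenvalues and metadata)."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(
            path,
            mean=self.mean,
            components=self.components,
            eigenvalues=self.eigenvalues,
            variance_fractions=self.variance_fractions,
            data=self.rep_matrix.data,
            reference_frame=self.rep_matrix.reference_frame,
            representation=np.array(self.representation),
            mass_weighted=np.array(self.rep_matrix.mass_weighted),
            n_atoms=np.array(self.rep_matrix.n_atoms),
            elements=np.array(self.rep_matrix.elements),
            flattening_order=np.array(self.rep_matrix.flattening_order),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PathPCAResults":
        with np.load(path, allow_pickle=False) as z:
            rep = RepresentationMatrix(
                data=z["data"],
                representation=str(z["representation"]),
                mass_weighted=bool(z["mass_weighted"]),
                n_atoms=int(z["n_atoms"]),
                elements=tuple(z["elements"]),
                reference_frame=z["reference_frame"],
                flattening_order=str(z["flattening_order"]),
            )
            return cls(
                model=None,
                rep_matrix=rep,
                mean=z["mean"],
                components=z["components"],
                eigenvalues=z["eigenvalues"],
                variance_fractions=z["variance_fractions"],
            )
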