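# Methods

## Model

`trajpca` treats a molecular path — an ordered series of `n` geometries of
`N` atoms — as a cloud of points in a structure-representation space and
fits ordinary PCA to it. The method is linear by construction: each
principal component is a fixed linear combination of the representation's
features, components are orthogonal, and variance is the only optimality
criterion. Those assumptions suit small-molecule reaction paths, where a
handful of strongly coupled geometric changes dominate; they are weaker for
large, slow, multi-basin systems, for which time-lagged or manifold methods
are the better tools (and are out of scope here).

Two representations are implemented.

* **Cartesians** — every frame is centroid-centered and rotated onto the
  first frame with the Kabsch algorithm, then flattened to a `3N`-vector.
  The Kabsch rotation is the closed-form SVD solution constrained to
  det = +1, so reflections are never introduced by alignment. The alignment
  reference is the *first frame*: it is deterministic, order-preserving,
  and matches how a chemist reads a path (reactant first). Iterative
  mean-structure alignment was deliberately not implemented.
* **Distances** — every frame becomes the flattened upper triangle
  (row-major, `i<j`; the scipy condensed-matrix order) of its squared
  interatomic distance matrix, length `N(N−1)/2`. This representation is
  exactly invariant to rigid motion, at the cost of quadratic scaling in
  `N` and of losing handedness.

Mass-weighting, when enabled, multiplies each atom's coordinates by `√m`
(amu) *after* alignment — rigid-motion removal is only meaningful on
unweighted geometry — and before any distance computation, so one weighting
definition serves both branches. Weighted squared distances are therefore
`m`-mixed quantities and are only translation-consistent because weighting
follows alignment; this is the single defensible reading given that no
distance-level weighting rule exists, and it keeps un-weighting an exact
inverse. Masses come from the IUPAC standard atomic weights (conventional
values where IUPAC gives an interval); the pseudo-element "X" (1 amu) is
provided for unit-mass toys.

## Fitting and numerics

The covariance eigenproblem is solved through the thin SVD of the centered
data matrix. This is algebraically identical to diagonalizing the `p × p`
covariance when `p ≤ n` and to the `n × n` inner-product (snapshot) route
when `p ≫ n` (the common case for distance features), without forming
either matrix. Choices that matter for reproducibility:

* covariance normalization is `1/(n−1)`; variance *fractions* are invariant
  to this, raw eigenvalues are comparable across runs;
* each component's sign is fixed by making its largest-magnitude entry
  positive;
* eigenvalues below `1e−12 × λ_max` are treated as exact zeros, so the rank
  and goodness-of-fit denominators are not polluted by numerical noise;
* the variance table's rounded percent column is largest-remainder
  corrected so it sums to exactly 100.0.

Projection of new data replays the recorded pre-processing exactly: new
frames are Kabsch-aligned onto the stored reference frame (not onto their
own first frame), identically mass-weighted, identically flattened. Models
serialize to a NumPy `.npz` key-value archive with a bit-exact round trip.

## Reconstruction

Back-projection is `X̃ = T·W + X̄` over any subset of fitted components; an
empty subset degenerates to `n` copies of the mean structure by design. On
the Cartesian branch the rows already are geometries. On the distances
branch each row is unflattened to a symmetric zero-diagonal *predistance*
matrix (entries may be negative after rank reduction — they are passed
through untouched), converted to a Gram matrix anchored on atom 1,
`G_ij = (D_i1 + D_j1 − D_ij)/2`, and eigendecomposed. Coordinates are the
top three eigenpairs, `U[:, :3]·√λ[:3]`, with:

* negative eigenvalues clamped to zero before the square root — the
  standard classical-MDS resolution, keeping output real;
* descending eigenvalue order, ties broken by original index, for
  determinism;
* the summed `|λ|` beyond the top three reported per frame as the
  trailing-spectrum mass — zero (to rounding) iff the matrix is a true 3-D
  distance matrix, strictly positive for genuinely reduced reconstructions.

Handedness is lost with the distances representation, so when the user
names four atoms around a stereogenic center, each recovered frame's
chirality — the sign of the 4×4 determinant with rows `(x_i, y_i, z_i, 1)`,
zero within `1e−6` of coplanarity — is compared with the analogous input
frame, and disagreeing frames are reflected through the xy-plane (any fixed
mirror works since re-alignment follows; a fixed one is reproducible).
Frames whose own or reference determinant is within tolerance of zero are
left alone. Without a center, frames keep the embedding's arbitrary
reflective configuration and a warning is issued.

Final alignment maps each reconstructed frame onto the *analogous aligned
input frame*. A sequential frame-to-previous-frame scheme was considered
and rejected: frames are aligned to the common reference during
pre-processing, so sequential re-alignment would rotate even an exact
full-rank Cartesian reconstruction away from the aligned input, breaking
the identity that full-rank reconstruction reproduces it; per-frame
alignment to the source preserves that identity, matches the convention the
chirality rule already uses, and gives flicker-free animations. For
mass-weighted distance models, the embedding's arbitrary rotation is
removed (and the reference centroid restored) *while still in weighted
space*, because per-atom `√m` scaling does not commute with rotation;
un-weighting then inverts the weighting exactly.

## Pipeline outputs

A reduction run writes `n_dim` single-component xyz files and one combined
file (`<stem>_PC<i>.xyz`, `<stem>_PCall.xyz` — `n_dim + 1` xyz files
total), the serialized model, the variance-fraction table, the training
scores, and 2-D/3-D projection plots drawn as start→end color-mapped
polylines. If the requested `n_dim` exceeds the data's numerical rank it is
truncated to the rank with a warning — asking three components of a
two-dimensional motion yields three files, not an error-free lie. All
outputs are deterministic: identical input and options give byte-identical
xyz and table files.

## Synthetic study systems

The generators in `trajpca.synthetic` produce the geometry classes the
method is meant to resolve, each with the controlling coordinate known
exactly:

* `make_stretch` — one atom departs a rigid ~1 Å-spaced random cluster
  linearly from 1.2 to 3.0 Å along a kept-clear channel; the analog of a
  single-coordinate dissociation. 40 frames by default.
* `make_torsion` — a six-atom, two-rigid-group 0→180° dihedral sweep with
  all bond lengths constant; the pure non-linear motion on which the
  distances representation should (and does, measurably) outperform
  Cartesians. 37 frames.
* `make_bifurcating` — a shared stem (a small opening coordinate) followed
  by two branches related by ±120° torsion under *fixed atom numbering*, so
  the branch endpoints have distinct distance matrices and opposite
  chirality signs; the analog of a post-transition-state bifurcation into
  enantiomers. 40 frames.
* `make_oscillating_path` — a base path plus a bounded sinusoidal
  displacement of one atom along a chosen direction; the analog of a
  dynamical trajectory vibrating about a minimum-energy path. Rejects
  amplitudes that drive new atomic contacts below 0.3 Å.
* `add_rigid_motion` — per-frame uniform SO(3) rotations (normalized
  quaternions) plus uniform translations in ±5 Å, for exercising the
  invariance claims with a documented distribution.

Default sizes (tens of frames, ≤6 atoms) keep every fit well-conditioned
and the whole test suite fast while leaving full numerical rank where the
tests need it. These fixtures are geometric, not energetic: no force field,
no thermal ensemble, no anharmonic coupling, and noise enters only where a
generator injects it. Passing tests therefore certify the *transformations*
— alignment, weighting, spectra, projection, reconstruction, chirality
repair — not the chemical interpretability of components fitted to any
real system, and say nothing about how many components a real reaction
needs.

## Known limitations

* Linear PCA only; no TICA, kernel PCA or diffusion maps.
* No atom-mapping or symmetry-corrected RMSD: frames must share one atom
  ordering, and paths whose branches are related by relabeling rather than
  by internal rotation will alias in distance space.
* Chirality repair tracks a single stereogenic quadruple; multi-center
  epimerization is not handled.
* Plain multi-frame xyz is the only I/O format, Å/amu the only units.
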