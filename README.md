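# trajpca

Dimensionality reduction of molecular reaction paths — intrinsic reaction
coordinates (IRCs), relaxed potential-energy-surface scans, and molecular
dynamics trajectories — by principal component analysis, with full
reconstruction of Cartesian geometries from the reduced space.

Chemical transformations live on hyperdimensional potential energy surfaces,
and the usual way to view them in two or three dimensions is to hand-pick
bond lengths, angles or dihedrals. That invites confirmation bias. `trajpca`
instead derives the low-dimensional view from the data itself: given a series
of `n` molecular geometries of `N` atoms, it represents each structure either
as its Kabsch-aligned Cartesian coordinate vector (length `3N`) or as the
flattened upper triangle of its squared interatomic distance matrix (length
`N(N−1)/2`), optionally mass-weighted by `√m` per atom, and diagonalizes the
mean-centered covariance matrix

```
Λ = U C Uᵀ,    C = (X − X̄)ᵀ(X − X̄) / (n − 1)
```

The eigenvectors `W_i` are the principal components — linear combinations of
coordinates or of squared distances — and the fraction of total variance
captured by the top `n_dim` of them is the goodness of fit of the reduced
space. Scores `T_i = (X − X̄)·W_iᵀ` place every frame in that space; new
trajectories can be projected into a space fitted on an IRC to classify
their routes at a glance.

Reduced paths are also transformed *back* to full dimension,
`X̃ = T·W + X̄`, one component at a time or combined. On the distances
branch each back-projected row is a *predistance* matrix; Cartesian
geometries are recovered per frame by the classical-MDS route — Gram matrix
`G_ij = (D_i1 + D_j1 − D_ij)/2`, eigendecomposition, embedding with the top
three eigenpairs (negative eigenvalues clamped) — with the trailing spectral
mass reported as a per-frame diagnostic of the information lost. Because
distance matrices carry no handedness, frames whose chirality (sign of the
4×4 determinant over four atoms at a stereogenic center) disagrees with the
analogous input frame are mirror-reflected before final alignment.

The distance representation is rotationally and translationally invariant
and handles non-linear motion (torsions in particular) in fewer components
than aligned Cartesians; both branches are provided and can be screened
against each other.

## Worked example

Fit a reduced space to a pure 180° dihedral sweep of a six-atom toy molecule
(two rigid groups about a central bond), in both representations:

```python
from trajpca import PathPCA, ChiralityCenter
from trajpca.synthetic import make_torsion

traj = make_torsion()                       # 37 frames, 6 atoms
res = PathPCA(traj, representation="distances").fit()
print(res.summary(4))
```

```
Path PCA Results
==========================================================
Representation:    distances     Mass-weighted: no
Frames: 37     Atoms: 6      Features: 15     Rank: 2
----------------------------------------------------------
  PC     eigenvalue   % variance  cumulative %
   1        8.58469         97.6          97.6
   2       0.214835          2.4         100.0
   3              0          0.0         100.0
   4              0          0.0         100.0
==========================================================
```

A single squared-distance component describes 97.6% of the variance of the
torsion. The same sweep in aligned Cartesian coordinates needs more
dimensions — PC1 captures only 74.8%:

```python
res.goodness_of_fit(1)                                    # 0.9756
PathPCA(traj, representation="cartesians").fit().goodness_of_fit(1)   # 0.7483
```

Back-projecting PC1 alone to full dimension returns a 37-frame Cartesian
trajectory you can write out and animate; the stereogenic quadruple keeps
the reconstructed handedness consistent with the input:

```python
rec = res.reconstruct(1, center=ChiralityCenter((3, 5, 6, 1)))
rec.per_pc[1]          # Trajectory: 37 frames, 6 atoms
```

The same workflow runs from the shell and writes `n_dim` single-component
xyz files plus one combined file, a variance table, a serialized model and
2-D/3-D projection plots:

```
trajpca reduce --input path.xyz --ndim 3 --representation distances --outdir out
trajpca project --model out/path_model.npz --input traj.xyz --outdir proj
```

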