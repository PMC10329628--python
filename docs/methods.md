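# Methods

## Problem

During open hepatic surgery the liver deforms under manipulation, and a
patient-specific biomechanical model (PBM) can only track those
deformations if its Dirichlet boundary conditions — the attachment
regions where the organ is fixed to surrounding anatomy — are known.
Attachments are not visible in preoperative imaging and differ between
patients. This package estimates them intraoperatively: a 3D U-Net,
trained entirely on synthetic finite-element deformations of the
patient's own geometry, maps F deformed partial-surface point clouds
(encoded as voxel distance fields) to a binary attachment mask on the
same voxel grid.

## Geometry and discretization

The organ is a closed triangulated surface in meters. It is embedded in
a regular grid of cubic cells; cells whose center lies inside the
surface (generalized winding number > 1/2) or that intersect a boundary
triangle (separating-axis test) are kept and become trilinear
hexahedral finite elements. Grid fitting keeps the requested cell
counts per axis and chooses the single spacing so that every axis
carries at least one empty cell of margin; the margin guarantees that
mapping a node's lattice index to the voxel with the same index is
injective, which is what makes the attachment mask exactly decodable
back to FE nodes (mask transferability).

The full-scale grid is 31 x 32 x 26; the experiments in this repository
run on 12 x 12 x 10 (about 450 cells / 700 nodes for the default
organ), a desk-scale choice set from solver and training throughput on
one CPU core. The resolution changes the numbers, not the mechanics;
see "Scaled-down regime" below.

## Procedural anatomy

Real pipelines segment the liver surface from a preoperative CT scan.
As a shippable stand-in, `synthetic_anatomy` generates liver-like
shapes: an ellipsoid radial field (default semi-axes 0.14, 0.10,
0.08 m, an adult liver envelope) perturbed by band-limited
spherical-harmonic noise plus a few Gaussian lobes, evaluated on an
icosphere (watertight and consistently oriented by construction). It
emulates the size, smoothness and mild lobedness of a liver; it does
not model real anatomical detail (vessel trees, ligament geometry,
segment boundaries), so passing tests demonstrate the method's
mechanics and learnability, not clinical accuracy on real livers.

## Constitutive model and solver

Soft tissue is modeled as compressible Neo-Hookean,

    W(F) = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2,

with E = 5000 Pa and nu = 0.48 (mu ~ 1689 Pa, lambda ~ 40540 Pa), a
standard near-incompressible liver parameterization. The specific
compressible extension is a choice; any quantity that depends on it is
treated as approximate. Elements are 8-node hexahedra with 2x2x2 Gauss
quadrature. Because every element is the same axis-aligned cube,
assembly is fully vectorized and the reference gradients are shared.

Equilibrium: Newton-Raphson under incremental loading (default 5 steps;
the data generator uses 2 — results agree when both converge, the
smaller count is cheaper), an energy backtracking line search, exact
constraint elimination, sparse LU (SuperLU, symmetric-mode MMD
ordering) for the linearized systems, and recursive step halving when
an increment inverts elements (J <= 0) or stalls. Convergence:
||r_free|| <= 1e-6 x max(||f_ext||, lambda h^2). Prescribed
displacements support per-component constraints (NaN = free), needed
for symmetry boundary conditions in verification problems.

Verification: element forces and tangents match central finite
differences of the energy to ~1e-10 relative; a single-element uniaxial
traction at 0.1% strain reproduces sigma/E to 0.1%; the full Newton
solution at small strain matches the one-step linear solve with the
rest tangent to < 2%; solutions under pure displacement constraints are
invariant to Young's modulus, the property that lets the method ignore
the (unknown) patient stiffness.

## Synthetic training data

Each sample draws one attachment region — a random surface node's
neighborhood under the score |x_i - x_seed| + eta u_i (u_i ~ U(0,1),
eta = 0.3 x organ diameter; Euclidean, not geodesic), grown to a
uniform 5-50% of surface nodes — and F = 3 manipulations: a force of
uniform random direction and total magnitude spread over a random 1-5%
surface patch disjoint from the attachment, solved to equilibrium.

The force magnitude is uniform in [0.5, 30] N. The range was fixed by
measurement on the default organ: 0.5 N produces a few millimeters of
deformation, 30 N reaches 0.1-0.4 m, so the stability filter (discard
non-converged solves and samples whose maximal nodal displacement
exceeds 0.3 m, the strictest reading of the displacement cap) is
operative, and rejected draws are a visible cost of generation, as in
practice.

Each deformed state is observed as a partial surface: boundary quads
whose deformed outward normal faces a fixed virtual camera are
candidates; a voxel z-buffer removes nodes hidden behind distinctly
nearer surface (a blocker must be > 1.5 cells nearer AND > 3 cells away
in 3D — the second condition stops a smooth organ's own voxelization
staircase from self-occluding); a region is grown inside the candidates
to a uniform 10-100% of all surface nodes. Visibility operates on
deformed coordinates (the camera sees the deformed organ).

Encodings. Visible deformed points are snapped to voxels and each
voxel stores the distance from its center to the nearest occupied voxel
center, normalized by the grid diagonal (a voxelized point cloud as a
distance field: exactly zero on occupied voxels, 1-Lipschitz per cell).
The attachment mask has a 1 exactly in each attachment node's voxel.
The displacement-input variant (for the input-representation
comparison) Gaussian-splats the visible nodes' displacement vectors
(sigma = 1 cell, unit kernel mass per node) onto its own grid plus a
signed-distance-field geometry channel; these channels are normalized
by the grid diagonal so all encodings share scale — unnormalized
meter-valued inputs measurably starved the first network layer.

Datasets are HDF5, one group per sample, with the per-frame force
specs, displacement fields and visible node sets stored so that any
stored sample can be re-solved and reproduced bit-for-bit from its
metadata; generation is deterministic given the config seed.

## Network and training

A small 3D U-Net: 3 resolution levels, two 3x3x3 convolutions +
instance normalization + ReLU per level, 16 base channels doubling per
level (8 in the reduced experiments), 2x max-pool down,
nearest-neighbor up-sampling with skip concatenation, final 1x1x1
convolution + sigmoid. Inputs are zero-padded per axis to the next
multiple of 2^(levels-1) and cropped back. Implemented directly in
numpy (im2col + GEMM convolutions with hand-written backprop, verified
against finite differences to 1e-4); no GPU or deep-learning framework
is required.

Loss: mean binary cross-entropy plus soft-Dice complement (eps = 1),
equally weighted. Optimizer: AdamW (lr 1e-3, decoupled weight decay
1e-2 on convolution weights only), batch size 5, cosine learning-rate
decay with a 5% floor, final-layer bias initialized at the attachment
prevalence log-odds (stabilizes the early epochs of a rare-positive
segmentation). Training splits 90/10 train/validation (seeded), early
stops on validation loss, and restores the best-validation checkpoint.
Everything is deterministic for a fixed seed on fixed BLAS.

Binarization at probability 0.5; by default predicted masks are
intersected with the surface-node voxel set (interior attachments are
physically meaningless), and results are reported with this
restriction.

## Evaluation

With ground truth (synthetic): hard Dice between predicted and true
masks; the three-arm input comparison (displacement-input F=1,
position-input F=1, position-input F=3) trains all arms on the same
samples with the same network size and epoch budget and reports mean
+- std test DSC per arm, at the voxel level and decoded to FE nodes
(the node level is the grid-independent comparison across arms that
encode on different grids; at this scale the two coincide because the
voxel snapping is injective). The headline quantity is the relative
improvement (DSC_F3 - DSC_F1) / DSC_F1 x 100. Because the arm
difference at desk scale is comparable to single-run training noise,
the experiment supports training each position arm several times
(`n_reps`) and averaging the per-arm test DSC before the improvement is
computed; the reproduction script uses two repetitions. The effect also
needs data to emerge: below roughly 200 training samples the
improvement estimate degenerates to seed noise around zero, so the
reproduction script keeps the training-set size at 300.

Without ground truth (the surgical protocol, emulated synthetically):
the observed cloud is split — the ~15% most deformed points (by
ground-truth correspondence; real clouds would use nearest rest-surface
node after the one-time rigid alignment) drive a prescribed-
displacement FE registration under a candidate attachment set; the
remaining points are held out and their nodal L2 errors (mm) scored.
Conditions are compared with two-sided Wilcoxon rank-sum tests (exact
enumeration when both sides have <= 10 untied values, tie-corrected
normal approximation otherwise; scipy's implementation behind this
package's interface) after Lilliefors normality screening
(statsmodels). Registering with the true attachments beats registering
with none on 9/10 synthetic cases (median held-out error ~0.4 mm vs
~8.6 mm at desk scale).

Frame-order consistency enumerates all F! input orderings (F <= 4) and
reports the Dice of each ordering's mask against the first.

## Scaled-down regime and what transfers

The reference results were produced at full scale (31 x 32 x 26 grid,
5263 training samples, GPU training). This repository runs the same
pipeline at desk scale: ~1300-face organ, 12 x 12 x 10 grid, 150-300
samples, 8-channel U-Net, 30-40 epochs, CPU only. Two consequences:

* absolute DSC is higher than at full scale (coarser voxels make the
  inverse problem easier), so arm-to-arm orderings and relative
  improvements are the meaningful quantities — and because the
  single-frame task is easier, the relative multi-frame gain is also
  smaller than at clinical resolution, though consistently positive;
* the advantage of displacement inputs over position inputs at F=1,
  which at full scale reflects the difficulty of implicit
  correspondence learning, shrinks at coarse resolution where
  correspondence is nearly trivial and the sigma = 1 cell splat is
  relatively much blurrier; the reduced-scale comparison can therefore
  compress or even invert that gap.

## Numerical and degenerate-case choices

* Dice of two empty masks is 1 (both predict "no attachment").
* Identical constant samples give a rank-sum p-value of 1; zero-variance
  samples reject normality degenerately.
* Deformed points leaving the grid are clipped to the boundary voxel
  during encoding (rare: the cap bounds displacements).
* Attachment candidates in the registration control set are dropped
  (their true displacement is zero, already enforced by the constraint).
* Solver failure modes: "underconstrained" (no Dirichlet constraint or
  singular reduced stiffness) is an error; non-convergence after step
  halving is a reported flag, and the data generator discards such
  draws, aborting only if >95% of the last 100 attempts were rejected.

## Known limitations

* Procedural anatomy and synthetic observations only; no RGB-D
  acquisition, color/depth segmentation, or rigid registration — real
  clouds are assumed pre-aligned in the organ frame.
* The compressible Neo-Hookean form and displacement-driven hexahedra
  are one reasonable realization; quantities sensitive to the
  constitutive extension or element order are approximate.
* Patient-specific by design: a trained network does not transfer to
  another geometry.
* Desk-scale defaults trade fidelity for CPU runtime, as quantified
  above.
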