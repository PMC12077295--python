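# Methods

## Problem setting and representation

The detector treats antibody finding as rigid-template object detection.
A map `X` is a scalar field on a 2 Å voxel lattice (node-centered: node
`(i,j,k)` sits at `origin + (i,j,k)·voxel`).  Preprocessing follows the
curation conventions of antibody map corpora: crop around the structure
with a 25 Å margin (bounds rounded outward to whole nodes), resample to
2 Å by trilinear interpolation (zero outside the source extent), zero the
negative values and divide by the maximum.  Trilinear resampling is an
assumption — it is monotone, exact on constants and adequate at 2 Å.

An antibody `A` is the placement `(R*, T*)` of a fixed template whose
center of mass is the coordinate origin and whose center-of-mass→CDR axis
is `u_z = (0,0,1)`.  The rotation is factored as

    R = R_axis(p, θ) · R_min(u_z → p),       p = R u_z,

where `R_min` is the minimal rotation taking `u_z` to `p` (about
`u_z × p`).  The factorization is exact and round-trippable for every
proper rotation; `θ ∈ [−π, π)` is recovered as the signed angle of
`R · R_minᵀ` about `p`.  Genuinely antipodal inputs (`p·u_z < −1 + 1e−13`)
use a fixed 180° rotation about the template x-axis as a deterministic
tie-break; the general cross-product construction stays numerically stable
down to that boundary, and round-trip accuracy near it degrades gracefully
to ~1e−6 (machine precision elsewhere).  The order of the two factors is a
convention; self-consistency under encode→decode is all that training and
inference require.

Translations decompose over a cell grid of fixed physical pitch
(`cell_size` = 8 Å = 4 input voxels; stored in configuration, not
hard-coded): `T* = T_cell + T_loc` with `T_cell` the owner-cell corner
(`floor((T − origin)/cell)`) and `T_loc ∈ [0, cell)³`.  Ground-truth
occupancy marks only the single owner cell — no neighborhood dilation —
and two antibodies may not own the same cell (≥ 20 Å separation guarantees
this: the cell diagonal is ~13.9 Å).

Channel layout of the 10-channel target/prediction grid: 0 occupancy,
1–3 `T_loc` (Å), 4–6 `p`, 7–8 `(cos θ, sin θ)`, 9 VHH indicator.  The
angle is regressed as a 2-vector to avoid the branch-cut singularity of
direct angle regression.

## Network

`f_θ` is a 3D UNet of depth 4 (four pooling levels), fully convolutional so
any map at least 16 voxels per axis can be processed; inputs are zero-padded
on the high side to a multiple of 16 and predictions cropped to
`ceil(extent / 4)` cells.  The decoder stops two levels above full
resolution, so the output stride is 4 voxels = 8 Å at 2 Å voxels, matching
the codec cell size (this coupling is asserted in configuration).  Blocks
are two 3³ convolutions with instance normalization and leaky-ReLU (0.1);
channel widths double per level from `base_channels` (default 8).  The
occupancy and class channels pass through sigmoids; pose channels are
unconstrained.  The occupancy head bias is initialized to `logit(0.01)`,
the standard low-prior initialization for focal-loss detectors, so the
network starts from "almost everything is empty" rather than spending its
first epochs discovering that.

The network, Adam, and all losses run on a small reverse-mode autodiff
core written on numpy (`cryoab.autograd`).  Convolutions are
shift-and-accumulate (one small GEMM per kernel tap); parameters are
float32, numerical tests run the same ops in float64.

Augmentation applies one of the 8 axis-aligned rotations generated by 90°
rotations about z and the 180° rotation about x, to map and target
together, then crops 0–3 whole cells per side (never below the 16-voxel
receptive minimum), dropping antibodies whose owner cell is removed.  The
full proper cubic rotation group has 24 elements; the 8-element subgroup is
a stated design choice.  Pose channels are not rotated component-wise:
poses are decoded, their rigid transforms composed with the grid rotation
(about the physical grid center), and re-encoded, which keeps `p`, `θ` and
`T_loc` exactly consistent with the rotated density (verified by
re-rendering in tests).

## Loss

With `γ = 4`, `λ = 30`, `λ_s = 0.2`, `λ_n = 1000/400`:

* `focal(p, y) = −[λ y (1−p)^γ log p + (1−y) p^γ log(1−p)]`, probabilities
  clamped to [1e−7, 1−1e−7].  The sign is chosen so the loss is ≥ 0 and
  minimized at the target.
* `L1` sums the focal loss over all occupancy cells.
* `L2` is the debiased Sinkhorn divergence
  `S_ε(a,b) = OT_ε(a,b) − ½OT_ε(a,a) − ½OT_ε(b,b)` between the occupancy
  channels viewed as measures on cell centers, squared-Euclidean ground
  cost, each grid floored by 1e−8 and normalized to unit mass.  Entropic
  scale `ε = blur²` with `blur = 8 Å` (one cell), annealed from the squared
  grid diameter by a factor `scaling² = 0.25` per sweep, then a few extra
  sweeps at the final scale (5 during training; until 1e−9 stationarity in
  tests).  Updates are the symmetrized (Jacobi, averaged) log-domain
  iterations, which make `S(a,b) = S(b,a)` exact at any iteration count and
  `S(a,a) = 0` exactly.  Gradients with respect to the masses are the
  converged dual potentials (`f_ab − f_aa`), the envelope-theorem shortcut;
  the normalization chain is differentiated exactly.
* `L3` = MSE on `T_loc`; `L4` = `1 − ⟨v, p⟩ + (‖v‖−1)²` on the direction;
  `L5` the same in 2D on `(cos θ, sin θ)`; `L6` = focal on the VHH channel
  with weight `λ_n`.  These are evaluated only at ground-truth occupied
  cells.  Note `L4`/`L5` are not uniquely minimized at the unit target
  (`v = 2p` also gives 0, and the infimum over scalings of `p` is −0.25);
  this is a documented property of the loss, not corrected.
* `L_tot = L1 + L2 + λ_s Σ_A (L3+L4+L5+L6)`.  A map with no antibody has no
  target measure; `L2` is dropped there and the total reduces to `L1`.

## Non-maximal suppression

Candidate detections are the 0-dimensional superlevel-set persistence
components of the occupancy channel, computed by union-find over cells
sorted by descending value.  The low-level routine defaults to
6-connectivity (face adjacency, the common voxel-grid convention); the
prediction pipeline runs it with full 26-connectivity.  The reason is
geometric: two antibody centers can never sit in diagonally adjacent cells
(their separation would be below the ~14 Å cell diagonal, impossible for
two Fv-sized objects), so a second occupancy peak one diagonal step from a
detection is always a duplicate of the same object — and face adjacency
cannot merge it.  With 26-connectivity such duplicates die during the
threshold sweep, which is exactly the non-maximal suppression the
persistence diagram is meant to provide.  A component is
born at its peak; on a merge the component with the higher birth survives
(elder rule) and the loser records the merge level as its death.  The
global survivor's death is the grid minimum, so a single-peak grid yields
one finite lifetime rather than an infinite bar.  Ties (equal values,
equal lifetimes) break lexicographically on the cell index, making output
deterministic.  Zero-lifetime merge pairs (plateau cells born and absorbed
at the same level) are diagonal points of the diagram and are dropped.
Selection: `num(k)` keeps the top-k lifetimes; `thresh(τ)` keeps lifetimes
strictly above τ, default 0.2 — the fully automatic mode.  An optional
`min_occupancy` filter discards detections whose peak probability is low,
a precision guard for maps that may contain no antibody.

## Synthetic data

The generator is scaffolding that emulates the statistical structure of a
curated antibody-map corpus; it is not a physical image-formation model.
Densities are sums of atom-centered isotropic Gaussians with
`σ = resolution/2.355` (FWHM convention), sampled on the 2 Å lattice,
plus additive Gaussian noise (sd = 5 % of the peak), then normalized.
Defaults: resolution 9.4 Å (σ = 4 Å, the low-resolution end of the
method's intended range), 1–4 antibodies per map drawn uniformly (mean 2.5,
near the ~2.25/system of real Fab corpora), 20 % VHHs (≈ the VHH share of
real test corpora), two antigen-like decoy blobs (single lobes at 1.6×
the Fv-lobe scale — diffuse, so distinguishable in principle from
antibodies), centers ≥ 20 Å apart and ≥ `border` from the faces, Haar-
uniform rotations.  Pseudo-templates are deterministic point clouds — a
two-lobe ~200-atom Fv shape and a one-lobe ~100-atom VHH — asymmetric both
across and around the canonical axis so `p` and `θ` are identifiable from
density.  What passing on such maps does *not* show: robustness to CTF
artifacts, anisotropic resolution, partial occupancy, conformational
heterogeneity, or the antigen shapes of real complexes.

## Desk-scale benchmark

`cryoab.experiments.run_recovery_experiment` is the package's end-to-end
self-check, sized for a single CPU: 64 Å maps (32³ voxels), 1–3 antibodies,
50 training and 20 held-out maps.  The detector is a single network
(`base_channels = 8`) with a slimmed encoder — one convolution per block at
the two finest encoder levels, which feed no decoder skip connection and
exist only to build features for the coarser levels; this halves the step
cost with no measured accuracy loss — trained 180 epochs with Adam at
lr 2e-3 (×0.3 at 55 % and 80 % of the schedule).  Augmentation runs for
the first 70 % of epochs and is then switched off: at this short schedule,
full-time augmentation leaves the occupancy channel underconfident on
held-out maps, while the annealed schedule keeps its robustness benefit.
The returned weights are the average over the last 12 % of epochs (Polyak
tail averaging), damping the noise of batch-1 updates.  A small deep
ensemble (`n_members`) is available and raises precision by suppressing
secondary peaks members disagree on, but at a fixed time budget it splits
training across members and costs threshold-mode recall, so the default is
the single longer-trained network.  The standalone reproduction script
trains 130 epochs, a runtime envelope for one-CPU runs; all randomness —
map generation, initialization, shuffling, augmentation — derives from a
single seed.

Measured behavior at this scale: detections are essentially always placed
(num-mode F1 ≈ 92–97 when the count is known) and precision in the
automatic mode is high, but antibodies whose centers lie within ~20–26 Å
of a neighbor — physically valid but, at σ = 4 Å smearing, rendered as a
single merged blob — are frequently returned as one persistence component
whose weaker peak dies below the 0.2 lifetime threshold.  With only ~10–15
such pairs in a 50-map corpus the network does not reliably learn to split
them, so automatic-mode F1 on held-out maps varies by a few points with
the random draw of close pairs.  This is the binding limitation of the
desk-scale study, not of the encoding or the NMS.  Held-out evaluation runs in `thresh(0.2)`
mode and reports pooled/per-system F1, center distances, direction/angle
errors and placement RMSD (template atoms under predicted vs true pose, no
re-superposition).

## Matching and metrics

Predicted and true centers are paired by minimum-total-distance Hungarian
assignment on the rectangular distance matrix; the 10 Å true-positive
threshold is applied *after* assignment, so a matched-but-distant pair
counts as one false positive plus one false negative.  `f1_ab` pools
TP/FP/FN over all antibodies; `f1_sys` averages per-system F1.  A system
with no antibodies and no predictions scores F1 = 1 (a perfect true
negative — relevant only to apo-style evaluations).  Direction error is
the angle between predicted and true `p`; `θ` error is the wrapped
absolute difference in [0°, 180°].

## Numerical choices and degenerate inputs

* Probability clamps at 1e−7 before logarithms; direction decoding rejects
  zero-norm vectors (`DegeneratePoseError`); `T_loc` is clamped into
  `[0, cell)` at decode.
* All-zero maps normalize to all-zero (no division); empty crops raise;
  non-orthogonal unit cells are rejected at map reading.
* The MRC `ORIGIN` record is preferred over `NXSTART` when nonzero,
  matching common visualization tools; detections are reported in the
  map's physical frame so output PDBs overlay the input map.
* Checkpoints are single `.npz` files holding parameters plus the model
  configuration; geometry (cell size) is derived from the stored stride and
  the map voxel size at load time.

## Template superposition

Ground-truth poses for real structures come from superposing the template
onto deposited antibody chains: template chains are greedily matched to
target chains by global sequence alignment (BLOSUM scoring), paired Cα
atoms are fitted by Kabsch, and pairs beyond 2σ of the residual distances
are dropped for up to 5 cycles (≥ 50 matched residues required).  Cα-only
fitting is an assumption.  The template entry is a configuration input, not
baked in; tests use the synthetic pseudo-template so no download is needed.

## Known limitations

* Trained networks shipped here are desk-scale demonstrations on synthetic
  maps; detecting antibodies in experimental maps requires training on a
  real curated corpus at larger compute.
* Pose-channel accuracy lags detection accuracy at desk scale: with tens of
  epochs and λ_s = 0.2 the orientation regressors receive far less
  effective gradient than the occupancy channels, so reported angular
  errors on the benchmark are markedly worse than what full-scale training
  achieves.  Center localization, which drives F1, does not suffer from
  this.
* Inference processes the whole padded grid at once; memory scales linearly
  with grid size and very large maps should be cropped first.
* No local rigid refinement of placements is performed; a hook point exists
  where a FitMap-style optimizer could be attached.
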