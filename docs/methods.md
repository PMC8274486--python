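# Methods

`laaecap` predicts per-vertex thrombosis-risk maps on left-atrial-appendage
(LAA) surface meshes directly from geometry, replacing the CFD solve that
normally produces them. This note records the models, the numerical
choices, and what the synthetic test bed does and does not establish.

## Hemodynamic indices

The wall shear stress tau(t) is a per-vertex 3-vector sampled over one
cardiac cycle of period T (seconds, stresses in Pa). The package computes

- TAWSS = (1/T) ∫ |tau| dt — time-averaged wall shear stress, Pa;
- OSI = 0.5 (1 − |∫ tau dt| / ∫ |tau| dt) — oscillatory shear index,
  dimensionless in [0, 0.5], 0 for unidirectional shear and 0.5 for a
  perfectly reversing one;
- ECAP = OSI / TAWSS — endothelial cell activation potential, 1/Pa. High
  ECAP (low, strongly oscillating shear) marks wall regions prone to blood
  stasis and mural thrombus formation.

Quadrature is a piecewise-constant left-sample rule: each sample holds
until the next one, and the last sample wraps to close the cycle. This is
exact for step series, which is precisely what CFD exports at a fixed
write interval are, and what the synthetic series generator emits — so the
index pipeline can be verified to machine precision (the two-phase
inversion identity below). Trapezoidal quadrature is available as an
option. Two conventions are fixed where the definitions degenerate: an
identically zero series has OSI = 0 (no oscillation), and the ECAP
denominator is floored at a configurable eps = 1e-8 Pa instead of
producing infinities. Skewed targets can be passed through log1p (not
log, so exact zeros are admissible) before training, with the exact
inverse applied to predictions.

## Mesh machinery

Meshes are connected, orientable, manifold triangle surfaces with at most
one boundary loop (the ostium), coordinates in millimetres, 0-based
indices. Normals are area-weighted face-normal averages. Mean curvature
is the signed cotangent formula H = (L x · n) / (2 A_v) with the lumped
(barycentric) vertex area A_v — positive on convex regions of an
outward-oriented surface; Gaussian curvature is the angle defect over the
lumped area. Both are undefined on the open ostium ring, so boundary
vertices receive the mean value of the interior vertices at minimal
edge-graph distance (a relabel-invariant rule; a single nearest neighbour
would depend on vertex ordering). Signed mean curvature is the default
input descriptor because it is the standard choice for smooth anatomical
surfaces; the Gaussian variant is exposed alongside it.

Graph conversion emits both orientations of every mesh edge with
pseudo-coordinates u(i→j) = (p_j − p_i)/(2s) + 1/2, where s is the
largest per-axis coordinate difference over the mesh's edges. The
normalization is per-mesh, so pseudo-coordinates fill [0,1]^3
symmetrically (u(i→j) + u(j→i) = 1) and are invariant under translation;
one trained model therefore serves meshes of any size and position.

## Geodesic flattening

Depth is the geodesic distance from the ostium ring, computed with the
heat method: solve (M + tL) u = δ_source with t the squared mean edge
length, normalize the negated gradient per face, and integrate it back
through a Poisson solve (the Laplacian's constant nullspace is pinned by
a 1e-10 M shift); distances are shifted so the source is exactly zero.
Measured discretization error is below 1% of the radius on a structured
planar disc and below 2% of the great-circle distance on a subdivided
icosphere (the test tolerances are 2% and 5%).

R isolines of the depth field are extracted at the inset levels
(r + 1/2)/R · d_max by marching triangles; crossing points interpolate
linearly along mesh edges, so every polyline point sits on its level to
1e-9. If a level splits into several closed loops (lobed anatomies), the
longest loop is kept and the event logged — a known limitation, fields
inside pinched-off lobe tips are represented only through the dominant
loop. Each loop is parameterized by angle about its centroid, in the
plane orthogonal to the mean depth-gradient direction (sign-fixed toward
the apex), counter-clockwise, with angle 0 at the point nearest the
circumflex-artery landmark. Mildly non-monotone angular traversals
(strongly non-convex loop projections) are repaired monotonically and
logged. Sampling A angles per isoline yields the (R, A) grid; every grid
sample keeps its source face and barycentric coordinates, so any grid
field transports back to the mesh (bilinear in depth × angle, angle
wrapping, depth clamped at the sampled range). The bull's-eye raster
places the apex at the centre (rho = 1 − depth/d_max) and the ostium at
the rim, with a validity mask on the unit disc; pixels outside the mask
hold a configurable pad value and never enter losses. Default resolution
is R = A = S = 128, chosen so seven stride-2 encoder blocks reduce the
image exactly to 1×1.

## Statistical shape model and dense regressor

Corresponded meshes (shared topology) are points in R^{3V}. The shape
model keeps the mean X̄ and the leading M eigenvectors W_i / eigenvalues
λ_i of the sample covariance (via thin SVD; dense eigendecomposition is
the test oracle). Coefficients follow the convention
α_i = W_i^T(Y − X̄)/λ_i with reconstruction X = X̄ + Σ α_i λ_i W_i —
projection divides by the eigenvalue and reconstruction multiplies it
back, an exact round trip on the model span; a `scaling='sqrt'` switch
gives unit-variance coefficients instead. M is capped at
min(requested, n−1, 3V) with a logged warning. No Procrustes
pre-alignment is applied by default (the synthetic shapes share a frame
by construction); a hook exists for externally aligned data.

The dense regressor maps 32 shape coefficients to per-vertex ECAP on the
registered 2,466-vertex template through five widening hidden layers
(128, 256, 512, 1024, 2048), ReLU + dropout 0.1 after each, linear
output: exactly 7,846,178 trainable parameters. Training uses Adam
(lr 0.01, 150 epochs, L1 loss) and returns the parameter state with the
best validation loss.

## Image surrogate over flattened maps

The encoder-decoder takes the 3-channel xyz image from flattening and
regresses a 1-channel ECAP image. Encoder blocks are 4×4 stride-2
convolutions with batch norm and ReLU (channels doubling from
base_channels = 32, capped at 8×); the decoder mirrors them with
nearest-neighbour upsampling, skip concatenation and 3×3 convolutions,
ends with a full-resolution 3×3 block and a linear 1×1 convolution. The
loss is L1 restricted to the validity mask, so padded bull's-eye corners
never contribute; with an all-true mask it equals plain L1 bit-exactly.
Inputs are z-scored per channel with statistics from mask-true training
pixels only, and the stored statistics are reused verbatim at test time.
For Cartesian (depth × angle) maps the angular axis is physically
periodic, so circular padding along that axis is available and on by
default — an extension motivated by the seam artifact that a hard 0/360°
cut produces. Unlike the other two architectures, the image network's
parameter total is not pinned to a reference value: it depends freely on
base_channels, and no canonical width multiplier exists for it.

## Geometric surrogate

The best-performing family operates on the mesh graph directly. Each of
12 consecutive spline convolutions aggregates neighbour features through
a continuous kernel: a degree-1 open uniform B-spline basis with k = 5
knots per dimension, steered by the 3-D edge pseudo-coordinates (at most
2^3 of the 5^3 tensor-product weights are active per edge; the basis
sums to one, so equal kernel weights reduce the layer to mean
aggregation — a tested identity). Aggregation is the mean over
in-neighbours, plus a root weight on the centre vertex and a bias. The
local features of all 12 layers (width 32 each) are concatenated
(C = 384), lifted per-vertex through 384 → 96 → 1024, and max-pooled
into a 1,024-dimensional global shape vector, which is broadcast back
and concatenated with the local features before the per-vertex head
(1408 → 80 → 16 → 1). ELU activations and dropout 0.1 throughout; Adam
with lr 0.001, batch size 16 graphs, 300 epochs, L1 loss,
best-validation checkpointing. This canonical configuration has exactly
1,686,097 trainable parameters — the reference total for the full-scale
network; the per-layer widths were fixed once by an exhaustive search
over PointNet-style structures realizing that total exactly, and the
instantiation is asserted against it. Desk-scale experiments use a
`reduced()` configuration (12×8 local widths, 96 → 32 → 64 lift, 64+...
head, 15–80 epochs) solely to keep runtimes in minutes on one CPU.

Inputs are four channels per vertex: mean curvature, power-transformed
(Yeo-Johnson, fitted on the pooled training vertices, then z-scored —
Yeo-Johnson rather than Box-Cox because curvature is signed) and the
three components of the unit normal. The transform record is reused
verbatim on test meshes. All operations are permutation-equivariant and
translation-invariant end to end (tested to 1e-6), and the model accepts
meshes of arbitrary vertex count.

The networks run on a small reverse-mode autodiff engine written on
numpy inside the package (`laaecap.nn`): broadcast arithmetic, matmul,
im2col convolutions, batch norm, gather/segment-sum message passing, and
a fused spline-convolution op whose scatter/gather and kernel-gradient
steps are CSR sparse-matrix products. Gradients are validated against
finite differences (1e-4) and the fused op against a dense brute-force
triple loop over all k^3 basis products (1e-6).

## Evaluation protocols

Accuracy is the vertex-pooled MAE of ECAP on the untransformed scale
(comparable across training configurations regardless of log1p), and the
true-positive rate of the binary "pro-thrombotic" classification: the
threshold is the 90th percentile (linear interpolation between order
statistics) of the pooled ground-truth vertex values, positives are
gt > τ, predicted positives are pred > τ, and TPR is pooled over all
test vertices. Pooling across cases (rather than per-case averaging)
matches a single population threshold; a per-case variant exists behind
a flag. Protocols: seeded k-fold cross-validation with folds as equal as
possible and 10% of each training set held out for checkpoint selection;
and sequential training-size scaling with nested subsets, a fixed test
fold, and an optional always-included baseline cohort. Results are
averaged over seeds (default 3).

## Synthetic anatomies and the hemodynamic oracle

Clinical LAA cohorts with matched CFD ground truth are not publicly
available, so the package ships a generator in their place. Shapes are deformations of
one fixed tube template (16 rings × 12 vertices + apex cap, 193
vertices; open ostium ring; landmark vertex on the ring standing in for
the circumflex reference): a quadratic centerline bend (±6 mm per axis),
low-order sinusoidal radius modulation (±18%), 1–3 outward Gaussian
lobes (2–5 mm amplitude), and a global scale of 0.85–1.15 around a
28 mm × 9 mm tube — magnitudes chosen once to bracket typical LAA
dimensions and lobe counts. Shared topology gives PCA-ready
correspondence by construction, replacing the out-of-scope non-rigid
registration. Samples that pinch below a 1 mm radius are rejected and
redrawn (up to 10 attempts). Two cohort presets ("synthetic-like":
lobe-heavy, echoing the prevalence of multi-lobed "cauliflower"
morphologies in statistical-shape-model samples; "real-like": 0–1 small lobes) separate the pooled ECAP
means by more than 10%, enabling the cross-cohort protocol analogues.

The oracle maps geometry to fields with the structure seen in
CFD-derived maps: with
normalized geodesic depth d and lobe indicator b (the sum of the
generator's own lobe kernels),

    OSI*   = osi_max · clip(0.01 + d^γ (1 + c2 b), 0, 1),   osi_max = 0.45, γ = 2
    TAWSS* = tawss_base (1 − 0.9 d) + c0,                   tawss_base = 1.2 Pa, c0 = 0.15 Pa
    ECAP*  = OSI* / TAWSS*

so risk increases with depth and inside lobes (stasis), and the pooled
population ECAP* is positively skewed (sample skewness > 1 over the
default 200-case bundle). The small 0.01 floor keeps OSI* strictly
positive on the ostium ring, where d = 0 would otherwise zero it against
the stated open-interval range. Optional smooth multiplicative noise
exists but defaults to 0, so the mapping is exactly recoverable. The
two-phase WSS series (+a ê for half a cycle, −b ê for the other half,
a = 2·TAWSS*(1 − OSI*), b = 2·TAWSS*·OSI*) inverts the index definitions
exactly under the step quadrature: running the full index pipeline on
the synthesized series reproduces the oracle to ~1e-15.

What the synthetic bed does not establish: hemodynamic realism (the
oracle is a monotone geometric function, not a flow solution), CT
segmentation or registration noise, inter-patient topology variation, or
the heavy-tailed ECAP distributions of whole-atrium simulations. Passing
results demonstrate the correctness and learnability of the pipeline,
not clinical accuracy.

## Experiment sizes and reproducibility

Default experiment sizes were chosen to run in minutes on a single CPU:
200 synthetic cases (~200 vertices each), the reduced geometric
configuration for training runs, 15 epochs for the learnability ladder
(training sizes 20/60/100/150 against a 50-case fixed test fold, 3
seeds). Under these conditions the geometric surrogate reaches a
held-out MAE of ~0.09–0.10 — about a third of the train-mean baseline
(~0.30) — and the seed-averaged MAE decreases strictly with training
size. All randomness flows through explicit integer seeds; identical
seeds reproduce training histories bit-for-bit.

## Known limitations

- Isoline levels that split into multiple loops keep only the longest
  loop; deep secondary lobes are under-resolved in flattened space.
- The angular coordinate in back-transport uses each isoline's own
  frame; strongly twisted anatomies could alias between rows (not
  observed on the generator's shapes).
- The U-Net parameter total is configuration-dependent and intentionally
  not pinned to a reference value.
- Degree-1 B-spline bases only; higher degrees would need a wider
  active-set computation.
- No graph pooling/coarsening: the architecture is strictly local
  convolution plus one global max-pool; multi-scale graph coarsening is
  deliberately out of scope.
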