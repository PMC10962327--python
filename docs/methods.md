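# Methods

## The inverse problem

Gradient-echo MRI measures a local magnetic field perturbation `B_M(r)`
(in ppm of the main field) produced by the tissue susceptibility
distribution `chi(r)` (ppm).  To first order in `chi`, the two are linked by
a convolution with the unit dipole response, which in k-space is the
pointwise multiplication

    B_M(k) = d(k) * chi(k),      d(k) = 1/3 - (k . o)^2 / |k|^2,

where `o` is the unit B0 direction expressed in image axes.  `d` vanishes on
the cone at the magic angle `arccos(1/sqrt(3)) ~ 54.7 deg`, so the inversion
(field to susceptibility) is ill-posed and needs regularization or a learned
prior.  `adaptqsm` implements a learned inversion: a 3D U-Net conditioned on
the acquisition geometry.

### Discretization of the dipole kernel

The continuum physics leaves the discretization open; the choices here
are:

* Unshifted FFT frequency layout (`numpy.fft.fftfreq`), per-axis spacing
  `1/(N_i v_i)` — anisotropic voxels stretch the k-grid; a tilted field of
  view enters only through `o` (no image resampling).
* The DC term is set to 0 by default (fields are defined up to a constant;
  susceptibility maps are referenced to their masked mean anyway).
  Configurable via `dc_convention`.
* On even-sized axes the Nyquist index represents the frequencies `+-1/(2v)`
  equally.  `(k . o)^2` is therefore evaluated as its average over
  independent sign choices of the Nyquist components, which removes the
  cross terms involving them.  Without this, the kernel is not even under
  index negation for oblique `o`, `d * chi_hat` loses conjugate symmetry for
  real `chi`, and the exact 90-degree rotation equivariance of the forward
  model breaks.  Non-Nyquist entries are unaffected.
* Periodic boundary conditions are implied by k-space multiplication.
  `forward_field(..., pad=True)` zero-pads to twice the grid for
  validation runs where wrap-around matters.

Units: `chi` in ppm, fields in ppm at a 1 T reference; conversion to Hz or
radians is out of scope.

## Adaptive convolution

A convolution layer whose weights are not stored but generated per
acquisition by a filter manifold network (FMN): four linear layers
`6 -> 12 -> 48 -> 196 -> 13824` with ELU (alpha = 1) between the hidden
layers.  The input is the side-information vector
`s = (vx, vy, vz, ox, oy, oz)` — voxel size in mm and unit B0 direction,
fed raw (components are O(1) under the training distribution).  The 13,824
outputs are reshaped to the `(32, 16, 3, 3, 3)` weight tensor of the
16 -> 32 convolution in the first encoder block; a static trainable bias
per output channel is kept alongside (the generated weights carry no bias).
The FMN holds 2,733,640 parameters (sum of `(fan_in + 1) * fan_out`).

Initialization: the final FMN layer's bias is drawn like a conventional
He-initialized convolution kernel and its weight matrix at 5% of the usual
He scale, so the generated filters start as a standard random
initialization with a weak, learnable dependence on `s`.

`kernel_sensitivity` reports `||w(s + delta) - w(s)|| / ||delta||`, the
finite-difference slope of the filter manifold, for inspecting how strongly
the generated kernels react to a geometry change.

## Network architecture

Standard 3D U-Net, 16 initial channels, two 3x3x3 convolutions per block
(channels double on the second), batch normalization then ELU after every
convolution, 2x2x2 max pooling, 2x2x2 transposed convolutions for
upsampling, encoder-decoder concatenation skips, and a global input-output
residual addition (the network learns the difference between field and
susceptibility).  The final 3x3x3 convolution to one channel is
zero-initialized, so an untrained model is exactly the identity.

The reference architecture pins the initial channel count, kernel sizes
and the total of ~8.3 million trainable parameters, but not the full
channel plan.  The plan used here doubles channels per encoder level up to a cap of
256 — encoder outputs 32, 64, 128, 256, bottleneck 256 — and uses a
lightweight fixed-width (16-channel) decoder.  The encoder carries the
representational load; the residual formulation keeps the decoder's job
small, and this split reproduces the reference total: 8,320,985 parameters
including the FMN (0.25% above 8.3e6).  A symmetric decoder would overshoot
that budget by ~30%.

Variants: `conventional` replaces the adaptive layer with a static 16 -> 32
convolution (ignores `s`); `adaptive_encoder` makes all 10 encoder +
bottleneck convolutions adaptive, each with its own FMN (hidden sizes
shared, final width matching that convolution's weight count).  The
default-size encoder variant is large (hundreds of millions of parameters);
tests exercise it at reduced width.

The adaptive layer sits on the second convolution of the first encoder
block, i.e. directly after the first two convolutions have extracted
edge-like features — the features most directly affected by voxel size and
orientation.

## Training

Loss (lambda = 1 by default):

    L = ||chi_gt - chi_rec||^2 + lambda ||B_gt - d * chi_rec||^2

The field term evaluates the dipole forward model on the reconstruction, so
optimization is pinned to solutions consistent with the physics.  Both
terms are per-voxel means by default, which decouples the loss scale from
the patch size; a `sum` mode reproduces plain squared L2 norms.  The field
term uses a patch-sized periodic dipole kernel (how patch boundaries are
handled is otherwise open).

Pre-training: per epoch and scene, sample an acquisition geometry (standard
geometry with probability 0.2, otherwise truncated-Gaussian voxel sizes and
perturbed orientation), cut 4 random patches, augment (susceptibility
scaling U[0.5, 2], random flips, random 90-degree rotations), simulate the
clean field on the patch grid, and feed the field plus Gaussian noise
(sd 0.01 ppm) to the model.  Noise corrupts only the network input; the
ground-truth susceptibility and the field target stay clean.  The
susceptibility scaling interval and the noise sd are free parameters of
the recipe; both are configurable.  Optimizer: AdamW (beta1 0.9,
beta2 0.99, eps 1e-8, weight decay 0.01).  Schedule: cosine annealing with
warm restarts, T0 = 500, Tmult = 0.5, eta from 1e-3 to 1e-8, stepped per
epoch.  A shrinking restart period (Tmult < 1) is unusual but kept as the
reference value, with periods floored at one epoch.

Transfer learning (30 epochs by default): the adaptive layer — the FMN and
its static bias — is frozen; decoder parameters train at 1e-3, everything
else at 1e-5.  Per volume, with probability 0.5 the stored (measured) field
patch is the input; otherwise the ground truth is re-scaled by a factor
drawn from U[0, 2] and its field re-simulated, preserving susceptibility
scale invariance.  96^3 patches are zero-padded to 128^3 so border regions
are seen.  Whether the chi term should be masked to brain voxels is not
pinned down; both modes are exposed (`mask_chi_term`, default off).

## Synthetic phantoms

A scene is 80-150 rectangles, 50 extruded polygons and 200-300 ellipsoids
with per-shape susceptibilities from N(0, 0.25 ppm), each shape blurred
individually with a Gaussian of sd U(0, 0.8) voxels; where shapes overlap,
contributions are averaged (the per-voxel value is the sum of blurred
contributions divided by the number of covering shapes, a symmetric rule,
so shape order is irrelevant).  The mask is the complement of 300 random
ellipsoids centered in a border band of 15% of each dimension.  Polygons
are realized as star-shaped 2D polygons (3-8 vertices) extruded over a
random slab — their exact 3D construction is otherwise unspecified.  Shape
extents are uniform fractions (3-15%) of the grid dimension.  Blur is
applied to the valued contribution (value times indicator), not to the
indicator alone.

Geometry sampling: with probability 0.8, voxel sizes are drawn per
component from N(1, 1.5) mm rejected outside [0.5, 3.5] mm (rejection
bounds are this package's choice; a raw N(1, 1.5) draw can be negative), and the axial B0
vector is perturbed additively — x/y components with sd 1/11, z with sd
1/5 — then re-normalized; the perturbation scales are a design choice here, so
both sds are exposed in the sampler spec.
Otherwise the standard geometry ((1,1,1) mm, axial) is returned.

Lesions: labelled regions are set to assigned susceptibilities (defaults
-1.0, -0.5, 0.5, 1.0 ppm), the inserted component smoothed with a Gaussian
of sd 0.5 voxels and added to the base map — emulating pathologic
out-of-distribution susceptibilities.

What the generator does *not* emulate: brain anatomy, susceptibility
anisotropy and microstructure, flow and chemical-shift artifacts, scanner-
and coil-specific field contributions, background-field-removal residuals.
Tests passing on these phantoms demonstrate the physics and the learning
machinery, not clinical-grade reconstruction quality.

## Numerical backend

The network stack — reverse-mode autodiff, Conv3d / ConvTranspose3d /
BatchNorm3d / MaxPool3d / Linear / ELU, AdamW, the warm-restart cosine
schedule — is implemented in-package on numpy (`adaptqsm.nn`).
Convolutions use slab-chunked im2col with BLAS matmuls (~4M scratch
elements per slab bounds peak memory); the input gradient reuses the
forward path with a flipped, channel-swapped kernel; the k-space dipole
operator is its own adjoint (real, even kernel) so its backward pass is the
same operator.  Every gradient is validated against central finite
differences in the test suite.  Float64 is the default; `Module.astype`
casts to float32 where throughput matters more than precision.

## Problem sizes used in tests and the acceptance script

Pre-training at the reference scale (1,000 scenes of 320^3, 500 epochs,
160^3 patches) is a multi-GPU, day-scale computation.  The test suite and
the acceptance script instead train a reduced surrogate chosen as this
package's standard desk-scale configuration: 8 initial channels, 2
resolution levels, 15 scenes of 48^3 (default shape counts and
susceptibility statistics), 2 patches of 32^3 per scene, 25 epochs, eta
2e-3 with a single cosine period.  Held-out evaluation uses 5 unseen scenes
and compares the trained model against the residual-identity baseline (the
untrained network, whose output equals its input field) on masked SSIM and
whole-volume OLS slope.

## Known limitations

* The reference architecture's exact channel plan and the adaptive-encoder
  layout are underdetermined; the parameter total is used as the arbiter
  (see above).
* Patch-based field loss assumes periodicity on the patch; large-scale
  field components spanning patch borders are approximated.
* In-vivo performance (NRMSE/SSIM against COSMOS ground truth) cannot be
  verified here without clinical data; the package verifies the method's
  desk-scale properties instead.
* The numpy backend is single-threaded except for BLAS; training at the
  reference scale is out of reach by design.
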