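# Methods

## Scene model

The dynamic refractive-index field n(**x**, t) = 1 − δ + iβ is represented
over the normalized spacetime cube [−1, 1]⁴ by six 2D feature planes, one
per coordinate pair: three purely spatial planes (xy, xz, yz) that carry
structure shared across all times, and three space–time planes (zt, yt, xt)
that modulate it along time.  Each plane is a (G₁, G₂, F) array; the three
spatial axes share one grid size N (`spatial_grid`), time has its own T
(`temporal_grid`), and all planes share the channel count F (`feature_dim`),
i.e. the three low-rank component counts of the tensor factorization are
taken equal to F.  Storage is 3N²F + 3NTF parameters instead of N³T for a
dense voxel movie.

A query point is projected onto each plane and bilinearly interpolated;
coordinates at ±1 clamp to the plane edge, so interpolation at a grid node
reproduces the stored feature exactly and out-of-range times extrapolate by
edge-clamping (flagged in the rendered volume's metadata).  The six feature
vectors are concatenated into a 6F descriptor (default) or multiplied
pairwise over complementary planes — (xy·zt, xz·yt, yz·xt) — and
concatenated into a 3F descriptor (`fusion_mode="paired-product"`); no
per-plane nonlinearity is applied before fusion.  A small ReLU MLP
(`mlp_layers` hidden layers of `mlp_width` units) decodes the descriptor
into one or two output channels, passed through a softplus so that δ and β
are non-negative (a physical constraint at hard-X-ray energies; a raw
linear output is available via configuration).  Plane features initialize
uniform(−0.1, 0.1)/√F and MLP weights with uniform fan-in scaling, all from
one seed; identical configurations are bitwise reproducible.  No
coarse-to-fine plane upsampling is used; the related visible-light scene
models employ it, but it is unnecessary at the problem sizes targeted here
and is left as an extension hook.

## Forward model

Parallel-beam geometry with the rotation axis along z, mapped to detector
rows.  At angle θ (degrees, counter-clockwise about +z) rays travel along
R_z(θ)(0,1,0) and detector columns run along R_z(θ)(1,0,0).  Under the
projection approximation the exit wave is ψ₀·exp(−ik∫(δ−iβ)dz), so the
rendered currencies are line integrals of δ and β along each pixel's ray;
conversions to intensity exp(−2k∫βdz) and phase −k∫δdz are explicit,
separate operations with exact inverses.  Rendering samples each ray's cube
chord with one point per equal sub-interval (midpoint rule when
deterministic, uniformly jittered per sub-interval during training); the
quadrature weight is chord/n_samples, so weights always sum to the chord
length, and points outside the cube contribute nothing (vacuum).  The
default n_samples equals the largest plane resolution.

A brute-force reference projector (`project_volume_oracle`) integrates a
dense voxel grid with fixed midpoint sampling and trilinear interpolation.
Voxels are cell-centered and cover their full cells, so interpolation
clamps to the edge cell inside the cube; this makes a uniform field project
exactly its chord length and keeps the detector mass equal to the voxel
mass to well under 1%.  It doubles as the phantom acquisition simulator and
as the independent oracle the stochastic renderer is tested against.

## Acquisition scheduling

A wedge schedule assigns time point i the half-open cumulative-angle window
[start + iΔθ, start + (i+1)Δθ); the temporal enhancement over half-turn
tomoscopy is 180/Δθ, total coverage is n·Δθ, and the same viewing angle
recurs every 360/Δθ time steps when that ratio is integral.  Two extraction
protocols carve wedge datasets out of continuous-rotation stacks:
*streaming* (default) takes consecutive frames — what a real wedge
acquisition records — while *per-rotation* takes time point i's window,
folded modulo 360°, from rotation i+1 of a repeated-rotation stack; the
latter exists to benchmark against tomoscopy ground truth assembled from
the same frames.  Full 360° rotations are used for that emulation rather
than 180° half-turns because combining mirrored half-turn frames introduces
4D inconsistencies.  Extraction is pure selection: pixels and angles are
untouched and only time stamps are rewritten, each wedge's frames getting
the wedge midpoint mapped linearly to normalized time.  Frames exactly on a
window edge belong to the upper window (half-open convention with a 1e-9
angle tolerance so floating-point angle rounding cannot double-assign).

## Training

The loss is the mean squared difference between rendered and measured
line-integral pixels over a random ray batch plus λ_reg times a plane
penalty: TV (mean over the six planes of the per-plane mean squared forward
difference along both plane axes, all channels) and L1 (mean over planes of
the mean absolute feature), mixed by `tv_weight_split` (default equal).
One "epoch" is one optimizer step on one batch: a frame drawn uniformly,
`rays_per_batch` pixels sampled without replacement within it.  Gradients
are computed analytically — the adjoint of the quadrature, fusion,
interpolation (scatter-add to plane corners) and MLP — and verified against
central finite differences in the test suite.  The optimizer is Adam
(β = 0.9/0.99) with separate learning rates for planes (2e-2) and MLP
(1e-3), cosine-decayed to a 1% floor; λ_reg defaults to 1e-4.  None of
these values come from the literature; all are exposed in `TrainConfig`.
Training is deterministic given the seed and aborts with the iteration
number if the loss turns non-finite.  With two output channels,
attenuation-domain targets supervise β and phase-domain targets supervise δ
(the unsupervised channel is constrained only by the regularizer); the
single-channel δ-only configuration mirrors experiments where phase
retrieval leaves a single usable contrast.

## Synthetic phantoms

The generator emulates the two dynamic regimes the engine targets, as
piecewise-constant δ fields (values are exactly the configured contrast
levels, so threshold segmentation of ground truth is exact):

* **merging_droplets** — two spheres (radii 0.30/0.26, initial center
  distance 1.0 in normalized units) approach linearly and coalesce; the
  surface is a smooth-min (k = 0.05) of the two sphere distance fields, and
  at every time point the iso-level is re-solved by bisection so the
  occupied voxel count matches the first frame — volume is conserved
  through the merge to within one lattice shell (< 1% at 32³).  Relaxation
  asymptotes: the centers never become exactly concentric, both physically
  and because an exactly concentric state makes whole lattice symmetry
  classes degenerate in the iso-level solve.
* **melt_pool** — a static substrate slab plus a higher-contrast ellipsoidal
  molten region translating at constant velocity (static background,
  localized dynamics).
* **static_ball** — the time-constant self-consistency target.

Virtual tomoscopy assigns frame j the cumulative angle j·360/P and holds
each phantom state over an equal run of frames (zero-order hold — the
sample is static within a wedge).  Optional Gaussian noise is added in
line-integral units; a stylized Poisson model draws counts at a given dose
on exp(−value).  What the phantoms deliberately omit: partial-volume and
sub-voxel surface smoothness, edge-enhancement/propagation contrast,
detector blur, ring artifacts, intra-wedge motion (a linear-interpolation
hold mode is not enabled by default) and frame-to-frame alignment errors.
Passing the recovery experiments therefore demonstrates the inverse-problem
machinery — not robustness to every artifact of beamline data.

## Evaluation

FSC uses shells one frequency bin wide (voxel counts per shell taken over
the full sphere), correlations Re⟨F_A·F̄_B⟩/√(⟨|F_A|²⟩⟨|F_B|²⟩), and the
half-bit threshold; the crossing is the first downward threshold crossing
with linear interpolation between shells, and resolution = 1/crossing,
floored at 2 voxels.  Non-cubic volumes are zero-padded to cubes.  PSNR and
NRMSE are normalized by the truth's value range (PSNR capped at 500 dB for
exact agreement), SSIM uses the standard windowed constants in 3D; all three
are computed per time point and aggregated as mean ± std.  The classical
baseline is a slice-wise filtered back projection built on the discrete
band-limited ramp kernel (h₀ = 1/(4d²), h_odd = −1/(πnd)²) with
angular-spacing weighting (π/n_angles for a uniform half-turn, halved for
full-turn coverage); it is a surrogate for Fourier-regridding
reconstructors, not a clone of them, and shares the projector's exact
geometry (the centering conventions of off-the-shelf 2D FBP routines differ
by half a pixel from this package's cell-centered grids).

A caveat worth knowing when comparing against limited-angle FBP under the
half-bit rule: a wedge-restricted FBP retains the sampled Fourier wedge
essentially exactly, so its shell correlation with the truth hovers near
√(wedge fraction) — about 0.32 for an 18° wedge — which can sit *above* the
half-bit threshold at every shell.  The baseline then ties the 2-voxel
Nyquist floor at individual time points despite severe streak artifacts,
and no method can be strictly better there.  The shell-averaged FSC is
simply weak at penalizing anisotropic missing-wedge errors; the per-time
comparison in the acceptance suite documents this where it occurs.

## Preprocessing

Flat-field correction is (raw − dark)/(flat − dark) with a strictly
positive denominator enforced and a 1e-9 clipping floor before logarithms.
Single-distance phase retrieval for a homogeneous object divides the
transmission's 2D spectrum by 1 + (R·(δ/β)·λ/4π)·|2πf|², with f in cycles
per physical length derived from the pixel size, then takes −ln/µ
(µ = 4πβ/λ supplied by the caller; published conventions for the filter
constant vary, and the implementation here is pinned by its R → 0 limit
−ln(I)/µ and by a direct-DFT oracle in the tests).  Images are
symmetrically padded to the next power of two before the FFT to suppress
wrap-around (configurable).  Radon-mass normalization rescales each frame
multiplicatively to its time group's mean pixel sum (idempotent; factors
returned for audit).  Rebinning merges consecutive pairs of 0–180° blocks
into 0–360° blocks by pure index bookkeeping, halving the time points and
doubling the projections per point.

## Problem sizes and reproducibility

The shipped experiments run on one CPU: the static self-consistency fit
uses a 32³ ball, 90 half-turn angles, a 32/8-grid F = 8 scene with a 2×32
MLP and 3000 steps; the dynamic recovery uses an 8-time-point 32³
merging-droplet phantom, 18° wedges in streaming mode with 4 frames per
wedge (80 frames per rotation, 144° total coverage, noiseless), a
32/16-grid scene and 5000 steps.  These sizes were chosen as the smallest
at which the wedge problem is meaningfully under-determined yet the fits
finish in minutes; the defaults in `SceneConfig` (64-point grids, F = 48,
3×64 MLP) are the full-scale configuration.  HDF5 outputs disable
timestamp tracking and training histories exclude wall time, so pipeline
manifests (SHA-256 per artifact) are byte-identical across repeat runs of
one configuration on one machine.

## Known limitations

Parallel-beam only (no fan/cone geometry); no Fresnel-propagation or
multi-slice forward model beyond the projection approximation; no
ring-artifact, beam-hardening or detector-distortion corrections; the pure
NumPy optimizer is single-threaded and minutes-per-fit at desk scale rather
than real-time; FSC-based scoring shares the missing-wedge blindness noted
above.
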