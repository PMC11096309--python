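# Methods

## Problem and measurement principle

Metallic and magnetic components of active cardiac implants perturb the
static B0 field of an MR scanner. Beyond the familiar signal void, the
perturbation geometrically distorts the image: structures appear displaced,
enlarged, shrunken, deformed, or changed in brightness. `mrdistort`
quantifies these effects with a reference phantom: a cartesian grid of
7 × 7 × 7 thin-walled, water-filled spheres (40.17 mm outer diameter,
0.2 mm wall, 40 mm center pitch), with five spheres omitted in the middle
slice so a device can sit at the magnet isocenter. Each bright sphere is a
3D fiducial; comparing each sphere's reconstruction in an implant scan
against the *same* sphere in an implant-free reference scan isolates the
implant's contribution and cancels scanner-intrinsic gradient
nonlinearity.

All coordinates are world millimetres with the origin at the phantom/grid
center (the isocenter), voxel-center convention, axes X left–right,
Y foot–head, Z bottom–up.

## Pipeline

1. **Ingest** (`mrdistort.io`): DICOM series or NIfTI volumes are
   assembled into a `Volume`, trilinearly resampled to an isotropic 2 mm
   grid (the common working resolution for all scans), and
   exposure-corrected by histogram stretching: the 1st/99th intensity
   percentiles map affinely to 0/1 with clipping. The percentiles (rather
   than min/max) keep large void or background regions from dominating the
   stretch; after correction one gray threshold applies to every scan.
2. **Segmentation** (`mrdistort.segmentation`): see below.
3. **Per-ball metrics** (`mrdistort.metrics`): gravity center (unweighted
   voxel centroid), volume `V` (voxel count × voxel volume), mean gray
   value `GV`, and the out-of-round measure
   `ORM = RM/Rm − 1`, where `RM` and `Rm` are the means of the radii at or
   above the 95th / at or below the 5th linear-interpolation percentile of
   the center-to-surface-voxel distances. The trimming suppresses rough
   surface outliers; ORM = 0 for a perfect sphere, ORM = 1 when the longest
   dimension is twice the shortest.
4. **Comparative metrics**: homologous spheres (same grid index) in an
   implant scan *d* and reference scan *r* yield
   `dCL = |c_d − c_r|`, `dV = (V_d − V_r)/V_r`, `dORM = ORM_d − ORM_r`,
   `dGV = (GV_d − GV_r)/GV_r`. A distorted ball with fewer than 8 voxels
   (64 mm³ at 2 mm) counts as *disappeared*: `dV = −1`, other deltas
   undefined.
5. **Uncertainty and critical radius** (`mrdistort.critical`): repeat
   implant-free scans are compared against the first; each metric's
   uncertainty is the maximum absolute deviation over all balls and
   repeats (worst-case logic, consistent with deriving a placement
   threshold from a min–max volume spread). Thresholds are structurally
   2 × the uncertainties. The critical radius of a metric is the largest
   isocenter distance of an affected reference ball center plus the 20 mm
   nominal ball radius (a conservative outer envelope; adding a length to
   the center distance is the only dimensionally consistent reading),
   or 0 when no ball is affected.

## Reaction–diffusion segmentation

Each present sphere is grown from a spherical seed (radius = ¼ of the
nominal ball radius) at its nominal center. Per label *l* a concentration
field u_l on the voxel lattice evolves under

    du_l/dt = D ∇²u_l + k · u_l (1 − U) (I − θ),    U = Σ_m u_m,

with the 6-neighbour Laplacian, explicit Euler stepping, u clamped to
[0, 1], and I the exposure-corrected intensity (internally clamped to
[0, 1] so over-unity inputs cannot push the explicit reaction step past its
relaxation limit). For a single label (U = u) this is the classical
bistable form u(1 − u)(I − θ). With several labels the shared saturation
term makes fronts compete: territory claimed by one front (U ≈ 1) offers no
growth capacity to another. This is what makes the segmentation robust to
*shunts* — distortion-induced bright bridges between neighbouring spheres:
a front arriving through a bridge finds the neighbour sphere already
claimed by its own seed and cannot invade, while plain thresholding or
uncompeted region growing would merge the two spheres. Narrow (1-voxel)
bridges additionally stall fronts outright, because transverse diffusive
loss into the dark surroundings exceeds the reactive gain inside the
channel.

A voxel is finally *claimed* when the total concentration U exceeds ½ —
equivalent to the plain u > ½ rule for an isolated label, but correct at
marginal boundary voxels whose capacity two fronts share — and is assigned
to the argmax label, ties breaking to the lowest label for determinism.
Each label is then pruned to the 6-connected component containing its seed,
so every segmented sphere is connected; a label whose seed voxel ends up
unclaimed keeps its largest component and is flagged displaced-seed.

### Numerical parameters

| parameter | default | units | rationale |
|---|---|---|---|
| D (diffusion) | 0.2 | lattice²/time | front smoothing; keeps the explicit bound step·D·6 ≤ 1 with margin |
| k (reaction) | 4.0 | 1/time | reaction-dominated front that pins to the I = θ contour; at k ≈ 1 the front settles one voxel short of the contour and per-ball Dice against the threshold oracle drops to ≈ 0.98 |
| θ (threshold) | 0.5 | — | water/background midpoint after exposure correction |
| step | 0.4 | time | half the diffusion stability bound; steps near the bound leave the lattice checkerboard mode undamped (sustained oscillation) |
| tol | 1e-4 | — | stop when the largest per-step change falls below this |
| max_iterations | 2000 | — | hard cap; non-convergence returns the partial result with a warning |
| box_halfwidth_mm | 30 | mm | per-label evolution box; admits ≈10 mm of ball displacement beyond the 20 mm radius while bounding memory (≈40 MB for 338 labels at 2 mm) |
| min_voxels | 8 | voxels | disappeared-ball criterion (64 mm³ at 2 mm) |

The clean 338-sphere phantom at 2 mm converges in ≈220 iterations
(≈1–2 min on one core); per-ball Dice against the independent
midpoint-threshold + connected-components oracle is ≥ 0.99 and per-ball
volumes are within 3 % of the closed-form water volume.

## Synthetic phantom and artifact simulator

The rasterizer (`mrdistort.phantom.rasterize`) draws each water sphere
(radius = outer radius − wall) with partial-volume antialiasing by midpoint
supersampling (default 4³ sub-samples per voxel) on a grid covering the
phantom plus one ball diameter of margin, a voxel centered on the
isocenter. Per-sphere occupancy patches are combined by maximum, not sum:
neighbouring shells touch tangentially, and summing the two sub-voxel caps
at a contact point would raster a bright bridge above the midpoint
threshold that the dark plastic walls prevent in the real phantom.
Integrated per-sphere volume converges to the closed form as supersampling
grows (≈0.05 % at the default).

The artifact simulator (`mrdistort.simulate`) emulates the artifact
*qualities* the metrics measure, with known ground truth:

- **off-resonance**: a point dipole, ΔB ∝ m (3 cos²θ − 1)/r³, the leading
  far-field term of any localized susceptibility distribution (B0 along
  the foot–head bore axis by default);
- **displacement**: `displacement_scale` × field along the readout axis
  only, mimicking frequency-encoding mis-mapping; volumes are pulled back
  through the field with trilinear interpolation (out(x) = in(x − d(x)),
  so features move *by* d);
- **signal void**: intensities suppressed where |field| exceeds
  `void_level`;
- **gray-value change**: a multiplicative gain;
- optional seeded Gaussian noise (off by default; every stochastic test
  passes an explicit seed).

The simulator is *not* a calibrated model of any real device: it makes no
claim about sequence-specific echo behaviour, eddy currents, or the actual
susceptibility maps of implants. What passing the recovery tests shows is
that the pipeline reads back known displacement, volume, gray-value and
localization ground truth through segmentation and metrics — not that it
reproduces any particular device's published artifact figures, which
require the physical phantom and scanner.

## Degenerate inputs and tie-breaks

- Constant-intensity volumes are rejected by exposure correction
  (degenerate histogram).
- A label with zero voxels raises `EmptyLabelError` on surface extraction
  — distinct from the disappeared flag, which marks a tiny-but-present
  ball; descriptors for empty labels carry NaN shape fields.
- A disappeared *reference* ball is an error (reference scans must be
  implant-free); repeats with disappeared balls are rejected in the
  uncertainty calibration.
- Argmax ties in labeling go to the lowest label; all operations are
  deterministic for identical inputs.
- Disappeared balls always count as affected for the dV critical radius
  (their volume loss is total); for other metrics their deltas are
  undefined and excluded.

## Problem sizes used in the shipped tests

Unit tests run on 1–27-sphere grids at 2 mm; the acceptance tests run the
full 338-sphere phantom at 2 mm for the oracle-equivalence and
parameter-recovery checks (one reference plus five simulated implant
segmentations). The dipole recovery ladder uses moments {1, 3, 10} × 10⁵
(field units · mm³) with unit displacement scale, spanning sub-voxel to
multi-voxel displacements inside the phantom.

## Known limitations

- Only axis-aligned (diagonal-affine) NIfTI volumes and axial single-frame
  DICOM series are supported; oblique acquisitions must be resampled
  upstream.
- The exact reaction–diffusion scheme used with the original scanner data
  is not public; the scheme here is specified by its required properties
  (seeded region growing, shunt robustness, threshold-oracle equivalence
  on clean data) and documented fully above.
- The omitted-sphere layout of the physical phantom's middle section is
  configurable (`PhantomSpec.omitted_indices`); the default omits the grid
  center and its four in-plane neighbours.
- Uncertainty aggregation is worst-case (max), so calibrated thresholds
  grow with the number of repeat scans; with few repeats they are
  optimistic.
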