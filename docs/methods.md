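# Methods

## Scope and model

`qfish3d` quantifies telomeres imaged by 3D super-resolution Q-FISH:
sparse, bright, near-diffraction-limited foci of hybridized peptide
nucleic acid (PNA) probes recorded as raw photon counts on anisotropic
voxel grids (default 30 × 30 nm laterally, 200 nm axially). The
pipeline has five analysis stages — detection, per-spot quantification,
molecular brightness calibration, hierarchical statistics, and
TRF densitometry — plus a ground-truthed simulator that makes every
stage testable without microscope data.

A core principle is that photon counts are never rescaled: detection
operates on a Gaussian-smoothed *copy* of the stack, while all
quantitative readouts are fitted to the raw counts.

## Spot detection

Foci are found by maxima-based peak detection with 3D segmentation,
in the spirit of interactive foci-finding plugins but fully
deterministic:

1. The stack is smoothed laterally (Gaussian, σ = 1 px by default;
   axial σ = 0 because the axial sampling is ~7× coarser). The filter
   σ is exposed because published analyses rarely state it.
2. Seeds are the 26-connected local maxima of the smoothed stack
   strictly above the background floor (default 10 photon counts).
   Equal-valued plateau maxima collapse onto the lexicographically
   smallest index.
3. Every above-background voxel follows its steepest ascending path
   (26-connectivity, deterministic tie-breaks) to a seed.
4. Touching peaks merge when the saddle between them exceeds
   `background + saddle_fraction × (lower_peak − background)`
   (default fraction 0.5).
5. Regions below `min_spot_voxels` (default 10) are discarded; the
   center of mass is computed over background-subtracted smoothed
   intensities.

26-connectivity is used uniformly despite the anisotropic voxels;
anisotropy is handled downstream by per-axis fitting, and a uniform
neighborhood guarantees that every ascent path terminates at a seed.
The full option space of interactive foci finders (search modes, peak
expansion criteria) is deliberately not reproduced; the algorithm
above, parameterized by the background floor, minimum size and saddle
fraction, is this package's fixed definition.

## Per-spot quantification

At each spot's brightest sampled z-plane (maximal smoothed value at
the rounded lateral center, among planes containing member voxels,
ties to lower z), two raw-count line profiles of 480 nm (16 px) are
taken along the x and y pixel axes and fitted with

    y = a + (b − a)·exp(−(x − c)² / (2 d²))

by bounded nonlinear least squares (`a ≥ 0`, amplitude `b − a > 0`,
`c` inside the profile, `0.5 ≤ d ≤ L` px; initialization from the
profile extrema, d₀ = 2 px). Profiles are axis-aligned pixel
rows/columns without interpolation; the continuous center `c` absorbs
sub-pixel offsets. Non-convergent and constant (zero-variance)
profiles yield r² = 0 and count as insufficient. Fits with
r² > 0.8 are accepted. Features:

- `FWHM_axis = 2√(2 ln 2) · d_axis · pixel_size`;
- axial width is not fitted (200 nm steps under-sample a ~400 nm
  axial PSF); it is interpolated as the mean of the lateral FWHMs;
- `volume = (π/6)·FWHM_x·FWHM_y·FWHM_z` (prolate ellipsoid, µm³);
- `integrated brightness = 2π · mean(b_x, b_y) · d_x · d_y` with `d`
  in pixels — a counts·px² quantity;
- `signal density = integrated brightness / volume`.

Two definitional subtleties are implemented as printed rather than
"fixed", because the calibration stage uses identical settings and the
conventions cancel:

- the integral uses the fitted *peak level* `b`, which includes the
  local background, not the amplitude `b − a`. An opt-in
  `background_corrected=True` variant integrates `mean(b) − mean(a)`
  when an absolute photon integral is wanted;
- when both fits are accepted, the reported peak brightness and
  background come from the higher-r² axis, while volume and integral
  use both axes. With exactly one accepted fit, only that axis's FWHM
  and peak brightness are reported. With none, the spot is kept with
  flag `rejected` (as are spots whose profile window would clip the
  image border).

A known property of brightest-plane quantification: a spot whose axial
center falls between sampled planes is read at an attenuated
amplitude (up to `exp(−½(100/170)²) ≈ 0.84` at the default geometry;
≈ −6% on average over uniform offsets). The fit machinery itself is
unbiased — validation compares against the analytic integral of the
brightest *sampled* plane — and the bias cancels in molecule counting
whenever the calibration standards are processed identically.

## Brightness calibration and molecule counting

DNA-origami standards with known fluorophore counts (defaults 17, 34,
60) are detected and quantified exactly like telomeres. Per standard,
the brightness histogram is fitted with a Gaussian (Scott's-rule bins;
sample mean/SD fallback below 30 beads; a normal-fit r² < 0.9 logs a
warning). Fluorophore counts are regressed on mean brightness
(weighted by bead counts; affine by default with a near-zero-intercept
check, optionally through the origin), so the slope is directly the
brightness→molecules conversion factor. Probe counts times the 18-nt
hybridization footprint of the (CCCTAA)₃ probe give labeled sequence
length; dividing by an independent mean telomere length (TRF) gives
the labeling efficiency.

Peak and integrated readouts can rank conditions differently (a
condition can have dimmer peaks yet more total probes); the package
computes both and leaves interpretation to the user.

## Nested statistics

Spots within a cell are not independent replicates. The nested test
treats condition as a fixed effect and cell as a random effect within
condition, computed through expected mean squares: the condition mean
square is tested against a Satterthwaite-synthesized denominator
`(k₁/k₂)·MS_cells + (1 − k₁/k₂)·MS_within`, where k₁ and k₂ are the
usual unbalanced-design EMS coefficients of the between-cell variance;
with balanced cells this reduces to the classical exact nested F test.
Lognormal features (brightness, density) are log10-transformed first,
and effects are reported as percent changes of geometric means, using
the unweighted mean of cell means per condition (cells are the
experimental units). Closed-source implementations of "nested t
tests" exist in commercial packages; rather than matching one
bit-for-bit, this formulation is validated by type-I-error simulation
(≈5% at nominal 5%) and by the pseudo-replication property (a pooled
t-test is almost always anti-conservative relative to it when cells
differ).

Frequency distributions are modeled by Gaussian
(`Y = A·exp(−½((X − µ)/σ)²)`, robust soft-L1 loss with scale 1
available) and lognormal
(`Y = (A/X)·exp(−½(ln(X/GeoMean)/ln(GeoSD))²)`, least squares) curves
on Scott's-rule histograms with left-closed bins and bin centers as X.
Dataset pairs are compared with the extra-sum-of-squares F test on a
common bin grid (one shared parameter set versus separate fits). Bins
with pooled counts below 5 are excluded from these comparison fits:
bin counts are Poisson, and the unweighted F statistic is otherwise
anti-conservative (null simulations reject ~3× too often); with the
standard sparse-cell exclusion the null rejection rate is close to
nominal. This is a fitting-range choice, fixed once.

## TRF densitometry

A Southern-blot smear is digitized as intensity versus migration
position; ≥ 3 ladder bands calibrate a log-linear migration model
(`log10 MW` vs position). The mean telomere length is

    MTL = Σ NIᵢ / Σ (NIᵢ / MWᵢ)

— total mass over total molar amount, i.e. the number-weighted mean
fragment length. The sum is applied to the discretized profile as
supplied (no trapezoidal reweighting); a few hundred positions across
the smear make the discretization error ≪ 1%. Cropping to the smear
region and background subtraction are the caller's responsibility
(a rolling-minimum helper is provided, off by default, since published
background conventions differ).

## The simulator

`simulate_nucleus_stack` renders separable anisotropic Gaussian spots
(defaults: lateral σ 56 nm → FWHM ≈ 132 nm; axial σ 170 nm → FWHM
≈ 400 nm, the axial resolution floor) on a constant background of 2
photon counts, Poisson-samples every voxel (photon-counting detection,
no read noise), and returns the exact ground truth. Peak amplitudes
are lognormal with geometric mean 50 counts and geometric SD 1.5 —
spots a few-fold above the 10-count detection floor with a realistic
brightness spread. Spots are rejection-sampled inside an ellipsoidal
nucleus (default semi-axes 1900 × 3300 × 3300 nm inside a
21 × 256 × 256 stack) under an anisotropic minimum-separation
constraint: lateral distance 400 nm, with axial distances scaled down
by the axial/lateral resolution ratio (3×), matching what the optics
can separate. `simulate_cell_cycle_experiment` composes per-cell
stacks for two conditions (9 vs 8 cells, ~90 vs ~207 spots, count CV
9%, between-cell amplitude GeoSD 1.1) with an optional amplitude
scaling of condition B at unchanged spot size — a density decrease at
constant geometry. `simulate_origami_field` places beads on a
jittered lateral grid at the central plane exactly (surface-
immobilized monolayer in focus). `simulate_trf_lane` draws lognormal
fragment lengths with a prescribed arithmetic mean, bins mass-weighted
intensity onto the migration axis through the inverse ladder model,
and reports the fragment-level mean as the analytic truth.

What the simulator deliberately does not model: STED PSF side lobes
and depletion-beam artifacts, photobleaching, detector afterpulsing,
optical aberrations deep in the sample, chromatin-driven clustering of
telomeres, and segmentation of real DAPI nuclei (masks are ideal
ellipses). Passing tests therefore demonstrate the correctness and
calibration of the *analysis*, under the stated image-formation model,
at the stated spot densities — not robustness to every artifact of
real acquisitions.

## Problem sizes and numerical choices

Validation runs use reduced stacks (256 × 256 × 21 voxels per cell;
512 × 512 × 11 origami fields; 200 beads per standard; 20 seeds for
the two-condition recovery study; 500 null simulations for test
calibration) — large enough for the statistical claims while keeping
a full suite run in minutes. Ties anywhere in detection resolve
lexicographically on (z, y, x); voxel indices are 0-based and refer to
voxel centers; polygon masking uses the even-odd rule with boundary
points inside. Profile fits bound `d ≥ 0.5` px to keep single-pixel
artifacts from collapsing the width. All generators take explicit
seeds and are bit-reproducible.

## Known limitations

- Axial size is never measured; `fwhm_z` is a lateral average, so the
  ellipsoid volume inherits lateral information only.
- Brightest-plane readout attenuates spots centered between planes
  (~6% mean, see above); absolute photon integrals need either the
  background-corrected 3D-aware variant of a future release or
  identically processed calibration standards.
- The extra-sum-of-squares F test on histograms is approximate for
  count data even with sparse-bin exclusion; it is a descriptive
  comparison, not a replacement for the nested test.
- The saddle-merge criterion compares against the lower peak only;
  heavily overlapping spots of very unequal brightness may still merge.
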