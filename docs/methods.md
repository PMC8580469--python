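# Methods

## The measure

For a strictly positive intensity function μ defined on a pixel grid and a
geometric transformation T, the package computes

    TI(μ, T) = (1/|D̃|) ∫_D̃ μ(x) · ln[ μ(x) / Tμ(x) ] dA,

where Tμ(x) = μ(T⁻¹x) and D̃ is the overlap domain — the set of pixels at
which both the original and the transformed field are defined.  The
functional has the form of a Kullback–Leibler divergence between
unnormalized densities: it vanishes exactly when T is a symmetry of μ on
D̃, and its local minima over a parametrized transformation family
(rotation angle; reflection-axis angle and offset; translation vector;
rotation angle × rescale factor) are reported as the approximate
symmetries of the image, ranked by depth.

Key analytic properties, all enforced by tests:

* **Identity null.** TI = 0 at the identity, exactly.
* **Scale covariance.** TI(cμ, T) = c·TI(μ, T) for c > 0: the constant
  cancels inside the logarithm.  Consequently argmin locations are
  invariant under intensity rescaling; raw (unnormalized) intensities are
  used by default, with an optional mean-normalization flag for
  cross-image comparison of TI magnitudes.
* **Sign.** When T preserves total mass on D̃ (periodic translations,
  full-overlap rotations of equal-mass fields), TI ≥ 0 by the log-sum
  inequality.  Mass-changing transforms (rescaling, crop-type overlaps)
  can produce negative values; minima remain meaningful, zero does not
  mark exactness there.
* **Role exchange.** On a periodic domain, swapping μ and Tμ at shift s
  yields the value at −s, exactly.

### Discretization

The integral is a midpoint-rule pixel sum, so TI reduces to the mean of
μ·ln(μ/Tμ) over D̃ — the pixel area cancels between the sum and |D̃|.
Transformed fields are resampled by bilinear interpolation at the
pre-image of each pixel centre; a pixel belongs to D̃ only when all four
interpolation neighbours of its pre-image lie inside the source grid
(with a 10⁻⁹-pixel tolerance at the boundary for float round-off), so no
undefined data ever enters an interpolated value.  Undefined samples are
*excluded*, never zero-filled, since the logarithm would otherwise be
corrupted.  Integer-lattice transforms (axis-aligned reflections through
the grid centre, 90° rotations of square grids, integer periodic shifts)
are bit-exact.

Coordinates: pixel centres at integer positions, x rightward along
columns, y upward, angles in degrees counterclockwise, rotation/reflection
origin at the field's `centre` attribute (default: geometric centre).

### Positivity

Pixel intensities are clamped from below at a floor ε (default 1 on the
0–255 scale) before any TI evaluation.  The relative-greenness channel
2g − r − b + 1, used to separate green specimens from grey backgrounds,
ranges over −509…511 and relies on this clamp for its negative half.  The
floor bounds the per-pixel log-ratio at ln(max/ε); a constant field — the
degenerate clamp output — has TI ≡ 0 for every transform.

## Symmetry detection

1-D TI curves are searched for interior local minima filtered by
topographic prominence (scipy's definition), with angular grids covering
a full turn treated periodically (0° ≡ 360°).  2-D surfaces (angle ×
scale) use 0-dimensional persistence: basins are merged in ascending
order of TI and each minimum's prominence is the merge level minus its
depth.  This was chosen over a fixed-neighbourhood relief because
truncated self-similar patterns produce shallow-gradient surfaces whose
minima are prominent globally but not within a 3×3 ring.  The default
threshold is 2% of the curve's TI range; the identity parameters are
excluded.  No sub-grid refinement is applied — the grid spacing is the
precision contract, which keeps detection deterministic.

Centre estimation offers three procedures:

* **Rotational (‖dTI/dθ‖).**  For each candidate centre in a search
  window, TI is computed at n evenly spaced rotations (default 12) on a
  block-downsampled image (default 16×), and the criterion is the
  Euclidean norm of consecutive differences around the angle ring,
  including the wrap-around difference.  A well-centred rotationally
  structured object maximizes the swing of TI with angle.  Block-mean
  downsampling (not decimation) is used so total intensity mass — which
  the measure weights by — is preserved.
* **Reflection.**  The x coordinate minimizes TI for reflections about
  vertical axes and y for horizontal axes, scanned independently;
  secondary local minima are reported because axially asymmetric objects
  (e.g. an organism with unequal halves along its axis) pull the
  along-axis coordinate away from the morphological centre.
* **Area balance.**  Split lines equalizing foreground mask area
  left/right and above/below, brute-forced over integer positions.

## Baselines

**SI** partitions the object mask into n equal-width bands along the
reflection axis (default n = 20, the band count being unspecified in the
source measure) and averages |Aᵢ−Bᵢ|/(Aᵢ+Bᵢ) over non-empty bands; it is
0 for mirror-symmetric masks, 1 for fully one-sided ones, and invariant
under rigid motions applied jointly to mask and axis.  **ZI** rotates
landmark points about a centre and sums squared distances to
nearest original landmarks (first-index tie-break, not optimal
assignment); for a regular n-gon it vanishes exactly at multiples of
360/n.

## The reaction–diffusion generator

The two-species model

    ∂u/∂t = D δ ∇²u + c δ ∂u/∂y + α u (1 − r₁v²) + v (1 − r₂u)
    ∂v/∂t =   δ ∇²v + β v (1 + (α r₁/β) u v) + u (γ + r₂v)

is integrated on a periodic square (default L = 10, N = 128) with a
fourth-order exponential time-differencing Runge–Kutta scheme in Fourier
space.  The per-mode linear operator contains diffusion and advection
only (a scalar per species per mode — the advection contributes an
imaginary part icδk_y to the u operator); all reaction terms, including
their linear parts, are handled in the nonlinear stage.  φ-function
coefficients are evaluated by averaging over 32 points on a unit contour
around each hL value, the standard remedy for cancellation at small
arguments.  Cubic products are dealiased by two-thirds truncation.

Defaults: dt = 0.05, initial condition u, v ~ independent uniform noise
in [−0.05, 0.05] from a seeded generator.  These resolve the unstable
band (up to k ≈ 14 at the stripe parameters, i.e. ≥ 9 grid points per
shortest unstable wavelength) and give a measured dt-halving change of
~10⁻¹⁰ RMS at t = 10 — comfortably fourth-order.  Non-finite states
raise a blow-up error naming the failing step and suggesting a smaller
dt.

The stripe parameter set δ = 5×10⁻³, D = 0.5, α = 1, β = −1, γ = −1,
r₁ = 1, r₂ = 0 makes the quadratic terms vanish, so stripes are
preferred to spots; at c = 0 the t = 100 state is an isotropic
labyrinth.  The linearization about the zero state has per-mode Jacobian
[[α − Dδk², 1], [γ, β − δk²]]; at these parameters both trace and
determinant vanish at k = 0 and the brute-force scan of the leading
eigenvalue's real part places the fastest-growing mode at k = 6.97
(2π convention, wavelength 2π/k = 0.90).  `fastest_mode` refines the
scan by bounded scalar minimization and reports both k and 2π/k.

### Pattern diagnostics

* **Translation TI map.** On the periodic domain, D̃ is the full grid
  for every shift and TI(s) = mean(μ ln μ) − mean(μ(x) ln μ(x−s)); the
  cross term is a circular cross-correlation evaluated by FFT.  The
  per-shift rolled sum is the reference semantics and the FFT path is
  verified against it to 10⁻⁹ relative.  Simulated patterns are mapped
  affinely onto [1, 2] before TI (the offset makes the logarithm well
  defined; the scale is immaterial by covariance).
* **Annulus radius.** The TI map is averaged over one-pixel-wide bins of
  shift magnitude and the bin-centre radius of the profile maximum is
  reported.  For the c = 0 stripe pattern this sits at ≈ 0.66 domain
  units, about half the pattern wavelength.  For a *single* plane wave
  the radially averaged profile peaks beyond the half-wavelength because
  off-axis shift directions reduce the effective phase; the antiphase
  property is therefore tested on the axis cut of the map, where it is
  exact.
* **Anisotropy ratio.** Mean TI over pure-y shifts divided by mean TI
  over pure-x shifts at matched magnitudes (axis cuts of the map).  An
  earlier design using ±15° sectors was discarded: for periodic
  patterns, sector averaging mixes wavelength-recurrent radii and the
  ratio collapses toward 1 even for perfectly aligned stripes.  Axis
  cuts give 1 for isotropic maps, +inf for a plane wave, and increase
  strictly with the advection rate across c = 0, 3, 6.
* **Radial spectrum.** Magnitude of the 2-D FFT of u+v minus its mean,
  averaged over wavenumber-magnitude bins of width 2π/L; the peak bin
  (zero mode excluded) characterizes the pattern scale, ≈ 5–6 at the
  stripe parameters (broad, seed-dependent), inside the linear band and
  below the fastest-growing mode, as expected from nonlinear coarsening.

## Synthetic specimens

The fixture generator renders Gaussian-edged shapes — hard binary edges
would make interpolation error dominate TI near exact symmetries and
obscure the quantity under test.  Ground truth is exact by construction
up to pixel sampling: n-fold rosettes (with an optional identical
one-sided lobe per petal that preserves rotations while destroying
reflections), bilateral leaf-like blobs mirror-symmetric about a single
axis, pentagon landmark bumps, decussate whorls whose successive levels
are rotated by a fixed angle and shrunk by a fixed factor (so the
rotation–rescale scan has minima at (θ, S) and (2θ, S²); the whorl's
opposite pairs additionally make θ and θ+180° equivalent), and plane
waves with an integer period count.  Noise is uniform, seeded, and
expressed as a fraction of the dynamic range.

What the fixtures do *not* emulate: perspective and curvature of real
photographs, non-planar specimens, illumination gradients, cluttered
backgrounds, and curved symmetry axes.  Passing the fixture-recovery
tests demonstrates the correctness of the measure and search machinery,
not robustness to photographic nuisance factors.

## Problem sizes and determinism

Tests and the acceptance script use 128² fixture images, 128² simulation
grids to t = 100 (three seeds for stochastic summaries, medians
reported), 1° rotation grids, 0.5° reflection grids, and 5° × 0.04
rotation–rescale grids.  Every stochastic component takes an explicit
seed; simulations and fixtures are bit-reproducible given one.

## Known limitations

* Bilinear resampling smooths high-frequency content; minima positions
  on rough images can shift by a fraction of the grid spacing relative
  to other interpolation schemes.
* The overlap rule is not tracked through *compositions* of transforms:
  each application treats its input as fully defined, so composed
  round-trips are only exact away from the overlap boundary.
* The Simple Indicator depends on the band count n for non-trivial
  shapes; comparisons should fix n.
* Centre search cost grows with window area × angle count; the default
  16× downsampling matches a 12-angle scan and recovers centres to one
  downsampled pixel on the fixtures.
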