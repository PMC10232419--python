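# Methods

## The correction model

X-ray scatter adds a smooth, nonnegative haze `S` to the primary
(Beer–Lambert) signal `P` of a planar radiograph, `I_ff = P + S`, which
compresses contrast, most visibly over the spine and mediastinum.
`bsscatter` estimates `S` from direct measurements: a second exposure is
taken with a perforated high-attenuation plate (the *beam stopper*) between
the source and the patient.  In the shadow of the plate no primary reaches
the detector, so shadow pixels record scatter only.  Because the plate also
blocks most of the primary fluence that *generates* scatter inside the
patient, the shadow carries a *reduced* scatter field `S'` rather than `S`
itself; recovering `S` from `S'` is the point of the five-step pipeline:

1. circle-mean samples of the deep shadow of the obstructed projection
   `I_BS` are interpolated by 2D LOESS into the reduced scatter map `Ŝ'`;
2. `Î_BS^Primary = I_BS − Ŝ'` estimates the primary at the hole sites
   (holes transmit the unobstructed beam, so they contain `P + S'`);
3. subtracting that primary estimate from the full-field image at the same
   sites yields samples of the *full* scatter, `Ŝ = I_ff − Î_BS^Primary`;
4. a second LOESS fit interpolates these hole-site samples over the whole
   grid and the result is upsampled to detector resolution → `I_s`;
5. `I_C = I_ff − I_s` (negative `I_s` pixels are clamped to zero first —
   scatter is physically nonnegative; the pre-clamp decomposition
   `I_C + I_s = I_ff` is exact and is what the conservation tests check).

Both projections are block-mean downsampled (default ×8 at the native
0.1 mm pitch) before fitting; scatter is low-frequency, so this changes the
estimate by less than the fit noise while cutting the 2D fit cost by ~64×.

Key assumptions: the two exposures are co-registered and exposure-matched
(an `exposure_ratio` rescale is available when they are not); the plate is
effectively opaque (3 mm of tungsten transmits a negligible fraction of a
100 kVp beam); and scatter varies slowly compared with the hole pitch, so
samples on the hole lattice suffice to reconstruct it.

## Hole and shadow sampling

The downsampled `I_BS` is binarized with Otsu's 256-bin threshold.  The
centroids of the resulting components *register* the projected square hole
lattice: its pitch and hole radius follow from the acquisition geometry
(magnification `SDD / source-to-plate distance`), and its unknown
translation is the circular mean of the centroid coordinates modulo the
pitch.  Sampling circles are then placed on every lattice node rather than
on the raw centroids, for two reasons observed on synthetic data: a single
global threshold misses holes over the mediastinum (their intensity is far
below that of holes over the lungs or outside the patient), and centroids
of components cut by the patient boundary are displaced by 1–2 px, which
leaks shadow pixels into hole means.  Registration-from-centroids keeps
the method independent of any assumed plate alignment.

Shadow circles sit at the diagonal midpoints of the lattice — the points
farthest from any hole — and are kept only if they clear every hole by the
hole radius plus the sampling radius.  All circles use radius
`radius_fraction` (default 0.6) times the projected hole radius, staying
clear of the penumbra (geometric edge blur
`focal_spot · (SDD − d_plate)/d_plate`).  Circle means of a curved field
differ from its centre value by `(r²/8)·∇²S`; with default settings this
bias is below 10⁻⁴ of the scatter magnitude and is the accuracy floor of
the pipeline on noiseless data (exact quadratic recovery holds for
harmonic fields, where the bias vanishes by symmetry).

## 2D LOESS

Each query point takes its `k = ⌈span·n⌉` nearest samples (Euclidean
distance, k-d tree), weights them with the tricube kernel of distance
scaled to the k-th neighbour distance, and solves a degree-2 bivariate
weighted least-squares fit; the value at the query is the intercept of the
fit in query-centred, span-scaled coordinates (this centring keeps the
6×6 normal equations well conditioned, which is why the batched solve
agrees with a naive per-point `lstsq` reference to 10⁻¹⁰).  The default
span of 1% of the samples is the smallest window that suppresses sampling
noise without flattening real scatter structure.  Samples tied with the
k-th distance would receive zero weight, so a fixed-k window is equivalent
to including ties.  Rank-deficient local systems (condition number above
10¹⁰, e.g. collinear neighbourhoods) fall back to degree 1, then to the
weighted mean; the k-th neighbour's zero weight means a 6-sample window
has only 5 effective points for the 6-term quadratic basis, so very small
spans silently degrade to local planes.  Queries outside the sample hull
(image borders) are extrapolated by their nearest local fit, because the
scatter map must cover the full field of view.

## Synthetic acquisitions

The simulator replaces Monte Carlo transport with the minimal model that
preserves what the correction relies on.  Primary: exact analytic
ray-tracing through a priority-resolved ellipsoid phantom,
`P = I₀·exp(−Σ μᵢLᵢ)` with chord lengths from the ray–ellipsoid quadratic;
overlaps are resolved per elementary ray segment by the highest-priority
ellipsoid.  Scatter: the fluence attenuated along each pixel's ray,
weighted by the attenuation-weighted mean *scatter yield* of the materials
traversed, is convolved with a normalized Gaussian
(`σ = 60 mm`, amplitude 0.5).  This source term is linear in the incident
fluence, so masking the beam with the plate scales the scatter field's
integral by the plate's open-area fraction — the reduced-scatter premise —
and the simulated ratio indeed matches π/16 to ~0.1%.

Defaults mirror a chest acquisition: SDD 1800 mm, sample 50 mm from the
detector, 4288×3520 detector at 0.1 mm, 1.2 mm focal spot, plate next to
the sample (5.132 mm holes, 10.264 mm pitch, 3 mm tungsten).  Material
parameters are single effective values at ~60 keV (soft tissue
0.022 mm⁻¹, bone 0.060 mm⁻¹, air 2.5·10⁻⁵ mm⁻¹, tungsten 7.2 mm⁻¹;
densities 1.060, 1.920, 1.205·10⁻³, 19.299 g/cm³), with scatter yields
1.0 / 0.65 / 0.02 — bone both attenuates more and scatters differently
from soft tissue, which is the tissue-dependence that defeats single
global correction factors.  The default phantom is a soft-tissue torso
with two air lungs, a bone spine and a soft-tissue heart, providing the
lung/heart/spine/liver regions the metrics interrogate.

What the simulator does **not** emulate: polychromatic spectra and beam
hardening, detector response, coherent-vs-incoherent scatter angular
structure, patient motion between exposures, and real anatomical texture.
Passing tests therefore demonstrate the pipeline's correctness under its
stated assumptions (low-frequency scatter, opaque plate, co-registered
exposures), not clinical performance.

### Problem sizes

Tests and the acceptance script run the simulation on a 536×440 grid at
0.8 mm — exactly the native detector divided by 8, i.e. the working
resolution the pipeline reaches after its ×8 downsampling — with
correction `downsample_factor=1`.  On this grid the projected holes are
6.6 px across on a 13.3 px pitch and yield ~1300 hole plus ~1250 shadow
samples, so the 1% LOESS span gives the same ~13-sample local windows as
the full-scale setting.  A full run (simulation + correction) takes a few
seconds on one CPU.

## Dehazing baseline

The comparison method treats scatter as haze:
`I_corr = (I − A)/max(t, ε)^δ + A`, with `A` the scatter floor of a region
(its minimum intensity), `t ∈ (0,1]` a transmission map and `δ` a
per-region exponent; the shipped parameter table carries the published
per-dataset values (ε = 10⁻⁸, δ = 0.3/0.15/0.4 for global/lung/spine,
C0 = 1, C1 = 4.8, λ = 1).  The original method obtains `t` by an ADMM
contrast maximisation; this package substitutes a documented surrogate — a
Gaussian-smoothed, range-normalised intensity mapped affinely into
`(C0/C1, 1]` — which preserves smoothness, monotonicity in intensity and
scale invariance.  The correction formula itself is applied exactly and is
analytically invertible given `(t, A, δ)`, which the tests exploit.

## Evaluation metrics

Images are first normalised to a common dynamic range by a robust min/max:
subtract the mean of pixels below the 2nd percentile, divide by the spread
to the mean of pixels above the 98th.  When more than 2% of pixels tie at
an extreme (the flat background of noiseless simulations) the strict tails
are empty and the inclusive tails are used.  Metrics: ROI RMSE between
corrected image and ground truth (lung, spine, global), SNR as mean over
population standard deviation in a homogeneous liver ROI, contrast
recovery as the lung–heart ROI-mean difference relative to ground truth,
and averaged line profiles.  Default ROI placements scale with the image
and follow the default phantom layout; they are parameters, not anatomy
detection.

## Dose accounting

The extra patient dose of the obstructed exposure equals the plate's
open-area fraction `(π/4)(d/p)²` — 19.6% (≈20%) for the 5.132/10.264 mm
plate, so the two-exposure protocol costs ~1.196 exposures.  A
cylinder-mesh blocker of 3 mm cylinders on an 11 mm pitch blocks only
5.8%, so its second exposure is nearly a full dose (~1.942 exposures in
total): the perforated-plate design halves the total dose relative to
that scheme while still sampling scatter across the whole field.

## Numerical choices and degenerate inputs

Block-mean downsampling averages whatever pixels a trailing partial block
contains; upsampling is bicubic with edge clamping (constants exact).
Otsu thresholding requires a non-constant image; sampling requires at
least 6 circles of each kind (LOESS feasibility) and drops border-touching
components.  The projected pitch must exceed 2 px on the working grid.
Poisson noise uses `Poisson(N·I)/N` with a seeded generator; `N = 0` is
the noiseless identity.  Scatter-map negatives are clamped before the
subtraction; the unclamped intermediates are retained so the exact
decomposition can always be audited.

## Known limitations

Square hole lattices only (no hexagonal layouts or tilted plates); no
registration or motion compensation between the two exposures; the
transmission surrogate is not the ADMM optimiser and the baseline's
published per-dataset `A` values are most meaningful on data resembling
their original dynamic range; the scatter surrogate's amplitude/width are
effective parameters, not dosimetric quantities.
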