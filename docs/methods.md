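# Methods

This note records the models implemented by `neotract`, the conventions and
numerical choices behind them, what the synthetic phantoms do and do not
emulate, and the design decisions that were genuinely open.

## Tensor model and scalar maps

Each voxel's diffusion is modeled as a symmetric 3×3 tensor **D** (mm²/s)
with the single-shell signal model *S*(**g**, *b*) =
*S*₀ exp(−*b* **g**ᵀ**D****g**). The fit is **ordinary least squares on the
log signal**: with at least one *b* = 0 volume and ≥ 6 linearly independent
gradient outer products, the design matrix has columns
[1, −*b*gₓ², −2*b*gₓg_y, −2*b*gₓg_z, −*b*g_y², −2*b*g_yg_z, −*b*g_z²] and
the solved coefficients are ln *S*₀ followed by the six stored elements in
the fixed order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz). A weighted or positive-
definite-constrained fit is deliberately out of scope: the log-linear LSQ
estimator is the simplest member of the family, is exact at zero noise, and
keeps the round-trip identity with the phantom synthesizer testable to
1e-8 relative error.

Choices around degenerate inputs:

* Non-positive signals (possible under Rician noise at very low SNR) are
  clamped to a floor — by default 10⁻³ × the smallest positive signal in
  the volume — before the log; the count of clamped samples is logged.
* Negative eigenvalues from noisy fits are retained in the maps, but voxels
  with λ₁ ≤ 0 are excluded from seeding and propagation. This matches how
  FA-threshold gating behaves anyway and avoids silently editing tensors.
* FA of the zero tensor is defined as 0 (the formula is 0/0 there).
* Eigenvalues are sorted descending; eigenvector signs are canonicalized so
  each vector's largest-magnitude component is positive. Exact eigenvalue
  ties (within 1e-12) are broken by lexicographic ordering of the
  eigenvectors, so degenerate voxels decompose deterministically.

The scalar maps are the standard rotation invariants: MD = (λ₁+λ₂+λ₃)/3,
AD = λ₁, RD = (λ₂+λ₃)/2, FA = √(3/2)·‖λ−λ̄‖/‖λ‖ ∈ [0, 1]. The identity
MD = (AD + 2·RD)/3 is algebraic and asserted voxelwise in tests.

## FACT tracking

Propagation is the classic nearest-neighbor FACT scheme: inside a voxel the
direction is that voxel's **e**₁ (constant, no interpolation); the path
advances exactly to the voxel's exit face, enters the neighbor, re-orients
to the neighbor's **e**₁ sign-aligned with the incoming direction, and
repeats. Stopping rules: the next voxel's FA is below `fa_stop`; the
unsigned angle between consecutive propagation directions exceeds
`max_angle`; or the path leaves the grid. Seeding is brute force — every
voxel with FA ≥ `fa_start` — and each seed is propagated in both ±**e**₁
directions from the voxel center, the backward branch reversed, its
duplicate seed point dropped, and the forward branch appended.

`fa_start` and `fa_stop` are independent (several shipped tract protocols
use a start threshold above the stop threshold, one uses 0.05/0.03), both
in [0, 1]; `max_angle` is strictly between 0° and 90°; streamlines shorter
than `min_points` (default 2) are discarded.

Geometry and tie-breaking conventions, all chosen for determinism:

* Tracking runs in continuous grid space where voxel *i* spans the
  half-open interval [*i*, *i*+1) with center *i*+0.5. NIfTI affines map
  integer indices to voxel-center world coordinates, so world = A·(x−0.5).
* When a ray exits exactly through an edge or corner, the face of the
  dominant direction component wins, ties broken in x→y→z order.
* A point lying exactly on a face may produce one zero-length step into the
  neighbor (whose orientation then takes over). Two zero-length steps in a
  row means the path is bouncing between two voxels whose eigenvectors
  disagree without making spatial progress; the branch terminates there.
  This situation arises in noisy near-isotropic regions and would otherwise
  cycle forever.
* No randomness exists anywhere in tracking: identical inputs yield
  bitwise-identical tractograms.

## ROI calculus and the tract registry

Tract segmentation filters the whole-volume tractogram with 2-D regions on
single slices (axial = grid axis 2, coronal = axis 1, sagittal = axis 0,
with volumes reoriented to a canonical RAS-like layout on load). A region
is a polygon (even-odd rule), oval (ellipse inequality), or rectangle
(half-extent inequality) over in-plane voxel centers in mm; boundary points
count as inside. Streamline–ROI hit testing is evaluated against the
streamline's **voxelization** (the same exact segment-marching used for
voxel counts), not against point-in-shape tests on the polyline, so
hit-testing and the macrostructural metrics are resolution-consistent by
construction.

The operations keep full streamline extents: OR selects streamlines
passing through a region (several leading OR regions are a union — the
middle-cerebellar-peduncle protocol seeds from a bilateral pair); AND
keeps survivors that also pass through a region without truncating them (a
"cut between regions" operation is deliberately absent); NOT removes
survivors passing through an exclusion region, applied last in listed
order. Protocol validation enforces the OR…, AND…, NOT… ordering. For the
three-region protocols (fornix, optic radiations) the AND regions filter
strictly sequentially; a streamline must hit every AND region to survive,
which is our stated convention.

The registry ships the ten neonatal tract parameter triples
(fa_start/fa_stop/max_angle): CC 0.10/0.10/70°, CST 0.05/0.03/41°,
ILF 0.11/0.05/41°, IFO 0.11/0.05/41°, UNC 0.12/0.12/60°, CG 0.05/0.05/70°,
FX 0.12/0.12/60°, OR 0.10/0.10/70°, MCP 0.13/0.05/41°, SCP 0.14/0.05/41° —
both as code and as a YAML data file, with each region's anatomical
placement guidance attached as documentation. ROI **geometry** is not
automated: on real neonatal data the regions are drawn per subject by a
trained rater against color-coded, FA, and trace maps, and landmark
detection is explicitly out of scope. Protocol files therefore carry the
subject-specific geometry.

## Tract metrics

A segmentation is summarized by fiber count (surviving streamlines), voxel
count (the union of voxels traversed by any segment, computed by exact
segment/boundary marching — each segment's parameter interval is split at
every integer-plane crossing and each sub-interval's midpoint assigned to
its voxel), and mean FA/MD/AD/RD over that voxel set. Means are
**voxel-weighted** (each voxel once) rather than point-weighted: voxel
counts are themselves the macrostructural measure, and voxel-weighted
statistics are the convention in DTI-Studio-style tract analysis.
Point-weighted means would over-count voxels crossed by many streamlines;
the voxel-weighted default makes `mean_*` and `n_voxels` refer to the same
support. Empty segmentations yield zero counts and NaN means (flagged, not
an error).

## Reliability battery

For two repeats per subject, the within-subject SD is
s_w = √((1/n) Σ dᵢ²/2) with dᵢ the paired difference — the square root of
the mean within-subject variance. The repeatability coefficient is
**2.77 × s_w**, the 95% bound for the absolute difference between two
repeated measurements under normal error; the constant is kept at the
conventional printed value 2.77 rather than the unrounded √2 × 1.96 =
2.7719…, which reproduces tabulated repeatability values computed at that
display precision. A Monte-Carlo helper verifies the coverage claim
directly: simulated pairs with difference SD s_w√2 fall below 2.77·s_w
about 95% of the time (the exact normal value is 2Φ(1.9587)−1 ≈ 94.99%).

ICC is the **one-way random-effects, single-measurement ICC(1)** from the
balanced ANOVA mean squares, (MSB − MSW)/(MSB + (k−1)·MSW), with the exact
F-based 95% interval obtained by inverting MSB/MSW ~ F(n−1, n(k−1)).
Two-way (rater-crossed) variants are out of scope; ICC(1) treats
rater/occasion as undifferentiated error, which is the appropriate model
when the repeats are exchangeable. The estimate and interval are
cross-checked in the tests against an independent implementation
(pingouin's ICC(1,1)). A constant measurement table raises (ICC undefined
at zero total variance); the constancy check uses a scaled tolerance
because exact-zero between-subject sums of squares are destroyed by
floating-point roundoff.

Dice similarity 2|A∩B|/(|A|+|B|) operates on voxelized tract sets, matching
its use as a spatial-overlap measure between two segmentations of the same
subject. Report tables round SD/repeatability of count-scale metrics to
one decimal and ICC/Dice to three, a fixed display schema so outputs are
diffable.

## Phantoms: what they emulate and what they do not

The phantom module exists so that every stage has ground truth. A bundle is
a tube of radius *r* around a straight, arc, or polyline centerline; voxels
whose centers fall within the radius get a cylindrically symmetric tensor
λ⊥I + (λ∥−λ⊥)**t****t**ᵀ oriented along the local tangent (defaults
λ = (1.7, 0.4, 0.4)×10⁻³ mm²/s, FA ≈ 0.726); everything else gets an
isotropic background (default 1.2×10⁻³ mm²/s, FA = 0). The default grid
spacing 1.6×1.6×2.0 mm mirrors a typical neonatal acquisition, as does the
default gradient scheme: one *b* = 0 volume plus 15 directions at
*b* = 800 s/mm², constructed as a deterministic golden-angle spiral on the
upper hemisphere so the scheme is reproducible without a seed (design
matrix condition number ≈ 10, verified in tests). Noise is Rician — the
magnitude-MR convention, √((S+n₁)² + n₂²) with independent Gaussian
channels — with Gaussian available implicitly at high SNR. All generators
are pure functions of (spec, seed).

What passing on phantoms does **not** show: phantoms have piecewise-smooth
single-orientation geometry, no crossing-fiber partial-volume structure
beyond simple overlap (where bundles overlap, the later-listed bundle's
tensor wins and both masks record the voxel), no susceptibility/motion
artifacts, no spatially varying SNR, and no anatomy. Results on real
neonatal data additionally depend on acquisition quality, preprocessing
(eddy-current and motion correction are assumed done upstream), and rater
ROI placement — which is exactly why the reliability battery exists.

The demo/acceptance pipeline uses a ~18×11×11 phantom with noise sigma 50
at S₀ = 1000 (SNR ≈ 20, a realistic neonatal figure); at that level the
background acquires spurious supra-threshold FA and brute-force seeding
floods the volume, which is the regime the multi-ROI calculus is designed
to clean up. Problem sizes in the tests (grids ≤ 20³, ICC simulations
n = 200–500 subjects, coverage simulations 100,000 pairs) were chosen as
the smallest sizes at which each statistical claim is decidable at its
stated tolerance.

## Known limitations

* Single-tensor model only; no multi-shell or crossing-fiber models, and
  no probabilistic tractography.
* Nearest-neighbor FACT cannot make diagonal voxel jumps: a sharp bend in
  a one-voxel-thick bundle terminates on the FA rule before the angle rule
  can act (visible in the phantom tests, which use bundles wide enough for
  the turn to happen in-bundle).
* A turning-angle limit of ≥ 90° is not representable (`max_angle` is
  strictly below 90°), so "continue through a right-angle bend" is outside
  the supported parameter space.
* ROI geometry is trusted input; nothing checks it against anatomy.
* The ICC confidence interval assumes the balanced one-way normal model;
  published intervals computed by other software/variants will not
  reproduce exactly.
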