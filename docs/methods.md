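# Methods

This note documents the models implemented in `memdomain`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Diffusion-law stage (svzFCS)

**ACF model.** Fluorescence autocorrelation curves are modelled as free 2D
lateral diffusion of one or two populations through a Gaussian focal spot,

    G(τ) = (1/N) Σ_k f_k (1 + τ/τ_dk)^-1  (+ baseline offset, generator only),

with `N` the mean occupancy of the spot, `τ_dk` the diffusion time of
population k (ms) and `f_k` its amplitude fraction.  No triplet-state term
is included: the synthetic curves contain none, and membrane measurements
at the relevant timescales (τ_d of 0.5–100 ms) are dominated by diffusion.
Fits are unweighted nonlinear least squares (no per-lag variance is
available from pre-averaged curves) with deterministic initialization:
`N` from 1/G at the first lag, `τ_d` from the lag where G halves; the
two-population start splits that `τ_d` by ×/÷10.  Bounded deterministic
restarts guard against rare non-convergence.

**Population-model selection.** Whether a curve holds one or two
populations is decided by an extra-sum-of-squares F-test at α = 0.05,
accepted as two populations only when the fitted diffusion-time ratio is
≥ 5 and the minor fraction is ≥ 0.1.  The two guards encode the physical
observation that populations with similar diffusion times are
indistinguishable on an autocorrelation curve and merge into one apparent
component; without them the F-test alone upgrades noise. Measured on
synthetic curves (2% multiplicative noise), the selector finds a
0.61 ms / 94 ms pair in ~100% of replicates and correctly merges a
ratio-1.2 pair in ~100%.

**z-scan.** The diffusion time is minimal when the focal plane coincides
with the membrane.  `τ_d(z)` is fitted with an unconstrained quadratic;
series with non-positive curvature (no interior minimum: the scan missed
the membrane) are rejected.  The fit's vertex value is the per-vesicle
`τ_d`, weighted downstream by the number of z points used.

**Diffusion law.** Per-waist weighted means of `τ_d` (frequency weights)
are regressed on ω² with weights 1/sd² (unweighted fallback when any
sd = 0).  `D_eff = 1/(4·slope)` with the ms↔s conversion; the slope's
standard error propagates to `D_eff` by the delta method.  Confinement is
classified from the intercept: free if |t₀| is within the critical value
times its standard error, domain-confined if significantly positive,
meshwork if significantly negative.  The critical value uses the
**Student-t quantile at the fit's residual degrees of freedom** (3–4 for
5–6 waists): with so few points the normal quantile is anti-conservative
(measured type-I error ~14% instead of 5%).

**Generator.** Synthetic grids evaluate
`τ_d(z) = [ω(z)²/(4 D_eff) + t₀]·(1+ε)`, `ε ~ N(0, noise_cv)`, with the
Gaussian-beam waist profile `ω(z)² = ω₀²(1 + (λz/(πnω₀²))²)` at λ = 488 nm
(the excitation wavelength; exposed as a parameter) and n = 1.333.  The
analysis only assumes "quadratic in z", so this choice is not load-bearing.
Noise is multiplicative Gaussian on `τ_d` and on G — adequate because the
analysis consumes curves, not photon streams; photon-level effects
(afterpulsing, detector noise) are out of scope.  Default study conditions
follow the experimental design: 5 waists of 0.20–0.40 µm, 5 z-offsets per
vesicle including the focus, 5 vesicles per waist, 5% noise.

Recovery under those conditions (100 replicates per system): median
`D_eff` within 5% of truth, median t₀ within 0.2 ms, and ≥ 90% correct
confinement calls for free (t₀ = 0), domain-confined (t₀ = 1.14 ms) and
meshwork (t₀ = −0.92 ms) ground truths.

## Vesicle Monte Carlo

**Model.** The membrane is a closed triangulated network of N vertices
(default 1447) joined by tethers of length `l ∈ [l_min, l_max]`,
`l_max/l_min = 1.7`; self-avoidance imposes a hard-core distance `l_min`
between all non-bonded vertices (enforced with a linked-cell list; an
explicit triangle-intersection mode exists for validation).  Units are
`l_min = 1`, `k_BT = 1`.  One Monte Carlo sweep is N vertex-move attempts
(uniform displacement in a ball of radius `s = 0.15 l_min`) followed by
`R_B·N = 3N` bond-flip attempts (the shared edge of two adjacent triangles
is rewired across the other diagonal), each accepted with probability
`min[1, exp(−ΔE/k_BT)]`.  Flips are the sole source of lateral fluidity;
vertex types never swap, so composition is conserved exactly.

**Energy.** Bending: Gompper–Kroll cotangent discretization of the
Helfrich energy, `E = Σ_i (κ_i/2) A_i |K_i|²`, with `K_i` the discrete
mean-curvature normal from the cotangent Laplace–Beltrami operator, `A_i`
the barycentric vertex area, zero spontaneous curvature, and per-vertex
rigidity κ_i (27.3 k_BT matrix; 32.6 or 96.3 k_BT domain).  On a
2562-vertex sphere the discrete energy is within 0.2% of the continuum
8πκ and is scale-invariant to machine precision.  Interaction: domain
vertices attract with `W = −w · #(domain–domain bonded pairs)`, each pair
counted once.  The contact set is mesh-bonded adjacency: the tether-length
bounds make bonded pairs the natural realization of "in-plane neighbours";
a Euclidean-cutoff mode (`r_ij < r₀`) is provided for sensitivity
analysis.  No volume or area constraints are imposed (the Hamiltonian is
bending + interaction only).

**Data structure.** Edges keep explicit opposite-vertex tables; a flip
rewires one edge in place and patches the four quad edges.  This keeps
face recovery unambiguous even when non-face 3-cliques arise.  Local
energies are cached per vertex; ΔE is computed from the closed
neighbourhood of the moved vertex (or the four quad vertices of a flip).
After 10⁴ sweeps at N = 1447 the incrementally tracked total energy agrees
with a full recomputation to better than 1e-9 k_BT.

**Initial mesh.** Vertices are placed on a Fibonacci (golden-angle)
lattice and triangulated by convex hull, which realizes sphere topology at
any N with a measured edge-length spread of ≈ 1.693.  The radius is chosen
so the edge-length band sits geometrically centred inside
`[l_min, l_max]` — centring the *mean* at `(l_min+l_max)/2` would push the
longest edges ≈ 6% past `l_max`.  `round(ρN)` vertices are labelled domain
type uniformly at random under the run seed.

**Equilibration and sampling.** Reference-scale defaults are 5·10⁴
thermalization sweeps and 200 samples every 500 sweeps.  The test suite
and acceptance script use scaled-down runs (N = 642–1447, 10³–10⁴ sweeps,
10–40 samples), sizes chosen so the full suite completes on one desktop
CPU; each test states its own conditions.

**Mixing baseline.** At w = 0 the Hamiltonian ignores labels, so the
domain–domain bond fraction must match the hypergeometric random-labelling
expectation `(n_d/N)((n_d−1)/(N−1))`.  A single run retains its one label
draw, whose assignment variance dominates, so the check averages over ≥ 5
independent label assignments and compares the grand mean within 3
standard errors.  With unequal rigidities (κ_domain ≠ κ_matrix) a small
but real curvature-mediated correlation appears even at w = 0; the
detailed-balance check therefore uses uniform κ.

## Domain quantification

**Mesh side.** Domains are connected components of domain-type vertices
under mesh bonds; per-domain area sums barycentric vertex areas; boundary
length sums the mixed-type frontier edges.

**Image side.** The vesicle sphere is located by Otsu thresholding →
intensity centroid → radial-profile peak → algebraic least-squares sphere
fit (with the profile peak as fallback when the fit disagrees wildly).
Near-uniform Fibonacci-lattice points on the fitted sphere are probed
along centre-to-point rays: trilinear samples in the radial window
R ± 3σ_shell are averaged per point and thresholded by Otsu over the
per-point means (skipped — all present — when the means are uniformly
high, i.e. an unbroken shell).  One majority-vote pass over the k = 6
neighbour graph removes salt-and-pepper misclassification at the
threshold boundary.  Rays leaving the stack are flagged invalid and
excluded.  Domains are connected components of signal-absent points; area
is the point-count fraction of 4πR².

**Shape descriptors.** Circularity `4πA/P²` and roundness
`4A/(π·major²)` are evaluated on a Lambert azimuthal equal-area projection
about the domain centroid (for band-like domains with a vanishing mean
direction, about the band axis — the smallest-variance eigenvector), so a
geodesic disk scores circularity 1 by construction and mesh- and
image-side descriptors are directly comparable.  The projected point set
becomes a polygon by morphological closing (radius 1.5× the lattice
spacing) followed by Douglas–Peucker simplification at 0.8× spacing;
closing bridges lattice gaps and keeps holes (annular stripes), while the
simplification removes lattice-scale boundary wobble that would otherwise
inflate the perimeter by ~15%.  Major/minor axes come from the polygon's
central second moments (the moment-equivalent ellipse), matching the Fiji
fit-ellipse convention.  Segmented geodesic caps score circularity ≥ 0.95
at ≥ 12000 points per sphere; equal-area stripes score far lower (~0.1),
reproducing the gel-vs-fluid morphology contrast.  Domains spanning more
than a hemisphere are flagged low-confidence (projection distortion);
domains of fewer than 3 points have undefined descriptors.

**Scale classes.** Nanodomain: maximal geodesic extent < 250 nm;
microdomain: ≥ 300 nm; intermediate in between.  The extent is R times the
largest pairwise angle between member directions (convex-hull reduced).

**Coverage histograms and w selection.** Per-domain relative coverage is
`100·area/total surface area`; histograms are normalized counts.
Correspondence between two histograms is the overlap coefficient
`Σ_bins min(p, q)` (Pearson correlation on counts is reported alongside);
`select_w` returns the grid w with maximal correspondence, ties toward
smaller w (the weaker-interaction assumption).

The self-consistency experiment (recovering the generating w = 1.2 from
the grid {1.2, 1.3, 1.4}) is run at ρ = 0.2 with the fluid-like domain
rigidity (32.6 k_BT), pooling 16 replicate runs per condition with common
random numbers across the grid and binning coverage at one-vertex
resolution.  These choices follow a sensitivity study: at the gel-like
rigidity (96.3 k_BT) the cluster statistics respond so weakly to
Δw = 0.1 at desk-scale run lengths that adjacent grid points are not
distinguishable — run-to-run label-assignment variance dominates.
Replicate pooling averages over label assignments; common random numbers
remove seed noise from grid comparisons; fine bins keep the signal (which
lives in the size-distribution tail) from being absorbed into a wide
first bin.  Even so, adjacent-w discrimination is the least powered check
in the package: in repeated trials of the full procedure at these sizes
the generating w is selected in roughly two thirds of attempts, with the
remainder selecting a neighbouring grid point.  Distinguishing
interaction strengths 0.1 k_BT apart from coverage histograms needs
substantially longer, larger ensembles than a desktop-scale run.

**GUV image generator.** Voxel intensities are a Gaussian shell of width
σ around the sphere (PSF proxy), zeroed inside planted domains (geodesic
caps, or bands bounded by two parallel small circles), scaled by an
expected photon count and Poisson-sampled.  Ground-truth areas are
analytic (cap `2πR²(1−cosθ)`, band `4πR²·sin(width/2)`).  Not emulated:
optical anisotropy (axial PSF elongation), agarose background, bleaching,
multi-vesicle scenes; passing tests therefore demonstrate correctness of
the geometry pipeline, not robustness to every imaging artifact.

## MSD utilities

Time- and ensemble-averaged MSD (exact cumulative form, verified against
the naive double loop); Einstein relation `MSD = 4Dτ` fitted over lags
10–50% of the trajectory (avoiding short-lag noise and long-lag
starvation), with a goodness-of-fit flag at R² < 0.99 — diffusive
ensemble-averaged MSDs exceed 0.999 already at 50 particles, while
ballistic input over a window touching τ = 0 stays near 0.94.
Temperature rescaling is the Stokes–Einstein proportionality
`D(T₂) = D(T₁)·T₂/T₁` at fixed friction.  Weighted mean/s.d. use the
frequency-weight convention; medians are reported with the median
absolute deviation.

## Pipeline

Runs are plain dictionaries (YAML-loadable): global seed, output
directory, per-stage blocks.  Each stage's sub-seed derives from the
global seed and the stage's position via `numpy.random.SeedSequence`, so
stages rerun independently and bitwise reproducibly.  The manifest records
config, seeds, stage outputs and SHA-256 hashes of written files; the
report generator is idempotent and tolerates missing stages.  The package
is library-first: the numbered scripts under `analysis/` are the
command-line surface, and `memdomain.pipeline.run_pipeline` is the
programmatic entry point.

## Known limitations

- The Monte Carlo model has no spontaneous curvature, volume/pressure
  constraints or hydrodynamics; κ values are inputs, not fitted.
- Self-avoidance is a hard-core minimum distance between non-bonded
  vertices, the standard realization at these parameter ratios; explicit
  triangle-intersection checking is available but slower.
- The ACF model omits triplet blinking and background; real curves with
  strong photophysics would need an extended model.
- Adjacent-w selection (Δw = 0.1) is at the edge of statistical power at
  desk-scale ensembles (see above).
- Image-side descriptors assume a single dominant spherical vesicle.
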