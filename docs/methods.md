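# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Curve representation

A backbone is an ordered polyline through its backbone atoms (N, CA, C per
residue; optionally CA only).  Chains are read with gemmi; alternate
locations keep blank or 'A' altLoc; residues missing a backbone atom
contribute their remaining atoms with a logged warning, since legacy PDB
files are ragged and a hard failure would reject usable structures.  NMR
files default to the first MODEL, with the index exposed.  Repeated
consecutive points are collapsed at read time (they would create
zero-velocity samples).

Curves are interpolated piecewise-linearly per coordinate.  For matching,
a curve is resampled to a common grid of m points (default m = 100),
rescaled to unit polyline length, converted to its square-root velocity
function (SRVF) q = β̇/√|β̇|, and projected onto the unit sphere of
L²([0,1], ℝ³).  Derivatives use second-order finite differences (central
interior, one-sided ends); all quadrature is the trapezoidal rule on the
uniform grid, one convention throughout so that norms, inner products and
the covariance are mutually consistent.  Zero-speed samples map to q = 0,
the SRVF limit.

By default the resampling is at *constant speed* (uniform arc length).
The registration optimizes over reparameterizations, so the initial
parameterization is mathematically arbitrary; constant speed is the
canonical neutral choice, and it matters in practice: it removes spurious
speed differences between inputs before the optimization starts, which
keeps the rotation/matching alternation out of poor local basins
(observed failures from 0.06 up to 0.6 radians on warped helices without
it).  Ensemble statistics are the one exception — see below.

Only the L² form of the elastic metric is implemented.  The underlying
family of bending/stretching metrics with free weights (a, b) is
background: under the SRVF representation the relevant member becomes the
flat L² metric, so the weights never need to be chosen and the general
form would add complexity without changing any computed quantity.

## Registration and the geodesic distance

The distance fixes q₁ and minimizes ‖q₁ − √γ̇·O q₂(γ)‖ jointly over
O ∈ SO(3) and monotone γ with γ(0)=0, γ(1)=1.

*Rotation.*  Closed form by SVD of the 3×3 cross-covariance
A = ∫ q₁q₂ᵀ dt with a determinant sign correction (no reflections).
Rank-deficient A (planar/collinear inputs) accepts the SVD's minimizer
and logs the degeneracy.

*Matching function.*  Dynamic programming over lattice paths from (0,0)
to (1,1) with steps (Δi, Δj), Δi, Δj ∈ {1…4}, gcd-filtered — local slopes
in [1/4, 4].  Segment costs integrate the local L² mismatch with γ linear
on the segment and trapezoidal weights, so the path cost telescopes to
the full integral.  Ties prefer the diagonal, making the identity the
unique result for identical inputs.  On grids ≤ 10 points the DP cost is
bit-identical to exhaustive enumeration over all monotone paths (tested).

The raw DP path has slopes quantized to small integer ratios.  Its
derivative therefore jumps, and the √γ̇ factor turns that into a spurious
distance floor of a few times 10⁻² even for identical shapes.  Two
post-processing steps remove it: a short moving-average smoothing of γ
(window 9 grid steps, boundary-reflected, monotonicity re-imposed, the
identity is a fixed point), and a projected-gradient *polish* that
minimizes the true registration cost over the γ node values (analytic
gradient, adaptive step, projection to the monotone set; ~100 iterations).
With both, a known smooth warp is undone to θ ≈ 5·10⁻³ instead of ≈ 4·10⁻².

*Alternation.*  Rotation and matching are alternated from γ = identity
until a sweep improves the cost by less than 10⁻⁵ or 20 sweeps.  Each
sweep re-warps the *original* q₂ with the accumulated (O, γ): re-warping
the already-warped SRVF compounds interpolation smoothing and lets the DP
erode the cost (and the distance, by ~10%) indefinitely — measured before
the design was changed.  The alternation is coordinate descent with local
minima, so it is run from two starts (rotation first, and DP before any
rotation) and the better result kept; a pre-rotation initialization is
useless here because the SVD step immediately replaces any initial
rotation.

*Distance.*  θ = arccos of the clipped inner product (clipping guards the
domain against round-off).  The true distance is symmetric but the
discrete optimizer is not exactly so; the public `geodesic_distance`
therefore runs the alignment in both directions and reports the smaller θ
(default `symmetric=True`) — a strictly better estimate of the common
optimum that is symmetric by construction.  Observed residual asymmetry
of the single-direction optimizer on diverse fixtures reaches ~0.1; the
symmetric estimate removes it.  Geodesic paths are great circles between
the registered preshapes; the antipodal case (θ = π) has no unique
direction and raises.

## Ensemble statistics

Sphere geometry is exact: log map v = (θ/sin θ)(q − cos θ·μ), exp map
cos‖v‖·μ + sin‖v‖·v/‖v‖, inverse to 10⁻⁸ for θ < π.

*Karcher mean.*  Initialized at the preshape-projected extrinsic average
of the shapes registered to the first one; each iteration re-registers
every shape to the current mean, averages the log maps, and steps along
the average with ε = 0.5.  If the objective Σθᵢ² increases the step is
reverted and ε halved (floor 10⁻³), so the recorded objective is
non-increasing by construction.  Convergence when ‖v̄‖ < 10⁻⁵ or after 50
iterations.

*Registration inside statistics.*  Ensemble members are encoded
**without** arc-length re-canonicalization (`arclength=False`) — members
of one ensemble share a single residue-level parameterization, and
re-canonicalizing each member separately would scramble their common
correspondence.  Registration to the mean uses the DP at lattice
resolution, single start, *without* the continuous γ polish: registration
to the mean is a near-identity nuisance problem, and a fully resolved
warp starts absorbing genuine transverse shape variation into the
registration, biasing the covariance downward (measured: top variance
halved and the top direction rotated to cosine ≈ 0.6 when polished
registration was used).

*Covariance.*  Tangent vectors are flattened with square-root trapezoid
weights so that the Euclidean SVD of the centered data matrix is exactly
the L² PCA; retained directions are L²-orthonormal, σ are tangent-space
variances, k = min(n−1, 3m) components with σ > 10⁻¹².  trace K equals
the mean squared centered tangent norm (tested).

*Gaussian model.*  Sampling draws z ~ N(0, I_k) and maps
v = Σ z_j √σ_j U_j through the exp map (σ are variances, consistent with
the t√σ sweep convention).  One seeded generator per call.  The density
is the k-dimensional tangent Gaussian evaluated on the retained
coordinates; the component orthogonal to the span is ignored and logged.
It is a density on tangent coordinates, not a normalized probability on
shape space, so only ratios and orderings between shapes under the same
model are meaningful.

*Per-residue variance.*  Samples are reconstructed as curves, superposed
on the mean curve rigidly (rotation from SRVF registration, common
centroid), and the mean squared deviation per grid sample is averaged
within each residue's parameter bin (each residue owns its contiguous
block of samples).

## Synthetic data

The fixture generator emulates backbone-like geometry: ideal α-helix CA
traces (radius 2.3 Å, rise 1.5 Å, 100°/residue — CA–CA spacing 3.83 Å,
matching the 3.8 ± 0.1 Å oracle), rigidly bent helices, helix-turn-helix
folds, β-hairpins, and smooth seeded random curves.  All fixtures are
deterministic in (spec, seed).

Ensembles are tangent Gaussians around a known mean shape.  Two
constructions make the recorded ground truth exact rather than nominal:

1. **Horizontal noise.**  Raw bump-shaped tangent fields overlap heavily
   with the nuisance subspace — the three infinitesimal rotations
   e_k × μ(t) and the reparameterization fields μ′w + ½w′μ — and any
   registration rightfully removes those components (measured: Procrustes
   rotation alone absorbed ~45% of the injected variance).  The generator
   therefore projects its directions onto the orthogonal complement of
   that subspace (rotations plus 25 sine warp fields), and starts bumps
   at two lobes, single-lobe bumps being the most rigid-motion-like.
   What remains is genuine shape variation, recoverable by the estimator.
   A side effect: noise nominally confined to a parameter window (the
   "flexible C-terminus" fixtures) leaks a small fraction of its energy
   outside the window, so support confinement is approximate (tested as
   < 20% energy outside, and ≳ 20× variance contrast in practice).

2. **Exact inverse encoding.**  Reconstructing a curve by cumulative
   trapezoid and re-encoding by finite differences is not an exact round
   trip; for helical curves marginally resolved at m = 100 the round trip
   moves the shape by θ ≈ 0.1, which would dwarf the quantities being
   recovered.  The generator instead solves the small linear system
   G·P = q|q| (G the finite-difference operator itself, anchored at the
   origin), so member curves re-encode to their target SRVFs to machine
   precision.  `srvf_to_curve` itself remains the plain cumulative
   trapezoid, which is adequate for visualization and reconstruction.

What passing tests do and do not show: the generator produces geometric,
pre-registered, Gaussian ensembles with noise orthogonal to the nuisance
subspace.  Real NMR ensembles are none of these exactly — their variation
includes components that registration legitimately absorbs, is not
Gaussian, and rides on real bond geometry.  Recovery results therefore
validate the estimator chain (registration → mean → tangent PCA →
sampling), not the adequacy of the Gaussian model for real ensembles.

## Problem sizes and costs

Matching uses m = 100 samples per curve (configurable); a symmetric
distance costs four alternation runs, ~0.15 s.  The validation suite uses
20 fixture curves for the metric axioms, n = 50 ensembles (m = 100) for
statistics recovery with 5,000 Monte-Carlo samples, and a 3-family × 10-
member benchmark (435 pairs) for classification.  Published-value checks
on deposited structures (1MP6/1G1J/2K98/2EOW worked examples, the
1ycc/1gu2 pair) run only when the PDB files are present under `data/pdb/`;
the pipeline for them (chain/model/residue-range selection, full-backbone
curves) is the same code path exercised by the synthetic tests.

## Known limitations

- Open curves in ℝ³ only; no closed curves, circular permutations,
  non-sequential alignment or domain-swap handling — the matching is
  sequential by construction.
- No auxiliary coordinates (secondary structure, sequence); matching uses
  geometry alone.
- The tangent Gaussian is the simplest two-moment model; mixtures or
  heavier-tailed models are out of scope.
- The alternation is a local optimizer; multi-start and arc-length
  canonicalization make failures rare in the tested regime but global
  optimality is not guaranteed.
- Distances shift at the second decimal with the grid size m and the DP
  slope bound; comparisons should fix one configuration.
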