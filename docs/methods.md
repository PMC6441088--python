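# Methods

`latmorph` re-implements, at desk scale, an analysis chain for mapping
functional brain lateralisation and relating it to corpus-callosum
connectivity: laterality-index (LI) maps on a mirror-symmetric grid,
varimax-rotated PCA with a rotation-aware maximal-statistic permutation
test for significantly lateralised voxels, a spectral "morphospace" of the
maps with a Pareto-style triangularity (t-ratio) test and archetype-map
reconstruction, and pooled comparisons of hemispheric dominance against
callosal connection probability and axonal water fraction (AWF).  A
synthetic-data generator stands in for meta-analytic term maps and
diffusion-derived connectivity so that every stage is verifiable offline.

## Symmetric grid and LI maps

Volumes live on a grid whose extent along the mirror axis is even, so the
interhemispheric plane falls between two voxel layers and every voxel has
a homologous partner (real analyses achieve this by non-linear
registration to a symmetric template; that step is out of scope here and
inputs are assumed already symmetric).  Half-grid fields index voxels by
distance from the midline, so homologous voxels of the two hemispheres
share indices.

`compute_li` splits a volume into hemisphere halves, smooths each half
with a Gaussian kernel (default from config; FWHM in mm, sigma =
FWHM/(2*sqrt(2 ln 2)), truncated at 4 sigma and renormalised inside the
brain mask so constants are preserved and nothing bleeds across the
midline), then subtracts the flipped left half from the right half.
Positive LI = right-hemisphere dominance.  The masked renormalisation is
row-stochastic: constants are preserved everywhere, and an impulse's mass
is preserved exactly when it sits at least two truncated-kernel radii from
the mask boundary (tested that way).

## Components and the permutation test

Terms are variables and voxels observations: the terms-by-terms covariance
(each term centred over voxels) is eigendecomposed, and components with
eigenvalues strictly above the grand average are retained — the same
retention rule as the study conditions.  Retained loadings (eigenvector
times sqrt eigenvalue) are varimax-rotated with Kaiser row normalisation
(criterion tolerance 1e-6 on the criterion increment, at most 1000
iterations; the rotation update is the orthogonal polar factor of the
criterion gradient).

Spatial maps come from a voxelwise ordinary-least-squares fit of the
across-term LI vector on the rotated loadings.  The design has **no
intercept column** by default.  This is a deliberate deviation from the
obvious default: the generator's convex (sum-to-one) mixture weights put a
constant-in-terms direction *inside* the retained components, so an
intercept column is nearly collinear with the loadings (observed variance
inflation ~700), which inflates every standard error ~80-fold and reduces
detection to zero even for strong planted effects.  Without the intercept
the constant direction is attributed to the loadings, where it belongs.
An `intercept=True` flag restores the augmented design.

Family-wise error control follows the maximal-statistic scheme: each of
`n_perm` permutations reorders the rows of the *unrotated* loading matrix,
re-applies varimax, refits the voxelwise GLM against the unpermuted LI
matrix, and records the single largest and smallest spatial-map value.  A
voxel is significant when its real value beats the permutation extremes in
at least 1 - alpha/2 of permutations (strict inequality, two-tailed,
default alpha 0.05) *and* survives a cluster-extent filter (default 20
voxels, 26-neighbourhood).  Both the raw beta and the beta/SE z value can
serve as the map statistic.  The operation's default is beta; the
end-to-end pipeline uses z, because beta is not scale-equivariant across
components — under permutation the betas of small-eigenvalue components
are amplified by the inverse eigenvalue and dominate the null maximum
(observed at 10x the real betas on planted data), making the beta variant
extremely conservative whenever the retained spectrum is steep.

The permutation loop is vectorised: row permutation leaves the loadings'
Gram matrix unchanged, so per-permutation inverses reduce to orthogonal
conjugations, varimax runs batched over permutations, and residual sums of
squares are computed from cross-products without forming residual
matrices.  A unit test pins the vectorised path to the plain
per-permutation computation.

## Morphospace and the t-ratio

Maps are denoised by reconstruction from the retained components
(`rotated_loadings @ betas`, plus the intercept map when one was fitted).
Similarity is the voxelwise dot product between denoised maps with
negative entries zeroed and a zero diagonal; the symmetric normalised
graph Laplacian `I - D^{-1/2} W D^{-1/2}` is eigendecomposed, eigenpairs
are sorted ascending, the zero-eigenvalue constant dimension is dropped,
and the next dimensions (degree-rescaled by default, raw by flag) are the
coordinates.  Signs are fixed (largest-magnitude entry positive) for
reproducibility; a disconnected similarity graph is an error reporting the
component count.

Triangularity of a 2-D subspace is the t-ratio: convex-hull area over the
area of the minimal-area enclosing triangle.  The minimal triangle is
computed exactly by candidate enumeration: a classical result guarantees a
flush side on some hull edge, and for a fixed flush side each remaining
side is, at the optimum, either flush or touched by the hull at the side's
midpoint; both conditions give closed-form candidates (the midpoint
condition follows from stationarity of `(a2-a1)^2 / (2 (t1-t2))` in the
support-line slopes).  All candidates over all flush edges are evaluated
vectorised, and the smallest valid one is returned.  An independent
numeric-minimisation oracle checks it in the tests (relative error <=
1e-6 on hulls up to 8 vertices); t-ratio affine invariance is asserted to
1e-9.

The null for the t-ratio permutes the voxel order of each hemisphere map
independently (fresh permutations per map) *before* LI differencing, then
reruns PCA (component count fixed to the real data's), varimax, denoising,
similarity, embedding, and the t-ratio per subspace.  The permutation
p-value is `(1 + #{null >= real}) / (1 + n_sets)`, Bonferroni-corrected
over the tested subspaces (default: all 10 pairs among the first five
informative dimensions).  Null sets whose pipeline fails (e.g. a
disconnected graph) are logged and resampled.

Archetype maps are obtained by regressing each voxel's denoised values on
the maps' embedding coordinates (with intercept) and evaluating the fit at
the vertices of the minimal enclosing triangle of the significant
subspace, with unfitted dimensions set to zero.  Far-outside-range
vertices trigger an extrapolation warning.

## Dominance and connectivity

Hemispheric dominance is `arctan(right/left) - pi/4` radians: 0 =
bilateral, +pi/4 = unilateral right, -pi/4 = unilateral left; both-zero
voxels are undefined (NaN, logged).  Per voxel the dominance is taken from
the component with the largest |z| (ties to the lowest index).  Two
strength conventions are provided: component-level left/right GLM betas at
the winning component (the default convention) and a raw-value mode using
the across-term mean hemisphere activations.  On synthetic data the raw
mode recovers the planted dominance field almost exactly (r >= 0.95 on
detected voxels), while the component mode carries a per-component
baseline that loosens recovery (r ~= 0.8); both are tested at their
simulated levels.

Non-lateralised comparison voxels are found by rerunning the whole
significance machinery per hemisphere on the *original* (un-differenced)
maps and keeping voxels that are significant for at least one component in
a hemisphere, do not overlap the lateralised mask, and whose homologue
also satisfies both conditions.

Connection probability is the fraction of subjects with at least one
streamline from the voxel to the corpus callosum.  Pool comparisons sample
5% of each pool without replacement, 1000 times, recording the
lateralised-minus-non-lateralised difference in mean connection
probability and in replicability-weighted mean AWF (a callosal voxel's
weight is the fraction of subjects in which it connects to a sampled
cortical voxel; with the generator's one-to-one cortical-callosal mapping
this is its connection probability within the sample).

For the graded relation, voxels are binned by connection probability with
log-spaced edges whose smallest (first) width equals exactly 1/n_subjects;
the edge count is the construction's free variable and shrinks for small
samples.  Values below the lowest edge join the first bin.  The Pearson
correlation between bin-mean |dominance| and bin-mean connection
probability is computed over populated bins, unweighted; with the
mean-activity covariate both binned variables are residualised on the
bin-mean covariate first (partial correlation, checked against pingouin in
the tests).  The midline-distance control rank-matches each lateralised
voxel to a non-lateralised voxel by distance to the interhemispheric plane
and correlates the per-pair connectivity difference with distance.

## Synthetic data: what it emulates, and what it does not

`generate_term_maps` plants K (3 or 4) archetype LI patterns — smoothed
Gaussian random fields, orthogonalised so the archetypes are exactly
uncorrelated over voxels (random smooth fields can come out strongly
correlated, which collapses the planted simplex in the embedding), unit sd
on the half-mask.  Term weights are convex: the first K terms are pure
archetypes and the rest are Dirichlet(0.35) draws, so the simplex corners
are occupied and its interior sampled.  Each term's LI pattern is the
convex mixture plus homoscedastic voxelwise Gaussian noise (default sd
0.1, the study condition used throughout).  Full volumes add a shared
symmetric background (offset 3.0 plus a rank-one smooth bilateral field
with term-varying amplitude) so the original maps have significant
bilateral structure for the non-lateralised definition; right and left
halves are background +- LI/2, making the computed (unsmoothed) LI equal
the planted mixture exactly.  The planted dominance field is the
arctangent form applied to the mean left/right activations.

`generate_null_maps` draws the same backgrounds plus full-grid i.i.d.
noise, so hemispheres are exchangeable and the expected LI is zero.

`generate_connectivity` draws per-subject Bernoulli connection indicators
with `p = 0.90 - 3.0 * |dominance| + N(0, 0.25)` clipped to
[1/n_subjects, 1], and AWF values `N(0.60 + offset * lateralised, 0.08)`
clipped to [0, 1] (default offset -0.05).  The slope and jitter defaults
were calibrated once, by simulation at the study size (2000 voxels, 163
subjects), so that the *binned* dominance-probability correlation sits at
the planted target of -0.8 (realised -0.80 +- 0.02 across seeds): with a
purely linear, unclipped relation the log-binned correlation is ~ -1
because bin means of a linear conditional expectation are collinear; it is
the saturation at the lower clip — strongly lateralised voxels losing
their callosal connections entirely — together with voxel-level jitter
that bends the bin-mean curve to the target.  Out-of-range probabilities
before clipping are warned about by design.

The generator does **not** emulate realistic BOLD spatial autocorrelation
beyond Gaussian smoothness, term-correlated noise, streamline geometry, or
distance-dependent connectivity.  Passing tests therefore demonstrate that
the machinery recovers what was planted under these idealised conditions,
not that the study's empirical numbers (which required the full
Neurosynth database and HCP 7T diffusion data) are reproduced.

## Determinism and problem sizes

One master seed expands into fixed-key child streams per stage
(`_seeds.py`), so identical (config, seed) pairs give byte-identical
outputs; the pipeline report's statistics block serialises
deterministically and is compared byte-for-byte in the tests.

Simulation sizes used by the tests and `scripts/acceptance.py` are chosen
for single-core desk runs: a 12^3 box grid (864 half-voxels) for
calibration and recovery, 40-60 terms, 500 permutations for the FWE test,
200 voxel-permutation null sets for the t-ratio, 120-200 null datasets for
the family-wise error calibration, and 2000 voxels x 163 subjects x 1000
resampling repetitions for the connectivity recovery.  The analysis
drivers use a 16^3 ellipsoid grid (1088 half-voxels).

## Known limitations

- The minimal-triangle candidate enumeration assumes a non-degenerate 2-D
  hull; collinear inputs are rejected rather than handled.
- FWER calibration is demonstrated empirically at alpha = 0.05 with the
  cluster filter active; the permutation scheme permutes component
  loadings rather than raw data, so exactness is not guaranteed in
  general — on exchangeable nulls it is conservative.
- The component-level dominance convention inherits a per-component
  baseline on synthetic data (see above); the raw-value mode is the
  faithful recovery route there.
- Degenerate (repeated) Laplacian eigenvalues leave within-eigenspace
  rotations arbitrary; they are logged, and the affine-invariant t-ratio
  is insensitive to them.
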