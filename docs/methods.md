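# Methods

This note documents the statistical procedures implemented in `surfglm`,
the choices made where several defensible options existed, and what the
synthetic-data tests do and do not demonstrate.

## Mass-univariate model

The unit of analysis is a vertex of a triangulated cortical surface. Every
vertex shares one design matrix **X** (*n* × *p*), built once per phenotype
table; the outcome **Y** (*n* × *V*) holds the per-vertex measure. The OLS
solution **B** = (**X**ᵀ**X**)⁻¹**X**ᵀ**Y** is computed through a
Householder QR factorization of **X** rather than by forming and inverting
**X**ᵀ**X**: mathematically identical, numerically better conditioned. The
diagonal of (**X**ᵀ**X**)⁻¹ needed for standard errors is recovered from
R⁻¹ as Σₖ (R⁻¹)²ⱼₖ.

Vertices are processed in chunks (default 1,000 vertices) so that peak
additional memory is *n* × chunk_size values regardless of *V*. Inside a
chunk each vertex column is solved with fixed-shape matrix–vector products;
because the arithmetic per vertex never depends on how vertices are grouped,
the output is **bitwise identical for every chunk size and chunk order**.
This makes chunking and (future) parallel scheduling pure performance knobs.

Numerical edge cases:

* **Perfect fits.** A residual sum of squares at most 10⁻²⁴ × ‖y‖² is
  treated as an exact zero (pure floating-point residue is ~ε² ≈ 5·10⁻³²
  relative; genuine residual variance is many orders larger). Such vertices
  get SE 0, *t* = ±∞ and the smallest positive double as p-value.
* **Masked vertices.** All output maps are exact zeros off-mask, the
  convention surface viewers expect.

The analysis mask keeps a vertex iff no subject has an exactly-zero value
there (zero is the conventional sentinel for off-cortex vertices), the
across-subject variance is positive, and — optionally — the vertex belongs
to a user-supplied cortex label map.

## Design matrices

Formulas use the familiar statistical syntax (`response ~ a + b`,
`a*b` = main effects + interaction, `a:b` = interaction only) with function
terms `poly` (orthonormal polynomials via QR of the centered Vandermonde
matrix), `pow` (raw powers), `ns` (natural cubic splines: boundary knots at
the data range, interior knots at equally spaced quantiles, second
derivative zero at the boundaries), `scale` (mean 0, SD 1 with the n−1
denominator) and `cut` (equal-width right-closed bins). The response must
name a surface measure with the `qdecr_` prefix; `qdecr_w_g.pct` decodes to
the `w-g.pct` measure because the hyphen is reserved formula syntax.

Deliberate conventions, chosen for determinism:

* Categorical variables (string/boolean columns) are treatment-coded with
  the **lexicographically first level as reference**. (Factor-level order in
  other ecosystems is data-dependent; lexicographic order makes the same
  formula give the same columns on any row ordering.)
* The intercept is mandatory; intercept-removal syntax is rejected, as is
  `-` anywhere on the right-hand side.
* No cardinality-based factor guessing: numeric columns are continuous.
* Column order is intercept first, then terms in formula order, with `*`
  expanding to main effects, then interactions by ascending order.

Rank deficiency is an error that names the dependent columns (via pivoted
QR), not a silent drop.

## Multiple imputation

Phenotype input may be a single table, a list of tables, a file glob with
one file per imputation, or one long file with an imputation index. Tables
are validated for identical schema and reordered to a common identifier
order; any residual missing value is an error — imputation itself is out of
scope (the synthetic module ships a deliberately simple regression imputer
for testing only).

Per-imputation design matrices are rebuilt from each table (covariate
values differ across imputations) while the vertex stack is loaded once.
Estimates are pooled with Rubin's rules: q̄ = mean estimate, within-variance
*W* = mean SE², between-variance *B* with the M−1 denominator, total
*T* = *W* + (1+1/M)·*B*. Inference uses the **Barnard–Rubin** adjusted
degrees of freedom (the behavior of the dominant imputation ecosystem);
the classical (M−1)/λ² is available via `df_method="old"`. When *B* is
exactly zero the degrees of freedom fall back to the complete-data n − p.
With M = 1 the pooled output is numerically identical to the single fit.

## Smoothness and cluster-wise correction

Residual spatial smoothness is summarized as a Gaussian FWHM derived from
the mean lag-one neighbor correlation ρ of per-vertex-standardized
residuals: FWHM = h̄·√(4 ln2 / (−ln ρ)), with h̄ the mean edge length;
ρ ≤ 0 maps to 0 (the field is rougher than the mesh resolves). Smoothness
is estimated once, from the first imputation's residuals — residual
smoothness is dominated by the data, not by which imputed covariate values
entered the fit — keeping the cost flat in M.

The cluster null distribution is **simulated on the fly**: standard-normal
fields are smoothed by iterated neighbor averaging
(x_v ← (x_v + Σ_adj x_u)/(1+deg v)), with the iteration count calibrated by
integer bisection (10% relative tolerance, cached per mesh/mask/target) so
the simulated fields match the estimated FWHM; each field is restandardized
to unit variance within the mask, converted to a two-sided normal p-map,
clustered exactly like the observed map, and its maximum cluster area
recorded. (Precomputed cluster-size tables for standard templates are the
historical alternative; an on-the-fly null needs no shipped tables, works
for any mesh, and is seedable.)

Cluster forming is two-sided at `mcz_thr` (default 0.001) and clusters are
**sign-coherent**: adjacent supra-threshold vertices with opposite *t* signs
belong to different clusters. Cluster area is the sum of barycentric vertex
areas (one third of each incident triangle), so areas are in mm² and sum
exactly to the mesh area. The corrected p-value uses the add-one estimator
cwp = (1 + #{null ≥ area})/(1 + n_sim), which never returns 0; significance
is cwp ≤ `cwp_thr` (default 0.025 = 0.05/2 for analyzing two hemispheres;
the correction itself is computed within one hemisphere). The family here
is one contrast within one hemisphere: each stack's map is corrected
against the shared null, which depends only on mesh, mask, smoothness and
threshold and is therefore simulated once per run.

The intercept stack is excluded from cluster inference: its "effect"
(mean thickness ≠ 0 everywhere) is not a hypothesis of interest and would
always produce a whole-cortex cluster. Its coefficient/SE/t/p maps are
still written.

## Synthetic data

The generator emulates smoothed, template-resampled cortical-thickness
maps on an icosphere standing in for a hemisphere template (radius 100 mm;
level-s subdivision gives 10·4ˢ+2 vertices). Each subject's map is
baseline + effect·patch + smooth noise:

* baseline 2.5 (a plausible mean cortical thickness in mm);
* noise: i.i.d. Gaussian, SD 0.3 mm, smoothed by 2 neighbor-averaging
  iterations and rescaled back to SD 0.3 — spatially correlated noise like
  real smoothed maps;
* covariates: age ~ Uniform(47, 80) years, sex balanced — the profile of a
  typical aging cohort; effects are βage·(age − 63.9) + βsex·1[M];
* the patch: effect weight 1 within a geodesic radius of a chosen vertex
  (graph distance × mean edge length approximates geodesics on the
  near-regular icosphere), tapering linearly to 0 over an extra half
  radius.

What these simulations demonstrate: correctness of the estimator (exact
recovery without noise, unbiased recovery with noise), calibration of the
cluster correction (family-wise error compatible with its nominal level on
zero-effect data), and sensitivity (a −0.01 mm/year patch effect at n = 200
is detected essentially always). What they do not demonstrate: behavior on
real cortical geometry (folded, inhomogeneous vertex density), realistic
scanner noise, non-Gaussian measure distributions, or covariate-dependent
missingness — the reference imputer is MCAR-only.

Default simulation sizes used by the test suite and the acceptance script
(162- or 642-vertex spheres, 40–200 subjects, 200 null simulations per
replicate) are chosen as the smallest problems at which the properties
under test are non-trivial; all scale knobs are ordinary function
arguments.

## File formats and outputs

MGH/MGZ and binary triangle surfaces are read and written natively,
big-endian throughout, with gzip handled transparently by the `.mgz`
suffix; round trips are bit-exact and cross-validated against an
independent reader in the tests. Vertex indices are 0-based everywhere,
including text reports. The output-file contract is described in the
`session` module docstring; the run manifest (`<project>.manifest.json`)
replaces a language-specific serialized object and is sufficient to
re-render the summary report. The `.voxel.mgh` vertex-wise-corrected map
and `.annot` cluster annotations are not produced (no vertex-wise null is
simulated by default, and anatomical annotation is out of scope).

## Known limitations

* OLS only: no weighted least squares, robust SEs, mixed models, or
  permutation inference.
* The null simulation assumes stationary Gaussian smoothness summarized by
  a single FWHM; strongly non-stationary residual fields violate this.
* The observed maps are thresholded via t-distribution p-values while the
  null fields use normal p-values; both are thresholded at the same
  marginal rate, so cluster-forming rates match, but very small n widens
  the tail mismatch.
* Smoothing-iteration calibration is integer-grained: on coarse meshes the
  achievable FWHM grid is coarse, and targets below the mesh resolution
  fall back to unsmoothed noise with a warning.
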