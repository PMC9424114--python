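# Methods

## Data model and conventions

All computation happens in Cartesian micrometres with the origin at the
image top-left and y increasing downward (raster order); pixel-space inputs
are converted on read (default 0.5 µm/px). Tissue outlines are simple
polygons with holes; outline area in mm² is polygon area in µm² / 10⁶.
Readers are schema-driven: a `CellTableDialect` maps source column names to
the canonical fields, so any per-cell export with coordinates and mean
intensities can be ingested. NA tokens `""`, `"NA"`, `"NaN"` are accepted on
read and written as `"NA"`.

Mask outlines are traced with marching squares at the 0.5 iso-level on the
zero-padded binary mask. For rectilinear masks the traced area equals the
foreground pixel count × scale² up to a 0.125 px² chamfer per convex corner
(relative error ≲ 10⁻⁵ at realistic mask sizes).

## Marker scoring

Positivity is a closed threshold: intensity ≥ τ is positive. Thresholds are
required inputs per patient series and stain (in practice they are set by
inspecting intensity distributions, which differ between staining batches);
`suggest_threshold` proposes the density valley between the negative and
positive components on the log scale but is never applied silently.

Phenotype categories are mutually exclusive with precedence
tpTreg ≻ FOXP3 ≻ CD8 ≻ other. The triple requirement (CD4⁺∧CD25⁺∧FOXP3⁺)
defines the tp-Treg; a co-positive FOXP3⁺CD8⁺ cell counts as FOXP3 (Treg
identity is the analytical focus) and the number of such conflicts is
logged.

All percentile thresholds use the nearest-rank order statistic
(⌈q·n⌉-th of the ascending sort): deterministic, interpolation-free, and
directly checkable against a sort oracle. All High/Low dichotomizations use
strict `>` against the cutoff, so boundary values fall Low; with continuous
intensities the single-marker High fraction at the 75th-percentile
threshold is ≤ 25% and converges to 25%.

The 75th-percentile Treg thresholds default to the pooled-per-series scope
(one threshold per marker per series, computed over all tp-Tregs of the
series); per-sample scope is available. Pooling matches how a single
cohort-level High/High fraction is defined.

The per-sample mean-CD25 class is Negative when the sample has no tp-Tregs,
otherwise High iff the mean CD25 across its tp-Tregs strictly exceeds the
per-series cutoff. The `auto` cutoff fits a Gaussian KDE (Silverman
bandwidth) to the per-sample means, requires ≥ 30 samples, finds the local
maxima on a 2048-point grid, and returns the deepest minimum between the
two highest modes; a unimodal density raises an error instructing a manual
cutoff — the automatic value is echoed so an analyst can confirm it.

## Spatial proximity

Voronoi tessellation is delegated to GEOS (via shapely); cells are matched
back to their generating sites by point-in-polygon query and clipped to the
tissue outline. Candidate neighbor pairs come from the scipy Delaunay
triangulation (every shared Voronoi boundary corresponds to a Delaunay
edge); a pair is adjacent iff its clipped regions share a boundary longer
than ε = 10⁻⁶ µm. Consequences of these choices:

* point-contact between cocircular regions does not create adjacency;
* holes and excluded regions in the outline break adjacency across them
  (cells separated by a necrotic gap are not neighbors);
* exact duplicate coordinates are jittered by a seeded offset < 0.01 µm
  (far below pixel scale) before tessellation, with the count logged;
* all clipped fragments of one site remain one node.

When no mask is available the outline falls back to the convex hull of the
cells buffered by the median nearest-neighbor distance (warned).

The permutation test randomizes the category labels over the fixed cell map
B = 2000 times (default), preserving category counts exactly, and computes
the neighbor count k on each relabeling. The critical value is the
nearest-rank 95th percentile (the 1900th of 2000 sorted counts) and the call
is strict: k_obs > q95. Ties at the critical value are non-significant,
which makes the test conservative on discrete counts (measured type-I rate
≈ 0.03–0.05 at the 5% nominal level). Permutations are drawn in a canonical
node order (lexicographic on coordinates), so the permuted distribution is
invariant to the row order of the input table. Per-sample RNG streams are
derived from (master seed, sample index); no multiplicity correction is
applied across samples — each sample receives its own 95th-percentile call.

The FOXP3-any target counts both the FOXP3 and tpTreg categories (a
tp-Treg is FOXP3⁺ by definition; category precedence would otherwise hide
triple-positives from the FOXP3 test).

## Synthetic cohort generator

The generator emulates tissue-microarray cores so that every stage of the
pipeline can be exercised and calibrated without patient data.

**Geometry and counts.** Circular cores (default 1.0 mm; 0.6 mm supported)
with cells placed uniformly (binomial/Poisson). Default cellularity is
400 cells/mm² (~314 cells per 1.0 mm core) — a desk-scale runtime choice,
not a fidelity claim. Immune category counts are Poisson around baseline
proportions (CD8 15%, FOXP3-only 10%, tp-Treg 5%) modulated by a shared
lognormal infiltration effect (sd 0.7) plus independent per-category
effects (sd 0.36): this produces the right-skew of infiltration scores
across samples and the strong correlation between FOXP3⁺ and tp-Treg
density scores (calibrated to r ≈ 0.85 on log₂ densities).

**Attraction.** Spatial dependence is injected by label assignment, not a
Gibbs process: CD8 labels are a uniform subset; Treg labels are drawn
without replacement with weight exp(θ·exp(−d/σ)), d = distance to the
nearest CD8⁺ cell, σ = 20 µm (≈ 1–2 cell diameters). θ = 0 is exactly the
permutation test's null, and category counts are preserved for every θ.

**Intensities.** Two-component lognormal mixtures per marker. The CD25 and
FOXP3 positive components carry a per-sample normal effect on the log-mean
(CD25: mean 1.571, sd 0.188; FOXP3: 0.645, 0.40) plus cell-level spread
(log-sd 0.70 / 0.80); within tp-Tregs the two markers share a Gaussian
copula with correlation 0.90. These values were calibrated once, through
the full generate→score pipeline, to the across-sample statistics the
generator emulates: mean-CD25 10th–90th percentile ≈ 3.9–9.1, mean-FOXP3
≈ 1.3–4.8, pooled CD25ᴴⁱᵍʰFOXP3ᴴⁱᵍʰ fraction ≈ 16%. The per-sample effects
for the two markers are independent (their per-sample means are
uncorrelated). A bimodal option on the CD25 sample effect supports testing
the automatic mean-CD25 cutoff.

**Spatial calibration config.** Operating characteristics of the proximity
test are characterized on a dedicated configuration
(`spatial_calibration_config`): 1.0 mm cores, 1600 cells/mm², fixed
category counts. The higher cellularity is deliberate: at 1600 cells/mm²
the typical cell spacing (~12–25 µm) matches the 20 µm attraction range, so
the alternative hypothesis is physically realizable — at 400 cells/mm²
almost no cell lies within kernel range of a CD8⁺ cell and no attainable
attraction strength produces near-certain detection. Under this config the
measured type-I rate at θ = 0 is ≈ 0.047 (300 samples, B = 500) and the
flag rate rises monotonically through ≈ 0.16 / 0.40 / 0.98 at θ = 1/2/5.
The type-I property also holds at the sparse default (≈ 0.033 at ~314
cells), as the unit suite checks.

**Survival.** Covariates are drawn from realistic marginals for two
colorectal-cancer series (stage, pT, pN coherently; MSI 15.5%; age ~N(72,
11) clipped to 27–97; R0 80%). Immune features default to their cohort
prevalences (mean-CD25 High 14%, significant proximity 18%, high
intraepithelial CD8 50%). Event times are exponential with proportional
hazards on the configured log-HRs (defaults: 0.62 for high intraepithelial
CD8, 1.35 for mean-CD25 High, 1.36 for proximity, plus pT/pN/MSI/age
effects), a per-cohort baseline (0.0075/month; cohort 2 scaled ×1.2 —
absorbed by stratification), uniform censoring on (0, 120] months and
administrative censoring at 60. About 40% of analyzed patients have an
event by 60 months. A quarter of events are recorded as deaths rather than
relapses, exercising the death-from-any-cause part of the RFS definition.
Cohort sizes are stated as generated patients; the cohort filters leave
~60% for analysis (mirroring the analyzed fraction of the studies this
emulates), so recovery checks that target ~1000 analyzed patients generate
1700.

**What the generator does not emulate:** stain spectra, segmentation error,
autofluorescence, batch effects beyond the per-sample random effects, or
any dependence of intensities on spatial position. Passing calibration
tests therefore shows the pipeline's statistics behave correctly under the
modeled data-generating process, not that real staining artifacts are
handled.

## Outcome analysis

Endpoints: RFS5 = time from surgery to the first of recurrence or death
from any cause, censored at follow-up and administratively at 60 months,
for stage I–III patients with R0 resection, no pre-operative radiotherapy
and no synchronous primary (exclusion reasons recorded in that order);
OS5 = death from any cause, for the separate stage IV analysis. Kaplan-
Meier estimation (Greenwood bands), the log-rank test and Cox fitting are
delegated to lifelines; Cox models use Efron tie handling, complete cases
only, and stratification by cohort (series). pT1 and pT2 are combined into
the reference level by a config-level recode (both are rare and behave
similarly), giving pT3/pT4 indicators.

Bootstrap variable retention: B resamples of patients with replacement;
within each, p-value-based backward elimination with stay criterion
p ≤ 0.157 (the 1-df AIC-equivalent; configurable, since the referenced
procedure does not fix one); variables retained in ≥ 30% of replicates form
the retained set. Degenerate resamples (constant covariates) drop the
lowest-variance covariate and continue. Fractional-polynomial
transformation of continuous covariates is out of scope; continuous
covariates enter linearly (documented limitation).

## Problem sizes in the shipped checks

The calibration suite scores 500 generated cores; type-I uses 300 samples
at B = 500 permutations; power uses 100 samples per θ ∈ {0, 1, 2, 5};
effect-recovery uses 50 replicate cohorts of ~1000 analyzed patients, and
the acceptance script averages 25 replicate Cox fits on the log scale.
These sizes were chosen so each check is decisively powered at desk scale.

## Known limitations

* The Treg stain carries no epithelial markers, so the spatial test is not
  stratified by tissue compartment (by design).
* Compartment areas for intraepithelial/stromal densities must come from
  the segmentation; for synthetic cores the CLI estimates them from cell
  fractions (exact under uniform placement).
* The automatic mean-CD25 cutoff assumes a clearly bimodal per-sample
  distribution; real series may need the manual per-series cutoff.
* Cross-K/Ripley statistics and distance-threshold neighborhoods are not
  implemented; neighborhood is strictly Voronoi adjacency.
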