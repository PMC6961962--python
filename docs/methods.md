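# Methods

This note documents the statistical machinery in `lakecolor`: the models
and their assumptions, the parameters that matter, the numerical choices
made where several defensible options existed, and what the synthetic
test bed does and does not establish about real survey data.

## Nutrient-color classification

Lakes are classified on total phosphorus (TP, µg/L) and true color
(PCU). The four rules — blue: TP ≤ 30 ∧ color ≤ 20; green: TP > 30 ∧
color ≤ 20; brown: TP ≤ 30 ∧ color > 20; murky: TP > 30 ∧ color > 20 —
are written so that they partition the non-negative quadrant exactly:
thresholds are inclusive on the low-TP / low-color side. Published
per-class summaries (blue TP maximum 30, green TP minimum 31, blue color
maximum 20, brown color minimum 21) pin the boundary to this convention.
Both thresholds are parameters (`tp_threshold`, `color_threshold`) and
can be moved; the partition property holds for any positive values.

"Extreme" class membership uses per-class quartiles of TP and color with
strict inequalities — blue below both first quartiles, murky above both
third quartiles, green below the color Q1 but above the TP Q3, brown the
mirror image. Quartiles are computed from the data at hand by linear
interpolation between order statistics (the "type 7" estimator; no
estimator is canonical here and type 7 is the numpy/R default). Published
operational bounds quote a murky TP bound of 302 µg/L against a tabled
third quartile of 297.5; we always recompute from data rather than fix
either printed constant.

## Design-based estimation

The surveys are stratified random samples with known design weights
w_i = 1/π_i (lakes represented). Class proportions use the
Horvitz–Thompson ratio estimator

    P̂_c = Σ w_i 1[class_i = c] / Σ w_i,

which is invariant to uniform weight rescaling and (as a ratio) very
nearly design-unbiased at these sample sizes.

**Variance.** The local-neighborhood estimator forms, for each site, a
neighborhood of itself plus its `neighborhood_size − 1` nearest sites by
great-circle (haversine) distance, with weights proportional to inverse
distance rank (1, 1/2, 1/3, 1/4 for the default size 4), normalized to
sum to one. With weighted residuals e_i = w_i(z_i − P̂)/Σw, the variance
estimate is

    V̂ = Σ_i [ Σ_{j∈N(i)} a_ij (e_j − ē_i)² ] / (1 − Σ_j a_ij²),

where ē_i is the neighborhood-weighted mean. The denominator is an
unbiasedness correction: without it, a weighted variance about a
weighted mean under-estimates by exactly the factor (1 − Σ a²) ≈ 0.67
for spatially unstructured residuals, which would bias every CI
narrow. With the correction the estimator averages within ~1 % of the
binomial p(1−p)/n closed form under random site placement, while
spatially clustered class patterns — the situation the estimator is
designed for — deflate it well below the SRS value. This is a
single-pass scheme; the iterative row/column balancing of the full
published neighborhood estimator is deliberately omitted as a
simplification, and no finite-population correction is applied (sampling
fractions in these surveys are ~2 %). When coordinates are missing or
n ≤ neighborhood size, the estimator falls back to the weighted SRS
ratio variance with a warning.

**Change.** Δ = P̂₂ − P̂₁ per scope × class, SE(Δ) = √(SE₁² + SE₂²)
treating the two surveys as independent (population estimates use the
full, mostly non-overlapping samples; a covariance term for the
revisited subset is out of scope), CIs are Δ ± 1.96·SE, and significance
is "CI excludes zero". Per-survey CIs are truncated to [0, 100] %.

## Change vectors and circular statistics

For a lake sampled in both cycles, (ΔTP, Δcolor) is treated as a vector
with TP on the x-axis: angle = atan2(Δcolor, ΔTP) mapped to [0°, 360°),
so 45° means equal native-unit increases on both axes. Magnitudes mix
µg/L and PCU deliberately — the analysis convention for these surveys —
and no standardization is applied by default (an optional z-scaling flag
exists). Zero-change lakes have an undefined angle: they are excluded
from all circular statistics but retained with magnitude 0 in magnitude
comparisons.

The mean direction is the angle of the resultant of unit vectors; it is
flagged unstable when the mean resultant length is ≈ 0. Its 95 %
confidence arc is a percentile bootstrap (default 999 resamples):
bootstrap means are expressed as signed deviations in (−180°, 180°] from
the point estimate and the 2.5/97.5 percentile deviations define the
arc, which therefore always contains the point estimate. Coverage on
von Mises simulations (κ = 2, n = 401) is ≈ 93–95 %, the usual mild
anti-conservatism of the percentile method.

The Rao spacing statistic is T = ½ Σ|gap_i − 360/n| over the sorted
angular gaps including wrap-around; T = 0 for equal spacing and
360 − 360/n when all angles coincide. The p-value is Monte-Carlo
(default 10,000 seeded uniform resamples, p = (1+#{T* ≥ T})/(n_mc+1))
rather than interpolated from published critical-value tables — exact at
any n and reproducible. Duplicated angles simply contribute zero gaps.

One-way ANOVAs of magnitude and angle across origin classes treat the
angle as a linear variable on [0, 360), matching the survey analysis
convention; this is a documented caveat, since a linear treatment of a
circular response is only sensible when directions are concentrated well
away from the wrap point (here they are, around ~33°).

## Community processing and comparisons

Phytoplankton biovolume (µm³/mL) converts to dry biomass (µg/L) assuming
unit wet density (1 µm³ = 10⁻⁶ µg), 10³ mL/L, and a 20 % dry:wet ratio —
so 10⁶ µm³/mL → 200 µg dw/L, linear in the input. Zooplankton biomass is
expected as an input column (length–weight regressions are upstream of
this package). Taxa counted in both the 50 µm and 150 µm net meshes are
replaced by the arithmetic mean of density and biomass per site × taxon
(single-mesh records pass through; the operation is idempotent).

The rare-taxon rule retains a taxon iff it contributes ≥ 5 % of at least
one sample's total, applied first at order level and then at genus level
within retained orders. The "at least one sample" reading (rather than
"in every sample") is the only one under which the two printed filter
descriptions are mutually consistent and the one that does not empty
typical data sets. The boundary is inclusive (exactly 5 % retains).
Order aggregation sums genus columns and conserves per-site totals
exactly. Zooplankton:phytoplankton ratios are reported in total,
crustacean-only (Calanoida + Cyclopoida + Diplostraca) and rotifer-only
(Ploima + Flosculariaceae) versions; sites with zero phytoplankton
biomass keep their row with the ratio flagged undefined.

Class comparisons: tie-corrected Kruskal–Wallis with χ² p-values
(an exact-enumeration option exists for total n ≤ 10), Dunn's pairwise
mean-rank z tests (two-sided, Bonferroni over the pairs; for two groups
z² equals the tie-corrected H), and a family-wise Bonferroni α = 0.05/14
for the survey's 14-test families. Community matrices are square-root
transformed before Bray–Curtis dissimilarity (a semi-metric: symmetric,
[0, 1], zero diagonal; the triangle inequality is *not* guaranteed).
Pairs of all-empty sites are undefined (NaN) and must be excluded before
downstream tests. PERMANOVA uses the distance-based sum-of-squares
decomposition (pseudo-F, R² = SS_between/SS_total) with free permutation
of labels (single-factor design, no strata) and
p = (1+#{F* ≥ F})/(n_perm+1). NMDS minimizes Kruskal stress-1 by
alternating isotonic regression of configuration distances on the rank
order of the dissimilarities with Guttman majorization updates; the
first start is the classical-scaling solution, the remaining restarts
(default 20) are random; iteration stops when the stress improvement
falls below 10⁻⁶ or a step would increase stress (majorization stalled
at numerical precision), so the recorded stress trace is non-increasing.

## Synthetic generator

The generator emulates the study conditions so that every estimator can
be checked against known truth:

* nine ecoregion strata, default 2000 population lakes and 115 sampled
  per stratum (≈ 1035 per survey, matching the ~1000-lake cycles);
  weights = population/sample size;
* the 2007 national class mixture (45.7/20.8/10.0/23.5 % for
  blue/green/brown/murky) as the default per-stratum mixture;
* per-class TP and color from lognormals matched to the published
  per-class quartiles (µ = log median, σ = log(Q3/Q1)/1.349), rejection-
  truncated into the class region so the classifier recovers the
  intended class for every lake;
* additive drift in native units: direction von Mises with mean 32.68°
  (the published national mean direction) and concentration κ = 2,
  magnitude lognormal (median 15, σ = 1), values floored at 0; κ = ∞ and
  a −∞ log-median magnitude encode the degenerate cases; year-2 classes
  are re-derived from year-2 values, never carried over;
* a revisit fraction of 0.39 (≈ 401/1028): the year-2 sample revisits
  that share of year-1 sites per stratum and draws the rest fresh;
* communities: per-site order compositions Dirichlet-distributed around
  class means (murky rotifer share ≈ 2× blue), total biomass lognormal
  around the published class medians (zoo: 49.2/88.4/54.7/150.0 µg dw/L
  for blue/green/brown/murky), fixed genus splits within orders, and a
  fixed set of small-bodied genera duplicated across both net meshes.
* TP detection limit 3.9 µg/L: lakes drawn below it are flagged, as a
  small share of real year-1 samples were.

What the generator does **not** emulate: spatially balanced (GRTS) site
selection (coordinates are uniform within stratum boxes, so spatial
balance is only as good as uniform random placement), measurement error
in TP/color, seasonal or within-summer dynamics, taxonomic richness
beyond ten orders/twenty genera, and genuine zero-inflation in plankton
counts. Passing recovery tests on this bed therefore demonstrates the
correctness of the estimators under the stated design assumptions, not
robustness to the messier features of field data.

## Problem sizes and numerical choices

Simulation-based checks use: 500 replicate surveys (3 strata × 70
sites, 4000-lake strata, ~1.75 % sampling fraction, comparable to the
real surveys') for CI coverage; 1000 draws of n = 100 for the
variance-estimator/SRS comparison; 5000 uniform samples (n = 100,
shared 10,000-replicate null) for the Rao type-I rate; and 500 von
Mises runs (n = 401, 999 bootstrap resamples) for arc coverage. These
sizes give Monte-Carlo standard errors of ~1 % on coverage-type
quantities. The pipeline subsamples ordination/PERMANOVA input to 200
sites (seeded) because both stages are O(n²)–O(n³); estimates and
circular statistics always use all sites. All random stages take
independent named integer seeds derived from one master seed, and reruns
are byte-identical.

Degenerate inputs are handled explicitly: empty samples, zero total
weights, single-class scopes (SE 0), resultant length ≈ 0 (unstable mean
direction), all-zero community matrices, and all-tied rank tests (H = 0,
p = 1) either return the documented value or raise a domain error.

## Known limitations

* The independent-surveys assumption in the change SE ignores the
  positive covariance contributed by the ~400 revisited lakes; the
  resulting CIs are slightly conservative for the difference.
* The local-mean variance estimator's single-pass weighting is a
  simplification of the published neighborhood estimator; its
  calibration is verified under random placement and clustered classes,
  not under adversarial weight/coordinate configurations.
* Linear ANOVA on angles is only meaningful for concentrated direction
  distributions.
* Bray–Curtis NaN pairs (two empty sites) are excluded, not imputed.
* NMDS is a local optimizer; with few restarts on large matrices the
  reported stress is an upper bound on the global minimum.
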