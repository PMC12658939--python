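# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Units of analysis and the outcome

All layers live on one planar equal-area lattice of square pixels (default
10 km side, ~100 km² area; row 0 is north). Rasterization uses the
center-containment dialect — a pixel is burned iff its center lies inside
the polygon — fixed so every count is reproducible; the alternative
any-overlap dialect would systematically inflate areas of small polygons.

The outcome is the per-pixel local extinction rate: the fraction of species
present in the past epoch that no longer cover the pixel in the recent
epoch, expressed as a percentage (0–100). Pixels with no past species carry
a missing value, not zero, and are excluded from all unit-of-analysis
tables: the statistic is conditional on past presence. Range gains never
offset losses; a "net" variant is deliberately not offered.

## Protection time frames

PA records carry an establishment year, status and IUCN category. Records
survive filtering only if currently existing, assigned to an IUCN category,
and spatially explicit; centroid-only records become regular 64-gons of the
equivalent circle (`r = sqrt(A/π)`; the 64-gon area is within 0.5% of `A`).
Pixels are classified P70 (covered by a PA established in or before the
past reference year — "established before 1970" is implemented as
`year ≤ 1970`), P15 (first covered 1971–2015), BUFFER (within one pixel,
a Moore-neighbourhood dilation ≈ 10 km, of any PA regardless of vintage) or
NEVER. Precedence in overlaps is P70 > P15 > BUFFER > NEVER: earliest
protection wins, and the buffer is carved only out of NEVER.
Degazettement is not modelled. In the three-way decomposition of each
species' lost range, buffer pixels count in the never-protected stratum so
the three shares sum to one.

## Matching estimator

The propensity model is an unpenalized maximum-likelihood logistic
regression of treatment on the quartile-binned continuous covariates
(one-hot, first level dropped) and bioanthrome indicators (levels with
fewer than 10 units pooled into "other" to avoid separation; if the
likelihood is still degenerate — non-convergence or |logit| > 15 — the fit
falls back to a ridge-penalized logistic with a warning). Quartile cut
points are computed on the pooled eligible-pixel distribution, closed on
the right, so treatment and control share one coarsening.

Matching is greedy 1:1 nearest neighbour on the score, without replacement
and without a caliper: treated units processed in decreasing score (ties by
unit id), each taking the unused control with the smallest absolute score
difference (ties by control id). The implementation uses path-compressed
neighbour pointers over score-sorted controls and is oracle-tested against
a direct simulation of the rule. When treated units outnumber controls the
excess treated units remain unmatched with a warning; roles are never
swapped.

Balance is reported as absolute standardized mean differences with the
denominator fixed at the *pre-matching* pooled SD (`sqrt((s_T² + s_C²)/2)`;
a treated-SD variant is exposed) and reused after matching so before/after
are comparable. SMDs are computed for the covariates **as entered in the
propensity model** — the quartile-categorized variables — plus the score
itself ("distance") and the average over bioanthrome indicators. This is
the convention of standard matching balance tables; raw continuous values
retain a small within-quartile residual that a bin-level matcher cannot
address, and reporting them would conflate coarsening error with matching
failure.

The ATT is the mean matched-pair difference in % species lost, with a 95%
CI from the paired-difference standard error under a normal approximation
(the CI construction is a package choice; a seeded percentile bootstrap is
a natural alternative and the paired SE was preferred for determinism).
Four contrasts are wired in — (a) protected (P70+P15) vs NEVER, (b) P70 vs
P15, (c) protected vs BUFFER, (d) BUFFER vs NEVER — the group with less
protection always serving as control. Contrast (a) pools P70 and P15 as
"protected".

## Boosted model

A stagewise least-squares ensemble of depth-2 regression trees (up to
two-way interactions), learning rate 0.1, no subsampling, backed by
scikit-learn's `GradientBoostingRegressor`. The boosting length is selected
as the iteration minimizing mean validation MSE across seeded 5-fold CV
splits, scanning up to the maximum of the configured tree grid; the final
model is refit on all rows at that length. Features are the protection
category (ordinal code), the quartile bins (ordinal 1–4) and the
bioanthrome id; protection effects are read off as partial dependence
(every row forced to each level, predictions averaged), and covariate
importance as split-gain relative influence normalized to 100. The
reference-scale grids of 10k–30k trees apply to continent-scale tables; the
package defaults to a 100–1000-tree grid appropriate to the 200×200 worlds
it ships with (the optimum on those worlds sits well inside the grid).

## Regressions

Species-level OLS models relate % range lost to (1) `ln(Δ proportion
protected + 0.01)` — the 0.01 offset (one percentage point of protection)
keeps zero-change species; species whose protected proportion *fell* by
more than the offset have an undefined predictor and are excluded with a
warning — and (2, 3) `ln(protected extent + 1 km²)` for the extent
protected since 1970 and the extent protected in 2015 only. The offsets are
part of the model definition and asserted, not configurable. The
bioanthrome-level model (4) regresses % species locally extinct on the
change in PA coverage plus bioanthrome area (km² or its log). Percentages
are on the 0–100 scale throughout; p-values are two-sided t-tests without
multiplicity correction.

## The synthetic world

The generator emulates the statistical structure of the global datasets the
workflow targets, with every parameter known:

* **Covariates.** Elevation, travel time and a population noise component
  are two-scale Gaussian random fields (a coarse component, blur radius 8
  px, plus fine texture carrying 40% of the variance — real covariate
  surfaces mix regional gradients with local heterogeneity). Slope is the
  standardized mix of the elevation-gradient magnitude and elevation itself
  (steep terrain is high terrain); population density loads negatively on
  travel time (people live near cities); anthromes are quantile classes of
  a population-driven field (land use follows people) and biomes of an
  independent field. These cross-correlations reproduce the empirical
  pattern that *all* matching covariates are imbalanced before matching.
* **PA placement (the confounder).** Seeds are drawn with probability
  ∝ `exp(γ·s)` where `s` is a unit-norm weighted sum (0.832 elevation,
  0.555 travel time) of the *quartile-class scores* of the two fields, and
  γ = 1.5 in the standard world. Placement policy is thus modelled as
  operating on coarse terrain/remoteness classes — uniform within a class —
  which (i) keeps common support (a continuous tilt of this strength pushes
  protected land ~2 SD into the covariate tail, where no comparable
  controls exist at any sample size), (ii) makes assignment depend on
  covariates only through the classes the propensity model conditions on,
  so the matched estimand is identified, and (iii) gives every
  (elevation, travel) class pair a distinct score, so matching can balance
  the two covariates individually. Seeds grow into wobbly-disc blobs
  (radius 2.5–6 px) realized as pixel-union polygons; a configurable 20%
  are emitted centroid-only to exercise the circle rule; establishment
  years split half before 1970, half 1971–2015.
* **Extirpation.** Each past-occupied pixel is lost independently with
  probability `logistic(β0 + Σ β_c·z_c + b_bioanthrome + δ_category)`,
  where `z_c` are the standardized quartile-class scores of the covariates
  (piecewise-constant effects: the adjustment set used by the analysis is
  sufficient *by construction*, the standard design for simulation studies
  of matching estimators), β = (−0.2 elevation, −0.05 slope, +0.25
  population, −0.2 travel time), and `b` are seeded N(0, 0.15) bioanthrome
  intercepts. The intercept is calibrated on the realized landscape so
  never-protected pixels average a 20.7% loss rate and δ_P70 so
  long-protected pixels average 10.3% — the headline contrast the standard
  world is built to echo; δ_P15 and δ_BUFFER are fixed at 0.6 and 0.3 of
  δ_P70, which guarantees the protective ordering
  δ_P70 < δ_P15 < δ_BUFFER < 0 on every draw. (Calibrating all four
  category means marginally is infeasible under strong confounding: the
  intermediate categories' marginal gaps are smaller than their covariate
  composition shift, which would force anti-protective offsets.) Species
  ranges are wobbly discs (radius 20–40 px); small protection-independent
  gains (rate 0.02) appear adjacent to the surviving range, so the
  extinction-rate statistic — which ignores gains — remains the correct
  outcome.
* **Ground truth.** `WorldTruth` records the calibrated offsets, realized
  per-category rates, and the true ATT of each contrast: the average over
  eligible treated pixels of the model-probability difference between the
  pixel's own protection level and the control category's level, in
  percentage points.

What the generator does **not** emulate: real biogeography and range
cohesion, temporally explicit protection histories (no degazettement),
spatially correlated extirpation shocks (losses are independent given the
covariates), measurement error in range maps, and real-world PA placement
that depends on unobserved drivers. Passing tests therefore demonstrate
estimator correctness under ignorability and desk-scale power — not that
matching removes confounding from drivers the covariates do not carry.

## Problem sizes and numerical choices

The standard world is 200×200 px (≈ 39k eligible pixels), 50 species, 60
PAs — sized so the full pipeline runs in well under a minute and a 50-seed
recovery study in minutes. Determinism: every random stream derives from
the single world seed via independent spawned generators per stage; reruns
of the pipeline are byte-identical, which the manifest (config hash +
per-file SHA-256) makes checkable. Degenerate inputs are handled
explicitly: constant covariate layers collapse to one quartile bin with a
warning; constant outcomes yield an intercept-only boosted model with zero
influence; zero-variance covariates with unequal group means are a hard
error in SMD computation; species with empty past ranges or bioanthromes
with no past species are dropped with logged reasons. Probabilities from
the extirpation model are clamped to (1e-12, 1−1e-12).

## Known limitations

* Matching assumes ignorability given the binned covariates and
  bioanthromes; no sensitivity analysis for hidden confounding is included.
* The paired-difference CI ignores propensity-estimation uncertainty; on
  strongly confounded contrasts with poor overlap — (b) and (c), exactly as
  in continental applications — balance fails and the ATT there should be
  read qualitatively.
* Spatial autocorrelation of outcomes is not corrected for; matched pairs
  are treated as independent.
* The buffer-in-never convention of the loss decomposition and the use of
  past-epoch bioanthromes for matching are documented conventions, both
  configurable at call sites.
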