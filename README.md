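# paguard

Counterfactual assessment of protected-area (PA) effectiveness against
terrestrial-mammal range contraction and local extinction, on a shared
equal-area grid of ~100 km² pixels.

## The problem

Species range maps from two epochs (a "past" snapshot around 1970 and a
"recent" one around 2015) can be overlaid to map where each species lost,
retained or gained range. Aggregating over species gives, for every pixel,
a **local extinction (extirpation) rate**

```
rate(px) = (# species lost from px) / (# species present in px in the past)
```

defined only where at least one species was present in the past; gains never
offset losses. The conservation question is whether protection *caused* lower
extirpation — but PAs are not placed at random: they concentrate in high,
steep, remote, sparsely populated land where extirpation would have been low
anyway. Naive protected-vs-unprotected contrasts therefore overstate PA
benefits. `paguard` implements the full causal-inference workflow:

1. **Range-change accounting** (`paguard.rangechange`): lost/retained/gained
   partitions, richness maps, extirpation-rate maps, per-species summaries.
2. **Protection time frames** (`paguard.protection`): WDPA-style records are
   filtered (currently existing, IUCN-categorized, spatially explicit;
   centroid-only PAs realized as circles of radius `r = sqrt(A/π)`), then every
   pixel is classified **P70** (protected continuously since ≤ 1970), **P15**
   (first protected 1971–2015), **BUFFER** (within one pixel ≈ 10 km of any
   PA) or **NEVER**.
3. **Matching substrate** (`paguard.covariates`): bioanthromes (unique
   biome × anthrome combinations) plus quartile-binned elevation, slope,
   population density and travel time to the nearest city.
4. **Propensity-score matching** (`paguard.matching`): logistic propensity
   scores, greedy 1:1 nearest-neighbour matching without replacement or
   caliper, balance diagnostics as absolute standardized mean differences
   (|SMD| < 0.1 ⇒ balanced), and the ATT on % species lost with a
   paired-difference 95% CI, for four pairwise contrasts:
   (a) protected vs never, (b) P70 vs P15, (c) protected vs buffer,
   (d) buffer vs never — the lower-protection group is always the control.
5. **Boosted trees** (`paguard.boosted`): stagewise least-squares boosting of
   depth-2 trees (learning rate 0.1, 5-fold CV tree selection), with
   partial-dependence protection effects and split-gain relative influence.
6. **Species/landscape regressions** (`paguard.regress`): OLS of % range lost
   on `ln(Δ proportion protected + 0.01)` and `ln(protected extent + 1 km²)`,
   and of bioanthrome-level % species lost on PA-coverage change + area.
7. **Synthetic worlds** (`paguard.synth`): seeded landscapes with spatially
   autocorrelated covariates, confounded PA placement and an extirpation
   process with *known* effects, so every estimator can be validated against
   ground truth.

## Worked example

```python
import paguard as pg
from paguard.rangechange import classify_change, extinction_rate, richness
from paguard.covariates import CONTINUOUS_COVARIATES, assemble_pixel_table
from paguard.matching import PropensityScoreMatch

world = pg.generate_world(pg.WorldConfig(seed=1))          # 200x200 px, 50 species, 60 PAs
past_rich = richness(world.past)
lost = [classify_change(p, r).lost for p, r in zip(world.past, world.recent)]
ext = extinction_rate(past_rich, richness(lost))
table = assemble_pixel_table(
    ext, world.pmap,
    {k: world.covariates[k] for k in CONTINUOUS_COVARIATES},
    world.covariates["bioanthromes"],
)
result = PropensityScoreMatch(table, ("P70", "P15"), ("NEVER",)).fit()
print(result.summary())
```

prints

```
Propensity-score matching (nearest neighbour, no replacement, no caliper)
treatment: P70+P15   control: NEVER
n treated: 3705   n control: 33789   pairs: 3705

ATT on % species lost: -5.409  (95% CI -6.363 to -4.455; SE 0.487)
matched means: treated 11.091  control 16.500

Covariate balance (|SMD|; < 0.1 indicates balance):
             covariate  smd_before  smd_after
              distance      0.9207     0.0023
             elevation      0.7618     0.0029
                 slope      0.4398     0.0109
    population density      0.1407     0.0231
           travel time      0.4279     0.0151
bioanthromes (average)      0.0808     0.0187
```

Protection lowers the matched % of species lost by ~5.4 points (the world's
generative truth is −4.6, inside the CI), while the naive unmatched contrast
on the same table is −9.8 — the confounding that matching removes. All
covariates move from badly imbalanced (SMD up to 0.9) to balanced (< 0.03).

## Command line

```bash
paguard run-all --seed 1 --out runs/demo     # full pipeline + report + manifest
paguard report --run runs/demo
paguard simulate --out world/                # world only (rasters, GeoJSON, truth.json)
paguard match --table runs/demo/pixel_table.csv --comparison a --out m/
paguard gbm   --table runs/demo/pixel_table.csv --out g/
```

Every run writes `manifest.json` (config hash, per-file content hashes) and
is byte-for-byte reproducible for a fixed seed.

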