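# Methods

## Model overview

`foodtrade` simulates annual global food trade among country agents and the
nutrition outcomes that follow. The model is relational rather than
price-driven: no prices are formed, and allocation is decided by whom each
country *prefers* to trade with. The simulation state is a `World`: a list
of country agents (static attributes plus per-commodity baseline and
current-year flows), a list of commodities with per-variant nutrient
composition, dense directed relation matrices (distance, historic trade,
emergent trade), a requirement table by age-sex group, and a household-waste
table by region and food group.

A simulated year executes in a fixed order:

1. **Exogenous update.** GDP, population and per-commodity production are
   replaced by the year's inputs (by default, baseline values held
   constant).
2. **Diet rescaling.** Each country's typical diet — its baseline
   per-commodity food consumption — is scaled entry-wise by the ratio of
   current to baseline global per-capita supply of that commodity. Global
   per-capita *production* is used as the supply measure: trade moves mass
   around but cannot create it, so production is the global supply.
3. **Positions.** The diet target (tonnes of food) is converted to its
   domestic-supply equivalent by dividing by the baseline food share of
   domestic supply; the gap to production becomes the import need or export
   surplus, so at most one of the two is positive. Intermediary countries
   (flagged per commodity where baseline exports exceed 80% of baseline
   imports with positive imports) additionally demand their baseline
   re-export volume, taken as min(baseline import, baseline export) and
   rescaled by the same global supply ratio as the diet.
4. **Markets.** One independent market per commodity (fixed list order;
   independence is asserted by a permutation test). See below.
5. **Supply identity.** Food supply = (production + realized imports −
   realized exports) × food share, floored at zero. Stock variation is set
   to zero: the accounting identity names a stock term but nothing in the
   model updates it.
6. **Nutrition.** See below.
7. **Emergent update.** Every transaction adds its tonnage to the
   exporter's emergent-export volume toward the importer and the importer's
   emergent-import volume toward the exporter. Accumulation is without
   decay (a deliberate default; decay semantics are not defined by the
   model description). Because this step runs at year end, within-year
   rankings are unaffected and path dependence operates year-over-year.

## The market procedure

Partner priority is a weighted average of four elements, each min–max
normalized over the candidate set of the current ranking event: partner GDP
per capita, distance (entering as one minus the normalized value), and the
role-appropriate historic and emergent volumes (importers look at their
import-side volumes, exporters at their export side). A degenerate
normalizer (all candidates equal on an element) maps the element to 1.
Scores therefore live in [0, 1]; exact ties are broken by one seeded
uniform draw per candidate. The default weights (1.40, 1, 1.40, 0.72 for
GDP, distance, historic, emergent) are the calibrated values shipped as
configuration; synthetic-world studies usually override them.

Markets run in two-phase rounds. Offer phase: every importer with
remaining demand offers min(remaining demand, cap) to its top-ranked
exporter with remaining stock (self excluded). Acceptance phase: every
offered exporter serves its offers in its own priority order until its
stock runs out. Tonnes an intermediary buys against its re-export demand
re-enter the market as that intermediary's export stock in the next round;
domestic demand is filled before re-export demand when a delivery covers
both. The per-round cap defaults to potential/10, where potential =
min(total demand, total supply) at market open; the cap prevents large
countries from flooding a round and only affects round counts, not
volumes.

Stopping (a point the model description leaves open, decided here):

* at saturation s < 1 the market closes once cumulative transaction volume
  reaches s × potential, truncating the final transaction to land on the
  target exactly — so realized volume is exactly s × potential whenever
  any trade is feasible, and monotonicity in s holds path-wise because a
  lower-s run is a prefix of a higher-s run under the same seed;
* at s = 1 the market trades to exhaustion, i.e. until no importer with
  remaining demand faces a distinct exporter with remaining stock. On
  markets without intermediaries this realizes exactly min(total demand,
  total supply). With intermediaries, re-export restocking can carry gross
  transaction volume past the market-open potential (one tonne moving
  exporter → intermediary → consumer counts twice), and a market can end
  with unmet re-export demand when the only remaining stock belongs to the
  demander itself; both are consequences of the procedure, not defects, and
  the test suite checks the exhaustion property ("no feasible pair
  remains") in that case.

Scheduling within a phase is by country index; because all offers are
posted before any acceptance, ordering matters only through the seeded
tie-break stream. Each (year, commodity) market draws its RNG from a
dedicated seed sequence, so trajectories are bit-reproducible and markets
are independent.

## Nutrition pipeline

Food supply per commodity is discounted by the household-waste fraction of
the country's region and the commodity's food group, then by the
commodity's edible fraction. The default waste table carries the
region × food-group percentages of the published global food-waste
estimates (seven regions, eleven food groups); the mapping from the 21
aggregate commodity groups onto the eleven waste groups is a documented
convention (sugar, spices, stimulants, beverages and miscellaneous map to
the low "oilseeds" rate as dry, shelf-stable goods; eggs share the milk
rate; animal fats the meat rate).

Refinable commodities (the cereal group) carry three composition variants:
unrefined, refined-unfortified and refined-fortified. A country's income
class selects its variant (low → unrefined, middle → refined fortified,
high → refined unfortified); refined variants have less fibre, fortified
variants restore micronutrients at unchanged energy. These relations are
enforced as load-time invariants.

Intake per person per day is Σ(consumed tonnes × composition per tonne) /
(population × 365). Requirements are population-share-weighted means over
the age-sex groups (default: four age bands × two sexes); the shipped
requirement table is a documented synthetic stand-in with energy rows
approximating average dietary energy requirements under physical-activity
level 1.75 and BMI 21 kg/m², and is replaceable via `requirements.csv`.
Classification: a nutrient is sufficient iff intake ≥ requirement (the
boundary counts as sufficient — a decided convention); total fat is banded
between 15% and 30% of energy (grams at 9 kcal/g) with inclusive edges and
three states (low / healthy / over). The band mechanism is generic; only
fat uses it by default.

## Synthetic worlds

The generator (`WorldGenConfig`) emulates the statistical shape of
food-balance-sheet data, not any particular year of it:

* **Scale.** Defaults 165 countries × 91 commodities, matching the
  empirical setting; tests run much smaller worlds.
* **Wealth and size.** GDP per capita log-normal (log-mean 9.0, log-sd
  1.2 → median ≈ 8 100, heavy right tail); population log-normal
  (log-mean 16, log-sd 1.5 → median ≈ 8.9 M). Income classes are
  GDP-per-capita quartiles.
* **Diets and production.** Per-commodity per-capita consumption averages
  0.5 t/person/year pooled over commodities (≈1.4 kg/day), partitioned
  log-normally; production is each country's domestic-supply demand times
  a log-normal imbalance factor (log-sd = `production_concentration`,
  default 0.8), so roughly half the countries are net importers of each
  commodity, then rescaled so global production lands within ±10% of
  global demand — both market sides always exist.
* **Trade history.** A gravity law: flow(i → j) ∝ GDP_i·GDP_j /
  distance^γ (γ = 1) with log-normal noise, scaled to pooled baseline
  imports; export and import matrices are exact transposes.
* **Intermediaries.** A configurable fraction of countries (default 10%)
  receives matched import/export re-export volumes on a tenth of
  commodities; flags are then *derived* from the flows by the 80% rule, so
  the flag and the rule cannot disagree.
* **Demographics.** Dirichlet across the eight groups with a
  younger-adult-heavy concentration vector.
* **Composition.** Per-nutrient per-tonne scales chosen so an average
  1.4 kg/day diet delivers roughly 2 500 kcal and typical nutrient
  amounts; log-normal variation across commodities.

What the generator does *not* emulate: regional diet structure (regions are
assigned uniformly), correlation between wealth and diet composition,
commodity-specific trade patterns (history is pooled over commodities, as
in the model), seasonal or within-year dynamics, and any real country's
marginals. Passing tests therefore demonstrate the *mechanics* of the
model — conservation, clearing, ranking, path dependence, recoverability
of weights — not empirical adequacy for any real food system.

`generate_observations` runs the annual cycle under known weights and
perturbs every recorded volume by a factor 1 + ε, ε uniform in ±noise,
leaving the partner set untouched; this yields ground-truthed calibration
inputs.

## Calibration

The protocol: draw n points from a three-dimensional Latin hypercube
(SciPy's sampler, one point per stratum per dimension), transform each
coordinate by w = 20^(2u−1) onto [0.05, 20] — the exponential form is
fixed by its printed range and by parity with the distance benchmark at
the design midpoint (w(0.5) = 1) — simulate each candidate over the
calibration years with several replicate seeds, and average two rates:

* **volume match**: share of observed (country, flow ∈ {import, export,
  food}, commodity, year) records with |sim − obs| ≤ 20% · obs (inclusive;
  an observed zero matches only an exact zero);
* **partner match**: share of observed (commodity, importer, exporter,
  year) pairs realized in the simulation, regardless of volume.

The Pareto front keeps points not strictly dominated on both rates
(computed by a sort-and-sweep; an O(n²) pairwise oracle cross-checks it in
tests). Selection takes the front point with the highest equal-weight mean
of the two rates; ties go to the higher partner rate, then to the
lexicographically largest weight tuple, making selection deterministic.

**Recovery experiment.** The acceptance suite generates observations from
truth (w_g, w_h, w_e) = (10, 0.3, 0.1) with 5% volume noise on 8-country ×
3-commodity worlds and calibrates with 200 design points × 5 replicates,
25 times. The 8×3 scale was chosen as the smallest at which both match
dimensions actually discriminate between candidate weights; on very small
worlds (≤3 countries) every weight vector reproduces the observations
perfectly and the experiment degenerates. The check requires GDP — the
dominant true weight — to be ranked above both other free weights in ≥80%
of repeats; truth gives no ordering between the two near-zero weights, so
none is required.

## Numerical choices

* Tonnage epsilon 1e-9: positions, offers and stocks below it count as
  exhausted; conservation identities hold to 1e-9 relative.
* Distances: haversine on a 6371 km sphere between country centroids
  (the source data's GIS layer does not name a metric; great-circle is
  reproducible and dependency-free). The distance matrix is symmetric with
  a zero diagonal.
* World serialization uses `%.17g` floats and round-trip parsing, so
  write → load → write is byte-identical.
* Seeds: every market draws from `SeedSequence((seed, year, commodity))`;
  calibration derives per-point seeds arithmetically; the same seed always
  reproduces the full trajectory.
* `max_rounds` (default 10 000) is a safety bound only; hitting it with
  feasible offers logs a warning and closes the market.

## Problem sizes

The test suite runs worlds from 2 to 30 countries and 1 to 8 commodities;
the brute-force market equivalence suite uses 100 random worlds of ≤5
countries; the ranking oracle 1 000 random candidate sets; the recovery
experiment 25 calibrations of 1 000 runs each. A full-scale default world
(165 × 91) generates in well under a second and simulates a year in a few
seconds.

## Known limitations

* No prices, tariffs, quotas or transport costs; allocation is purely
  relational.
* No within-country distribution or inequality: sufficiency compares
  national averages.
* Emergent volumes never decay, so early trades cast long shadows over
  long horizons.
* Intermediary re-export demand uses a single pooled baseline volume per
  commodity; gross transaction volume double-counts re-exported tonnes by
  construction.
* The requirement table and nutrient composition scales are synthetic
  stand-ins; conclusions about any real country require user-supplied
  tables.
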