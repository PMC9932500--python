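# Model and methods

This note documents the model that `snakesim` implements, the choices
behind its defaults, and what its synthetic inputs do and do not
represent. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from outside
the package.

## Purpose and scope

The package simulates the contact process between smallholder farmers
and three medically important snake species on a wet-zone Sri Lankan
landscape, and compares snakebite outcomes between a baseline farming
practice and a climate-adaptation strategy for each of three crops
(rice, rubber, tea). It is a mechanism-exploration tool: the question is
how a labour-reallocation strategy changes exposure, not a forecast of
absolute bite numbers. Out of scope by design: snake demography and
range shifts, envenoming severity and treatment, economic yield, and
validation against hospital records (which requires field data the
package does not ship).

## Environmental forcing

**Rainfall generator.** Daily rainfall is generated month by month in
two stages. The month's total is gamma-distributed (shape 12, i.e. CV
~0.29) around its expected value; a wet-day count is binomial around the
climatological number of rainy days; the total is split across the wet
days with a symmetric Dirichlet (concentration 3); dry days get zero. A
day is *rainy* iff its rainfall is at least `rainy_day_threshold_mm`
(default 2.5 mm, a common meteorological convention; the cited
historical definition is not reproduced in the source material). The
packaged climatology (`data/climatology_ratnapura_synthetic.csv`) is a
12-row table of Ratnapura-like monthly means — annual total ~3450 mm,
bimodal with peaks in May and October, ~211 climatological rainy days —
chosen jointly with the threshold so that a baseline rubber farmer who
taps on every non-rainy day gets roughly 150 workdays per year (the
generator realises ~157 under a neutral ENSO state, within the ±15-day
acceptance band).

**ENSO.** A synthetic Oceanic Niño Index is a sinusoid (default
amplitude 1.8, period 45 months, seeded phase) plus AR(1) noise, so a
decade spans both El Niño and La Niña phases. Rainfall responds through
a season-block sign table: Jan–Mar both phases dry; Apr–Jun El Niño wet,
La Niña dry; Jul–Sep La Niña wet, El Niño dry (September is carried with
the July–August block — the block structure otherwise skips it); Oct–Dec
El Niño wet, La Niña dry. The monthly shift is
`enso_gain × |ONI| × sign` (default gain 60 mm per ONI unit), applied
only when |ONI| ≥ 0.5 (the standard phase threshold). The expected
rainy-day count scales with the same relative shift, so ENSO also moves
the number of tappable rubber days, not just rain amounts. Note the
table is net-drying over a full cycle (Jan–Mar is negative in both
phases), so ENSO-forced decades are drier than the neutral climatology;
this asymmetry is inherited from the sign structure itself.

**Landscape.** A 50×50 grid of one-hectare cells with default class mix
rice 20%, tea 20%, rubber 20%, forest 25%, water 5%, homes 10%. Class
counts are allocated exactly (largest-remainder), and a `clustering`
parameter in [0, 1] interpolates between uniform scatter and patch
growth from random seeds. ASCII-grid I/O only.

## Snakes

Each species carries:

* **Abundance intensity** (per m², within [0, 3×10⁻⁸]) mapped to agent
  counts by a Poisson draw with a scale factor (default 300) sized so
  the default grid holds ~300 snakes — enough for non-degenerate contact
  statistics at desk scale.
* **Movement**: once per day a snake samples a destination cover class
  with probability ∝ association × class area (association weights in
  [0, 2.429]), then a uniform cell of that class. Within-day position is
  static; there is no home range.
* **Seasonal activity**: a logistic function of monthly rainfall
  (floor 0.1, ceiling 0.95, midpoint 250 mm, slope 80 mm) evaluated on
  rainfall **lagged by two months** (`activity_lag_months`). The lag
  represents the delayed numerical and functional response of snakes and
  their prey (rodents, amphibians) to monsoon rains; it places peak
  activity in July–August and December, after the May and October rain
  peaks. Months before the simulation start use the climatology means.
* **Wet-day modulation**: same-day multipliers 1.4 (rainy) / 0.8 (dry),
  clipped so the product stays in [0, 1]. Rain flushes snakes into the
  open; this is the channel through which "skip rainy days" schedules
  avoid risk.
* **Diel profile**: 24 hourly values interpreted as the propensity to be
  *encountered* active — diel activity folded with exposure — so
  daylight values stay substantial even for the nocturnal-leaning
  Russell's viper (people step on sheltering snakes). Hump-nosed viper:
  crepuscular peaks over a daytime plateau; cobra: diurnal plateau.
* **Aggressiveness** (1–10): relative propensity to bite on contact
  (hump-nosed viper 6, Russell's viper 8, cobra 5).

All species-level values are packaged configuration
(`data/species_defaults.yaml`), not field estimates: the qualitative
shape (which species is common where, who is active when) follows the
species' natural history, while the specific numbers are the package's
synthetic defaults. They were revised once during development, when
testing showed that pure diel-activity curves made every marginal
afternoon work-hour near-riskless and thereby inverted the tea
experiment's direction; the encounter-propensity framing above is the
fix, and the values have been frozen since.

## Farmers and crop scenarios

Farmers have a start hour drawn once from 4–9 AM, daily working hours in
[4, 14] (uniform 6–10 h for rice and rubber; the tea baseline fixes 6 h),
a home cell and up to three field cells of their crop; each workday they
work one of their field cells, drawn uniformly. Thirty farmers of the
focal crop populate each preset.

* **Rice** — two cultivation cycles: Maha anchored to September, Yala to
  April. A cycle is one full-presence planting month, growing months at
  15% presence (about one field day a week for weeding and water
  management, implemented as thinned days at full hours so the 4–14 h
  bound always holds), and a full-presence harvest month. Conventional
  variety: three growth months, harvest in cycle month 4; short-duration
  variety: two growth months, harvest in month 3, so each adapted cycle
  ends a month earlier. Monsoon-onset anchor shifting (first 5-day
  window accumulating 75 mm) is implemented but off by default.
* **Rubber** — baseline taps on exactly the non-rainy days; the adapted
  schedule taps every 5th day of the year irrespective of rain (73
  workdays in a normal year, 74 in a leap year, via day-of-year mod 5).
* **Tea** — baseline works every day at constant hours. The adapted rule
  adds `0.514 labour hours × plot hectares × previous-month rainfall
  (mm)` to the month's hours (the rain-yield tracking rule; slope fixed
  by the scenario), absorbed by lengthening workdays up to the 14 h
  ceiling before any capping is logged. Default plot size 0.5 ha per
  farmer, a typical smallholding.

## Contact and bites

Time advances in 1-hour steps (the coarsest step that resolves the 4–9
AM start-hour spread); snakes relocate each morning. For each co-located
(working farmer, snake) pair, each hour: the snake is active with
probability `diel(hour) × seasonal(lagged rain) × wet/dry factor`, and
an active snake bites with probability `bite_scale × aggressiveness/10`,
so the per-pair-hour bite probability is exactly the product contract
used throughout the statistics. A farmer records at most one bite per
hour (first success); partial first/last work hours carry fractional
exposure weights. `bite_scale` (default 0.04) is the one free scale of
the contact process, calibrated so a default 10-year run yields order
10²–10³ bites (`scripts/derive_bite_scale.py`); it cancels out of every
percent-change comparison.

Hours actually worked accumulate in a labour ledger; the bite log holds
(time, cell, species, farmer, scenario) per event. One seed expands into
independent substreams (climate, landscape, farmers, snakes, schedule,
contact), so paired arms share everything except the scenario, and every
run is bit-reproducible.

## Outcome statistics

* **Simulation points** are per-(replicate, year) totals: bites, hours,
  and their ratio (incidence per farmer work-hour). Yearly granularity is
  deliberate: the adaptations act by *reallocating labour across months*,
  which cancels out of any within-month bites/hours ratio; only a window
  spanning the reallocation (a year) can express it. The default
  experiment is 20 replicates × 10 years = 200 points per arm.
* **Comparisons**: Mann–Whitney U (exact for small tie-free samples,
  normal approximation with tie correction otherwise) and a percentile
  bootstrap (10,000 paired resamples) for the 99% CI of the percent
  change of the mean, `(mean_adapted − mean_baseline)/mean_baseline`.
* **ENSO regressions**: OLS of monthly bite totals (pooled across
  replicates) on the monthly ONI, fitted separately within each rainfall
  season (NEM Dec–Feb, FIM Mar–Apr, SWM May–Sep, SIM Oct–Nov); adjusted
  R² uses n−2 degrees of freedom. A constant ONI within a season is an
  error (slope unidentifiable); a constant bite series yields R² = 0.

## What the synthetic inputs do and do not show

The generator reproduces the *structure* the analysis needs — bimodal
monsoon seasonality, ENSO sign pattern, rainy-day statistics consistent
with ~150 tappable days, species-by-land-cover contrasts — but not any
particular observed decade, map or species parameterisation. Passing
tests therefore demonstrate that the mechanisms (labour reallocation ×
seasonal snake activity) produce the expected direction and rough size
of each effect under plausible conditions; they do not validate bite
numbers against real surveillance data.

Two quantitative limits are structural and worth stating plainly. First,
because incidence ≡ bites/hours, the three quantities (incidence change,
totals change, hours ratio) are linked by an exact identity; with the
rubber schedules fixed at ~150 vs 73 equal-length workdays, an incidence
increase near +30% forces a totals decrease near −45%, so the two rubber
effects cannot simultaneously sit at +33% and −17% — the simulation
reproduces the signs and the incidence magnitude, and overshoots the
totals decrease. Second, the tea totals increase scales with the
labour-hours ratio, which under the net-drying synthetic ENSO realises
~1.37–1.45; the resulting totals increase (~+39 to +45%) sits at or
below the low end of its reference band depending on the ENSO
realisation.

## Numerical and degenerate-input conventions

Probabilities are clipped to [0, 1] after the wet/dry multiplier; a
month with positive expected rain but a zero binomial wet-day draw gets
one wet day; a zero-expectation species population warns and returns an
empty list; a comparison whose baseline arm has zero mean bites is
rejected rather than reported; landscape class counts guarantee at least
one cell for any positive requested fraction. Leap days are simulated
(366-day years; 74 adapted tapping days). All generators accept either a
seed or a `numpy.random.Generator`.
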