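# Methods

## The estimation problem

Two municipal street-tree censuses, taken about a decade apart, each record
(ZIP, street address, species common name, DBH in whole inches, survey
condition fields). Coordinates in the older snapshot are unreliable, so
re-identification must come from the fields themselves. The package treats the
triple (ZIP, normalized address, normalized species) as the identity key:
exact equality, no fuzzy matching, no coordinate fallback. ZIP is part of the
key because street names and building numbers repeat across a city.

### Normalization

Addresses are uppercased; punctuation is removed except the hyphen in numeric
building ranges ("45-47"), which separates distinct addresses and must
survive; abbreviations are expanded through an explicit rule table shipped as
versioned data (`data/address_abbreviations.csv`); ordinal suffixes are
stripped from numerics (120TH → 120); whitespace is collapsed. The transform
is idempotent (property-tested). Species names fold through a many-to-one
variant dictionary (`data/species_dictionary.csv`) onto canonical common
names; unmapped names are kept verbatim, flagged, and excluded from linkage
(species equality is part of the identification claim — failing safe beats
matching wrongly). Both tables are configuration: they are *a* reasonable
vocabulary, not a reconstruction of any particular city's, and swapping them
adapts the pipeline.

### Linkage

Within each census, every key with multiplicity ≥ 2 is wholly removed — two
same-species trees at one address cannot be told apart a decade later.
Uniqueness is enforced per census *independently*: a key duplicated in one
year is dropped from both sides. The remaining keys are inner-joined
one-to-one. The step is symmetric in its inputs and keeps a full count
partition (unmapped / non-unique / matched / unmatched per census).

### Growth and QC

Growth is the integer DBH difference; the rate divides by exactly 10 years
even though real survey waves straddle two calendar years — the key-based
design cannot date individual visits, and the bias is < 10%. With whole-inch
DBH all rates are multiples of 0.1 in/yr.

The cleaning cascade runs in a fixed, enforced order:

| stage | rule | default | rationale |
|---|---|---|---|
| 5a | drop growth < cutoff | −5 in | replacements/gross errors; −5 kept as plausible error |
| 5b | drop DBH_early < min or > max | [1, 40] in | rounded-down saplings; implausible giants |
| 5c | per 1-inch DBH_early bin, trim `floor(f·n)` per tail | f = 0.05 | size-conditional outliers |

Tail-trim counts use floor; ties break on record id, so removal is
deterministic. Every record keeps a `qc_status` rather than being deleted, so
the accounting always partitions. Filters are idempotent; running a stage
before its predecessors is a hard error.

Validation statistics for repeatedly measured trees: Theil–Sen slope (median
of pairwise slopes; delegated to `scipy.stats.theilslopes` and property-tested
against brute-force enumeration) and Kendall tau-b (`scipy.stats.kendalltau`;
the b variant because whole-inch ties are common).

## Spatial covariates

Geometry arrives pre-projected in a planar metre CRS; the package never
reprojects. The street orientation is the length-weighted *axial* mean of the
centerline's edge bearings via angle doubling (mod 180°; 10° and 170° average
to 0°, not 90°) — axial, because "side of the street" is axis-relative. The
roadside quadrant splits at 45°: streets within 45° of the east–west axis
(boundary inclusive) assign North/South by the offset's northing, otherwise
East/West by its easting; a zero deciding component resolves North/East.
These tie rules are fixed conventions chosen for determinism — the original
GIS implementations leave them unstated. Nearest-segment search uses an
STRtree with a 100 m default radius (ties → lowest segment id); point-in-
polygon joins treat boundary points as inside (ties → lowest zone id). All
three primitives are tested against brute-force scans on random scenes.
Zone aggregation reports per-zone mean rate, mean DBH, count and density, and
drops zones below a minimum tree count or on an explicit exclusion list, with
reasons logged.

## Statistical layer

Continuous predictors are standardized by subtracting the mean and dividing
by **twice** the sample SD (n−1 denominator), putting their coefficients on
the scale of a binary indicator flip. The species factor keeps the 15 most
abundant species and pools the rest into the reference level "other"; if the
pool would be empty (fewer distinct species than the cutoff) the most
abundant species becomes the reference instead. Declared reference levels:
tree guards "Harmful", surveyor class "NYC Parks Staff"; all other factors
default to the alphabetically first level, stated in the output. Complete
cases only, with counts reported. Non-significant controlled terms stay in
the model.

GVIF uses the Fox–Monette determinant-ratio construction on the predictor
correlation matrix; for a one-column term it reduces to 1/(1−R²), which the
tests verify directly. `GVIF^(1/(2df))` is reported for cross-term
comparability.

Group comparisons: two levels → Student's t-test; three or more → one-way
ANOVA with Tukey HSD (studentized range); the significance structure is
summarized as a compact letter display built by insert–absorb. No
multiple-testing correction is applied across factors, only Tukey within a
factor. Levels with fewer than two observations are excluded with a warning.

The SVI analysis refits the model **without** the borough factor (an
arbitrary spatial correction that would absorb exactly the geographic signal
under study), averages tree-level residuals by ZIP zone, and regresses the
zone-mean residual on the zone-mean SVI, unweighted by default (a
tree-count-weighted variant is a flag). SVI itself is never a model term —
the `ModelSpec` constructor rejects it.

## The synthetic city

The generator is the package's ground-truth instrument, not a fixture. It
emulates, with one knob each, the processes that make decadal census pairs
hard:

* **demography** — i.i.d. 4.4%/yr mortality with immediate same-species
  sapling replacement (DBH ~ U(1, 3) in). Replacement at the same key is the
  linkage method's one systematic failure mode, and the generator makes it
  measurable. Expected ten-year survival is (1−0.044)^10 ≈ 64%.
* **growth** — per-tree linear truth: rate ~ N(species mean, 0.21 in/yr),
  clipped at 0, plus a size penalty (−0.008 in/yr per inch of starting DBH
  above the species mean), optional categorical effects (defaults: health
  Good +0.02 / Fair −0.03 / Poor −0.08; harmful guards −0.02 in/yr), and an
  SVI boost (default 0.05 in/yr per unit tract SVI). Linear truth is
  deliberate: decadal differencing cannot identify curvature. The species
  table (name, frequency, mean starting DBH, mean rate) mirrors the species
  mix and per-species growth rates observed for New York City street trees
  for the 15 leading species, plus an invented minor-species tail so
  abundance pooling has something to pool.
* **observation** — reported DBH = round(true + N(0, σ)) with σ = 0.5 in per
  surveyor class; with probability 0.002 the record is the rounded
  *circumference* (π·DBH); with probability 0.001 a trailing digit drops
  (10 → 1). Those error rates are nominal: real instances are documented but
  their rates are not, so the defaults are order-of-magnitude choices.
  Addresses and species are re-rendered through the inverse of the
  normalization tables (abbreviations, punctuation, case), so the cleaning
  stage faces realistic raw text. 8% of addresses hold a same-species
  duplicate. Surveyor classes mix 32/42/26% volunteer/hired/parks citywide,
  with volunteers concentrated in the dense first fifth of ZIPs to reproduce
  the volunteer–geography confound; only the late census records the class.
* **geometry** — square ZIP cells (2 km) on a grid, each with ~8 named
  streets (a quarter vertical), 2×2 census tracts (SVI ~ U(0.02, 1),
  log-normal population density) and 8×8 parcels (categorical land use,
  log-normal built FAR).

Everything is deterministic given the seed, byte for byte. The default scale
is 200 streets × 250 addresses ≈ 50,000 originally planted trees.

Scoring: linkage precision/recall against identity labels (recall's
denominator is the persisting trees whose key is unique in both snapshots —
what the method could possibly find), with every false match attributed to
its cause in the event log; rate-recovery bias/RMSE per species over the
correctly matched retained trees, which isolates measurement and rounding
error from selection effects.

### What the generator does not emulate

No spatial ecology (competition, shading), no climate forcing, no
growth-curve nonlinearity, no removal-without-replacement, and replacement is
*always* same-species — which overstates the false-match rate relative to a
real city, where removed trees are often not replaced or replaced with a
different species. Passing recovery tests therefore shows the pipeline is
correct under these processes, not that any real census meets them. Two
visible consequences on default synthetic runs: small-tree replacements that
pass the −5 in cutoff dilute species means and attenuate the fitted species
effects, and they null out the raw size–growth correlation (truth ≈ −0.33)
even though correctly matched pairs preserve it (≈ −0.31).

## Numerical choices and degenerate inputs

DBH cells parse to integers; exact decimals ("6.0") truncate, fractional
values reject the row. Empty addresses/species reject with reason codes.
Theil–Sen requires ≥ 2 points with distinct times; tau is undefined (NaN)
below 3 points. The directional mean returns undefined on a vanishing
resultant (length tolerance 1e−9 of total length). Standardization refuses
constant vectors; the OLS refuses rank-deficient designs and names the
collinearity. Zone aggregation refuses zero-area zones; the SVI regression
requires ≥ 3 surviving zones. CSV artifacts are read with "None" preserved as
a categorical level (it is a real tree-guard value), only empty cells are
missing.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: the full
pipeline and linkage scoring run on the ≈50,000-tree default city; recovery
and power checks use 60-street cities (≈6,000 addresses) with 100 replicates
for the positive-SVI detection check and 30 for the null; the Tukey type-I
simulation uses 1,000 replicates of 3×20 observations. These sizes were
chosen to give comfortable Monte-Carlo margins at interactive runtimes.

## Known limitations

* Linkage precision is structurally < 1 under replacement; the package
  reports it rather than hiding it, and the QC cascade only removes the
  large-swap class.
* Serial plantings of one species along a street remove whole blocks of
  trees from the sample (the `duplicate_series_prob` knob exposes the
  mechanism); densely built areas with few addresses are similarly
  under-sampled. Both are selection effects the key design cannot avoid.
* The trim stage is distribution-agnostic: with heavy true skew it removes
  real signal along with errors.
* The abbreviation table and species dictionary are declared stand-ins; on
  real data their coverage, not the algorithm, usually binds recall.
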