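# treegrowth — street-tree growth rates from paired decadal censuses, without coordinates

Decadal street-tree censuses record every tree's species, street address and
diameter at breast height (DBH, whole inches), but older snapshots often carry
unreliable map coordinates, so the same physical tree cannot be re-identified
by location. `treegrowth` implements a coordinate-free alternative: link each
tree across two snapshots taken ten years apart by the deterministic key

```
(ZIP code, normalized street address, normalized species common name)
```

dropping any key that is not unique within a census, and estimate the
individual decadal growth rate

```
rate = (DBH_late − DBH_early) / 10   [in/yr]
```

through a staged quality-control cascade:

* **5a** drop growth < −5 in (same-species sapling replacements and gross
  errors; −5 itself is kept as plausible measurement error),
* **5b** drop first-census DBH = 0 or ≥ 41 in,
* **5c** within each 1-inch first-census DBH bin, trim the 5% smallest and 5%
  largest growths (smaller trees grow faster, so outliers are judged within
  size class).

On top of the cleaned rates the package provides the determinants analysis:
group comparisons (t-test / one-way ANOVA with Tukey HSD and compact letter
displays), a Pearson screen of continuous covariates, an OLS of growth rate on
species, survey condition and urban-form terms with all continuous predictors
standardized to mean 0 / SD 0.5 (divide by **two** standard deviations, so
coefficients are comparable to binary indicators), generalized variance
inflation factors (GVIF) for collinearity, and a residual analysis that
regresses zone-mean model residuals on the zone-mean social vulnerability
index (SVI — deliberately **never** a model term). Validation statistics for
repeatedly measured trees (Theil–Sen slope, Kendall tau-b) are included.

Because real census releases cannot ship with the package, a first-class
**synthetic city generator** (`treegrowth.synthetic`) produces paired
snapshots with full ground truth — true per-tree growth rates, identity
labels, mortality with same-species sapling replacement, whole-inch rounding,
circumference-for-diameter and dropped-digit entry errors, free-text address
variants, and three surveyor classes — so linkage precision/recall and rate
recovery can be scored exactly.

## Who this is for

Urban-forestry and environmental-health researchers working with repeated
municipal tree inventories (or any paired entity censuses keyed by address),
who need individual growth estimates, their determinants, and an honest
account of what deterministic record linkage can and cannot recover.

## Worked example

```python
from treegrowth import pipeline
from treegrowth.determinants import ModelSpec
from treegrowth.synthetic import CityConfig, generate_city, evaluate_linkage

city = generate_city(CityConfig(seed=1))          # ~54,000 trees
res = pipeline.run_from_frames(
    city.observe_census("early"), city.observe_census("late"),
    model=ModelSpec(),
    segments=city.segments, segment_props=city.segment_props,
    zone_layers=city.layers,
)
s = res.summary
print(f"retained {s.n_retained}, mean rate {s.mean_rate:.3f}±{s.sd_rate:.3f} in/yr")
ev = evaluate_linkage(res.pairs, city.truth)
print(f"linkage precision {ev.precision:.3f}, recall {ev.recall:.3f}")
```

prints (seed 1):

```
retained 31593, mean rate 0.227±0.264 in/yr
linkage precision 0.638, recall 1.000
```

Reading: of 53,874 records per snapshot, 46,126 form unique-key pairs, and
31,593 survive QC with a mean growth rate of 0.227 in/yr. Recall is perfect —
every persisting unique-keyed tree is found — but precision is 0.638: under
the city's 4.4%/yr mortality with same-species sapling replacement, about a
third of the decade's pairs silently swap in a replacement tree at the same
key. That is the method's designed blind spot; the −5 in cutoff (stage 5a)
removes the large mature-to-sapling swaps downstream, while small-tree swaps
survive and dilute species means — the generator makes that cost measurable
(per-species recovery bias over correctly matched trees is ≈ 0.000, RMSE
≈ 0.081 in/yr).

The same flow is scripted end to end in `analysis/01…05` (simulate → link/QC →
determinants OLS → SVI residuals → ground-truth scoring); each step prints
its findings and writes small tables under `results/`. The cascade is also
available as a CLI: `treegrowth simulate|clean|link|qc|covariates|fit|residuals|run-all`.

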