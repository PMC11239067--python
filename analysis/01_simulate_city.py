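#!/usr/bin/env python
"""Generate the default synthetic city and write its observable artifacts.

Emits the two raw census snapshots (ten simulated years apart), the street
centerline and zone GeoJSON layers, and the ground-truth table. Bulky data
goes to scratch/city/; a small config echo and cohort summary go to results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from treegrowth import spatial
from treegrowth.synthetic import CityConfig, generate_city, survival_fraction

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cfg = CityConfig(seed=SEED)
    city = generate_city(cfg)
    out = ROOT / "scratch" / "city"
    out.mkdir(parents=True, exist_ok=True)

    early = city.observe_census("early")
    late = city.observe_census("late")
    early.to_csv(out / "census_early.csv", index=False)
    late.to_csv(out / "census_late.csv", index=False)
    spatial.write_geojson_layer(out / "streets.geojson", city.segments, city.segment_props)
    for name, (geoms, props) in city.layers.items():
        spatial.write_geojson_layer(out / f"{name}s.geojson", geoms, props)
    city.truth.to_csv(out / "ground_truth.csv", index=False)

    t0 = city.truth[city.truth["present_t0"]]
    survived = int(t0["death_year"].isna().sum())
    summary = {
        "seed": SEED,
        "n_identities": len(city.truth),
        "n_census_early": len(early),
        "n_census_late": len(late),
        "n_survived": survived,
        "observed_survival_frac": survived / len(t0),
        "expected_survival_frac": survival_fraction(cfg.annual_mortality, cfg.years),
        "n_replacement_identities": int((city.truth["predecessor"].notna()).sum()),
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    with open(res / "city_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(f"city seed {SEED}: {len(early)} early records, {len(late)} late records")
    print(
        f"survival over {cfg.years} yr: observed {summary['observed_survival_frac']:.3f}, "
        f"expected {summary['expected_survival_frac']:.3f}"
    )
    print(f"wrote censuses + layers to {out}, summary to {res/'city_summary.json'}")


if __name__ == "__main__":
    main()
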