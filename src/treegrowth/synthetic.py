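"""A synthetic street-tree city with known ground truth.

The generator lays a grid city: square ZIP cells, each holding a handful of
named streets; every street carries evenly spaced addresses and each address
one tree (occasionally two of the same species — the "planted in series"
failure mode that linkage must drop). Trees grow linearly at a per-tree true
rate drawn around a species mean; every year each tree dies with a fixed
probability and is immediately replaced by a same-species sapling, which is
exactly the event that shows up downstream as a large negative growth.

Two census snapshots ten years apart are *observed* from the evolved city
with the error taxonomy of real decadal surveys: whole-inch rounding of DBH,
surveyor measurement noise, occasional circumference-recorded-as-diameter
errors, occasional dropped trailing digits (10 -> 1), and free-text address
and species spellings drawn from the inverse of the normalization rule
tables. Zone layers (ZIP cells, census tracts with SVI and population
density, parcels with land use and built FAR) and street centerlines are
emitted as planar GeoJSON.

Everything is deterministic given the seed; the ground-truth table carries
every identity, true rate, event and engineered error, so linkage precision/
recall and rate-recovery bias can be scored exactly.

Default scale and rates: species frequencies, mean first-census DBH and mean
growth rates mirror the species mix and per-species growth rates observed for
New York City street trees; annual mortality 4.4%; the surveyor mix is
volunteer/hired-staff/parks-staff = 32/42/26% with volunteers concentrated in
the dense "Manhattan-like" ZIPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

__all__ = [
    "SpeciesSpec",
    "CityConfig",
    "SyntheticCity",
    "generate_city",
    "survival_fraction",
    "evaluate_linkage",
    "evaluate_recovery",
    "LinkageEvaluation",
    "RecoveryReport",
    "DEFAULT_SPECIES",
]


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    frequency: float
    rate_mean: float  # in/yr
    rate_sd: float  # in/yr
    dbh_mean: float  # inches, first-census size


def _default_species() -> tuple[SpeciesSpec, ...]:
    rows = [
        # (name, abundance, mean dbh_05 in, mean rate in/yr)
        ("London Planetree", 32058, 22.5, 0.163),
        ("Honeylocust", 15974, 9.1, 0.356),
        ("Callery Pear", 15903, 6.6, 0.334),
        ("Norway Maple", 13149, 13.4, 0.174),
        ("Pin Oak", 11563, 16.8, 0.352),
        ("Littleleaf Linden", 6343, 9.7, 0.318),
        ("Ginkgo", 5518, 9.0, 0.257),
        ("Green Ash", 4893, 10.9, 0.366),
        ("Red Maple", 4116, 10.1, 0.273),
        ("Silver Maple", 3948, 20.4, 0.265),
        ("Japanese Zelkova", 3643, 8.2, 0.425),
        ("Sweetgum", 2620, 11.0, 0.308),
        ("Silver Linden", 1149, 6.7, 0.510),
        ("Northern Red Oak", 1026, 12.7, 0.375),
        ("American Linden", 868, 10.8, 0.399),
        # a minor-species tail so the abundance-pooled "other" reference level
        # is populated, as in a real census with a long species tail
        ("Willow Oak", 600, 10.0, 0.40),
        ("Sophora", 550, 9.5, 0.29),
        ("Cherry", 500, 8.0, 0.25),
        ("Crabapple", 450, 7.0, 0.22),
        ("Hedge Maple", 400, 7.5, 0.20),
        ("White Oak", 350, 14.0, 0.30),
        ("American Elm", 300, 18.0, 0.35),
        ("Black Locust", 250, 12.0, 0.32),
    ]
    total = sum(n for _, n, _, _ in rows)
    return tuple(
        SpeciesSpec(name, n / total, rate, 0.21, dbh) for name, n, dbh, rate in rows
    )


DEFAULT_SPECIES = _default_species()

_STREET_WORDS = [
    "MAPLE", "OAK", "ELM", "CEDAR", "WALNUT", "CHESTNUT", "WILLOW", "BIRCH",
    "SPRUCE", "LAUREL", "MAGNOLIA", "SYCAMORE", "HOLLY", "ASPEN", "LINDEN",
    "HAWTHORN", "POPLAR", "MULBERRY", "JUNIPER", "DOGWOOD", "HICKORY",
    "CYPRESS", "ALDER", "LOCUST", "CATALPA", "BEECH", "SASSAFRAS", "SUMAC",
    "TULIP", "PAWPAW", "BUCKEYE", "HORNBEAM", "REDBUD", "SERVICEBERRY",
    "PERSIMMON", "HACKBERRY", "IRONWOOD", "BASSWOOD", "TAMARACK", "LARCH",
]
_STREET_TYPES = ["STREET", "AVENUE", "ROAD", "BOULEVARD", "PLACE", "DRIVE",
                 "LANE", "TERRACE"]

# inverse of the normalization rule table: canonical token -> raw spellings
_INVERSE_TOKENS = {
    "STREET": ["ST", "ST.", "STREET", "Street", "St."],
    "AVENUE": ["AVE", "AVE.", "AVENUE", "Avenue", "Ave."],
    "ROAD": ["RD", "RD.", "ROAD", "Road"],
    "BOULEVARD": ["BLVD", "BLVD.", "BOULEVARD", "Blvd."],
    "PLACE": ["PL", "PL.", "PLACE", "Place"],
    "DRIVE": ["DR", "DR.", "DRIVE", "Drive"],
    "LANE": ["LN", "LN.", "LANE", "Lane"],
    "TERRACE": ["TER", "TERR", "TERRACE", "Terrace"],
    "NORTH": ["N", "N.", "NORTH", "North"],
    "SOUTH": ["S", "S.", "SOUTH", "South"],
    "EAST": ["E", "E.", "EAST", "East"],
    "WEST": ["W", "W.", "WEST", "West"],
}

_BOROUGHS = ["Manhattan", "Bronx", "Brooklyn", "Queens", "Staten Island"]


@dataclass
class CityConfig:
    """Generative conditions of the synthetic city (see module docstring)."""

    seed: int = 0
    n_streets: int = 200
    addresses_per_street: int = 250
    n_zips: int = 25
    species: tuple = DEFAULT_SPECIES
    annual_mortality: float = 0.044
    replacement_dbh_range: tuple = (1.0, 3.0)
    duplicate_series_prob: float = 0.08
    circumference_error_prob: float = 0.002
    digit_error_prob: float = 0.001
    surveyor_mix: dict = field(
        default_factory=lambda: {
            "Volunteer": 0.32,
            "TreesCount Staff": 0.42,
            "NYC Parks Staff": 0.26,
        }
    )
    surveyor_sd: dict = field(
        default_factory=lambda: {
            "Volunteer": 0.5,
            "TreesCount Staff": 0.5,
            "NYC Parks Staff": 0.5,
        }
    )
    #: measurement noise SD (inches) for the early census, which has no
    #: recorded surveyor class
    early_measurement_sd: float = 0.5
    svi_effect: float = 0.05  # in/yr of extra growth per unit tract SVI
    size_effect_per_in: float = -0.008  # in/yr per inch of DBH above species mean
    covariate_effects: dict = field(
        default_factory=lambda: {
            "health": {"Good": 0.02, "Fair": -0.03, "Poor": -0.08},
            "guards": {"Harmful": -0.02},
        }
    )
    years: int = 10
    zip_cell_m: float = 2000.0

    def __post_init__(self) -> None:
        freqs = [s.frequency for s in self.species]
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("species frequencies must sum to 1")
        for p in (
            self.annual_mortality,
            self.duplicate_series_prob,
            self.circumference_error_prob,
            self.digit_error_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_streets < 1 or not self.species:
            raise ValueError("need at least one street and one species")


def survival_fraction(annual_mortality: float, years: int) -> float:
    """Fraction of a cohort still standing after ``years`` of i.i.d. mortality."""
    if not 0.0 <= annual_mortality <= 1.0:
        raise ValueError("annual_mortality must lie in [0, 1]")
    if years < 0:
        raise ValueError("years must be >= 0")
    return (1.0 - annual_mortality) ** years


@dataclass
class SyntheticCity:
    """The generated city: truth table, street and zone geometry."""

    cfg: CityConfig
    truth: pd.DataFrame = field(repr=False)
    segments: list = field(repr=False)
    segment_props: list = field(repr=False)
    layers: dict = field(repr=False)  # name -> (geoms, props)

    def zones_frame(self, layer: str = "zip") -> pd.DataFrame:
        geoms, props = self.layers[layer]
        rows = []
        for g, p in zip(geoms, props):
            row = dict(p)
            row["area_km2"] = g.area / 1e6
            rows.append(row)
        return pd.DataFrame(rows)

    def observe_census(self, which: str) -> pd.DataFrame:
        """Emit one census snapshot ('early' or 'late') as raw records."""
        return _observe(self, which)


def _zip_codes(n: int) -> list[str]:
    return [f"{10001 + i:05d}" for i in range(n)]


def generate_city(cfg: CityConfig) -> SyntheticCity:
    """Build the city and evolve it one decade. Deterministic given the seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    zips = _zip_codes(cfg.n_zips)
    grid = math.ceil(math.sqrt(cfg.n_zips))
    W = cfg.zip_cell_m
    n_manhattan = max(1, cfg.n_zips // 5)
    borough_of = {
        z: _BOROUGHS[min(4, i * 5 // cfg.n_zips)] for i, z in enumerate(zips)
    }

    zip_cells = {}
    for i, z in enumerate(zips):
        r, c = divmod(i, grid)
        zip_cells[z] = (c * W, r * W)

    # streets
    per_zip = {z: 0 for z in zips}
    segments, seg_props, street_rows = [], [], []
    for i in range(cfg.n_streets):
        z = zips[i % cfg.n_zips]
        k = per_zip[z]
        per_zip[z] += 1
        word = _STREET_WORDS[k % len(_STREET_WORDS)]
        stype = _STREET_TYPES[(k // len(_STREET_WORDS)) % len(_STREET_TYPES)]
        name = f"{word} {stype}"
        x0, y0 = zip_cells[z]
        n_in_zip = cfg.n_streets // cfg.n_zips + 1
        offset = (k + 1) * W / (n_in_zip + 1)
        vertical = k % 4 == 3
        if vertical:
            line = LineString([(x0 + offset, y0), (x0 + offset, y0 + W)])
        else:
            line = LineString([(x0, y0 + offset), (x0 + W, y0 + offset)])
        width = float(np.clip(rng.normal(34.0, 10.0), 12.0, 90.0))
        segments.append(line)
        seg_props.append({"segment_id": i, "st_width": round(width, 1)})
        street_rows.append((i, z, name, vertical, x0, y0, offset))

    # zone layers
    zip_geoms = [box(x, y, x + W, y + W) for x, y in zip_cells.values()]
    zip_props = [{"zone_id": z} for z in zips]

    tract_geoms, tract_props = [], []
    for zi, z in enumerate(zips):
        x0, y0 = zip_cells[z]
        dense = zi < n_manhattan
        for r in range(2):
            for c in range(2):
                tract_geoms.append(
                    box(x0 + c * W / 2, y0 + r * W / 2,
                        x0 + (c + 1) * W / 2, y0 + (r + 1) * W / 2)
                )
                dens = float(rng.lognormal(math.log(30000.0), 0.8))
                tract_props.append(
                    {
                        "zone_id": f"{z}-T{r}{c}",
                        "svi": round(float(rng.uniform(0.02, 1.0)), 3),
                        "pop_density": round(dens * (3.0 if dense else 1.0), 1),
                    }
                )

    parcel_geoms, parcel_props = [], []
    land_uses = ["Multifamily", "Single family", "non-res", "open&rec"]
    for zi, z in enumerate(zips):
        x0, y0 = zip_cells[z]
        dense = zi < n_manhattan
        for r in range(8):
            for c in range(8):
                parcel_geoms.append(
                    box(x0 + c * W / 8, y0 + r * W / 8,
                        x0 + (c + 1) * W / 8, y0 + (r + 1) * W / 8)
                )
                lu = land_uses[rng.choice(4, p=[0.45, 0.25, 0.2, 0.1])]
                far = float(rng.lognormal(0.0, 0.8)) * (3.0 if dense else 1.0)
                parcel_props.append(
                    {
                        "zone_id": f"{z}-P{r}{c}",
                        "land_use": lu,
                        "builtFAR": round(far, 2),
                    }
                )

    # trees: one per address slot, sometimes a same-species duplicate
    addr_rows = []
    for sid, z, name, vertical, x0, y0, offset in street_rows:
        for j in range(cfg.addresses_per_street):
            along = (j + 0.5) * W / cfg.addresses_per_street
            side = 1 if rng.random() < 0.5 else -1
            perp = float(rng.uniform(4.0, 9.0)) * side
            if vertical:
                x, y = x0 + offset + perp, y0 + along
            else:
                x, y = x0 + along, y0 + offset + perp
            addr_rows.append((sid, z, f"{j + 1} {name}", x, y))
    addr = pd.DataFrame(addr_rows, columns=["segment_id", "zip", "address", "x", "y"])

    dup = rng.random(len(addr)) < cfg.duplicate_series_prob
    dup_frame = addr.loc[dup].copy()
    # a duplicate stands a couple of metres from its sibling
    dup_frame["x"] = dup_frame["x"] + rng.uniform(1.0, 3.0, len(dup_frame))
    dup_frame["is_duplicate"] = True
    addr["is_duplicate"] = False
    trees = pd.concat([addr, dup_frame], ignore_index=True)
    # the duplicate must share its sibling's species: assign per address slot
    n_addr = len(addr)
    freqs = np.array([s.frequency for s in cfg.species])
    sp_idx_addr = rng.choice(len(cfg.species), size=n_addr, p=freqs)
    sp_idx = np.concatenate([sp_idx_addr, sp_idx_addr[dup]])
    trees["species_idx"] = sp_idx
    trees["species"] = [cfg.species[i].name for i in sp_idx]
    n = len(trees)
    trees["identity"] = [f"I{i:06d}" for i in range(n)]
    trees["borough"] = trees["zip"].map(borough_of)

    # zone membership from construction geometry (no polygon join needed here)
    cell_x = np.array([zip_cells[z][0] for z in trees["zip"]])
    cell_y = np.array([zip_cells[z][1] for z in trees["zip"]])
    tr = np.minimum(((trees["y"].values - cell_y) // (W / 2)).astype(int), 1)
    tc = np.minimum(((trees["x"].values - cell_x) // (W / 2)).astype(int), 1)
    trees["tract_id"] = [f"{z}-T{r}{c}" for z, r, c in zip(trees["zip"], tr, tc)]
    pr = np.minimum(((trees["y"].values - cell_y) // (W / 8)).astype(int), 7)
    pc = np.minimum(((trees["x"].values - cell_x) // (W / 8)).astype(int), 7)
    trees["parcel_id"] = [f"{z}-P{r}{c}" for z, r, c in zip(trees["zip"], pr, pc)]
    tract_lookup = {p["zone_id"]: p for p in tract_props}
    parcel_lookup = {p["zone_id"]: p for p in parcel_props}
    trees["svi"] = [tract_lookup[t]["svi"] for t in trees["tract_id"]]
    trees["pop_density"] = [tract_lookup[t]["pop_density"] for t in trees["tract_id"]]
    trees["land_use"] = [parcel_lookup[t]["land_use"] for t in trees["parcel_id"]]
    trees["builtFAR"] = [parcel_lookup[t]["builtFAR"] for t in trees["parcel_id"]]

    # survey-style categorical attributes (drawn once, surveyed in the late census)
    trees["health"] = rng.choice(["Good", "Fair", "Poor"], size=n, p=[0.8, 0.15, 0.05])
    trees["steward"] = rng.choice(
        ["None", "1or2", "3or4", "4orMore"], size=n, p=[0.62, 0.28, 0.07, 0.03]
    )
    trees["guards"] = rng.choice(
        ["None", "Helpful", "Harmful", "Unsure"], size=n, p=[0.75, 0.12, 0.08, 0.05]
    )
    trees["sidewalk"] = rng.choice(["NoDamage", "Damage"], size=n, p=[0.72, 0.28])
    trees["curb_loc"] = rng.choice(["OnCurb", "OffsetFromCurb"], size=n, p=[0.96, 0.04])
    for col in ("root_blocked", "trunk_altered", "branch_problems"):
        trees[col] = rng.choice(["No", "Yes"], size=n, p=[0.9, 0.1])

    # true size and growth
    sp_dbh = np.array([cfg.species[i].dbh_mean for i in sp_idx])
    sp_rate = np.array([cfg.species[i].rate_mean for i in sp_idx])
    sp_sd = np.array([cfg.species[i].rate_sd for i in sp_idx])
    shape = (1.0 / 0.45) ** 2  # gamma with CV 0.45 around the species mean
    dbh0 = rng.gamma(shape, sp_dbh / shape)
    dbh0 = np.clip(dbh0, 0.2, 48.0)
    trees["dbh_t0"] = dbh0

    effect = np.zeros(n)
    for factor, levels in cfg.covariate_effects.items():
        if factor in trees.columns:
            effect += trees[factor].map(lambda v: levels.get(v, 0.0)).values
    rate = (
        rng.normal(sp_rate, sp_sd)
        + cfg.size_effect_per_in * (dbh0 - sp_dbh)
        + effect
        + cfg.svi_effect * trees["svi"].values
    )
    trees["true_rate"] = np.clip(rate, 0.0, None)

    # mortality with immediate same-species sapling replacement
    truth = trees.copy()
    truth["present_t0"] = True
    truth["predecessor"] = None
    truth["birth_year"] = 0
    cohort = truth
    all_frames = []
    gen = 0
    while len(cohort) > 0:
        m = cfg.annual_mortality
        if m > 0:
            death_wait = rng.geometric(m, size=len(cohort))
        else:
            death_wait = np.full(len(cohort), cfg.years + 1)
        death_year = cohort["birth_year"].values + death_wait
        dies = death_year <= cfg.years
        cohort = cohort.copy()
        cohort["death_year"] = np.where(dies, death_year, np.nan)
        cohort["event"] = np.where(
            dies, "replaced", "replacement" if gen > 0 else "survived"
        )
        cohort.loc[dies, "event"] = "replaced"
        all_frames.append(cohort)
        dead = cohort.loc[dies]
        if len(dead) == 0:
            break
        gen += 1
        repl = dead.copy()
        repl["identity"] = [f"R{gen}{i:06d}" for i in range(len(repl))]
        repl["predecessor"] = dead["identity"].values
        repl["birth_year"] = dead["death_year"].values.astype(int)
        repl["present_t0"] = False
        lo, hi = cfg.replacement_dbh_range
        repl["dbh_t0"] = np.nan
        repl["dbh_birth"] = rng.uniform(lo, hi, len(repl))
        sp_idx_r = repl["species_idx"].values
        sp_rate_r = np.array([cfg.species[i].rate_mean for i in sp_idx_r])
        sp_sd_r = np.array([cfg.species[i].rate_sd for i in sp_idx_r])
        sp_dbh_r = np.array([cfg.species[i].dbh_mean for i in sp_idx_r])
        eff_r = np.zeros(len(repl))
        for factor, levels in cfg.covariate_effects.items():
            if factor in repl.columns:
                eff_r += repl[factor].map(lambda v: levels.get(v, 0.0)).values
        r_rate = (
            rng.normal(sp_rate_r, sp_sd_r)
            + cfg.size_effect_per_in * (repl["dbh_birth"].values - sp_dbh_r)
            + eff_r
            + cfg.svi_effect * repl["svi"].values
        )
        repl["true_rate"] = np.clip(r_rate, 0.0, None)
        cohort = repl

    truth = pd.concat(all_frames, ignore_index=True)
    if "dbh_birth" not in truth.columns:
        truth["dbh_birth"] = np.nan
    truth["dbh_birth"] = truth["dbh_birth"].fillna(truth["dbh_t0"])
    truth["present_t10"] = truth["death_year"].isna()
    # continuous true DBH at the two census instants
    truth["dbh_t10"] = np.where(
        truth["present_t10"],
        truth["dbh_birth"] + (cfg.years - truth["birth_year"]) * truth["true_rate"],
        np.nan,
    )

    layers = {
        "zip": (zip_geoms, zip_props),
        "tract": (tract_geoms, tract_props),
        "parcel": (parcel_geoms, parcel_props),
    }
    return SyntheticCity(cfg, truth, segments, seg_props, layers)


def _format_address(canonical: str, rng: np.random.Generator) -> str:
    """Re-render a canonical address with raw-survey formatting noise."""
    tokens = canonical.split()
    out = []
    for tok in tokens:
        if tok in _INVERSE_TOKENS and rng.random() < 0.7:
            variants = _INVERSE_TOKENS[tok]
            tok = variants[rng.integers(len(variants))]
        out.append(tok)
    s = " ".join(out)
    style = rng.random()
    if style < 0.25:
        s = s.title()
    elif style < 0.35:
        s = s.lower()
    return s


def _observe(city: SyntheticCity, which: str) -> pd.DataFrame:
    cfg = city.cfg
    if which == "early":
        t, stream, prefix = 0, 1, "E"
    elif which == "late":
        t, stream, prefix = cfg.years, 2, "L"
    else:
        raise ValueError("which must be 'early' or 'late'")
    rng = np.random.default_rng([cfg.seed, stream])
    present = city.truth["present_t0"] if t == 0 else city.truth["present_t10"]
    obs = city.truth.loc[present].copy()
    n = len(obs)

    true_dbh = (
        obs["dbh_t0"].values if t == 0 else obs["dbh_t10"].values
    ).astype(float)

    if t == 0:
        sd = np.full(n, cfg.early_measurement_sd)
        user_type = None
    else:
        classes = list(cfg.surveyor_mix)
        mix = np.array([cfg.surveyor_mix[c] for c in classes])
        mix = mix / mix.sum()
        n_dense = max(1, cfg.n_zips // 5)
        dense_zips = set(_zip_codes(cfg.n_zips)[:n_dense])
        # volunteers concentrate in the dense zips; renormalize the rest so the
        # citywide mix still matches the configured proportions in expectation
        p_dense = len(dense_zips) / cfg.n_zips
        p_vol_dense = min(0.95, mix[0] * 2.4)
        p_vol_rest = max(0.0, (mix[0] - p_dense * p_vol_dense) / (1 - p_dense)) if p_dense < 1 else mix[0]
        in_dense = obs["zip"].isin(dense_zips).values
        p_vol = np.where(in_dense, p_vol_dense, p_vol_rest)
        u = rng.random(n)
        is_vol = u < p_vol
        rest = mix[1:] / mix[1:].sum()
        other = rng.choice(len(classes) - 1, size=n, p=rest) + 1
        class_idx = np.where(is_vol, 0, other)
        user_type = np.array(classes, dtype=object)[class_idx]
        sd = np.array([cfg.surveyor_sd[classes[i]] for i in class_idx])

    noisy = true_dbh + rng.normal(0.0, 1.0, n) * sd
    reported = np.maximum(np.rint(noisy), 0).astype(int)

    circ = rng.random(n) < cfg.circumference_error_prob
    reported[circ] = np.rint(np.pi * true_dbh[circ]).astype(int)
    digit = (rng.random(n) < cfg.digit_error_prob) & (reported >= 10) & ~circ
    reported[digit] = np.array([int(str(v)[:-1]) for v in reported[digit]])

    addresses = [_format_address(a, rng) for a in obs["address"]]

    # species spelling variants via the inverse of the dictionary
    from .census import SpeciesDictionary

    inverse: dict[str, list[str]] = {}
    for variant, canon in SpeciesDictionary.default().variants.items():
        inverse.setdefault(canon, []).append(variant)
    species_raw = []
    for s in obs["species"]:
        variants = inverse.get(s, [s.lower()])
        raw = variants[rng.integers(len(variants))]
        style = rng.random()
        species_raw.append(raw.upper() if style < 0.3 else raw.title() if style < 0.8 else raw)

    out = pd.DataFrame(
        {
            "record_id": [f"{prefix}{i}" for i in obs["identity"]],
            "zip": obs["zip"].values,
            "address_raw": addresses,
            "species_raw": species_raw,
            "dbh_in": reported,
        }
    )
    out["circ_error"] = circ
    out["digit_error"] = digit
    if t != 0:
        for col in (
            "health", "steward", "guards", "sidewalk", "curb_loc",
            "root_blocked", "trunk_altered", "branch_problems", "borough",
        ):
            out[col] = obs[col].values
        out["user_type"] = user_type
        out["x"] = obs["x"].values
        out["y"] = obs["y"].values
    return out.reset_index(drop=True)


@dataclass
class LinkageEvaluation:
    precision: float
    recall: float
    n_reported: int
    n_true_pairs: int
    n_true_recovered: int
    false_match_causes: dict


def evaluate_linkage(pairs: pd.DataFrame, truth: pd.DataFrame) -> LinkageEvaluation:
    """Score pipeline pairs against the generator's identity labels."""
    surv = truth.loc[truth["present_t0"] & truth["present_t10"], "identity"]
    true_pairs = {(f"E{i}", f"L{i}") for i in surv}
    reported = set(zip(pairs["record_id_05"], pairs["record_id_15"]))
    tp = reported & true_pairs
    precision = len(tp) / len(reported) if reported else float("nan")

    # denominator for recall: persisting trees whose key is unique in both censuses
    key_cols = ["zip", "address", "species"]
    t0 = truth.loc[truth["present_t0"], key_cols + ["identity"]]
    t10 = truth.loc[truth["present_t10"], key_cols + ["identity"]]
    uniq0 = t0.groupby(key_cols)["identity"].transform("size") == 1
    uniq10 = t10.groupby(key_cols)["identity"].transform("size") == 1
    ids0 = set(t0.loc[uniq0, "identity"])
    ids10 = set(t10.loc[uniq10, "identity"])
    persisting_unique = {
        i for i in surv if i in ids0 and i in ids10
    }
    recovered = {a[1:] for a, _ in tp}
    recall = (
        len(recovered & persisting_unique) / len(persisting_unique)
        if persisting_unique
        else float("nan")
    )

    causes: dict[str, int] = {}
    event_of = truth.set_index("identity")["event"]
    present_events = truth.set_index("identity")
    for e_id, l_id in reported - true_pairs:
        late_identity = l_id[1:]
        row = present_events.loc[late_identity]
        cause = (
            "replacement"
            if row["predecessor"] is not None and not pd.isna(row["predecessor"])
            else "other"
        )
        causes[cause] = causes.get(cause, 0) + 1
    return LinkageEvaluation(
        precision=precision,
        recall=recall,
        n_reported=len(reported),
        n_true_pairs=len(true_pairs),
        n_true_recovered=len(recovered & persisting_unique),
        false_match_causes=causes,
    )


@dataclass
class RecoveryReport:
    per_species: pd.DataFrame
    overall_bias: float
    overall_rmse: float


def evaluate_recovery(records: pd.DataFrame, truth: pd.DataFrame) -> RecoveryReport:
    """Compare pipeline growth rates against generator truth, per species.

    Bias is computed over the trees the pipeline retained *and* matched
    correctly (false matches carry no meaningful truth), so it isolates
    measurement/rounding error from selection effects.
    """
    retained = records.loc[records["qc_status"] == "retained"].copy()
    retained["identity"] = [r[1:] for r in retained["record_id_05"]]
    late_identity = [r[1:] for r in retained["record_id_15"]]
    correct = retained["identity"].values == np.array(late_identity)
    retained = retained.loc[correct]
    tr = truth.set_index("identity")
    retained["true_rate"] = tr.loc[retained["identity"], "true_rate"].values
    retained["err"] = retained["rate_in_per_yr"] - retained["true_rate"]
    per_species = (
        retained.groupby("species_norm")
        .agg(
            n=("err", "size"),
            est_mean_rate=("rate_in_per_yr", "mean"),
            true_mean_rate=("true_rate", "mean"),
            bias=("err", "mean"),
            rmse=("err", lambda e: float(np.sqrt(np.mean(e**2)))),
        )
        .sort_values("n", ascending=False)
        .reset_index()
        .rename(columns={"species_norm": "species"})
    )
    return RecoveryReport(
        per_species=per_species,
        overall_bias=float(retained["err"].mean()),
        overall_rmse=float(np.sqrt(np.mean(retained["err"] ** 2))),
    )
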