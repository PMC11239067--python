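"""Reading and normalizing raw street-tree census tables.

A census snapshot arrives as a CSV with one row per surveyed tree. Column
vocabularies differ between census years, so reading goes through a *dialect*:
a mapping from logical field names (``zip``, ``address``, ``species``, ``dbh``,
plus optional survey fields) to the column names actually present in the file.

Normalization makes the linkage key comparable across snapshots:

* species common names are folded through a many-to-one variant dictionary
  onto canonical names ("LONDON PLANE TREE" -> "London Planetree"); names not
  in the dictionary are kept verbatim and flagged unmapped;
* street addresses are uppercased, stripped of punctuation (hyphens between
  building numbers, e.g. "45-47", are the one exception), abbreviations are
  expanded through a versioned rule table (ST -> STREET, W -> WEST, ...), and
  ordinal suffixes are dropped from numerics (120TH -> 120).

Both normalizers are idempotent. The abbreviation table and species dictionary
ship as CSV data files and are configuration, not code: swap them to adapt the
pipeline to another city's vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import pandas as pd

__all__ = [
    "SpeciesDictionary",
    "load_abbreviations",
    "normalize_address",
    "normalize_species",
    "read_census_csv",
    "normalize_census",
    "read_table",
    "write_canonical_csv",
    "read_canonical_csv",
    "CANONICAL_DIALECT",
    "DIALECT_2005",
    "DIALECT_2015",
    "REQUIRED_FIELDS",
    "EXTRA_FIELDS",
]

#: logical fields every census row must provide
REQUIRED_FIELDS = ("zip", "address", "species", "dbh")

#: optional categorical survey fields passed through to the analysis layer
EXTRA_FIELDS = (
    "health",
    "steward",
    "guards",
    "sidewalk",
    "curb_loc",
    "root_blocked",
    "trunk_altered",
    "branch_problems",
    "borough",
    "user_type",
)

#: canonical dialect: logical names are the column names
CANONICAL_DIALECT: dict[str, str] = {
    "record_id": "record_id",
    "zip": "zip",
    "address": "address_raw",
    "species": "species_raw",
    "dbh": "dbh_in",
    **{f: f for f in EXTRA_FIELDS},
}

#: default dialects mirroring the NYC Open Data field vocabularies
DIALECT_2005: dict[str, str] = {
    "record_id": "objectid",
    "zip": "zipcode",
    "address": "address",
    "species": "spc_common",
    "dbh": "tree_dbh",
    "health": "status",
    "borough": "boroname",
}
DIALECT_2015: dict[str, str] = {
    "record_id": "tree_id",
    "zip": "zipcode",
    "address": "address",
    "species": "spc_common",
    "dbh": "tree_dbh",
    "health": "health",
    "steward": "steward",
    "guards": "guards",
    "sidewalk": "sidewalk",
    "curb_loc": "curb_loc",
    "root_blocked": "root_other",
    "trunk_altered": "trunk_other",
    "branch_problems": "brch_other",
    "borough": "borough",
    "user_type": "user_type",
}

_DATA = files("treegrowth.data")


def load_abbreviations(path: str | Path | None = None) -> dict[str, str]:
    """Load the address-abbreviation expansion table (token -> expansion)."""
    if path is None:
        path = _DATA / "address_abbreviations.csv"
    with (path.open("r") if hasattr(path, "open") else open(path)) as fh:
        table = pd.read_csv(fh, dtype=str)
    return dict(zip(table["abbreviation"].str.upper(), table["expansion"].str.upper()))


@dataclass(frozen=True)
class SpeciesDictionary:
    """Many-to-one map from common-name variants to canonical common names.

    Lookups are case- and whitespace-insensitive. Canonical names are
    themselves valid lookup keys, so normalization is idempotent.
    """

    variants: dict[str, str]
    scientific: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for canon in set(self.variants.values()):
            self.variants.setdefault(canon.lower(), canon)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesDictionary":
        table = pd.read_csv(path, dtype=str)
        variants = {
            v.strip().lower(): c.strip()
            for v, c in zip(table["variant"], table["canonical"])
        }
        sci = {}
        if "scientific" in table:
            sci = {
                c.strip(): s.strip()
                for c, s in zip(table["canonical"], table["scientific"])
                if isinstance(s, str)
            }
        return cls(variants, sci)

    @classmethod
    def default(cls) -> "SpeciesDictionary":
        with (_DATA / "species_dictionary.csv").open("r") as fh:
            table = pd.read_csv(fh, dtype=str)
        variants = {
            v.strip().lower(): c.strip()
            for v, c in zip(table["variant"], table["canonical"])
        }
        sci = {
            c.strip(): s.strip()
            for c, s in zip(table["canonical"], table["scientific"])
        }
        return cls(variants, sci)

    def normalize(self, name: str) -> tuple[str, bool]:
        """Return ``(canonical_name, True)`` or ``(verbatim_name, False)``.

        Raises ``ValueError`` on an empty (after trimming) name.
        """
        cleaned = re.sub(r"\s+", " ", str(name).strip())
        if not cleaned:
            raise ValueError("empty species name")
        canon = self.variants.get(cleaned.lower())
        if canon is None:
            return cleaned, False
        return canon, True


# hyphen between digits is a building-number range ("45-47") and is retained
_NUMERIC_HYPHEN = re.compile(r"(?<=\d)-(?=\d)")
_PUNCT = re.compile(r"[^A-Z0-9\x00 ]+")
_ORDINAL = re.compile(r"^(\d+)(ST|ND|RD|TH)$")


def normalize_address(address_raw: str, rules: dict[str, str] | None = None) -> str:
    """Canonicalize a free-text street address.

    Uppercase, punctuation removed (numeric-range hyphens excepted),
    abbreviations expanded token-wise through ``rules``, ordinal suffixes
    stripped from numerics, whitespace collapsed. Idempotent.
    """
    if rules is None:
        rules = load_abbreviations()
    s = str(address_raw).upper()
    s = s.replace("'", "")  # apostrophes vanish without splitting the word
    s = _NUMERIC_HYPHEN.sub("\x00", s)
    s = _PUNCT.sub(" ", s)
    tokens = []
    for tok in s.split():
        tok = rules.get(tok, tok)
        tok = _ORDINAL.sub(r"\1", tok)
        tokens.append(tok)
    out = " ".join(tokens).replace("\x00", "-")
    if not out:
        raise ValueError("address empty after normalization")
    return out


def normalize_species(name: str, dictionary: SpeciesDictionary) -> tuple[str, bool]:
    """Normalize a species common name; see :meth:`SpeciesDictionary.normalize`."""
    return dictionary.normalize(name)


def _parse_dbh(value: str):
    """Parse a DBH cell to a whole-inch integer.

    Survey DBH is recorded in whole inches; exact decimals ("6.0") are
    accepted and truncated, anything fractional or non-numeric is rejected.
    Returns ``(dbh, reason)`` with exactly one of the two set.
    """
    text = str(value).strip()
    if not text:
        return None, "missing dbh"
    try:
        out = int(text)
    except ValueError:
        try:
            as_float = float(text)
        except ValueError:
            return None, "bad dbh"
        if not as_float.is_integer():
            return None, "bad dbh"
        out = int(as_float)
    if out < 0:
        return None, "negative dbh"
    return out, None


def read_census_csv(
    path: str | Path,
    dialect: dict[str, str],
    census_year: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a raw census CSV into canonical raw records.

    Parameters
    ----------
    path
        CSV file, one row per surveyed tree.
    dialect
        Mapping from logical field names to the file's column names. Must
        cover ``zip``, ``address``, ``species`` and ``dbh``; ``record_id``
        and the optional survey fields are used when present.
    census_year
        Year tag attached to every record.

    Returns
    -------
    (records, rejects)
        ``records`` has columns ``record_id, census_year, zip, address_raw,
        species_raw, dbh_in`` plus any mapped extra fields. ``rejects`` holds
        the dropped raw rows with a ``reject_reason`` column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    missing = [f for f in REQUIRED_FIELDS if f not in dialect]
    if missing:
        raise KeyError(f"dialect missing required fields: {missing}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for logical in REQUIRED_FIELDS:
        if dialect[logical] not in raw.columns:
            raise KeyError(
                f"column {dialect[logical]!r} (logical {logical!r}) not in {path.name}"
            )

    out = pd.DataFrame(index=raw.index)
    if "record_id" in dialect and dialect["record_id"] in raw.columns:
        out["record_id"] = raw[dialect["record_id"]].str.strip()
    else:
        out["record_id"] = [f"{census_year}-{i}" for i in raw.index]
    out["census_year"] = census_year
    out["zip"] = raw[dialect["zip"]].str.strip()
    out["address_raw"] = raw[dialect["address"]].str.strip()
    out["species_raw"] = raw[dialect["species"]].str.strip()
    dbh_parsed = raw[dialect["dbh"]].map(_parse_dbh)
    out["dbh_in"] = [d for d, _ in dbh_parsed]
    reasons = pd.Series([r for _, r in dbh_parsed], index=raw.index, dtype=object)
    for logical in EXTRA_FIELDS:
        col = dialect.get(logical)
        if col is not None and col in raw.columns:
            out[logical] = raw[col].str.strip()

    for logical, label in (("zip", "missing zip"), ("address_raw", "missing address"),
                           ("species_raw", "missing species")):
        empty = out[logical].astype(str).str.strip() == ""
        reasons = reasons.where(~(empty & reasons.isna()), label)

    if out["record_id"].duplicated().any():
        dupes = out.loc[out["record_id"].duplicated(), "record_id"].head().tolist()
        raise ValueError(f"duplicate record_id within census {census_year}: {dupes}")

    bad = reasons.notna()
    rejects = raw.loc[bad].copy()
    rejects["reject_reason"] = reasons[bad]
    records = out.loc[~bad].copy()
    records["dbh_in"] = records["dbh_in"].astype(int)
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def normalize_census(
    records: pd.DataFrame,
    dictionary: SpeciesDictionary | None = None,
    rules: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Add ``address_norm``, ``species_norm`` and ``species_unmapped`` columns."""
    if dictionary is None:
        dictionary = SpeciesDictionary.default()
    if rules is None:
        rules = load_abbreviations()
    out = records.copy()
    out["address_norm"] = [normalize_address(a, rules) for a in out["address_raw"]]
    normed = [dictionary.normalize(s) for s in out["species_raw"]]
    out["species_norm"] = [n for n, _ in normed]
    out["species_unmapped"] = [not ok for _, ok in normed]
    return out


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV artifact.

    Survey categoricals legitimately use the level "None" (e.g. no tree
    guard), which pandas' default NA handling would silently turn into
    missing values; here only the empty cell is missing. ZIP codes stay
    strings.
    """
    kwargs.setdefault("keep_default_na", False)
    kwargs.setdefault("na_values", [""])
    dtype = kwargs.pop("dtype", {})
    if isinstance(dtype, dict):
        dtype.setdefault("zip", str)
    return pd.read_csv(path, dtype=dtype, **kwargs)


def write_canonical_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_canonical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["census_year"] = df["census_year"].astype(int)
    df["dbh_in"] = df["dbh_in"].astype(int)
    if "species_unmapped" in df.columns:
        df["species_unmapped"] = df["species_unmapped"].map(
            {"True": True, "False": False}
        ).astype(bool)
    return df
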