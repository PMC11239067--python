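"""Growth computation, staged QC filters, and validation statistics.

Growth for a linked tree is the whole-inch DBH difference between the two
snapshots; the rate is that difference divided by exactly 10 years, so with
integer DBH every rate is a multiple of 0.1 in/yr.

Cleaning is a fixed three-stage cascade applied to the linked pairs:

5a. negative-growth cutoff — growth below −5 in is a replacement or gross
    error and is dropped; −5 itself is kept (measurement error of a tree that
    did not grow can plausibly reach that far);
5b. size bounds — first-census DBH of 0 (rounded-down saplings) or ≥ 41 in
    (implausible outliers) is dropped;
5c. per-bin tail trim — within each 1-inch first-census DBH bin, the 5% of
    trees with the smallest and the 5% with the largest growth are dropped
    (smaller trees grow faster, so trimming is done within size bins).

No record is ever deleted: each carries a ``qc_status`` so the cascade's
accounting can always be reconstructed. The stage order is enforced — each
filter refuses to run before its predecessors.

Validation statistics for repeatedly-measured trees: the Theil–Sen slope
(median of pairwise slopes, robust to outliers) and Kendall's tau-b
(tie-corrected; whole-inch DBH ties are common).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCConfig",
    "GrowthSummary",
    "compute_growth",
    "filter_negative",
    "filter_dbh_bounds",
    "trim_bin_tails",
    "apply_qc",
    "summarize_growth",
    "theil_sen",
    "kendall_tau",
]

YEARS_BETWEEN_CENSUSES = 10.0

RETAINED = "retained"
DROP_NEGATIVE = "drop_negative"
DROP_DBH0 = "drop_dbh0"
DROP_DBH41 = "drop_dbh41plus"
DROP_TRIMMED = "drop_trimmed"

_STAGE_ORDER = ("negative", "dbh_bounds", "trim")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the three-stage cleaning cascade (all in whole inches)."""

    negative_cutoff_in: int = -5
    dbh_min: int = 1
    dbh_max: int = 40
    trim_fraction_per_tail: float = 0.05
    bin_width_in: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.trim_fraction_per_tail < 0.5):
            raise ValueError("trim_fraction_per_tail must be in [0, 0.5)")
        if self.dbh_min > self.dbh_max:
            raise ValueError("dbh_min > dbh_max")


def _stages_applied(df: pd.DataFrame) -> tuple[str, ...]:
    return tuple(df.attrs.get("qc_stages", ()))


def _require_stage(df: pd.DataFrame, stage: str) -> None:
    done = _stages_applied(df)
    needed = _STAGE_ORDER[: _STAGE_ORDER.index(stage)]
    missing = [s for s in needed if s not in done]
    if missing:
        raise RuntimeError(
            f"QC stage {stage!r} requires earlier stage(s) {missing}; "
            f"applied so far: {list(done) or 'none'}"
        )
    if stage in done:
        # idempotent by construction; re-application is allowed and a no-op
        pass


def _mark_stage(df: pd.DataFrame, stage: str) -> None:
    done = list(_stages_applied(df))
    if stage not in done:
        done.append(stage)
    df.attrs["qc_stages"] = tuple(done)


def compute_growth(pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach growth and growth-rate columns to a linked-pairs frame.

    Requires integer ``dbh_in_05``/``dbh_in_15`` columns. No filtering happens
    here; every record starts ``retained``.
    """
    for col in ("dbh_in_05", "dbh_in_15"):
        if col not in pairs.columns:
            raise KeyError(f"pairs frame lacks {col!r}")
    out = pairs.copy()
    out["dbh_in_05"] = out["dbh_in_05"].astype(int)
    out["dbh_in_15"] = out["dbh_in_15"].astype(int)
    out["growth_in"] = out["dbh_in_15"] - out["dbh_in_05"]
    out["rate_in_per_yr"] = out["growth_in"] / YEARS_BETWEEN_CENSUSES
    out["qc_status"] = RETAINED
    out.attrs["qc_stages"] = ()
    return out


def filter_negative(records: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Stage 5a: drop growth below the negative cutoff (default < −5 in)."""
    out = records.copy()
    out.attrs["qc_stages"] = _stages_applied(records)
    mask = (out["qc_status"] == RETAINED) & (out["growth_in"] < cfg.negative_cutoff_in)
    out.loc[mask, "qc_status"] = DROP_NEGATIVE
    _mark_stage(out, "negative")
    return out


def filter_dbh_bounds(records: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Stage 5b: drop first-census DBH below ``dbh_min`` or above ``dbh_max``."""
    _require_stage(records, "dbh_bounds")
    out = records.copy()
    out.attrs["qc_stages"] = _stages_applied(records)
    retained = out["qc_status"] == RETAINED
    out.loc[retained & (out["dbh_in_05"] < cfg.dbh_min), "qc_status"] = DROP_DBH0
    out.loc[retained & (out["dbh_in_05"] > cfg.dbh_max), "qc_status"] = DROP_DBH41
    _mark_stage(out, "dbh_bounds")
    return out


def trim_bin_tails(records: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Stage 5c: per 1-inch DBH bin, trim the extreme-growth tails.

    Within each first-census DBH bin, the ``floor(f * n)`` currently-retained
    records with the smallest growth and the ``floor(f * n)`` with the largest
    growth are marked ``drop_trimmed`` (f = ``trim_fraction_per_tail``). Ties
    are broken by record id, so the removal is deterministic.
    """
    _require_stage(records, "trim")
    out = records.copy()
    out.attrs["qc_stages"] = _stages_applied(records)
    if "trim" in _stages_applied(records):
        return out
    id_col = "record_id_05" if "record_id_05" in out.columns else "record_id"
    retained = out.loc[out["qc_status"] == RETAINED]
    bins = retained["dbh_in_05"] // cfg.bin_width_in
    for _, idx in retained.groupby(bins).groups.items():
        grp = out.loc[idx]
        k = math.floor(cfg.trim_fraction_per_tail * len(grp))
        if k == 0:
            continue
        low = grp.sort_values(["growth_in", id_col], kind="mergesort").index[:k]
        high = grp.sort_values(
            ["growth_in", id_col], ascending=[False, True], kind="mergesort"
        ).index[:k]
        out.loc[low.union(high), "qc_status"] = DROP_TRIMMED
    _mark_stage(out, "trim")
    return out


def apply_qc(records: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Run the full cascade 5a → 5b → 5c in its fixed order."""
    return trim_bin_tails(filter_dbh_bounds(filter_negative(records, cfg), cfg), cfg)


@dataclass
class GrowthSummary:
    """Descriptive statistics of the retained growth-rate distribution."""

    n_retained: int
    mean_rate: float
    sd_rate: float
    min_rate: float
    max_rate: float
    n_negative: int
    frac_negative: float
    n_zero_to_one: int
    frac_zero_to_one: float
    per_species: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_species"] = self.per_species.to_dict(orient="records")
        return d


def summarize_growth(records: pd.DataFrame) -> GrowthSummary:
    """Summarize retained records; per-species table sorted by abundance."""
    retained = records.loc[records["qc_status"] == RETAINED]
    if len(retained) == 0:
        raise ValueError("no retained records to summarize")
    rate = retained["rate_in_per_yr"]
    if "species_norm" in retained.columns:
        species_col = "species_norm"
    elif "species_raw" in retained.columns:
        species_col = "species_raw"
    else:
        retained = retained.assign(species_norm="all")
        species_col = "species_norm"
    per_species = (
        retained.groupby(species_col)
        .agg(
            n=("rate_in_per_yr", "size"),
            mean_dbh_05=("dbh_in_05", "mean"),
            mean_rate=("rate_in_per_yr", "mean"),
        )
        .sort_values("n", ascending=False)
        .reset_index()
        .rename(columns={species_col: "species"})
    )
    n_neg = int((rate < 0).sum())
    n_01 = int(((rate >= 0) & (rate <= 1)).sum())
    return GrowthSummary(
        n_retained=len(retained),
        mean_rate=float(rate.mean()),
        sd_rate=float(rate.std(ddof=1)),
        min_rate=float(rate.min()),
        max_rate=float(rate.max()),
        n_negative=n_neg,
        frac_negative=n_neg / len(retained),
        n_zero_to_one=n_01,
        frac_zero_to_one=n_01 / len(retained),
        per_species=per_species,
    )


def theil_sen(times, values) -> float:
    """Theil–Sen slope: median of all pairwise slopes (in/yr).

    Pairs with equal times contribute nothing; with an even number of pairwise
    slopes the two central values are averaged.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(t) == 0:
        raise ValueError("all measurement times are equal")
    slope, _, _, _ = stats.theilslopes(y, t)
    return float(slope)


def kendall_tau(times, values) -> float:
    """Kendall tau-b between time order and DBH; +1 ⇔ monotone increase.

    Returns NaN for series shorter than 3 points (undefined).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        return float("nan")
    tau, _ = stats.kendalltau(t, y)
    return float(tau)
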