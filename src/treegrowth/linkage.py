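"""One-to-one alignment of two census snapshots on (ZIP, address, species).

The match key is exact string equality on the triple (zip, address_norm,
species_norm). ZIP is part of the key because street names and building
numbers repeat across a city. Any key occurring more than once *within* a
census is wholly removed from that census before alignment — two London
Planetrees at one address cannot be told apart ten years later, so both go.
Records whose species could not be mapped onto the canonical dictionary are
likewise excluded from linkage (species equality is part of the
identification claim) but counted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = ["KEY_COLUMNS", "LinkageReport", "drop_nonunique_keys", "align_censuses"]

KEY_COLUMNS = ("zip", "address_norm", "species_norm")


@dataclass
class LinkageReport:
    """Record counts at each alignment step, one census pair."""

    n_input_early: int
    n_input_late: int
    n_unmapped_early: int
    n_unmapped_late: int
    n_nonunique_early: int
    n_nonunique_late: int
    n_retained_early: int
    n_retained_late: int
    n_matched: int
    n_unmatched_early: int
    n_unmatched_late: int

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        """Conservation: dropped + retained = input, per census."""
        assert (
            self.n_unmapped_early + self.n_nonunique_early + self.n_retained_early
            == self.n_input_early
        )
        assert (
            self.n_unmapped_late + self.n_nonunique_late + self.n_retained_late
            == self.n_input_late
        )
        assert self.n_matched + self.n_unmatched_early == self.n_retained_early
        assert self.n_matched + self.n_unmatched_late == self.n_retained_late


def _require_normalized(records: pd.DataFrame) -> None:
    missing = [c for c in KEY_COLUMNS if c not in records.columns]
    if missing:
        raise KeyError(f"records lack normalized key columns: {missing}")


def drop_nonunique_keys(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one census into key-unique and key-duplicated records.

    Every key with multiplicity >= 2 has *all* of its records moved to the
    dropped frame; retained keys occur exactly once.
    """
    _require_normalized(records)
    if len(records) == 0:
        return records.copy(), records.copy()
    counts = records.groupby(list(KEY_COLUMNS), sort=False)["record_id"].transform("size")
    dup = counts >= 2
    return records.loc[~dup].copy(), records.loc[dup].copy()


def align_censuses(
    early: pd.DataFrame, late: pd.DataFrame
) -> tuple[pd.DataFrame, LinkageReport]:
    """Pair key-unique records of two censuses into one-to-one matches.

    Inputs must already be deduplicated (``drop_nonunique_keys``); duplicate
    keys here are a contract violation and abort. Records flagged
    ``species_unmapped`` are excluded before matching and counted.

    Returns the pairs frame (early columns suffixed ``_05``, late ``_15``,
    key columns unsuffixed) and a :class:`LinkageReport`.
    """
    _require_normalized(early)
    _require_normalized(late)

    def split_unmapped(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        if "species_unmapped" in df.columns:
            n = int(df["species_unmapped"].sum())
            return df.loc[~df["species_unmapped"].astype(bool)], n
        return df, 0

    early_m, n_unm_e = split_unmapped(early)
    late_m, n_unm_l = split_unmapped(late)

    for name, df in (("early", early_m), ("late", late_m)):
        if df.duplicated(subset=list(KEY_COLUMNS)).any():
            raise ValueError(
                f"{name} census contains duplicate match keys; "
                "run drop_nonunique_keys first"
            )

    e = early_m.set_index(list(KEY_COLUMNS))
    l = late_m.set_index(list(KEY_COLUMNS))
    pairs = e.join(l, how="inner", lsuffix="_05", rsuffix="_15").reset_index()

    report = LinkageReport(
        n_input_early=len(early),
        n_input_late=len(late),
        n_unmapped_early=n_unm_e,
        n_unmapped_late=n_unm_l,
        n_nonunique_early=0,
        n_nonunique_late=0,
        n_retained_early=len(early_m),
        n_retained_late=len(late_m),
        n_matched=len(pairs),
        n_unmatched_early=len(early_m) - len(pairs),
        n_unmatched_late=len(late_m) - len(pairs),
    )
    report.validate()
    return pairs, report


def link(
    early: pd.DataFrame, late: pd.DataFrame
) -> tuple[pd.DataFrame, LinkageReport]:
    """Exclude unmapped species, dedupe both censuses, then align.

    The one-call wrapper producing the full step accounting.
    """

    def prep(df: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
        if "species_unmapped" in df.columns:
            unmapped = df["species_unmapped"].astype(bool)
            mapped = df.loc[~unmapped]
            n_unm = int(unmapped.sum())
        else:
            mapped, n_unm = df, 0
        uniq, dup = drop_nonunique_keys(mapped)
        return uniq, len(dup), n_unm

    early_u, n_dup_e, n_unm_e = prep(early)
    late_u, n_dup_l, n_unm_l = prep(late)
    pairs, _ = align_censuses(early_u, late_u)
    report = LinkageReport(
        n_input_early=len(early),
        n_input_late=len(late),
        n_unmapped_early=n_unm_e,
        n_unmapped_late=n_unm_l,
        n_nonunique_early=n_dup_e,
        n_nonunique_late=n_dup_l,
        n_retained_early=len(early_u),
        n_retained_late=len(late_u),
        n_matched=len(pairs),
        n_unmatched_early=len(early_u) - len(pairs),
        n_unmatched_late=len(late_u) - len(pairs),
    )
    report.validate()
    return pairs, report
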