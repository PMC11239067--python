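"""Growth arithmetic, the staged QC cascade, and validation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treegrowth import growth as gw
from treegrowth.growth import (
    QCConfig,
    apply_qc,
    compute_growth,
    filter_dbh_bounds,
    filter_negative,
    kendall_tau,
    summarize_growth,
    theil_sen,
    trim_bin_tails,
)


def pairs_frame(rows):
    """rows: (record_id, dbh_05, dbh_15)"""
    df = pd.DataFrame(rows, columns=["record_id_05", "dbh_in_05", "dbh_in_15"])
    df["record_id_15"] = df["record_id_05"] + "x"
    return df


def brute_force_median_slope(points):
    slopes = [
        (y2 - y1) / (t2 - t1)
        for (t1, y1), (t2, y2) in itertools.combinations(points, 2)
        if t2 != t1
    ]
    return float(np.median(slopes))


class TestComputeGrowth:
    @pytest.mark.parametrize(
        "d05,d15,g,r",
        [(6, 10, 4, 0.4), (10, 10, 0, 0.0), (22, 17, -5, -0.5)],
    )
    def test_arithmetic(self, d05, d15, g, r):
        records = compute_growth(pairs_frame([("a", d05, d15)]))
        assert records["growth_in"].iloc[0] == g
        assert records["rate_in_per_yr"].iloc[0] == pytest.approx(r)

    def test_no_filtering_here(self):
        records = compute_growth(pairs_frame([("a", 30, 2)]))
        assert (records["qc_status"] == "retained").all()


class TestCascadeSemantics:
    def test_negative_boundary(self):
        # growth of exactly -5 is plausible measurement error and stays
        records = compute_growth(
            pairs_frame([("a", 10, 5), ("b", 10, 4), ("c", 10, 11)])
        )
        out = filter_negative(records)
        assert out["qc_status"].tolist() == ["retained", "drop_negative", "retained"]

    def test_dbh_bounds_boundary(self):
        records = filter_negative(
            compute_growth(
                pairs_frame([("a", 0, 2), ("b", 41, 44), ("c", 40, 44), ("d", 1, 3)])
            )
        )
        out = filter_dbh_bounds(records)
        assert out["qc_status"].tolist() == [
            "drop_dbh0",
            "drop_dbh41plus",
            "retained",
            "retained",
        ]

    def test_stage_order_enforced(self):
        records = compute_growth(pairs_frame([("a", 10, 12)]))
        with pytest.raises(RuntimeError, match="requires earlier stage"):
            trim_bin_tails(records)
        with pytest.raises(RuntimeError, match="requires earlier stage"):
            filter_dbh_bounds(records)

    def test_filters_idempotent(self, rng):
        d05 = rng.integers(0, 45, 500)
        d15 = d05 + rng.integers(-10, 15, 500)
        records = compute_growth(
            pairs_frame([(f"r{i}", a, max(b, 0)) for i, (a, b) in enumerate(zip(d05, d15))])
        )
        once = apply_qc(records)
        twice = trim_bin_tails(filter_dbh_bounds(filter_negative(once)))
        assert once["qc_status"].tolist() == twice["qc_status"].tolist()


class TestTrim:
    def test_bin_of_100_loses_5_per_tail(self, rng):
        growths = rng.permutation(100)
        records = apply_qc(
            compute_growth(
                pairs_frame([(f"r{i:03d}", 10, 10 + g) for i, g in enumerate(growths)])
            ),
            QCConfig(negative_cutoff_in=-1000),
        )
        assert (records["qc_status"] == "drop_trimmed").sum() == 10

    def test_bin_of_10_loses_none(self, rng):
        records = apply_qc(
            compute_growth(pairs_frame([(f"r{i}", 10, 11 + i % 5) for i in range(10)]))
        )
        assert (records["qc_status"] == "drop_trimmed").sum() == 0

    def test_matches_brute_force_sort_and_slice(self, rng):
        growths = rng.integers(0, 30, 40)
        records = apply_qc(
            compute_growth(
                pairs_frame([(f"r{i:02d}", 10, 10 + g) for i, g in enumerate(growths)])
            )
        )
        k = int(np.floor(0.05 * 40))
        order = sorted(range(40), key=lambda i: (growths[i], f"r{i:02d}"))
        expected = {f"r{i:02d}" for i in order[:k]} | {
            f"r{i:02d}"
            for i in sorted(range(40), key=lambda i: (-growths[i], f"r{i:02d}"))[:k]
        }
        got = set(records.loc[records["qc_status"] == "drop_trimmed", "record_id_05"])
        assert got == expected

    def test_removed_bracket_retained_within_bins(self, rng):
        d05 = rng.integers(1, 40, 2000)
        d15 = d05 + rng.integers(-5, 15, 2000)
        records = apply_qc(
            compute_growth(
                pairs_frame(list(zip([f"r{i:04d}" for i in range(2000)], d05, d15)))
            )
        )
        for _, grp in records.groupby("dbh_in_05"):
            kept = grp.loc[grp["qc_status"] == "retained", "growth_in"]
            cut = grp.loc[grp["qc_status"] == "drop_trimmed", "growth_in"]
            if len(kept) and len(cut):
                assert ((cut <= kept.min()) | (cut >= kept.max())).all()
            n_bin = (grp["qc_status"].isin(["retained", "drop_trimmed"])).sum()
            assert len(cut) == 2 * int(np.floor(0.05 * n_bin))


class TestSummarize:
    def test_small_example(self):
        records = apply_qc(
            compute_growth(pairs_frame([("a", 10, 11), ("b", 10, 12), ("c", 10, 13)]))
        )
        s = summarize_growth(records)
        assert s.mean_rate == pytest.approx(0.2)
        assert s.n_negative == 0 and s.frac_zero_to_one == 1.0

    def test_negative_rate_counted(self):
        records = apply_qc(
            compute_growth(pairs_frame([("a", 10, 9), ("b", 10, 12), ("c", 10, 13)]))
        )
        s = summarize_growth(records)
        assert s.frac_negative > 0

    def test_empty_retained_errors(self):
        records = apply_qc(compute_growth(pairs_frame([("a", 0, 2)])))
        with pytest.raises(ValueError):
            summarize_growth(records)

    def test_rates_are_tenth_inch_multiples_on_synthetic(self, small_city):
        from treegrowth import pipeline

        res = pipeline.run_from_frames(
            small_city.observe_census("early"), small_city.observe_census("late")
        )
        retained = res.growth.loc[res.growth["qc_status"] == "retained"]
        rates = retained["rate_in_per_yr"].values
        assert np.allclose(np.round(rates * 10), rates * 10)
        assert rates.min() >= -0.5


class TestTheilSen:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 10), (10, 13), (14, 14.2)], 0.3),
            ([(0, 10), (10, 12)], 0.2),
        ],
    )
    def test_examples(self, points, expected):
        t, y = zip(*points)
        assert theil_sen(t, y) == pytest.approx(expected)

    def test_outlier_series_matches_brute_force(self):
        points = [(0, 10), (5, 11), (10, 12), (11, 50)]
        t, y = zip(*points)
        assert theil_sen(t, y) == pytest.approx(brute_force_median_slope(points))

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 20), st.floats(0, 60, allow_nan=False, width=32)
            ),
            min_size=2,
            max_size=8,
            unique_by=lambda p: p[0],
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_pairwise_median(self, points):
        t, y = zip(*points)
        assert theil_sen(t, y) == pytest.approx(brute_force_median_slope(points))

    def test_all_times_equal_errors(self):
        with pytest.raises(ValueError):
            theil_sen([5, 5, 5], [1, 2, 3])


def brute_force_tau_b(t, y):
    n = len(t)
    conc = disc = 0
    for i, j in itertools.combinations(range(n), 2):
        s = np.sign(t[j] - t[i]) * np.sign(y[j] - y[i])
        conc += s > 0
        disc += s < 0
    def tie_term(v):
        counts = pd.Series(v).value_counts()
        return float((counts * (counts - 1) / 2).sum())

    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tie_term(t)) * (n0 - tie_term(y)))
    return (conc - disc) / denom


class TestKendallTau:
    def test_monotone_series(self):
        assert kendall_tau([0, 10, 14], [10, 13, 14]) == pytest.approx(1.0)
        assert kendall_tau([0, 10, 14], [14, 13, 10]) == pytest.approx(-1.0)

    def test_nonmonotone_matches_pair_enumeration(self):
        t, y = [0, 1, 2], [10, 12, 11]
        assert kendall_tau(t, y) == pytest.approx(brute_force_tau_b(t, y))

    def test_ties_match_pair_enumeration(self):
        t, y = [0, 1, 2, 3, 4], [10, 10, 11, 11, 12]
        assert kendall_tau(t, y) == pytest.approx(brute_force_tau_b(t, y))

    def test_short_series_undefined(self):
        assert np.isnan(kendall_tau([0, 1], [1, 2]))
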