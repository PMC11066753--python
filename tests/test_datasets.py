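"""Ingest: CSV loading, inclusion screening, segment selection, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvvarnet import (
    load_diary_csv,
    screen_inclusion,
    select_longest_segment,
    z_standardize,
)

from conftest import make_dataset


# ---------------------------------------------------------------- loading
class TestLoadDiaryCsv:
    def test_absent_days_become_masked_rows(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text(
            "date,mood\n2021-01-01,3\n2021-01-02,4\n2021-01-04,5\n"
        )
        ds = load_diary_csv(f, "date", ["mood"])
        assert ds.T == 4
        assert not ds.mask[2, 0] and np.isnan(ds.values[2, 0])
        assert list(ds.values[[0, 1, 3], 0]) == [3, 4, 5]

    def test_duplicate_dates_error(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("date,mood\n2021-01-01,3\n2021-01-01,4\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_diary_csv(f, "date", ["mood"])

    def test_full_series_dimensions(self, tmp_path):
        # a complete 539-day, 6-variable file (the longest series in the
        # study's regime) loads with T=539, p=6
        T, p = 539, 6
        dates = pd.date_range("2017-06-01", periods=T, freq="D")
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(0, 100, (T, p)), columns=[f"item{j}" for j in range(p)]
        )
        df.insert(0, "date", dates.strftime("%Y-%m-%d"))
        f = tmp_path / "full.csv"
        df.to_csv(f, index=False)
        ds = load_diary_csv(f, "date")
        assert (ds.T, ds.p) == (539, 6)
        assert ds.mask.all()

    def test_empty_cells_are_missing(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("date,a,b\n2021-01-01,3,\n2021-01-02,,4\n")
        ds = load_diary_csv(f, "date")
        assert ds.mask.tolist() == [[True, False], [False, True]]

    def test_unparseable_dates_error(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("date,a\nnot-a-date,3\n")
        with pytest.raises(ValueError, match="unparseable"):
            load_diary_csv(f, "date")

    def test_zero_variables_error(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("date\n2021-01-01\n")
        with pytest.raises(ValueError, match="zero usable"):
            load_diary_csv(f, "date")


# ---------------------------------------------------------------- screening
class TestScreenInclusion:
    def test_too_short_excluded(self):
        ds = make_dataset(np.ones((129, 2)) + np.arange(129)[:, None])
        rep = screen_inclusion(ds)
        assert not rep.included and rep.reasons == ["min_days"]

    def test_missingness_excluded(self):
        vals = np.random.default_rng(1).normal(size=(130, 2))
        mask = np.ones((130, 2), bool)
        mask[:41, 1] = False  # 41/130 = 31.5% missing
        rep = screen_inclusion(make_dataset(vals, mask))
        assert not rep.included and rep.reasons == ["missingness"]

    def test_complete_long_series_included(self):
        vals = np.random.default_rng(2).normal(size=(130, 3))
        rep = screen_inclusion(make_dataset(vals))
        assert rep.included and rep.reasons == []

    def test_boundary_is_strict(self):
        # exactly 30% missing fails the "<30%" rule; 130 days passes ">=130"
        vals = np.random.default_rng(3).normal(size=(130, 1))
        mask = np.ones((130, 1), bool)
        mask[:39, 0] = False  # 39/130 = 30% exactly
        rep = screen_inclusion(make_dataset(vals, mask))
        assert not rep.included

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 40))
    def test_monotone_in_observed_days(self, seed, n_extra):
        """Appending observed days never flips included -> excluded."""
        rng = np.random.default_rng(seed)
        T = int(rng.integers(100, 200))
        vals = rng.normal(size=(T, 2))
        mask = rng.random((T, 2)) > 0.2
        base = screen_inclusion(make_dataset(vals, mask))
        bigger = make_dataset(
            np.vstack([vals, rng.normal(size=(n_extra, 2))]),
            np.vstack([mask, np.ones((n_extra, 2), bool)]),
        )
        rep = screen_inclusion(bigger)
        if base.included:
            assert rep.included


# ---------------------------------------------------------------- segment selection
def brute_force_segment(mask, max_gap):
    """Longest window overlapping no full-series item-wise missing run > max_gap."""
    T, p = mask.shape
    barrier = np.zeros(T, bool)
    for j in range(p):
        run = 0
        for t in range(T + 1):
            if t < T and not mask[t, j]:
                run += 1
            else:
                if run > max_gap:
                    barrier[t - run : t] = True
                run = 0
    best = (0, 0)  # (length, start)
    for a in range(T):
        for b in range(a, T):
            if barrier[a : b + 1].any():
                break
            if b - a + 1 > best[0]:
                best = (b - a + 1, a)
    return best[1], best[0]


class TestSelectLongestSegment:
    def test_eight_day_gap_splits_series(self):
        # variable 1 missing on days 11..18 (run of 8 > 7): phases are days
        # 1-10 and 19-30; the latter (length 12) wins
        mask = np.ones((30, 2), bool)
        mask[10:18, 0] = False
        ds = make_dataset(np.random.default_rng(4).normal(size=(30, 2)), mask)
        seg = select_longest_segment(ds, max_gap_days=7)
        assert seg.T == 12
        assert seg.dates[0] == ds.dates[18]

    def test_no_missing_identity(self):
        ds = make_dataset(np.random.default_rng(5).normal(size=(40, 2)))
        seg = select_longest_segment(ds)
        assert seg.T == ds.T
        np.testing.assert_array_equal(seg.values, ds.values)

    def test_seven_day_run_is_retained(self):
        # run of exactly 7 does not split (the rule is strictly "> 7")
        mask = np.ones((30, 2), bool)
        mask[10:17, 0] = False
        ds = make_dataset(np.random.default_rng(6).normal(size=(30, 2)), mask)
        seg = select_longest_segment(ds, max_gap_days=7)
        assert seg.T == 30

    def test_matches_brute_force_on_random_patterns(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            T = int(rng.integers(20, 120))
            p = int(rng.integers(1, 4))
            mask = rng.random((T, p)) > rng.uniform(0.05, 0.5)
            gap = int(rng.integers(1, 9))
            start, length = brute_force_segment(mask, gap)
            ds = make_dataset(rng.normal(size=(T, p)), mask)
            if length < 2:
                with pytest.raises(ValueError):
                    select_longest_segment(ds, gap)
                continue
            seg = select_longest_segment(ds, gap)
            assert seg.T == length
            assert seg.dates[0] == ds.dates[start]

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        mask = rng.random((60, 2)) > 0.3
        ds = make_dataset(rng.normal(size=(60, 2)), mask)
        seg1 = select_longest_segment(ds)
        seg2 = select_longest_segment(seg1)
        assert seg1.T == seg2.T and seg1.dates[0] == seg2.dates[0]


# ---------------------------------------------------------------- standardization
class TestZStandardize:
    def test_observed_moments(self):
        rng = np.random.default_rng(8)
        mask = rng.random((80, 3)) > 0.1
        ds = make_dataset(rng.normal(2, 5, (80, 3)), mask)
        out, _ = z_standardize(ds)
        for j in range(3):
            obs = out.values[out.mask[:, j], j]
            assert abs(obs.mean()) < 1e-8
            assert abs(obs.std(ddof=1) - 1) < 1e-8
        assert out.standardized
        np.testing.assert_array_equal(out.mask, ds.mask)

    def test_round_trip(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(rng.normal(10, 3, (50, 2)))
        out, params = z_standardize(ds)
        back = params.inverse(out)
        np.testing.assert_allclose(back.values, ds.values, atol=1e-10)

    def test_constant_variable_error(self):
        ds = make_dataset(np.column_stack([np.full(20, 2.0), np.arange(20.0)]))
        with pytest.raises(ValueError, match="constant"):
            z_standardize(ds)

    def test_scaling_invariance_of_result(self):
        ds = make_dataset(np.random.default_rng(10).normal(size=(50, 2)))
        a, _ = z_standardize(ds)
        scaled = make_dataset(ds.values * 7.3 + 2.0)
        b, _ = z_standardize(scaled)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
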