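import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synchroscope.synchrony import (
    REASON_FEW_SHARED,
    REASON_ZERO_POSITIVE,
    SynchronyParams,
    Window,
    climate_synchrony,
    eligible_pairs,
    log_growth_rates,
    moving_window_synchrony,
    pearson,
    site_to_grid_cell,
    window_synchrony,
    windows_for_years,
)
from synchro_oracles import oracle_moving_window


class TestGrowthRates:
    def test_plus_one_offset(self):
        r = log_growth_rates(pd.Series({2000: 0, 2001: 9, 2002: 99}))
        assert r.loc[2001] == pytest.approx(math.log(10), abs=1e-12)
        assert r.loc[2002] == pytest.approx(math.log(10), abs=1e-12)

    def test_constant_counts_give_zero(self):
        r = log_growth_rates(pd.Series({2000: 5, 2001: 5, 2002: 5}))
        assert (r == 0).all()

    def test_gap_breaks_definition(self):
        r = log_growth_rates(pd.Series({2000: 3, 2002: 7}))
        assert r.empty

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            log_growth_rates(pd.Series({2000: -1, 2001: 2}))

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=15)
    )
    @settings(max_examples=50, deadline=None)
    def test_rates_finite_and_reversible(self, counts):
        s = pd.Series(counts, index=range(2000, 2000 + len(counts)))
        r = log_growth_rates(s)
        assert np.isfinite(r.to_numpy()).all()
        # growth rates of the reversed series are the negated reversed rates
        rev = pd.Series(counts[::-1], index=range(2000, 2000 + len(counts)))
        assert np.allclose(log_growth_rates(rev).to_numpy(), -r.to_numpy()[::-1])


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (6, 4, 2), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_nan(self):
        assert math.isnan(pearson([1, 1, 1], [1, 2, 3]))

    @given(
        st.lists(st.floats(-100, 100).map(lambda v: round(v, 6)), min_size=3, max_size=20),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_matches_scipy(self, x, data):
        from scipy import stats

        y = data.draw(
            st.lists(
                st.floats(-100, 100).map(lambda v: round(v, 6)),
                min_size=len(x),
                max_size=len(x),
            )
        )
        x, y = np.array(x), np.array(y)
        if x.var() == 0 or y.var() == 0:
            assert math.isnan(pearson(x, y))
        else:
            r = pearson(x, y)
            assert -1.0 <= r <= 1.0
            assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-9)


class TestGridCell:
    @pytest.mark.parametrize(
        "e,n,cell",
        [(4999, 0, "c_0_0"), (5000, 0, "c_1_0"), (12345, 67890, "c_2_13"), (-1, -1, "c_-1_-1")],
    )
    def test_floor_convention(self, e, n, cell):
        assert site_to_grid_cell(e, n) == cell

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            site_to_grid_cell(float("nan"), 0)


class TestEligiblePairs:
    def test_distance_threshold(self):
        sites = pd.DataFrame(
            {
                "site_id": ["a", "b", "c"],
                "easting_m": [0.0, 50_000.0, 120_000.0],
                "northing_m": [0.0, 0.0, 0.0],
            }
        )
        kept, excluded = eligible_pairs(sites, max_distance_km=100)
        kept_set = set(zip(kept["site_a"], kept["site_b"]))
        assert kept_set == {("a", "b"), ("b", "c")}
        assert set(zip(excluded["site_a"], excluded["site_b"])) == {("a", "c")}

    def test_subsample_reproducible(self):
        rng = np.random.default_rng(0)
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(25)],
                "easting_m": rng.uniform(0, 50_000, 25),
                "northing_m": rng.uniform(0, 50_000, 25),
            }
        )
        k1, _ = eligible_pairs(sites, max_pairs=50, seed=9)
        k2, _ = eligible_pairs(sites, max_pairs=50, seed=9)
        assert len(k1) == 50
        pd.testing.assert_frame_equal(k1, k2)

    def test_subsample_stability_of_mean_synchrony(self, small_study):
        """Reseeded pair subsamples give nearly the full-set mean synchrony."""
        ab, sites = small_study.abundance, small_study.sites
        full, _ = moving_window_synchrony(ab, sites, SynchronyParams(max_pairs=10**9))
        full_mean = full["r"].mean()
        diffs = []
        for s in range(5):
            sub, _ = moving_window_synchrony(
                ab, sites, SynchronyParams(max_pairs=len(full) // 40, seed=s)
            )
            diffs.append(abs(sub["r"].mean() - full_mean))
        assert np.mean(diffs) < 0.02


class TestWindowRules:
    def test_identical_series_r_one(self):
        counts = pd.Series(
            [3, 5, 2, 8, 4, 9, 1, 6, 7, 3], index=range(2000, 2010)
        )
        r, n = window_synchrony(counts, counts.copy(), Window(2000))
        assert r == pytest.approx(1.0)
        assert n == 9

    def test_six_shared_years_dropped(self):
        a = pd.Series(
            {y: 5 + (y % 3) for y in range(2000, 2007)}  # growth years 2001-2006
        )
        b = pd.Series({y: 4 + (y % 4) for y in range(2000, 2010)})
        res = window_synchrony(a, b, Window(2000))
        assert res == (None, REASON_FEW_SHARED)

    def test_zero_then_positive_dropped(self):
        a = pd.Series([3, 5, 2, 8, 0, 4, 1, 6, 7, 3], index=range(2000, 2010))
        b = pd.Series([4, 6, 3, 9, 5, 8, 2, 7, 8, 4], index=range(2000, 2010))
        res = window_synchrony(a, b, Window(2000))
        assert res == (None, REASON_ZERO_POSITIVE)

    def test_window_count(self):
        assert len(windows_for_years(range(1990, 2010))) == 11

    def test_mid_year_is_continuous(self):
        assert Window(1990).mid_year == 1994.5


class TestMovingWindowOracle:
    def test_matches_bruteforce_enumeration(self, oracle_fixture):
        """Vectorised moving-window synchrony equals the nested-loop oracle."""
        abundance, sites = oracle_fixture
        rec, drop = moving_window_synchrony(
            abundance, sites, SynchronyParams(max_pairs=10**9)
        )
        orec, odrop = oracle_moving_window(abundance, sites)
        key = ["species", "site_a", "site_b", "start_year"]
        merged = rec.merge(orec, on=key, suffixes=("", "_oracle"))
        assert len(merged) == len(rec) == len(orec)
        assert np.allclose(merged["r"], merged["r_oracle"], atol=1e-12)
        assert (merged["n_shared"] == merged["n_shared_oracle"]).all()
        dk = key + ["reason"]
        assert (
            drop[dk].sort_values(dk).reset_index(drop=True).equals(
                odrop[dk].sort_values(dk).reset_index(drop=True)
            )
        )

    def test_scaling_counts_preserves_sign(self, oracle_fixture):
        abundance, sites = oracle_fixture
        rec, _ = moving_window_synchrony(abundance, sites, SynchronyParams(max_pairs=10**9))
        scaled = abundance.assign(count=abundance["count"] * 10)
        rec10, _ = moving_window_synchrony(scaled, sites, SynchronyParams(max_pairs=10**9))
        key = ["species", "site_a", "site_b", "start_year"]
        m = rec.merge(rec10, on=key, suffixes=("", "_x10"))
        same_sign = np.sign(m["r"]) == np.sign(m["r_x10"])
        assert same_sign.mean() >= 0.95


class TestClimateSynchrony:
    def test_same_cell_pair_r_one(self):
        sites = pd.DataFrame(
            {
                "site_id": ["a", "b"],
                "easting_m": [1000.0, 2000.0],  # same 5-km cell
                "northing_m": [1000.0, 2000.0],
            }
        )
        rng = np.random.default_rng(3)
        rows = []
        for y in range(1990, 2002):
            for season in ("winter", "spring", "summer", "autumn"):
                for var in ("temperature", "precipitation"):
                    rows.append(
                        {
                            "grid_cell": "c_0_0",
                            "year": y,
                            "season": season,
                            "variable": var,
                            "value": rng.normal(),
                        }
                    )
        climate = pd.DataFrame(rows)
        pairs = pd.DataFrame({"site_a": ["a"], "site_b": ["b"]})
        rec = climate_synchrony(climate, sites, pairs)
        assert len(rec) == 8 * len(windows_for_years(range(1990, 2002)))
        assert np.allclose(rec["r"], 1.0)

    def test_missing_mapping_raises(self, small_study):
        pairs = pd.DataFrame({"site_a": ["nosite"], "site_b": ["S000"]})
        with pytest.raises(ValueError, match="nosite"):
            climate_synchrony(small_study.climate, small_study.sites, pairs)
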