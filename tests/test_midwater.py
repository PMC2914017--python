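"""Midwater classification, stratum proportions, and the rank correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pelagos as pg

from conftest import make_flat_grid, make_records


class TestIsMidwater:
    @pytest.mark.parametrize(
        "sample,bottom,expected",
        [
            (5.0, 100.0, False),     # within 10 m of the surface on the shelf
            (50.0, 100.0, True),     # interior of the shelf band
            (95.0, 100.0, False),    # within 10 m of the shelf sea bed
            (2900.0, 3000.0, False), # within 200 m of the bathypelagic sea bed
            (1500.0, 3000.0, True),
            (50.0, 500.0, False),    # within 100 m of the surface off the shelf
            (7000.0, 8000.0, False), # within 1000 m of the hadal sea bed
            (5000.0, 8000.0, True),
        ],
    )
    def test_band_rules(self, sample, bottom, expected):
        assert pg.is_midwater(sample, bottom) is expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(21.0, 11000.0, allow_nan=False))
    def test_midwater_set_is_one_contiguous_band(self, bottom):
        """At fixed bottom depth the midwater indicator is 0..1..0 over depth."""
        depths = np.linspace(0.0, bottom, 500)
        ind = pg.is_midwater(depths, np.full_like(depths, bottom)).astype(int)
        flips = int(np.abs(np.diff(ind)).sum())
        assert flips in (0, 2)
        # band edges are exclusive
        surf, bed = pg.DEFAULT_MIDWATER_RULE.bands(bottom)
        assert not pg.is_midwater(float(surf), bottom)
        assert not pg.is_midwater(bottom - float(bed), bottom)


class TestMidwaterByStratum:
    def test_pure_benthic_records_give_zero_proportions(self, fine_scheme):
        bottoms = np.linspace(30, 10_500, 300)
        rec = make_records(bottoms, bottoms)
        tab = pg.midwater_by_stratum(rec, fine_scheme)
        contributing = ~tab["excluded"] & tab["proportion"].notna()
        assert (tab.loc[contributing, "proportion"] == 0).all()

    def test_two_shallowest_fine_strata_excluded(self, fine_scheme):
        tab = pg.midwater_by_stratum(make_records([5.0], [5.0]), fine_scheme)
        assert tab["excluded"].sum() == 2
        assert tab.loc[0, "upper"] == 10.0 and tab.loc[1, "upper"] == 20.0

    def test_56_contributing_strata_give_df_54(self, fine_scheme):
        # one record per stratum midpoint populates all 58 strata
        mids = fine_scheme.midpoints
        rec = make_records(mids, mids)
        summary = pg.summarize_midwater(rec, fine_scheme)
        contributing = ~summary.strata["excluded"] & summary.strata["proportion"].notna()
        assert int(contributing.sum()) == 56
        assert summary.correlation.df == 54

    def test_proportions_match_analytic_oracle(self, fine_scheme):
        """Monte-Carlo stratum proportions agree with the closed form."""
        bottom = 3000.0
        grid = make_flat_grid(bottom)
        n = 30_000
        rec = pg.generate_occurrences(n, grid, seed=21)
        tab = pg.midwater_by_stratum(rec, fine_scheme)
        row = tab.iloc[fine_scheme.assign(bottom)]
        p = pg.expected_midwater_fraction(pg.DEFAULT_MIXTURE, bottom)
        se = np.sqrt(p * (1 - p) / row["n_records"])
        assert abs(row["proportion"] - p) <= 3 * se


class TestRankCorrelation:
    def test_perfect_monotone_decrease(self):
        depths = np.arange(10.0)
        props = np.linspace(0.9, 0.1, 10)
        res = pg.rank_correlation(depths, props)
        assert res.rho == pytest.approx(-1.0)
        assert res.df == 8

    def test_matches_hand_rank_formula_on_toy(self):
        """No ties: Spearman equals 1 - 6*sum(d^2) / (n(n^2-1))."""
        depths = np.array([10.0, 20, 30, 40, 50, 60])
        props = np.array([0.3, 0.1, 0.6, 0.2, 0.5, 0.4])
        rx = stats.rankdata(depths)
        ry = stats.rankdata(props)
        d2 = ((rx - ry) ** 2).sum()
        expected = 1 - 6 * d2 / (6 * (36 - 1))
        res = pg.rank_correlation(depths, props)
        assert res.rho == pytest.approx(expected)

    def test_exact_permutation_p_for_monotone_n5(self):
        depths = np.arange(5.0)
        props = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        res = pg.rank_correlation(depths, props, method="exact")
        # only the two perfectly monotone orderings reach |rho| = 1
        assert res.p_value == pytest.approx(2 / 120)

    def test_constant_proportions_undefined(self):
        res = pg.rank_correlation(np.arange(6.0), np.full(6, 0.3))
        assert np.isnan(res.rho)

    def test_too_few_strata_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            pg.rank_correlation([1.0, 2, 3], [0.1, 0.2, 0.3])

    def test_negative_under_default_generator(self, small_bathy, fine_scheme):
        rec = pg.generate_occurrences(30_000, small_bathy, seed=33)
        clean, _ = pg.clean_records(rec)
        summary = pg.summarize_midwater(clean, fine_scheme)
        assert summary.correlation.rho < 0
        assert summary.correlation.df == summary.correlation.n - 2


class TestZoneSummaries:
    @staticmethod
    def _table(uppers, props):
        return pd.DataFrame(
            {
                "lower": np.asarray(uppers) - 1.0,
                "upper": uppers,
                "midpoint": np.asarray(uppers) - 0.5,
                "n_records": np.ones(len(uppers), dtype=int),
                "n_midwater": np.zeros(len(uppers), dtype=int),
                "proportion": props,
                "excluded": np.zeros(len(uppers), dtype=bool),
            }
        )

    def test_median_and_range(self):
        tab = self._table([50.0, 100.0, 150.0], [0.1, 0.2, 0.3])
        out = pg.zone_summaries(tab).set_index("zone")
        assert out.loc["A", "median"] == pytest.approx(0.2)
        assert out.loc["A", "min"] == pytest.approx(0.1)
        assert out.loc["A", "max"] == pytest.approx(0.3)

    def test_single_stratum_zone(self):
        tab = self._table([7000.0], [0.25])
        out = pg.zone_summaries(tab).set_index("zone")
        assert out.loc["E", "median"] == pytest.approx(0.25)
        assert out.loc["E", "q3"] - out.loc["E", "q1"] == pytest.approx(0.0)

    def test_empty_zone_absent(self):
        tab = self._table([50.0], [0.1])
        out = pg.zone_summaries(tab)
        assert list(out["zone"]) == ["A"]

    def test_every_zone_median_below_half_under_default_mixture(self, small_bathy, fine_scheme):
        """Surface/seabed-concentrated sampling keeps midwater a minority in
        every zone."""
        rec = pg.generate_occurrences(50_000, small_bathy, seed=17)
        clean, _ = pg.clean_records(rec)
        summary = pg.summarize_midwater(clean, fine_scheme)
        assert (summary.zones["median"] < 0.5).all()
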