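"""Strata schemes and the volume-standardized bottom x sample matrix."""

import numpy as np
import pytest

import pelagos as pg

from conftest import make_flat_grid, make_records


def brute_force_valid_cells(n_strata: int) -> int:
    """Enumerate (bottom, sample) stratum pairs with sample <= bottom."""
    return sum(1 for b in range(n_strata) for s in range(n_strata) if s <= b)


class TestBuildScheme:
    def test_default_scheme_has_42_strata(self, default_scheme):
        assert default_scheme.n_strata == 42
        # 4 shelf + 8 mesopelagic + 25 deep + 5 hadal
        widths = default_scheme.widths
        assert (widths[:4] == 50).all()
        assert (widths[4:12] == 100).all()
        assert (widths[12:37] == 200).all()
        assert (widths[37:] == 1000).all()

    def test_default_scheme_valid_cells_903(self, default_scheme):
        assert default_scheme.n_valid_cells == 903
        assert default_scheme.n_valid_cells == brute_force_valid_cells(42)

    def test_fine_scheme_has_58_strata(self, fine_scheme):
        assert fine_scheme.n_strata == 20 + 8 + 25 + 5

    @pytest.mark.parametrize("n", [1, 5, 17])
    def test_triangular_count_any_scheme(self, n):
        scheme = pg.build_scheme(((100.0 * n, 100.0),))
        assert scheme.n_strata == n
        assert scheme.n_valid_cells == brute_force_valid_cells(n)

    def test_strata_tile_without_gaps(self, default_scheme, fine_scheme):
        for sch in (default_scheme, fine_scheme):
            assert sch.lowers[0] == 0.0
            np.testing.assert_allclose(sch.lowers[1:], sch.uppers[:-1])
            assert sch.max_depth == 11000.0

    def test_non_dividing_resolution_rejected(self):
        with pytest.raises(ValueError, match="does not divide"):
            pg.build_scheme(((200.0, 60.0),))

    def test_unordered_bounds_rejected(self):
        with pytest.raises(ValueError, match="ascend"):
            pg.build_scheme(((200.0, 50.0), (100.0, 50.0)))


class TestAssignStratum:
    def test_surface_in_first_stratum(self, default_scheme):
        assert default_scheme.assign(0.0) == 0

    def test_boundary_belongs_to_shallower_stratum(self, default_scheme):
        assert default_scheme.assign(200.0) == 3  # the 150-200 m stratum

    def test_deepest_recorded_sample(self, default_scheme):
        assert default_scheme.assign(10_670.0) == 41  # the 10000-11000 m stratum

    def test_beyond_coverage_raises(self, default_scheme):
        with pytest.raises(ValueError, match="coverage"):
            default_scheme.assign(11_001.0)
        with pytest.raises(ValueError, match="coverage"):
            default_scheme.assign(-1.0)


class TestBuildMatrix:
    def test_single_cell(self, default_scheme):
        rec = make_records([25.0] * 3, [25.0] * 3)
        areas = np.full(42, 1 / 42)
        mat = pg.build_matrix(rec, default_scheme, areas)
        assert mat.counts[0, 0] == 3
        assert mat.counts.sum() == 3
        assert mat.column_proportions[0, 0] == 1.0

    def test_density_inverse_to_volume(self, default_scheme):
        # equal counts in two cells of the same column whose volumes differ 2:1
        rec = make_records([25.0, 75.0], [150.0, 150.0])
        areas = np.full(42, 1 / 42)
        mat = pg.build_matrix(rec, default_scheme, areas)
        b = default_scheme.assign(150.0)
        v0, v1 = mat.volumes[0, b], mat.volumes[1, b]
        assert mat.density[0, b] / mat.density[1, b] == pytest.approx(v1 / v0)

    def test_conservation(self, default_scheme, small_bathy):
        rec = pg.generate_occurrences(20_000, small_bathy, seed=6)
        clean, _ = pg.clean_records(rec)
        areas = pg.stratum_area_fractions(small_bathy, default_scheme)
        mat = pg.build_matrix(clean, default_scheme, areas)
        assert mat.n_records == len(clean)
        prod = mat.density * mat.volumes
        ok = mat.valid & np.isfinite(prod)
        np.testing.assert_allclose(prod[ok], mat.counts[ok])

    def test_column_proportions_normalized(self, default_scheme, small_bathy):
        rec = pg.generate_occurrences(20_000, small_bathy, seed=6)
        clean, _ = pg.clean_records(rec)
        areas = pg.stratum_area_fractions(small_bathy, default_scheme)
        mat = pg.build_matrix(clean, default_scheme, areas)
        colsums = np.nansum(np.where(mat.valid, mat.column_proportions, 0.0), axis=0)
        nonempty = mat.counts.sum(axis=0) > 0
        np.testing.assert_allclose(colsums[nonempty], 1.0, atol=1e-9)

    def test_proportions_invariant_to_count_scaling(self, default_scheme):
        rec = make_records([25.0, 75.0, 25.0], [150.0] * 3)
        areas = np.full(42, 1 / 42)
        once = pg.build_matrix(rec, default_scheme, areas)
        import pandas as pd

        tripled = pd.concat([rec] * 3, ignore_index=True)
        thrice = pg.build_matrix(tripled, default_scheme, areas)
        np.testing.assert_allclose(
            once.column_proportions[once.valid], thrice.column_proportions[thrice.valid],
            equal_nan=True,
        )

    def test_empty_cells_flagged_not_minus_inf(self, default_scheme):
        rec = make_records([25.0], [25.0])
        mat = pg.build_matrix(rec, default_scheme, np.full(42, 1 / 42))
        assert np.isnan(mat.log_density[1, 1])
        assert not np.isneginf(mat.log_density[mat.valid]).any()

    def test_structural_cells_absent(self, default_scheme):
        rec = make_records([25.0], [25.0])
        mat = pg.build_matrix(rec, default_scheme, np.full(42, 1 / 42))
        assert mat.n_valid_cells == 903
        assert not mat.valid[1, 0]  # sample stratum below bottom stratum
        assert np.isnan(mat.volumes[1, 0])

    def test_unclean_records_rejected(self, default_scheme):
        rec = make_records([300.0], [100.0])
        with pytest.raises(ValueError, match="clean"):
            pg.build_matrix(rec, default_scheme, np.full(42, 1 / 42))

    def test_merging_adjacent_sample_strata(self, small_bathy):
        """A coarser sample tiling sums counts/volumes; untouched cells keep
        their density."""
        coarse = pg.build_scheme(((200.0, 50.0), (1000.0, 100.0), (6000.0, 200.0), (11000.0, 1000.0)))
        merged = pg.build_scheme(((200.0, 100.0), (1000.0, 100.0), (6000.0, 200.0), (11000.0, 1000.0)))
        rec = pg.generate_occurrences(5_000, small_bathy, seed=12)
        clean, _ = pg.clean_records(rec)
        a_c = pg.stratum_area_fractions(small_bathy, coarse)
        a_m = pg.stratum_area_fractions(small_bathy, merged)
        mc = pg.build_matrix(clean, coarse, a_c)
        mm = pg.build_matrix(clean, merged, a_m)
        # merged first sample stratum (0,100] = sum of the two 50 m strata,
        # within every bottom column deep enough to hold all of them
        for b_depth in (500.0, 3000.0):
            bc, bm = coarse.assign(b_depth), merged.assign(b_depth)
            assert mm.counts[0, bm] == mc.counts[0, bc] + mc.counts[1, bc]
            assert mm.volumes[0, bm] == pytest.approx(mc.volumes[0, bc] + mc.volumes[1, bc])
            # a deep cell untouched by the merge keeps its density
            s_deep_c, s_deep_m = coarse.assign(b_depth), merged.assign(b_depth)
            assert mc.density[s_deep_c, bc] == pytest.approx(mm.density[s_deep_m, bm], nan_ok=True)

    def test_long_frame_covers_valid_cells(self, default_scheme):
        rec = make_records([25.0], [25.0])
        mat = pg.build_matrix(rec, default_scheme, np.full(42, 1 / 42))
        frame = mat.to_frame()
        assert len(frame) == 903
        assert frame["count"].sum() == 1
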