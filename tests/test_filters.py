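"""The four post-classification filters, each against hand traces or
independent oracles."""

import numpy as np
import pandas as pd
import pytest

from scarmap import (
    BURNED_NEW,
    BURNED_REPEAT,
    UNBURNED,
    BurnHistory,
    GridSpec,
    MonthKey,
    apply_nbr_floor,
    mask_repeats,
    mask_with_hotspots,
    morphological_refine,
    remove_small_patches,
)
from scarmap.filters import apply_filters, FilterParams, load_hotspots

from oracles import hotspot_survivors_oracle, remove_small_oracle

SEPT = MonthKey(2019, 9)


def _blob(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


class TestRemoveSmallPatches:
    def test_threshold_keeps_exactly_at_and_above(self):
        """Components of 100, 156 and 400 pixels: only the last two stay."""
        m = np.zeros((60, 60), dtype=bool)
        m[1:11, 1:11] = True  # 100 px
        m[20:33, 1:13] = True  # 156 px
        m[40:56, 20:45] = True  # 400 px
        out = remove_small_patches(m, min_pixels=156)
        assert not out[1:11, 1:11].any()
        assert out[20:33, 1:13].all()
        assert out[40:56, 20:45].all()

    def test_empty_map(self):
        out = remove_small_patches(np.zeros((10, 10), bool))
        assert not out.any()

    def test_isolated_pixel_removed(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        assert not remove_small_patches(m, min_pixels=156).any()

    def test_never_adds_pixels(self, rng):
        m = rng.random((40, 40)) > 0.6
        out = remove_small_patches(m, min_pixels=10)
        assert not (out & ~m).any()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(20):
            m = rng.random((64, 64)) > 0.7
            got = remove_small_patches(m, min_pixels=12, connectivity=connectivity)
            want = remove_small_oracle(m, min_pixels=12, connectivity=connectivity)
            np.testing.assert_array_equal(got, want)


class TestMorphology:
    def test_solid_square_is_fixed_point(self):
        m = _blob((20, 20), 5, 5, 10, 10)
        np.testing.assert_array_equal(morphological_refine(m), m)

    def test_thin_protrusion_removed_by_opening(self):
        """A 1-pixel-wide spur on a solid patch disappears; the body stays."""
        m = _blob((12, 12), 2, 2, 6, 6)
        m[5, 8:11] = True  # 1-px protrusion sticking out to the right
        out = morphological_refine(m)
        assert not out[5, 8:11].any()
        assert out[2:8, 2:8].all()

    def test_interior_hole_filled_by_closing(self):
        m = _blob((12, 12), 2, 2, 8, 8)
        m[5, 5] = False
        out = morphological_refine(m)
        assert out[5, 5]

    def test_speckle_noise_removed(self, rng):
        m = np.zeros((30, 30), bool)
        idx = rng.integers(0, 30, size=(15, 2))
        m[idx[:, 0], idx[:, 1]] = True  # isolated salt noise
        assert morphological_refine(m).sum() == 0


class TestNbrFloor:
    def test_vegetated_pixel_reverted(self):
        burned = np.ones((2, 2), bool)
        nbr = np.full((2, 2), 0.3)
        assert not apply_nbr_floor(burned, nbr).any()

    def test_charred_pixel_kept(self):
        burned = np.ones((1, 1), bool)
        assert apply_nbr_floor(burned, np.full((1, 1), -0.5)).all()

    def test_boundary_is_strict(self):
        """post NBR exactly -0.1 stays burned (strict > in the rule)."""
        burned = np.ones((1, 1), bool)
        assert apply_nbr_floor(burned, np.full((1, 1), -0.1)).all()
        assert not apply_nbr_floor(burned, np.full((1, 1), -0.0999)).any()

    def test_unburned_never_promoted(self):
        burned = np.zeros((2, 2), bool)
        assert not apply_nbr_floor(burned, np.full((2, 2), -0.9)).any()


def _hotspots(rows):
    return pd.DataFrame(rows, columns=["acq_date", "x", "y", "sensor_resolution_m"])


class TestHotspotMasking:
    grid = GridSpec(40, 40, pixel_size=20.0)

    def _scar(self):
        return _blob(self.grid.shape, 10, 10, 10, 10)

    def test_in_scar_hotspot_keeps_component(self):
        x, y = self.grid.pixel_centres(np.array([15]), np.array([15]))
        hs = _hotspots([("2019-09-10", x[0], y[0], 375.0)])
        out = mask_with_hotspots(self._scar(), hs, self.grid, SEPT)
        np.testing.assert_array_equal(out, self._scar())

    def test_hotspot_beyond_buffer_removes_component(self):
        """Nearest burned pixel 150 m away: beyond the 100-m buffer."""
        x_edge, y = self.grid.pixel_centres(np.array([15]), np.array([19]))
        hs = _hotspots([("2019-09-10", x_edge[0] + 150.0, y[0], 375.0)])
        out = mask_with_hotspots(self._scar(), hs, self.grid, SEPT)
        assert not out.any()

    def test_hotspot_within_buffer_keeps_component(self):
        x_edge, y = self.grid.pixel_centres(np.array([15]), np.array([19]))
        hs = _hotspots([("2019-09-10", x_edge[0] + 90.0, y[0], 375.0)])
        out = mask_with_hotspots(self._scar(), hs, self.grid, SEPT)
        assert out.any()

    def test_out_of_window_hotspot_removes_component(self):
        x, y = self.grid.pixel_centres(np.array([15]), np.array([15]))
        hs = _hotspots([("2019-02-10", x[0], y[0], 375.0)])
        out = mask_with_hotspots(self._scar(), hs, self.grid, SEPT, window_months=4)
        assert not out.any()

    def test_window_anchored_at_reference_month(self):
        """With the 4-month window for ref 2019-09, June counts, May not."""
        x, y = self.grid.pixel_centres(np.array([15]), np.array([15]))
        june = _hotspots([("2019-06-01", x[0], y[0], 375.0)])
        may = _hotspots([("2019-05-31", x[0], y[0], 375.0)])
        assert mask_with_hotspots(self._scar(), june, self.grid, SEPT, window_months=4).any()
        assert not mask_with_hotspots(self._scar(), may, self.grid, SEPT, window_months=4).any()
        # under the 3-month reading June is excluded too
        assert not mask_with_hotspots(self._scar(), june, self.grid, SEPT, window_months=3).any()

    def test_empty_table_removes_everything(self):
        out = mask_with_hotspots(self._scar(), _hotspots([]), self.grid, SEPT)
        assert not out.any()

    def test_infinite_buffer_removes_nothing(self):
        hs = _hotspots([("2019-09-10", 1e7, -1e7, 375.0)])
        out = mask_with_hotspots(self._scar(), hs, self.grid, SEPT, buffer_m=1e9)
        np.testing.assert_array_equal(out, self._scar())

    def test_matches_euclidean_oracle_on_random_scenes(self, rng):
        for _ in range(15):
            mask = remove_small_oracle(rng.random((48, 48)) > 0.75, 4)
            grid = GridSpec(48, 48, pixel_size=20.0, origin=(5000.0, 9000.0))
            n_h = int(rng.integers(1, 6))
            xs = rng.uniform(5000, 5000 + 48 * 20, n_h)
            ys = rng.uniform(9000 - 48 * 20, 9000, n_h)
            hs = _hotspots([("2019-09-01", x, y, 375.0) for x, y in zip(xs, ys)])
            got = mask_with_hotspots(mask, hs, grid, SEPT, buffer_m=100.0)
            want = hotspot_survivors_oracle(
                mask, np.column_stack([xs, ys]), grid, buffer_m=100.0
            )
            np.testing.assert_array_equal(got, want)

    def test_csv_loader_normalises_columns(self, tmp_path):
        p = tmp_path / "firms.csv"
        p.write_text(
            "acq_date,latitude,longitude,instrument\n"
            "2019-09-01,-2.5,112.3,VIIRS\n"
            "2019-09-02,-2.6,112.4,MODIS\n"
        )
        df = load_hotspots(str(p))
        assert list(df["sensor_resolution_m"]) == [375.0, 1000.0]
        assert df["x"].iloc[0] == pytest.approx(112.3)


class TestMaskRepeats:
    def test_persistent_scar_counted_once_then_flagged(self):
        """Detected in Feb and re-detected Mar/Apr/May: burned_new once,
        burned_repeat in all three following months."""
        shape = (10, 10)
        scar = _blob(shape, 2, 2, 4, 4)
        history = BurnHistory(shape)
        months = [MonthKey(2019, m) for m in (2, 3, 4, 5)]
        maps = [mask_repeats(scar, history, mk, lookback=3) for mk in months]
        assert (maps[0].codes[scar] == BURNED_NEW).all()
        for m in maps[1:]:
            assert (m.codes[scar] == BURNED_REPEAT).all()
            assert not m.burned_new_mask().any()

    def test_lookback_boundary_reburn_counts_again(self):
        """Burned in Feb, detected again in June (4 months later):
        burned_new again."""
        shape = (6, 6)
        scar = _blob(shape, 1, 1, 3, 3)
        history = BurnHistory(shape)
        mask_repeats(scar, history, MonthKey(2019, 2), lookback=3)
        out = mask_repeats(scar, history, MonthKey(2019, 6), lookback=3)
        assert (out.codes[scar] == BURNED_NEW).all()

    def test_empty_history_all_new(self):
        shape = (5, 5)
        scar = _blob(shape, 0, 0, 2, 2)
        out = mask_repeats(scar, BurnHistory(shape), SEPT)
        assert (out.codes[scar] == BURNED_NEW).all()
        assert (out.codes[~scar] == UNBURNED).all()

    def test_lookback_crosses_year_boundary(self):
        shape = (5, 5)
        scar = _blob(shape, 0, 0, 2, 2)
        history = BurnHistory(shape)
        mask_repeats(scar, history, MonthKey(2019, 12), lookback=3)
        out = mask_repeats(scar, history, MonthKey(2020, 2), lookback=3)
        assert (out.codes[scar] == BURNED_REPEAT).all()

    def test_history_months_strictly_increasing(self):
        shape = (4, 4)
        scar = np.ones(shape, bool)
        history = BurnHistory(shape)
        mask_repeats(scar, history, MonthKey(2019, 1), lookback=3)
        mask_repeats(scar, history, MonthKey(2019, 6), lookback=3)
        months = history.months_at(0, 0)
        assert months == sorted(months)
        ords = [m.ordinal for m in months]
        assert all(b - a > 3 for a, b in zip(ords, ords[1:]))


class TestFilterChain:
    def test_filters_never_create_burned_pixels_beyond_closing(self, rng):
        grid = GridSpec(64, 64)
        raw = remove_small_oracle(rng.random((64, 64)) > 0.6, 20)
        nbr = np.full((64, 64), -0.4)
        hs = _hotspots([])
        log: list[dict] = []
        history = BurnHistory(grid.shape)
        bm = apply_filters(
            raw, nbr, hs, history, grid, SEPT,
            params=FilterParams(min_pixels=20), log=log,
        )
        # empty hotspot table: everything removed at the hotspot stage
        assert not bm.burned_any_mask().any()
        stages = {rec["stage"]: rec["burned_px"] for rec in log}
        assert stages["hotspot_mask"] == 0
        assert stages["raw"] >= stages["min_mapping_unit"]
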