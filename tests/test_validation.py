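"""Stratified accuracy estimators, temporal confusion, size distributions."""

import numpy as np
import pandas as pd
import pytest

from scarmap import (
    GridSpec,
    MonthKey,
    accuracy_assessment,
    cumulative_curve,
    patch_sizes,
    rebalance_sample,
    size_distribution_tests,
    temporal_confusion,
)
from scarmap.filters import BURNED_NEW, BurnMap
from scarmap.validation import SizeDistribution, cross_stratum


def _points(map_cls, true_cls, strata=None):
    df = pd.DataFrame({"map_class": map_cls, "true_class": true_cls})
    df["stratum"] = strata if strata is not None else df["map_class"]
    return df


class TestRebalance:
    def _maps(self, rng):
        monthly = rng.random((80, 80)) > 0.8
        # annual mostly contains the monthly burns but misses some (the
        # cyan stratum of a monthly/annual disagreement) and adds others
        annual = (monthly & (rng.random((80, 80)) > 0.1)) | (rng.random((80, 80)) > 0.9)
        return monthly, annual

    def _initial_points(self, monthly, annual, rng, n=300):
        rows = rng.integers(0, 80, n)
        cols = rng.integers(0, 80, n)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "map_class": np.where(monthly[rows, cols], "burned", "unburned"),
                "true_class": np.where(annual[rows, cols], "burned", "unburned"),
            }
        )

    def test_reaches_explicit_targets(self, rng):
        monthly, annual = self._maps(rng)
        pts = self._initial_points(monthly, annual, rng)
        targets = {"unburned_burned": 20, "burned_unburned": 4, "burned_burned": 150}
        out = rebalance_sample(pts, monthly, annual, targets, seed=5, true_burned=annual)
        counts = out["stratum"].value_counts()
        for stratum, n in targets.items():
            assert counts[stratum] == n

    def test_identity_when_targets_match(self, rng):
        monthly, annual = self._maps(rng)
        pts = self._initial_points(monthly, annual, rng)
        strata = cross_stratum(monthly, annual)
        pts["stratum"] = strata[pts["row"], pts["col"]]
        targets = pts["stratum"].value_counts().to_dict()
        out = rebalance_sample(pts, monthly, annual, targets, seed=5)
        assert len(out) == len(pts)
        assert out["stratum"].value_counts().to_dict() == targets

    def test_deterministic(self, rng):
        monthly, annual = self._maps(rng)
        pts = self._initial_points(monthly, annual, rng)
        targets = {"burned_burned": 40, "unburned_unburned": 100}
        a = rebalance_sample(pts, monthly, annual, targets, seed=9, true_burned=annual)
        b = rebalance_sample(pts, monthly, annual, targets, seed=9, true_burned=annual)
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_target_raises(self, rng):
        monthly = np.zeros((10, 10), bool)
        monthly[0, 0] = True
        annual = monthly.copy()
        pts = pd.DataFrame(
            {"row": [0], "col": [0], "map_class": ["burned"], "true_class": ["burned"]}
        )
        with pytest.raises(ValueError):
            rebalance_sample(pts, monthly, annual, {"burned_burned": 5}, seed=0)


class TestAccuracyAssessment:
    def test_perfect_agreement(self):
        pts = _points(["burned"] * 30 + ["unburned"] * 70,
                      ["burned"] * 30 + ["unburned"] * 70)
        rep = accuracy_assessment(pts, {"burned": 500.0, "unburned": 1500.0})
        assert rep.oa == pytest.approx(100.0)
        assert rep.ua["burned"] == pytest.approx(100.0)
        assert rep.pa["burned"] == pytest.approx(100.0)
        assert rep.oa_ci == (100.0, 100.0)

    def test_hand_computed_two_by_two(self):
        """Counts (45,5 / 10,40) with equal strata areas: the area-weighted
        matrix gives OA 85, UA 90/80, PA 81.82/88.89."""
        pts = _points(
            ["burned"] * 50 + ["unburned"] * 50,
            ["burned"] * 45 + ["unburned"] * 5 + ["burned"] * 10 + ["unburned"] * 40,
        )
        rep = accuracy_assessment(pts, {"burned": 1000.0, "unburned": 1000.0})
        assert rep.oa == pytest.approx(85.0)
        assert rep.ua["burned"] == pytest.approx(90.0)
        assert rep.ua["unburned"] == pytest.approx(80.0)
        assert rep.pa["burned"] == pytest.approx(100 * 0.45 / 0.55)
        assert rep.pa["unburned"] == pytest.approx(100 * 0.40 / 0.45)
        assert abs(rep.proportions.to_numpy().sum() - 1.0) < 1e-12

    def test_commission_and_omission_are_complements(self):
        pts = _points(
            ["burned"] * 50 + ["unburned"] * 50,
            ["burned"] * 45 + ["unburned"] * 5 + ["burned"] * 10 + ["unburned"] * 40,
        )
        rep = accuracy_assessment(pts, {"burned": 800.0, "unburned": 3200.0})
        for c in ("burned", "unburned"):
            assert rep.commission[c] == pytest.approx(100.0 - rep.ua[c])
            assert rep.omission[c] == pytest.approx(100.0 - rep.pa[c])
        assert rep.oa_ci[0] <= rep.oa <= rep.oa_ci[1]

    def test_estimates_track_exhaustive_truth(self, rng):
        """Stratified estimates from a sample sit near the exhaustively
        computed accuracy of a known map/truth pair."""
        truth = rng.random((200, 200)) > 0.8
        noise = rng.random((200, 200))
        mapped = np.where(noise < 0.9, truth, ~truth)  # 10% class noise
        true_ua = (mapped & truth).sum() / mapped.sum() * 100
        rows_b, cols_b = np.nonzero(mapped)
        rows_u, cols_u = np.nonzero(~mapped)
        take_b = rng.choice(len(rows_b), 250, replace=False)
        take_u = rng.choice(len(rows_u), 250, replace=False)
        rows = np.concatenate([rows_b[take_b], rows_u[take_u]])
        cols = np.concatenate([cols_b[take_b], cols_u[take_u]])
        pts = _points(
            np.where(mapped[rows, cols], "burned", "unburned"),
            np.where(truth[rows, cols], "burned", "unburned"),
        )
        rep = accuracy_assessment(
            pts, {"burned": float(mapped.sum()), "unburned": float((~mapped).sum())}
        )
        assert rep.ua_ci["burned"][0] - 1 <= true_ua <= rep.ua_ci["burned"][1] + 1

    def test_unsampled_stratum_with_area_raises(self):
        pts = _points(["burned"] * 10, ["burned"] * 10)
        with pytest.raises(ValueError):
            accuracy_assessment(pts, {"burned": 100.0, "unburned": 500.0})


class TestTemporalConfusion:
    def test_all_exact(self):
        pts = pd.DataFrame(
            {"detected_month": ["2019-09"] * 5, "true_burn_month": ["2019-09"] * 5}
        )
        tc = temporal_confusion(pts)
        assert tc.exact_agreement == 1.0
        assert tc.over_one_month == 0.0
        assert tc.matrix.to_numpy().sum() == 5

    def test_hand_built_lags(self):
        """10 sites: 7 exact, 2 one-month late, 1 two-months late ->
        70% agreement, 10% beyond one month."""
        true = ["2019-08"] * 10
        detected = ["2019-08"] * 7 + ["2019-09"] * 2 + ["2019-10"]
        tc = temporal_confusion(
            pd.DataFrame({"detected_month": detected, "true_burn_month": true})
        )
        assert tc.exact_agreement == pytest.approx(0.7)
        assert tc.exact_agreement_pct == pytest.approx(70.0)
        assert tc.over_one_month == pytest.approx(0.1)

    def test_requires_both_months(self):
        pts = pd.DataFrame({"detected_month": [""], "true_burn_month": ["2019-08"]})
        with pytest.raises(ValueError):
            temporal_confusion(pts)


def _map_with_blocks(shape, blocks, month=MonthKey(2019, 9)):
    codes = np.zeros(shape, dtype=np.uint8)
    for r0, c0, h, w in blocks:
        codes[r0 : r0 + h, c0 : c0 + w] = BURNED_NEW
    return BurnMap(grid=GridSpec(*shape), codes=codes, month=month)


class TestPatchSizes:
    def test_component_areas_in_hectares(self):
        m = _map_with_blocks((60, 60), [(1, 1, 12, 13), (20, 20, 16, 25)])
        dist = patch_sizes([m])
        assert sorted(dist.areas_ha) == pytest.approx([6.24, 16.0])

    def test_empty_map(self):
        m = _map_with_blocks((10, 10), [])
        assert len(patch_sizes([m]).areas_ha) == 0

    def test_disjoint_events_merge_equals_per_month(self):
        a = _map_with_blocks((40, 40), [(1, 1, 5, 5)], MonthKey(2019, 1))
        b = _map_with_blocks((40, 40), [(20, 20, 7, 7)], MonthKey(2019, 2))
        merged = _map_with_blocks((40, 40), [(1, 1, 5, 5), (20, 20, 7, 7)])
        got = sorted(patch_sizes([a, b]).areas_ha)
        want = sorted(patch_sizes([merged]).areas_ha)
        assert got == pytest.approx(want)


class TestSizeDistributionTests:
    def test_identical_samples_give_zero_ks(self, rng):
        areas = rng.lognormal(3, 1, 300)
        d = SizeDistribution(areas)
        table = size_distribution_tests(d, SizeDistribution(areas.copy()))
        row25 = table[table["threshold_ha"] == 25.0].iloc[0]
        assert row25["ks_stat"] == pytest.approx(0.0)
        assert row25["kw_p"] > 0.9

    def test_empty_threshold_row_marked_na(self, rng):
        small = SizeDistribution(rng.uniform(7, 20, 50))
        table = size_distribution_tests(small, small)
        row = table[table["threshold_ha"] == 1000.0].iloc[0]
        assert np.isnan(row["ks_p"])

    def test_p_decreases_with_shift(self, rng):
        base = rng.lognormal(3.0, 0.5, 200)
        pvals = []
        for shift in (1.0, 1.3, 1.8):
            other = SizeDistribution(base * shift)
            table = size_distribution_tests(SizeDistribution(base), other, thresholds=(0.1,))
            pvals.append(table.iloc[0]["mwu_p"])
        assert pvals[0] > pvals[1] > pvals[2]


class TestCumulativeCurve:
    def test_terminal_value_is_total(self):
        curve = cumulative_curve(SizeDistribution(np.array([1.0, 2.0, 3.0])))
        assert curve["cumulative_ha"].iloc[-1] == pytest.approx(6.0)

    def test_monotone_sorted(self, rng):
        curve = cumulative_curve(SizeDistribution(rng.lognormal(2, 1, 100)))
        assert (np.diff(curve["size_ha"]) >= 0).all()
        assert (np.diff(curve["cumulative_ha"]) >= 0).all()

    def test_power_law_tail_slope_recovered(self, rng):
        """For Pareto(alpha) patch sizes the cumulative-area curve grows as
        size^(2-alpha); the log-log tail slope matches."""
        alpha = 1.5
        sizes = (rng.pareto(alpha, 60_000) + 1.0)
        curve = cumulative_curve(SizeDistribution(sizes))
        x = np.log(curve["size_ha"].to_numpy())
        y = np.log(curve["cumulative_ha"].to_numpy())
        sel = (x > np.quantile(x, 0.55)) & (x < np.quantile(x, 0.97))
        slope = np.polyfit(x[sel], y[sel], 1)[0]
        assert slope == pytest.approx(2 - alpha, abs=0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_curve(SizeDistribution(np.array([])))
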