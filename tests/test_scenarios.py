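"""Scenario catalog, correlation against manual counts, ranking, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from pollencount import (
    ManualCount,
    ScenarioEvaluation,
    SceneParams,
    UndefinedCorrelationError,
    evaluate_scenarios,
    generate_scene,
    pearson_correlation,
    run_scenarios,
    scenario_catalog,
    select_best_scenario,
    summarize_by_group,
)
from pollencount.pipeline import ImageCountResult


class TestScenarioCatalog:
    def test_exactly_seven_scenarios(self):
        assert [s.name for s in scenario_catalog()] == [
            "S0", "S1", "S2", "S3", "S4", "S5", "S6",
        ]

    def test_s0_asymmetric_windows(self):
        s0 = scenario_catalog()[0]
        assert (s0.red_filter.size_min, s0.red_filter.size_max) == (60, 800)
        assert (s0.green_filter.size_min, s0.green_filter.size_max) == (100, 800)
        for f in (s0.red_filter, s0.green_filter):
            assert (f.circ_min, f.circ_max) == (0.4, 1.0)

    def test_grid_windows(self):
        expected = {
            "S1": (100, 900, 0.4), "S2": (200, 900, 0.4),
            "S3": (100, 900, 0.5), "S4": (200, 900, 0.5),
            "S5": (100, 900, 0.6), "S6": (200, 900, 0.6),
        }
        for sc in scenario_catalog()[1:]:
            lo, hi, clo = expected[sc.name]
            for f in (sc.red_filter, sc.green_filter):
                assert (f.size_min, f.size_max) == (lo, hi)
                assert (f.circ_min, f.circ_max) == (clo, 1.0)


class TestRunScenarios:
    def test_cartesian_product_rows(self):
        imgs = [generate_scene(SceneParams(width=320, height=240, n_viable=4,
                                           n_nonviable=2, seed=s))[0]
                for s in (1, 2, 3)]
        table = run_scenarios(imgs, scenario_catalog())
        assert len(table) == 3 * 7
        assert set(table["scenario_name"]) == {f"S{i}" for i in range(7)}

    def test_empty_scenario_list(self):
        img, _ = generate_scene(SceneParams(width=320, height=240, n_viable=2,
                                            n_nonviable=1, seed=4))
        assert len(run_scenarios([img], [])) == 0

    def test_no_images_is_an_error(self):
        with pytest.raises(ValueError):
            run_scenarios([], scenario_catalog())

    def test_nested_windows_monotone_counts(self):
        # S1 >= S3 >= S5 (circularity tightens), S1 >= S2 (size tightens)
        imgs = [generate_scene(SceneParams(width=640, height=480, n_viable=10,
                                           n_nonviable=5, seed=50 + s))[0]
                for s in range(3)]
        table = run_scenarios(imgs, scenario_catalog())
        piv = table.pivot(index="image_id", columns="scenario_name",
                          values="total_count")
        assert (piv["S1"] >= piv["S3"]).all()
        assert (piv["S3"] >= piv["S5"]).all()
        assert (piv["S1"] >= piv["S2"]).all()


class TestPearsonCorrelation:
    def test_perfect_self_correlation(self):
        r, p = pearson_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r, _ = pearson_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_summation_value(self):
        # x=(1,2,3), y=(2,2,4): direct summation gives sqrt(3)/2
        r, _ = pearson_correlation([1, 2, 3], [2, 2, 4])
        assert r == pytest.approx(math.sqrt(3) / 2, abs=1e-12)

    def test_matches_direct_summation_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x, y = rng.normal(size=(2, n))
            r, _ = pearson_correlation(x, y)
            xm, ym = x - x.mean(), y - y.mean()
            oracle = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
            assert r == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2, 3], [1, 2])
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1, 2], [3, 4])
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


def make_results(rows):
    """results table from (image_id, scenario, total, viable) tuples."""
    recs = []
    for image_id, sc, total, viable in rows:
        pv = np.nan if total == 0 else 100.0 * viable / total
        recs.append(
            {"image_id": image_id, "scenario_name": sc, "total_count": total,
             "viable_count": viable, "viability_pct": pv,
             "over_100": bool(total and viable > total), "error": ""}
        )
    return pd.DataFrame(recs)


class TestEvaluateScenarios:
    manual = [ManualCount(f"i{k}", t, v) for k, (t, v) in
              enumerate([(50, 40), (80, 20), (30, 25), (100, 50)])]

    def test_identical_counts_give_r_one(self):
        rows = [(m.image_id, "S1", m.manual_total, m.manual_viable)
                for m in self.manual]
        (ev,) = evaluate_scenarios(make_results(rows), self.manual)
        assert ev.r_count == pytest.approx(1.0)
        assert ev.r_viability == pytest.approx(1.0)
        assert ev.n_images == 4

    def test_constant_viability_flagged_undefined(self):
        rows = [(m.image_id, "S1", m.manual_total, m.manual_total // 2)
                for m in self.manual]
        (ev,) = evaluate_scenarios(make_results(rows), self.manual)
        assert math.isnan(ev.r_viability)
        assert not math.isnan(ev.r_count)

    def test_undefined_pv_excluded_pairwise(self):
        rows = [(m.image_id, "S1", m.manual_total, m.manual_viable)
                for m in self.manual[:3]] + [("i3", "S1", 0, 0)]
        (ev,) = evaluate_scenarios(make_results(rows), self.manual)
        assert ev.n_excluded_viability == 1

    def test_permutation_invariant(self):
        rows = [(m.image_id, "S1", m.manual_total + 3, m.manual_viable)
                for m in self.manual]
        (e1,) = evaluate_scenarios(make_results(rows), self.manual)
        (e2,) = evaluate_scenarios(make_results(rows[::-1]), self.manual[::-1])
        assert e1.r_count == pytest.approx(e2.r_count, abs=1e-12)
        assert e1.r_viability == pytest.approx(e2.r_viability, abs=1e-12)
        assert (e1.n_images, e1.n_excluded_viability) == (
            e2.n_images, e2.n_excluded_viability)

    def test_missing_manual_count_is_an_error(self):
        rows = [("mystery", "S1", 10, 5)]
        with pytest.raises(ValueError, match="mystery"):
            evaluate_scenarios(make_results(rows), self.manual)


def ev(name, r_count, r_viab):
    return ScenarioEvaluation(name, r_count, 0.001, r_viab, 0.001, 10)


class TestSelectBestScenario:
    def test_dominant_scenario_wins(self):
        assert select_best_scenario(
            [ev("S1", 0.99, 0.86), ev("S2", 0.95, 0.80)]) == "S1"

    def test_single_candidate(self):
        assert select_best_scenario([ev("S4", 0.5, 0.2)]) == "S4"

    def test_tie_broken_by_viability_then_name(self):
        assert select_best_scenario(
            [ev("S2", 0.9, 0.7), ev("S1", 0.9, 0.8)]) == "S1"
        assert select_best_scenario(
            [ev("S3", 0.9, 0.8), ev("S1", 0.9, 0.8)]) == "S1"

    def test_all_undefined_is_an_error(self):
        nan = float("nan")
        with pytest.raises(ValueError):
            select_best_scenario([ev("S1", nan, nan)])


class TestSummarizeByGroup:
    def _results(self, pvs, group="g"):
        return [
            ImageCountResult(f"{group}{i}", 100, int(pv), pv)
            for i, pv in enumerate(pvs)
        ]

    def test_two_point_statistics(self):
        res = self._results([40.0, 60.0])
        groups = {r.image_id: "A" for r in res}
        row = summarize_by_group(res, groups).iloc[0]
        assert row["pv_mean"] == pytest.approx(50.0)
        assert row["pv_sd"] == pytest.approx(math.sqrt(200), abs=1e-9)
        assert row["n"] == 2

    def test_groups_with_distinct_viability_separate(self):
        high = self._results([88.0, 91.0, 90.0, 92.5], "h")
        low = self._results([19.0, 22.0, 18.5, 21.0], "l")
        groups = {r.image_id: ("high" if r.image_id.startswith("h") else "low")
                  for r in high + low}
        s = summarize_by_group(high + low, groups).set_index("group")
        pooled = math.sqrt((s.loc["high", "pv_sd"] ** 2 + s.loc["low", "pv_sd"] ** 2) / 2)
        assert s.loc["high", "pv_mean"] - s.loc["low", "pv_mean"] > 3 * pooled

    def test_undefined_pv_excluded_and_counted(self):
        res = self._results([40.0, 60.0]) + [ImageCountResult("g9", 0, 0, None)]
        groups = {r.image_id: "A" for r in res}
        row = summarize_by_group(res, groups).iloc[0]
        assert row["n"] == 3 and row["n_excluded_pv"] == 1
        assert row["pv_mean"] == pytest.approx(50.0)

    def test_empty_group_row(self):
        res = self._results([50.0])
        groups = {res[0].image_id: "A", "phantom": "B"}
        with pytest.raises(ValueError):
            summarize_by_group(res + [ImageCountResult("x", 1, 1, 100.0)], groups)
        s = summarize_by_group(res, groups).set_index("group")
        assert s.loc["B", "n"] == 0
        assert math.isnan(s.loc["B", "pv_mean"])
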