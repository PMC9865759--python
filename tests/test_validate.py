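"""Validation calculators: ME/RE/PE algebra, LOI rule, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from toxscreen.simulate import SimulationConfig
from toxscreen.validate import (
    AreaSet,
    CampaignConfig,
    LOITable,
    determine_loi,
    matrix_effect,
    process_efficiency,
    recovery,
    read_area_csv,
    replicate_ratios,
    run_validation_campaign,
    spectra_reproducibility,
)

pos_areas = st.lists(
    st.floats(1e2, 1e9, allow_nan=False, allow_infinity=False), min_size=2, max_size=8
)


def _sets(neat, after, before, level=50.0):
    return (
        AreaSet("cmpd", "neat", level, np.asarray(neat)),
        AreaSet("cmpd", "spiked_after_extraction", level, np.asarray(after)),
        AreaSet("cmpd", "spiked_before_extraction", level, np.asarray(before)),
    )


class TestRatioCalculators:
    def test_identical_sets_give_unity_zero_rsd(self):
        neat, after, _ = _sets([1e6, 2e6, 3e6], [1e6, 2e6, 3e6], [1e6, 2e6, 3e6])
        stat = matrix_effect(after, neat)
        assert stat.mean == pytest.approx(1.0)
        assert stat.rsd == pytest.approx(0.0, abs=1e-12)
        assert stat.n == 3

    def test_suppression_ratio(self):
        neat_v = np.array([1e6, 1.1e6, 0.9e6, 1.05e6])
        neat, after, _ = _sets(neat_v, 0.12 * neat_v, neat_v)
        assert matrix_effect(after, neat).mean == pytest.approx(0.12, abs=1e-12)

    def test_recovery_ratio(self):
        base = np.array([2e6, 2.2e6])
        neat, after, before = _sets(base, base, 0.9 * base)
        assert recovery(before, after).mean == pytest.approx(0.90, abs=1e-12)

    def test_constructed_me_re_product(self):
        base = np.array([1e6, 1.2e6, 0.8e6])
        neat, after, before = _sets(base, 0.5 * base, 0.5 * 0.8 * base)
        assert process_efficiency(before, neat).mean == pytest.approx(0.40, abs=1e-12)

    def test_replicate_count_mismatch_is_error(self):
        neat = AreaSet("cmpd", "neat", 50.0, np.array([1.0, 2.0]))
        before = AreaSet(
            "cmpd", "spiked_before_extraction", 50.0, np.array([1.0, 2.0, 3.0])
        )
        with pytest.raises(ValueError, match="replicate"):
            process_efficiency(before, neat)

    def test_level_mismatch_is_error(self):
        neat = AreaSet("cmpd", "neat", 50.0, np.array([1.0, 2.0]))
        after = AreaSet("cmpd", "spiked_after_extraction", 500.0, np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="level"):
            matrix_effect(after, neat)

    def test_condition_roles_enforced(self):
        neat, after, before = _sets([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            matrix_effect(neat, after)

    def test_nonpositive_areas_rejected(self):
        with pytest.raises(ValueError):
            AreaSet("cmpd", "neat", 50.0, np.array([1.0, 0.0]))

    @given(pos_areas, pos_areas, pos_areas)
    @hyp_settings(deadline=None, derandomize=True)
    def test_pe_equals_me_times_re_pairwise(self, a, b, c):
        n = min(len(a), len(b), len(c))
        neat, after, before = _sets(a[:n], b[:n], c[:n])
        me = replicate_ratios(after, neat)
        re_ = replicate_ratios(before, after)
        pe = replicate_ratios(before, neat)
        assert np.all(np.abs(pe - me * re_) <= 1e-9 * np.abs(pe))
        # and therefore the reported means obey the same identity
        assert process_efficiency(before, neat).mean == pytest.approx(
            float(np.mean(me * re_)), rel=1e-12
        )

    @given(pos_areas, st.floats(1e-3, 1e3))
    @hyp_settings(deadline=None, derandomize=True)
    def test_rsd_scale_invariant(self, areas, k):
        areas = np.asarray(areas)
        after_v = areas * (1.0 + 0.1 * np.arange(len(areas)))  # non-constant ratios
        neat, after, _ = _sets(areas, after_v, areas)
        scaled_after = AreaSet("cmpd", "spiked_after_extraction", 50.0, k * after_v)
        scaled_neat = AreaSet("cmpd", "neat", 50.0, k * areas)
        s1 = matrix_effect(after, neat)
        s2 = matrix_effect(scaled_after, scaled_neat)
        assert s2.rsd == pytest.approx(s1.rsd, rel=1e-9, abs=1e-12)


class TestLoiRule:
    def _table(self, rows, levels=None):
        rows = np.asarray(rows, dtype=bool)
        levels = levels or [float(2**i) for i in range(rows.shape[0])]
        return LOITable("cmpd", levels, rows)

    def test_lowest_all_pass_level(self):
        t = self._table(
            [[1, 1, 1, 1, 1, 0], [1, 1, 1, 1, 1, 1], [1, 1, 1, 1, 1, 1]],
            levels=[1.0, 5.0, 10.0],
        )
        assert determine_loi(t) == 5.0

    def test_all_rows_pass_gives_lowest(self):
        t = self._table([[1, 1], [1, 1], [1, 1]])
        assert determine_loi(t) == t.levels[0]

    def test_top_row_failing_means_not_reached(self):
        t = self._table([[1, 1], [1, 1], [1, 0]])
        assert determine_loi(t) is None

    def test_monotone_guard_skips_flukes(self):
        t = self._table([[1, 1], [0, 1], [1, 1]])
        assert determine_loi(t) == t.levels[2]
        assert determine_loi(t, require_monotone=False) == t.levels[0]

    def test_adding_passes_at_higher_levels_never_raises_loi(self):
        rows = np.array([[0, 1], [1, 1], [0, 1], [1, 1]], dtype=bool)
        t1 = self._table(rows)
        improved = rows.copy()
        improved[2] = [1, 1]
        t2 = self._table(improved)
        l1, l2 = determine_loi(t1), determine_loi(t2)
        assert (l1 is None) or (l2 is not None and l2 <= l1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            LOITable("cmpd", [], np.zeros((0, 2), dtype=bool))


class TestReproducibility:
    def test_constant_scores_zero_rsd(self):
        stat = spectra_reproducibility([800.0] * 6)
        assert stat.rsd == pytest.approx(0.0, abs=1e-12)

    def test_two_scores_hand_value(self):
        stat = spectra_reproducibility([900.0, 1000.0])
        assert stat.mean == pytest.approx(950.0)
        assert stat.rsd == pytest.approx(100.0 * np.std([900, 1000], ddof=1) / 950.0)
        assert stat.rsd == pytest.approx(7.44, abs=0.01)

    def test_single_score_is_error(self):
        with pytest.raises(ValueError):
            spectra_reproducibility([900.0])


class TestAreaCsv:
    def test_round_trip_grouping(self, tmp_path):
        df = pd.DataFrame(
            {
                "compound": ["a"] * 4 + ["b"] * 2,
                "condition": ["neat"] * 2 + ["spiked_after_extraction"] * 2 + ["neat"] * 2,
                "level": [50.0] * 6,
                "replicate": [1, 2, 1, 2, 1, 2],
                "area": [1e5, 1.1e5, 5e4, 5.4e4, 2e5, 2.1e5],
            }
        )
        path = tmp_path / "areas.csv"
        df.to_csv(path, index=False)
        sets = {(s.compound, s.condition): s for s in read_area_csv(str(path))}
        assert len(sets) == 3
        me = matrix_effect(sets[("a", "spiked_after_extraction")], sets[("a", "neat")])
        assert me.mean == pytest.approx(np.mean([0.5, 5.4 / 11]), rel=1e-9)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"compound": ["a"], "area": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_area_csv(str(path))


@pytest.fixture(scope="module")
def small_campaign(fixture_lib):
    cfg = CampaignConfig(
        compounds=["Tramadol", "Oxazepam", "Morphine"],
        me_levels=(50.0,),
        loi_levels=(5.0, 50.0, 200.0),
        n_replicates=3,
        matrix_factors={"Morphine": 0.12},
        sim=SimulationConfig(gradient_length=420.0),
        seed=5,
    )
    return cfg, run_validation_campaign(fixture_lib, cfg)


class TestCampaign:
    def test_summary_complete(self, small_campaign):
        _, summary = small_campaign
        assert len(summary.ratios) == 3 * 3  # compounds x {ME, RE, PE}
        assert not summary.ratios["mean"].isna().any()
        assert set(summary.loi["compound"]) == {"Tramadol", "Oxazepam", "Morphine"}
        assert len(summary.reproducibility) == 3

    def test_pe_equals_me_times_re_in_summary(self, small_campaign):
        _, summary = small_campaign
        wide = summary.ratios.pivot_table(
            index=["compound", "level_ug_per_l"], columns="metric", values="mean"
        )
        # means of pairwise ratios from the same runs: identity holds closely
        assert np.allclose(wide["PE"], wide["ME"] * wide["RE"], rtol=0.02)

    def test_suppressed_compound_flagged(self, small_campaign):
        _, summary = small_campaign
        me = summary.ratios.query("compound == 'Morphine' and metric == 'ME'")["mean"]
        assert float(me.iloc[0]) < 0.2

    def test_campaign_deterministic(self, fixture_lib, small_campaign):
        cfg, summary = small_campaign
        again = run_validation_campaign(fixture_lib, cfg)
        pd.testing.assert_frame_equal(summary.ratios, again.ratios)
        pd.testing.assert_frame_equal(summary.loi, again.loi)
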