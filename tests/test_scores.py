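import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoquant import (
    CtTable,
    LickSession,
    LickTrial,
    TwoBottleRecord,
    ddct_fold_change,
    lick_ratio,
    thirst_metric,
    two_bottle_preference,
)


class TestTwoBottle:
    def test_equal_volumes_is_no_preference_line(self):
        assert two_bottle_preference(TwoBottleRecord(5.0, 5.0)) == 50.0

    def test_three_to_one(self):
        assert two_bottle_preference(TwoBottleRecord(9.0, 3.0)) == 75.0

    def test_zero_tastant(self):
        assert two_bottle_preference(TwoBottleRecord(0.0, 4.0)) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            two_bottle_preference(TwoBottleRecord(0.0, 0.0))

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            TwoBottleRecord(-1.0, 2.0)

    @settings(deadline=None, derandomize=True)
    @given(
        t=st.floats(0, 100, allow_nan=False),
        w=st.floats(0, 100, allow_nan=False),
    )
    def test_complementarity(self, t, w):
        if t + w == 0:
            return
        fwd = two_bottle_preference(TwoBottleRecord(t, w))
        rev = two_bottle_preference(TwoBottleRecord(w, t))
        assert fwd + rev == pytest.approx(100.0)
        assert 0.0 <= fwd <= 100.0


def _session(day, blocks, tastant="SC45647"):
    """blocks: list of dicts bottle -> licks, one dict per block."""
    trials = [
        LickTrial(block=i + 1, bottle=b, licks=licks)
        for i, block in enumerate(blocks)
        for b, licks in block.items()
    ]
    return LickSession(trials=tuple(trials), day=day, tastant=tastant)


class TestLickRatio:
    def test_simple_ratio(self):
        s = _session(1, [{"water": 30, "c1": 60}], tastant="quinine")
        assert lick_ratio([s], "c1") == pytest.approx(2.0)

    def test_equal_means_give_one(self):
        s = _session(1, [{"water": 25, "c1": 25}] * 3, tastant="citric")
        assert lick_ratio([s], "c1") == pytest.approx(1.0)

    def test_first_block_exclusion_changes_worked_example(self):
        s = _session(
            1,
            [{"water": 40, "c1": 40}, {"water": 20, "c1": 30}],
            tastant="SC45647",
        )
        # with block 1: (40+30)/2 over (40+20)/2 = 35/30
        assert lick_ratio([s], "c1", exclude_first_block=False) == pytest.approx(
            35 / 30
        )
        # sweet panel default: block 1 dropped -> 30/20
        assert lick_ratio([s], "c1") == pytest.approx(1.5)

    def test_exclusion_defaults_off_for_non_sweet(self):
        s = _session(
            1, [{"water": 40, "c1": 40}, {"water": 20, "c1": 30}], tastant="quinine"
        )
        assert lick_ratio([s], "c1") == pytest.approx(35 / 30)

    def test_pools_across_days_by_default(self):
        s1 = _session(1, [{"water": 10, "c1": 30}] * 2, tastant="quinine")
        s2 = _session(2, [{"water": 30, "c1": 30}] * 2, tastant="quinine")
        pooled = lick_ratio([s1, s2], "c1")
        assert pooled == pytest.approx(30 / 20)
        per_day = lick_ratio([s1, s2], "c1", per_day=True)
        assert per_day == pytest.approx((3.0 + 1.0) / 2)

    def test_scale_invariance(self):
        blocks = [{"water": 10, "c1": 25}, {"water": 14, "c1": 30}]
        s = _session(1, blocks, tastant="quinine")
        s3 = _session(
            1, [{b: v * 3 for b, v in blk.items()} for blk in blocks], "quinine"
        )
        assert lick_ratio([s3], "c1") == pytest.approx(lick_ratio([s], "c1"))

    def test_no_eligible_trials_rejected(self):
        s = _session(1, [{"water": 40, "c1": 40}], tastant="SC45647")
        with pytest.raises(ValueError):  # only block 1 exists and is excluded
            lick_ratio([s], "c1")

    def test_zero_water_mean_rejected(self):
        s = _session(1, [{"water": 0, "c1": 40}], tastant="quinine")
        with pytest.raises(ValueError):
            lick_ratio([s], "c1")


class TestThirstMetric:
    def test_mean_of_day_totals(self):
        s1 = _session(1, [{"water": 40, "a": 30, "b": 20, "c": 20, "d": 10}])
        s2 = _session(2, [{"water": 20, "a": 20, "b": 20, "c": 10, "d": 10}])
        assert thirst_metric([s1, s2]) == pytest.approx((120 + 80) / 2)

    def test_identical_days(self):
        s = _session(1, [{"water": 25, "c1": 30}])
        assert thirst_metric([s, s]) == pytest.approx(55.0)

    def test_missing_first_block_rejected(self):
        bad = LickSession(
            trials=(LickTrial(block=2, bottle="water", licks=10),), day=2
        )
        good = _session(1, [{"water": 10}])
        with pytest.raises(ValueError):
            thirst_metric([good, bad])


def _ct_table(rows):
    return CtTable(pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"]))


class TestDdct:
    def test_hand_computed_fold_of_four(self):
        table = _ct_table(
            [
                ("c1", "control", "Rpl19", 20.0),
                ("c1", "control", "Lgr5", 26.0),
                ("t1", "treated", "Rpl19", 20.0),
                ("t1", "treated", "Lgr5", 24.0),
            ]
        )
        out = ddct_fold_change(table, "Lgr5")
        fold = out.set_index("sample_id")["fold"]
        assert fold["t1"] == pytest.approx(4.0)
        assert fold["c1"] == pytest.approx(1.0)

    def test_sample_at_control_mean_is_one(self):
        table = _ct_table(
            [
                ("c1", "control", "Rpl19", 18.0),
                ("c1", "control", "Gnat3", 25.0),
                ("c2", "control", "Rpl19", 18.0),
                ("c2", "control", "Gnat3", 25.0),
                ("t1", "treated", "Rpl19", 18.0),
                ("t1", "treated", "Gnat3", 25.0),
            ]
        )
        out = ddct_fold_change(table, "Gnat3")
        assert np.allclose(out["fold"], 1.0)

    def test_control_folds_have_unit_geometric_mean(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(6):
            rows.append((f"c{i}", "control", "Rpl19", 18 + rng.normal(0, 0.3)))
            rows.append((f"c{i}", "control", "Trpm5", 24 + rng.normal(0, 0.5)))
        out = ddct_fold_change(_ct_table(rows), "Trpm5")
        geo = np.exp(np.mean(np.log(out["fold"])))
        assert geo == pytest.approx(1.0, abs=1e-12)

    def test_shared_ct_offset_invariance(self):
        rng = np.random.default_rng(4)
        rows = []
        for i, grp in enumerate(["control"] * 3 + ["treated"] * 3):
            rows.append((f"s{i}", grp, "Rpl19", 18 + rng.normal(0, 0.2)))
            rows.append((f"s{i}", grp, "Kit", 23 + rng.normal(0, 0.4)))
        base = ddct_fold_change(_ct_table(rows), "Kit")
        shifted = _ct_table([(s, g, gene, ct + 1.7) for s, g, gene, ct in rows])
        out = ddct_fold_change(shifted, "Kit")
        np.testing.assert_allclose(out["fold"], base["fold"])

    def test_missing_housekeeping_rejected(self):
        with pytest.raises(ValueError):
            _ct_table([("s1", "control", "Lgr5", 24.0)])

    def test_empty_control_group_rejected(self):
        table = _ct_table(
            [("t1", "treated", "Rpl19", 18.0), ("t1", "treated", "Lgr5", 24.0)]
        )
        with pytest.raises(ValueError):
            ddct_fold_change(table, "Lgr5", control_group="control")

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            _ct_table([("s1", "control", "Rpl19", np.nan)])
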