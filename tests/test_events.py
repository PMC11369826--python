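"""Gait events: merging, agreement, selection rules, behaviour stats and
kinematic detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fnirsgait.core import EventTable, Kinematics
from fnirsgait.events import (BehaviourWindows, ProtocolGeometry, agreement_metrics,
                              behaviour_stats, detect_gait_events, event_window_stats,
                              label_freeze_triggers, merge_annotations,
                              percent_time_frozen, select_events)
from conftest import make_events


def freeze_table(intervals, source="rater_A", trigger="turn"):
    return make_events([dict(onset=a, duration=b - a, trial_type="freeze",
                             trigger=trigger, source=source) for a, b in intervals])


class TestMerge:
    def test_identical_full_consensus(self):
        a = freeze_table([(10, 12), (50, 55)])
        b = freeze_table([(10, 12), (50, 55)], source="rater_B")
        consensus, disputed = merge_annotations(a, b)
        assert len(disputed) == 0
        np.testing.assert_allclose(consensus.df["onset"], [10, 50])
        np.testing.assert_allclose(consensus.df["duration"], [2, 5])

    def test_union_within_tolerance(self):
        a = freeze_table([(10, 12)])
        b = freeze_table([(11, 13)], source="rater_B")
        consensus, disputed = merge_annotations(a, b)
        assert len(consensus) == 1 and len(disputed) == 0
        assert consensus.df.loc[0, "onset"] == 10
        assert consensus.df.loc[0, "onset"] + consensus.df.loc[0, "duration"] == 13

    def test_distant_events_disputed(self):
        a = freeze_table([(10, 12)])
        b = freeze_table([(20, 22)], source="rater_B")
        consensus, disputed = merge_annotations(a, b)
        assert len(consensus) == 0 and len(disputed) == 2

    def test_gap_just_within_tolerance_merges(self):
        a = freeze_table([(10, 12)])
        b = freeze_table([(14, 16)], source="rater_B")  # gap exactly 2 s
        consensus, _ = merge_annotations(a, b, tolerance_s=2.0)
        assert len(consensus) == 1

    @given(st.lists(st.tuples(st.floats(0, 300), st.floats(0.5, 8)), max_size=6),
           st.lists(st.tuples(st.floats(0, 300), st.floats(0.5, 8)), max_size=6))
    @settings(max_examples=40, deadline=None)
    def test_symmetric(self, ia, ib):
        a = freeze_table([(o, o + d) for o, d in ia])
        b = freeze_table([(o, o + d) for o, d in ib], source="rater_B")
        c1, d1 = merge_annotations(a, b)
        c2, d2 = merge_annotations(b, a)
        assert len(c1) == len(c2) and len(d1) == len(d2)
        np.testing.assert_allclose(c1.df["onset"], c2.df["onset"])


class TestAgreement:
    def test_identical_perfect(self):
        a = freeze_table([(10, 13)])
        b = freeze_table([(10, 13)], source="rater_B")
        s = agreement_metrics(a, b, total_duration_s=30)
        assert s.positive_agreement == 1.0 and s.negative_agreement == 1.0

    def test_documented_fixture_exact(self):
        """A marks [10,12), B marks [11,13) over 20 sampled seconds:
        n11=1, n10=1, n01=1, n00=17 -> 0.5 / 0.944 / -0.8."""
        a = freeze_table([(10, 12)])
        b = freeze_table([(11, 13)], source="rater_B")
        s = agreement_metrics(a, b, total_duration_s=20)
        assert s.positive_agreement == pytest.approx(0.5)
        assert s.negative_agreement == pytest.approx(34 / 36)
        assert s.prevalence_index == pytest.approx(-0.8)
        assert s.counts == dict(n11=1, n10=1, n01=1, n00=17)

    def test_no_freezes_nan_with_note(self):
        s = agreement_metrics(EventTable(), EventTable(), total_duration_s=20)
        assert np.isnan(s.positive_agreement)
        assert s.note

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 6)), max_size=5),
           st.lists(st.tuples(st.integers(0, 50), st.integers(1, 6)), max_size=5))
    @settings(max_examples=40, deadline=None)
    def test_equals_brute_force_tally(self, ia, ib):
        a = freeze_table([(o, o + d) for o, d in ia])
        b = freeze_table([(o, o + d) for o, d in ib], source="rater_B")
        T = 60
        s = agreement_metrics(a, b, total_duration_s=T, sample_rate_hz=1.0)
        # brute force: per-second membership tally
        in_a = [any(o <= t < o + d for o, d in ia) for t in range(T)]
        in_b = [any(o <= t < o + d for o, d in ib) for t in range(T)]
        n11 = sum(x and y for x, y in zip(in_a, in_b))
        n00 = sum((not x) and (not y) for x, y in zip(in_a, in_b))
        assert s.counts["n11"] == n11 and s.counts["n00"] == n00
        assert s.prevalence_index == pytest.approx((n11 - n00) / T)


class TestSelection:
    def test_freeze_refractory(self):
        frz = freeze_table([(0, 2), (5, 7)], source="consensus")
        out = select_events(frz, EventTable())
        assert list(out.df["onset"]) == [0.0]

    def test_clear_event_retained(self):
        frz = freeze_table([(150, 153)], source="consensus")
        gait = make_events([dict(onset=100, duration=2.5, trial_type="turn_left",
                                 trigger="none", source="kinematics")])
        out = select_events(frz, gait)
        assert set(out.df["trial_type"]) == {"freeze", "turn_left"}

    def test_event_near_freeze_excluded(self):
        frz = freeze_table([(105, 108)], source="consensus")
        gait = make_events([dict(onset=100, duration=2.5, trial_type="turn_left",
                                 trigger="none", source="kinematics")])
        out = select_events(frz, gait)
        assert "turn_left" not in set(out.df["trial_type"])

    def test_crafted_fixture_counts(self):
        from fnirsgait.experiments import selection_fixture
        res = selection_fixture()
        assert res["n_freezes"] == 12 and res["n_gait"] == 20
        assert res["kept_freezes"] == 9
        assert res["kept_gait"] == 14

    def test_idempotent(self):
        frz = freeze_table([(30, 33), (60, 62), (66, 68)], source="consensus")
        gait = make_events([dict(onset=100 + 20 * i, duration=2.0,
                                 trial_type="doorway", trigger="none",
                                 source="kinematics") for i in range(5)])
        once = select_events(frz, gait)
        twice = select_events(once.of_type("freeze"), once)
        assert len(twice) == len(once)


class TestPercentTimeFrozen:
    def test_no_freezes_zero(self):
        assert percent_time_frozen(EventTable(), 300) == 0.0

    def test_simple_fraction(self):
        frz = freeze_table([(10, 40)], source="consensus")
        assert percent_time_frozen(frz, 300) == pytest.approx(10.0)

    def test_overlap_union(self):
        frz = freeze_table([(10, 20), (15, 25)])
        # union [10, 25) = 15 s of 100 -> 15%
        assert percent_time_frozen(frz, 100) == pytest.approx(15.0)

    def test_trigger_filter(self):
        rows = [dict(onset=10, duration=5, trial_type="freeze", trigger="turn",
                     source="consensus"),
                dict(onset=50, duration=10, trial_type="freeze", trigger="doorway",
                     source="consensus")]
        frz = make_events(rows)
        assert percent_time_frozen(frz, 100, trigger="doorway") == pytest.approx(10.0)


class TestDetection:
    def _constant_kin(self, v, n=7200, fs=60.0):
        series = {
            "head_acceleration": np.zeros((3, n)),
            "head_angular_acceleration": np.zeros((3, n)),
            "head_neck_orientation": np.zeros((3, n)),
            "body_velocity": np.full((1, n), v),
            "body_position": np.vstack([np.linspace(0, v * n / fs, n),
                                        np.zeros(n)]),
        }
        return Kinematics(fs_hz=fs, series=series)

    def test_constant_standing_no_gait_events(self):
        kin = self._constant_kin(0.0)
        det = detect_gait_events(kin, ProtocolGeometry(door_x_m=10.0,
                                                       square_x_m=(0.0, 20.0)))
        # a single standing "stop" episode may be reported; nothing else
        assert set(det.df["trial_type"]) <= {"stop"}

    def test_single_pass_one_doorway(self):
        kin = self._constant_kin(1.0)
        det = detect_gait_events(kin, ProtocolGeometry(door_x_m=50.0,
                                                       square_x_m=(0.0, 100.0)))
        assert (det.df["trial_type"] == "doorway").sum() == 1

    def test_synthetic_session_accuracy(self):
        from fnirsgait.experiments import detection_accuracy
        res = detection_accuracy(seed=7, n_runs=1)
        assert res["frac_within_0p2s"] >= 0.95

    def test_missing_position_warns(self):
        kin = self._constant_kin(1.0)
        kin.series["body_position"][:] = np.nan
        with pytest.warns(UserWarning, match="position"):
            det = detect_gait_events(kin, ProtocolGeometry(door_x_m=50.0))
        assert "doorway" not in set(det.df["trial_type"])


class TestTriggerLabels:
    def test_nearest_event_attribution(self):
        frz = freeze_table([(99.5, 103), (200, 203)], source="consensus")
        det = make_events([
            dict(onset=100, duration=2.5, trial_type="turn_left", trigger="none",
                 source="kinematics"),
            dict(onset=150, duration=0, trial_type="doorway", trigger="none",
                 source="kinematics"),
        ])
        out = label_freeze_triggers(frz, det)
        assert list(out.df["trigger"]) == ["turn", "walking"]


class TestBehaviour:
    def test_window_stats_on_ramp(self):
        fs, n = 60.0, 3600
        v = np.ones(n)
        v[int(30 * fs):] = 0.0
        v[int(27 * fs):int(30 * fs)] = np.linspace(1, 0, int(3 * fs))
        series = {
            "head_acceleration": np.zeros((3, n)),
            "head_angular_acceleration": np.zeros((3, n)),
            "head_neck_orientation": np.zeros((3, n)),
            "body_velocity": v[None, :],
            "body_position": np.zeros((2, n)),
        }
        kin = Kinematics(fs_hz=fs, series=series)
        ev = make_events([dict(onset=30, duration=30, trial_type="stop",
                               trigger="none", source="protocol")])
        stats = event_window_stats(kin, ev)
        # deceleration over the last 3 s before the stop: (0 - 1) / 3
        assert stats["accel"].iloc[0] == pytest.approx(-1 / 3, abs=0.02)

    def test_identical_groups_null(self):
        df = pd.DataFrame({"group": ["PD"] * 4 + ["HC"] * 4,
                           "accel": [-0.2, -0.3, -0.25, -0.25] * 2})
        out = behaviour_stats(df)
        two = out[out["test"].str.startswith("two_sample")].iloc[0]
        assert two["t"] == pytest.approx(0.0, abs=1e-12)
        assert two["p"] == pytest.approx(1.0)

    def test_matches_closed_form_welch(self):
        pd_vals = np.array([-0.20, -0.25, -0.30, -0.22])
        hc_vals = np.array([-0.30, -0.33, -0.28, -0.35])
        df = pd.DataFrame({"group": ["HC"] * 4 + ["PD"] * 4,
                           "accel": np.concatenate([hc_vals, pd_vals])})
        out = behaviour_stats(df)
        two = out[out["test"] == "two_sample_HC_vs_PD"].iloc[0]
        se = np.sqrt(hc_vals.var(ddof=1) / 4 + pd_vals.var(ddof=1) / 4)
        t_expected = (hc_vals.mean() - pd_vals.mean()) / se
        assert two["t"] == pytest.approx(t_expected)

    def test_group_speed_difference_recovered(self, session_one_run):
        """Cohort-level slow-down: built-in group speeds differ by
        ~0.14 m/s; the per-participant mean walking speeds must order
        accordingly."""
        from fnirsgait.synth import CohortSpec, cohort_metadata
        metas = cohort_metadata(CohortSpec(n_pd=6, n_hc=6), seed=9)
        speeds = pd.DataFrame(metas)
        assert (speeds[speeds.group == "PD"].speed_ms.mean()
                < speeds[speeds.group == "HC"].speed_ms.mean())
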