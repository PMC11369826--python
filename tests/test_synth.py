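"""Synthetic-session generator: schedule arithmetic, determinism, and the
forward model's construction guarantees."""

import dataclasses

import numpy as np
import pytest

from fnirsgait.synth import (GroundTruth, ProtocolSpec, double_gamma_hrf,
                             generate_protocol, generate_session, rater_annotations)


def enumerate_schedule(spec: ProtocolSpec):
    """Independent arithmetic enumeration of one run's non-freeze schedule:
    walk legs of ``walk_leg_s`` alternating door/square arrivals, a stop
    every ``legs_per_stop`` legs, turns at squares otherwise."""
    events = [("stand", 0.0), ("start", spec.initial_stand_s)]
    t = spec.initial_stand_s
    legs = 0
    at_square = True
    while True:
        end = t + spec.walk_leg_s
        if end + spec.turn_duration_s > spec.run_length_s:
            break
        t = end
        at_square = not at_square
        legs += 1
        if legs % spec.legs_per_stop == 0:
            if t + spec.stop_duration_s + spec.start_duration_s > spec.run_length_s:
                break
            events.append(("stop", t))
            t += spec.stop_duration_s
            events.append(("start", t))
        elif at_square:
            events.append(("turn", t))
            t += spec.turn_duration_s
        else:
            events.append(("doorway", t))
    return events


class TestProtocol:
    def test_deterministic(self):
        spec = ProtocolSpec()
        assert generate_protocol(spec, seed=5) == generate_protocol(spec, seed=5)

    def test_no_freezes_when_rate_zero(self):
        spec = ProtocolSpec(freeze_rates={}, walking_freeze_rate_per_s=0.0)
        tbl = generate_protocol(spec, seed=3)
        assert set(tbl.df["trial_type"]) <= {"stand", "start", "stop", "doorway",
                                             "turn_left", "turn_right"}

    def test_matches_enumerated_schedule(self):
        spec = ProtocolSpec()
        tbl = generate_protocol(spec, seed=1, freezer=False)
        expected = enumerate_schedule(spec)
        got = [(t if t not in ("turn_left", "turn_right") else "turn", o)
               for t, o in zip(tbl.df["trial_type"], tbl.df["onset"])]
        got = [(t, o) for t, o in got if t != "freeze"]
        assert got == [(t, pytest.approx(o)) for t, o in expected]

    def test_turn_directions_alternate(self):
        spec = ProtocolSpec()
        tbl = generate_protocol(spec, seed=2, freezer=False)
        turns = tbl.df[tbl.df["trial_type"].isin(["turn_left", "turn_right"])]
        stops = tbl.df[tbl.df["trial_type"] == "stop"]["onset"].to_numpy()
        prev_type, prev_onset = None, None
        for _, ev in turns.iterrows():
            if prev_type is not None:
                n_stops_between = int(((stops > prev_onset) & (stops < ev.onset)).sum())
                if n_stops_between == 0:
                    assert ev.trial_type != prev_type  # alternates between squares
                else:  # direction switch after each instructed stop
                    assert ev.trial_type == prev_type
            prev_type, prev_onset = ev.trial_type, ev.onset

    def test_events_fit_run(self):
        tbl = generate_protocol(ProtocolSpec(), seed=9)
        df = tbl.df[tbl.df["trial_type"] != "freeze"]
        assert (df["onset"] + df["duration"] <= ProtocolSpec().run_length_s + 1e-9).all()


class TestHrf:
    def test_peaks_near_stated_delay(self):
        t = np.arange(0, 30, 0.02)
        h = double_gamma_hrf(t)
        assert h.max() == pytest.approx(1.0)
        assert t[np.argmax(h)] == pytest.approx(6.0, abs=0.1)
        assert h[t > 25].max() < 0.05  # returns toward baseline


class TestSession:
    def test_deterministic(self):
        spec = ProtocolSpec(n_runs=1)
        a = generate_session(spec, GroundTruth(), {"group": "PD"}, seed=11)
        b = generate_session(spec, GroundTruth(), {"group": "PD"}, seed=11)
        np.testing.assert_array_equal(a.runs[0].recording.data, b.runs[0].recording.data)

    def test_zero_everything_constant_intensity(self):
        truth = GroundTruth(roi_amplitudes={}, systemic_scale_uM=0.0,
                            kinematic_gain_uM_per_deg=0.0, noise_od_sd=0.0,
                            spike_prob=0.0, shift_prob=0.0)
        s = generate_session(ProtocolSpec(n_runs=1), truth, {"group": "PD"}, seed=1)
        data = s.runs[0].recording.data
        assert np.allclose(data, data[:, :1])

    def test_nonfinite_amplitude_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(roi_amplitudes={("stop", "SMA"): np.nan})

    def test_systemic_only_long_short_coupling(self):
        """With neural/noise off, each channel's OD tracks its own known
        systemic loading (correlation > 0.9 by construction)."""
        truth = GroundTruth(roi_amplitudes={}, kinematic_gain_uM_per_deg=0.0,
                            noise_od_sd=1e-5, spike_prob=0.0, shift_prob=0.0)
        s = generate_session(ProtocolSpec(n_runs=1), truth, {"group": "PD"}, seed=2)
        run = s.runs[0]
        od = -np.log10(run.recording.data / run.recording.data.mean(1, keepdims=True))
        from fnirsgait.synth import systemic_components
        # reconstruct the component matrix from the same seed stream is not
        # possible post hoc; instead check long-vs-short coupling via the
        # pooled subspace: any long channel row must be nearly explained by
        # the short rows (shared rank-8 structure)
        kinds = [c.kind for c in s.montage.channels for _ in range(2)]
        kinds = np.array(kinds)
        shorts = od[kinds == "short"]
        longs = od[kinds == "long"]
        X = shorts.T
        beta, *_ = np.linalg.lstsq(X, longs.T, rcond=None)
        fitted = (X @ beta).T
        r = [np.corrcoef(fitted[i], longs[i])[0, 1] for i in range(0, len(longs), 8)]
        assert min(r) > 0.9

    def test_short_channels_have_no_neural_component(self, session_one_run):
        """Regressing short-channel concentrations on the neural time
        courses explains almost nothing (construction invariant)."""
        s = session_one_run
        run = s.runs[0]
        clean = run.clean_neural_hbo  # long channels x samples (µM, 50 Hz)
        od = -np.log10(run.recording.data / run.recording.data.mean(1, keepdims=True))
        kinds = np.array([c.kind for c in s.montage.channels for _ in range(2)])
        shorts = od[kinds == "short"]
        # unique ROI drive signatures as the neural design
        X = clean[::6].T
        X = (X - X.mean(0)) / X.std(0)
        for row in shorts[::8]:
            beta, res, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(row)), X]), row, rcond=None)
            fitted = np.column_stack([np.ones(len(row)), X]) @ beta
            r2 = 1 - np.var(row - fitted) / np.var(row)
            assert r2 < 0.25  # systemic autocorrelation only, no neural term

    def test_rater_b_within_merge_tolerance(self):
        spec = ProtocolSpec(n_runs=1)
        s = generate_session(spec, GroundTruth(), {"group": "PD"}, seed=31)
        for run in s.runs:
            a, b = run.events_rater_a.df, run.events_rater_b.df
            for _, evb in b.iterrows():
                assert np.abs(a["onset"] - evb.onset).min() <= 2.0


class TestRaters:
    def test_rater_a_tracks_truth(self, session_one_run):
        run = session_one_run.runs[0]
        true = run.protocol_events.of_type("freeze").df
        a = run.events_rater_a.df
        assert len(a) == len(true)
        np.testing.assert_allclose(a["onset"], true["onset"], atol=1.0)
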