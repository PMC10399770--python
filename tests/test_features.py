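import numpy as np
import pandas as pd
import pytest

import cavesong as cs
from cavesong.audio_io import Recording
from cavesong.features import (CLICK_FEATURE_NAMES, SERIAL_FEATURE_NAMES,
                               SNR_CAP, FeatureTable, build_feature_table,
                               build_feature_tables, click_features,
                               reduce_variables, serial_features)
from cavesong.segmentation import Pulse, SoundEvent
from cavesong.synthgen import ClickSpec, synth_click

FS = 44_100.0


def _pulse(onset, duration):
    return Pulse(onset=onset, offset=onset + duration,
                 peak_amplitude=1.0, peak_time=onset + duration / 2)


def _serial_event(onsets, duration):
    pulses = [_pulse(o, duration) for o in onsets]
    return SoundEvent(event_type="serial", pulses=pulses,
                      window=(pulses[0].onset, pulses[-1].offset))


def _click_in_noise(seed=41, amplitude=0.5, noise_rms=0.05, freq=2000.0):
    rec, ann = cs.random_soundscape(
        n_singles=1, duration=6.0,
        click=ClickSpec(dominant_freq=freq, amplitude=amplitude),
        noise_rms=noise_rms, seed=seed, min_gap=1.0)
    t = ann.entries[0].time
    dur = ann.details.duration_ms[0] / 1e3
    event = SoundEvent(event_type="single", pulses=[_pulse(t, dur)],
                       window=(t, t + dur))
    return rec, event, ann


class TestClickFeatures:
    def test_recovers_generated_click(self):
        rec, event, ann = _click_in_noise()
        f = click_features(event, rec)
        assert f.dominant_frequency_hz == pytest.approx(2000, abs=15)
        assert f.duration_ms == pytest.approx(ann.details.duration_ms[0],
                                              rel=0.01)
        assert f.snr == pytest.approx(ann.details.snr[0], rel=0.25)

    def test_amplitude_scale_invariance(self):
        rec, event, _ = _click_in_noise()
        f1 = click_features(event, rec)
        scaled = Recording(10 * rec.samples, rec.sample_rate)
        f10 = click_features(event, scaled)
        assert f10.snr == pytest.approx(f1.snr, rel=1e-9)
        assert f10.dominant_frequency_hz == f1.dominant_frequency_hz
        assert f10.duration_ms == f1.duration_ms

    def test_zero_noise_snr_capped(self):
        w = synth_click(ClickSpec(amplitude=0.5), FS)
        x = np.zeros(int(4 * FS))
        x[int(2 * FS):int(2 * FS) + w.size] = w
        rec = Recording(x, FS)
        event = SoundEvent(event_type="single", pulses=[_pulse(2.0, 0.005)],
                           window=(2.0, 2.005))
        f = click_features(event, rec)
        assert f.snr == SNR_CAP
        assert f.snr_capped

    def test_degenerate_window_rejected(self):
        rec = Recording(np.zeros(int(1 * FS)), FS)
        ev = SoundEvent(event_type="single",
                        pulses=[Pulse(0.5, 0.5 + 1e-5, 1.0, 0.5)],
                        window=(0.5, 0.5 + 1e-5))
        with pytest.raises(ValueError, match="degenerate"):
            click_features(ev, rec)

    def test_wrong_type_rejected(self):
        ev = _serial_event([0.0, 0.015], 0.005)
        with pytest.raises(ValueError):
            click_features(ev, Recording(np.zeros(100), FS))


class TestSerialFeatures:
    def test_eight_pulse_arithmetic(self):
        # 8 pulses of 5 ms with 10 ms silent gaps: onset step 15 ms
        ev = _serial_event([0.015 * k for k in range(8)], 0.005)
        f = serial_features(ev)
        assert f.pulse_number == 8
        assert f.mean_pulse_duration_ms == pytest.approx(5.0)
        assert f.mean_interpulse_duration_ms == pytest.approx(10.0)
        # 8 x 5 ms of pulses + 7 x 10 ms of gaps
        assert f.total_duration_ms == pytest.approx(110.0)
        assert f.pulse_rate_hz == pytest.approx(8 / 0.110, rel=1e-6)

    def test_two_pulse_arithmetic(self):
        # 2 pulses of 4 ms separated by a 16 ms silent gap
        ev = _serial_event([0.0, 0.020], 0.004)
        f = serial_features(ev)
        assert f.total_duration_ms == pytest.approx(24.0)
        assert f.pulse_rate_hz == pytest.approx(2 / 0.024, rel=1e-6)
        assert f.mean_interpulse_duration_ms == pytest.approx(16.0)

    def test_interpulse_rate_mode(self):
        ev = _serial_event([0.015 * k for k in range(8)], 0.005)
        f = serial_features(ev, pulse_rate_mode="interpulse")
        assert f.pulse_rate_hz == pytest.approx(1 / 0.015, rel=1e-6)


class TestFeatureTable:
    def _single_events(self, n, source="rec"):
        events = []
        for k in range(n):
            t = 1.0 + 2.0 * k
            events.append(SoundEvent(event_type="single",
                                     pulses=[_pulse(t, 0.005)],
                                     window=(t, t + 0.005), source_id=source))
        return events

    def test_empty_table_has_columns(self):
        table = build_feature_table([], None, "g", "single")
        assert len(table) == 0
        assert set(CLICK_FEATURE_NAMES) <= set(table.df.columns)

    def test_groups_preserved(self):
        rec, ann = cs.random_soundscape(n_singles=10, duration=25.0,
                                        noise_rms=0.05, seed=51, min_gap=1.6)
        events = []
        for i, a in enumerate(ann.entries):
            dur = ann.details.duration_ms[i] / 1e3
            src = "caveA" if i % 2 else "caveB"
            events.append(SoundEvent(
                event_type="single", pulses=[_pulse(a.time, dur)],
                window=(a.time, a.time + dur), source_id=src))
        table = build_feature_table(
            events, {"caveA": rec, "caveB": rec},
            {"caveA": "A", "caveB": "B"}, "single")
        assert len(table) == 10
        assert table.groups == ["A", "B"]

    def test_mixed_types_partitioned(self):
        rec, ann = cs.random_soundscape(n_singles=4, duration=12.0,
                                        noise_rms=0.05, seed=52, min_gap=1.6)
        singles = [SoundEvent(event_type="single",
                              pulses=[_pulse(a.time,
                                             ann.details.duration_ms[i] / 1e3)],
                              window=(a.time, a.time + 0.005))
                   for i, a in enumerate(ann.entries)]
        serials = [_serial_event([10.0 + 0.015 * k for k in range(8)], 0.005)]
        tables = build_feature_tables(singles + serials, rec, "g")
        assert len(tables["single"]) + len(tables["serial"]) == 5
        assert list(tables["serial"].feature_names) == SERIAL_FEATURE_NAMES

    def test_unknown_group_label_rejected(self):
        events = self._single_events(2, source="mystery")
        with pytest.raises(KeyError):
            build_feature_table(events, None, {"known": "A"}, "single")


class TestReduceVariables:
    def _table(self, X, names, groups=None):
        df = pd.DataFrame(X, columns=names)
        df["group"] = groups if groups is not None else "g"
        return FeatureTable(df=df, event_type="single",
                            feature_names=list(names))

    def test_duplicate_column_removed(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([x, x * 2.0 + 1.0, rng.normal(size=200)])
        chosen, _ = reduce_variables(self._table(X, ["a", "b", "c"]), 0.9)
        assert len(chosen) == 2
        assert "c" in chosen
        assert ("a" in chosen) != ("b" in chosen)

    def test_independent_columns_all_kept(self, rng):
        X = rng.normal(size=(300, 4))
        chosen, report = reduce_variables(
            self._table(X, ["a", "b", "c", "d"]), 0.9)
        assert sorted(chosen) == ["a", "b", "c", "d"]
        assert report.adequate  # 300 rows >= 10 * 4

    def test_adequacy_flag(self, rng):
        X = rng.normal(size=(25, 3))
        chosen, report = reduce_variables(self._table(X, ["a", "b", "c"]), 0.9)
        assert len(chosen) == 3
        assert report.required == 30
        assert report.flagged_groups == ["g"]

    def test_required_exceeds_available(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(ValueError):
            reduce_variables(self._table(X, ["a", "b"]), 0.9, required=5)


class TestMonteCarloRecovery:
    def test_serial_feature_sweep(self):
        """Seeded serial sweep: each recovered feature within 10% of truth
        in the median, measured through the full pipeline."""
        from cavesong.detection import matched_filter, detect_events
        from cavesong.segmentation import segment_recording

        serial = cs.SerialSpec(pulse_count=8, interpulse=0.015,
                               jitter_fraction=0.1,
                               pulse=ClickSpec(amplitude=0.5))
        rec, ann = cs.random_soundscape(n_serials=25, duration=60.0,
                                        serial=serial, noise_rms=0.05,
                                        seed=61, min_gap=1.6)
        from conftest import template_from

        dets = detect_events(matched_filter(rec, template_from(rec, ann)), 0.5)
        events = segment_recording(rec, dets)
        table = build_feature_table(events, None, "g", "serial")
        truth = ann.details
        mapping = {"pulse_number": "pulse_count",
                   "mean_pulse_duration_ms": "mean_pulse_duration_ms",
                   "mean_interpulse_duration_ms": "mean_interpulse_duration_ms",
                   "pulse_rate_hz": "pulse_rate_hz",
                   "total_duration_ms": "total_duration_ms"}
        assert len(table) >= 23
        for feat, tcol in mapping.items():
            errs = []
            for _, row in table.df.iterrows():
                j = (truth.time_s - row.onset_s).abs().idxmin()
                errs.append(abs(row[feat] - truth[tcol][j]) / truth[tcol][j])
            assert np.median(errs) < 0.10, feat
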