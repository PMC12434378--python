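"""Break detection, timestamp regression (batch and online), clock correction."""

import numpy as np
import pytest

from streamsync.clock_sync import ClockOffsetSeries, OffsetModel, ModelPiece, fit_offset_model
from streamsync.config import SyncConfig
from streamsync.dejitter import (
    RlsRegressor,
    Segment,
    apply_clock_offsets,
    detect_breaks,
    effective_srate,
    regress_timestamps,
    rls_dejitter,
    srate_deviates,
    synchronize_recording,
)
from streamsync.simulator import DeviceSpec, VirtualClock, ZERO_NETWORK, simulate_session
from streamsync.streams import RecordedStream, StreamInfo


def _constant_model(value: float) -> OffsetModel:
    return OffsetModel([ModelPiece(start=0.0, stop=0.0, intercept=value, slope=0.0)])


class TestDetectBreaks:
    def test_clean_stream_single_segment(self):
        ts = np.arange(1000) / 100.0
        segs = detect_breaks(ts, 100.0)
        assert len(segs) == 1 and (segs[0].start, segs[0].stop) == (0, 1000)

    def test_injected_gap_splits(self):
        # threshold = max(1 s, 500 samples / 100 Hz) = 5 s
        ts = np.arange(1000) / 100.0
        ts[501:] += 6.0  # 6 s gap after index 500
        cfg = SyncConfig(break_threshold_seconds=1.0, break_threshold_samples=500)
        segs = detect_breaks(ts, 100.0, cfg)
        assert [(s.start, s.stop) for s in segs] == [(0, 501), (501, 1000)]

    def test_sub_threshold_gap_kept_whole(self):
        ts = np.arange(1000) / 100.0
        ts[501:] += 2.0  # below the 5 s sample-count threshold
        cfg = SyncConfig(break_threshold_seconds=1.0, break_threshold_samples=500)
        assert len(detect_breaks(ts, 100.0, cfg)) == 1

    def test_irregular_stream_never_split(self):
        ts = np.array([0.0, 10.0, 11.0, 500.0])
        segs = detect_breaks(ts, 0.0)
        assert len(segs) == 1

    def test_threshold_is_max_of_both(self):
        # at 10 Hz, 500 samples => 50 s threshold dominates the 1 s threshold
        ts = np.arange(100) / 10.0
        ts[50:] += 40.0  # below 50 s: no break
        segs = detect_breaks(ts, 10.0, SyncConfig())
        assert len(segs) == 1
        ts[50:] += 20.0  # now 60 s: break
        segs = detect_breaks(ts, 10.0, SyncConfig())
        assert len(segs) == 2


class TestRegressTimestamps:
    def test_exact_line_unchanged(self):
        ts = 10.0 + np.arange(1000) / 256.0
        seg, fitted = regress_timestamps(ts, Segment(0, 1000))
        assert fitted == pytest.approx(ts, abs=1e-9)
        assert seg.slope == pytest.approx(1 / 256.0, abs=1e-12)
        assert seg.effective_srate == pytest.approx(256.0, rel=1e-9)

    def test_uniform_jitter_suppressed(self):
        # +-1 ms uniform jitter on a 256 Hz line, n = 10^4: the fitted line
        # recovers the true stamps to well under 50 us RMSE
        rng = np.random.default_rng(7)
        n = 10_000
        true = 10.0 + np.arange(n) / 256.0
        noisy = true + rng.uniform(-1e-3, 1e-3, size=n)
        _, fitted = regress_timestamps(noisy, Segment(0, n))
        rmse = np.sqrt(np.mean((fitted - true) ** 2))
        assert rmse < 50e-6

    def test_two_points_interpolated_exactly(self):
        ts = np.array([1.0, 1.5])
        _, fitted = regress_timestamps(ts, Segment(0, 2))
        assert fitted == pytest.approx(ts, abs=1e-12)

    def test_single_sample_passthrough(self):
        seg, fitted = regress_timestamps(np.array([3.0]), Segment(0, 1))
        assert fitted == pytest.approx([3.0])
        assert seg.slope is None


class TestRls:
    def test_matches_batch_ols_without_forgetting(self):
        rng = np.random.default_rng(0)
        ts = 5.0 + np.arange(200) * 0.004 + rng.normal(0, 1e-4, 200)
        running = list(rls_dejitter(enumerate(ts), forgetting=1.0))
        slope_b, intercept_b = np.polyfit(np.arange(200), ts, 1)
        intercept_r, slope_r = running[-1]
        assert intercept_r == pytest.approx(intercept_b, abs=1e-9)
        assert slope_r == pytest.approx(slope_b, abs=1e-9)

    def test_chunk_partition_invariance(self):
        # feeding the same pairs in any chunking yields the same final state
        ts = 2.0 + np.arange(100) * 0.01
        pairs = list(enumerate(ts))
        final_states = []
        for split in (1, 7, 50):
            reg = RlsRegressor(forgetting=1.0)
            for i in range(0, len(pairs), split):
                for idx, t in pairs[i : i + split]:
                    reg.update(idx, t)
            final_states.append(reg.estimate())
        ref = final_states[0]
        for state in final_states[1:]:
            assert state == pytest.approx(ref, abs=1e-12)

    def test_forgetting_tracks_rate_change(self):
        # sample interval doubles mid-stream; with forgetting 0.99 the slope
        # re-converges to the new interval within 1000 samples
        ts = np.concatenate([np.arange(2000) * 0.001, 2.0 + np.arange(2000) * 0.002])
        reg = RlsRegressor(forgetting=0.99)
        for idx, t in enumerate(ts):
            intercept, slope = reg.update(idx, t)
        assert slope == pytest.approx(0.002, rel=0.01)

    def test_invalid_forgetting(self):
        with pytest.raises(ValueError):
            RlsRegressor(forgetting=0.0)


class TestApplyClockOffsets:
    def test_zero_offset_identity(self):
        ts = np.linspace(0, 10, 50)
        assert apply_clock_offsets(ts, _constant_model(0.0)) == pytest.approx(ts, abs=0)

    def test_constant_offset_subtracted(self):
        # the device clock runs 0.5 s ahead: mapping into the recorder
        # timebase subtracts the offset
        ts = np.linspace(0, 10, 50)
        corrected = apply_clock_offsets(ts, _constant_model(0.5))
        assert corrected == pytest.approx(ts - 0.5, abs=1e-12)

    def test_linear_offset_rescales_intervals(self):
        slope = 1e-4
        model = OffsetModel([ModelPiece(start=0.0, stop=1e6, intercept=0.2, slope=slope)])
        ts = 100.0 + np.arange(1000) * 0.01
        corrected = apply_clock_offsets(ts, model)
        # closed form: t - (0.2 + slope*t) has intervals scaled by (1 - slope)
        assert np.diff(corrected) == pytest.approx(0.01 * (1 - slope), abs=1e-12)
        assert corrected == pytest.approx(ts - 0.2 - slope * ts, abs=1e-9)

    def test_disabled_clock_sync_is_noop(self):
        ts = np.linspace(0, 10, 50)
        cfg = SyncConfig(handle_clock_sync=False)
        assert apply_clock_offsets(ts, _constant_model(0.5), cfg) == pytest.approx(ts)


class TestSynchronizeRecording:
    def test_full_recovery_in_noiseless_limit(self, noiseless_session):
        synchronize_recording(noiseless_session)
        stream = noiseless_session.streams[0]
        truth = noiseless_session.truth["clean"]
        assert stream.timestamps_sync == pytest.approx(truth.t_actual, abs=1e-9)

    def test_idempotent(self, small_session):
        synchronize_recording(small_session)
        first = [s.timestamps_sync.copy() for s in small_session.streams]
        synchronize_recording(small_session)
        for before, after in zip(first, small_session.streams):
            assert np.array_equal(before, after.timestamps_sync)

    def test_recovers_drift_and_offset(self, small_session):
        synchronize_recording(small_session)
        eeg = small_session.stream("eeg")
        truth = small_session.truth["eeg"]
        resid = eeg.timestamps_sync - truth.t_actual
        # constant tau = 0 here; residual should be well under a millisecond
        assert np.max(np.abs(resid)) < 1e-3

    def test_jitter_handling_off_keeps_offset_corrected_raw(self, small_session):
        cfg = SyncConfig(handle_jitter=False)
        synchronize_recording(small_session, cfg)
        eeg = small_session.stream("eeg")
        model = fit_offset_model(eeg.offsets, cfg.jump_threshold)
        expected = eeg.timestamps_raw - model(eeg.timestamps_raw)
        assert np.array_equal(eeg.timestamps_sync, expected)

    def test_order_preserved_within_segments(self, small_session):
        synchronize_recording(small_session)
        for stream in small_session.streams:
            for seg in stream.segments:
                if stream.info.nominal_srate > 0:
                    chunk = stream.timestamps_sync[seg.start : seg.stop]
                    assert np.all(np.diff(chunk) > 0)

    def test_irregular_streams_never_regressed(self, small_session):
        synchronize_recording(small_session)
        markers = small_session.stream("markers")
        model = fit_offset_model(markers.offsets)
        expected = markers.timestamps_raw - model(markers.timestamps_raw)
        assert np.array_equal(markers.timestamps_sync, expected)
        assert markers.segments[0].slope is None

    def test_segments_fitted_independently_around_gap(self):
        dev = DeviceSpec(
            info=StreamInfo(name="g", type="EEG", nominal_srate=100.0, source_id="g1"),
            dropout_windows=[(5.0, 11.0)],
            timestamp_noise_std=1e-4,
        )
        bundle = simulate_session(
            [dev], [VirtualClock()], ZERO_NETWORK, cfg=SyncConfig(), duration=20.0, seed=2
        )
        synchronize_recording(bundle)
        stream = bundle.streams[0]
        assert len(stream.segments) == 2
        truth = bundle.truth["g"]
        assert stream.timestamps_sync == pytest.approx(truth.t_actual, abs=5e-5)


class TestDriftRecovery:
    def _session(self, noise_std: float, seed: int = 21):
        dev = DeviceSpec(
            info=StreamInfo(name="d", type="EEG", nominal_srate=100.0, source_id="d1"),
            timestamp_noise_std=noise_std,
        )
        clock = VirtualClock(epoch_offset=0.4, drift=1e-5)
        return simulate_session(
            [dev], [clock], ZERO_NETWORK, cfg=SyncConfig(), duration=600.0, seed=seed
        )

    def test_ten_ppm_drift_recovered_noiseless(self):
        bundle = self._session(noise_std=0.0)
        model = fit_offset_model(bundle.streams[0].offsets)
        assert len(model.pieces) == 1
        assert model.pieces[0].slope == pytest.approx(1e-5, abs=1e-6)

    def test_ten_ppm_drift_recovered_with_default_noise(self):
        bundle = self._session(noise_std=2e-4)
        model = fit_offset_model(bundle.streams[0].offsets)
        assert model.pieces[0].slope == pytest.approx(1e-5, abs=3e-6)


class TestEffectiveSrate:
    def _stream(self, ts, nominal=100.0):
        return RecordedStream(
            info=StreamInfo(name="s", nominal_srate=nominal, source_id="s"),
            timestamps_raw=ts,
            values=np.zeros(len(ts)),
        )

    def test_count_over_span(self):
        stream = self._stream(np.linspace(0.0, 10.0, 1001))
        assert effective_srate(stream) == pytest.approx(100.1)

    def test_alternating_frame_rate_flagged(self):
        # webcam-like: intervals alternate between 1/30 and 1/60 against a
        # nominal 30 fps declaration
        intervals = np.tile([1 / 30.0, 1 / 60.0], 200)
        ts = np.concatenate([[0.0], np.cumsum(intervals)])
        stream = self._stream(ts, nominal=30.0)
        assert srate_deviates(stream)

    def test_flag_suppressed_within_tolerance(self):
        ts = np.arange(1000) / 100.0
        assert not srate_deviates(self._stream(ts))

    def test_undefined_below_two_samples(self):
        with pytest.raises(ValueError):
            effective_srate(self._stream(np.array([1.0])))
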