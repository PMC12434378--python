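"""Canonical simulated validation experiments.

These scenarios reproduce, in silico, the bench experiments used to
characterize synchronization performance:

* :func:`professional_pair_session` — two regularly sampled 2000 Hz streams
  carrying one shared 2 Hz square wave for ten simulated minutes.  Stream A
  models a professional device that stamps every sample at capture; stream B
  models a device that transmits (and stamps) in ~20 ms chunks.  Each device
  clock runs 0.5 s ahead of the recorder with 10 ppm drift; sample stamps
  carry 0.2 ms Gaussian noise; clock-offset probes follow the default
  schedule (bursts of 10 exchanges, 10 ms apart, every 5 s).

* :func:`edge_jitter` — the analysis applied to such a session: extract
  half-maximum rising-edge markers from both streams, pair nearest edges,
  center the paired differences, and report their standard deviation.

* :func:`clock_filter_trial` — repeated probe bursts against a drifting
  clock through a spiky network, reporting each retained offset's error
  against the simulated truth.
"""

from __future__ import annotations

import numpy as np

from .config import SyncConfig, DEFAULT_CONFIG
from .dejitter import synchronize_recording
from .simulator import (
    DeviceSpec,
    NetworkSpec,
    VirtualClock,
    child_rng,
    measure_offset_series,
    simulate_session,
    square_wave,
)
from .streams import RecordingBundle, StreamInfo
from .validation import extract_threshold_markers, pairwise_offset_stats

__all__ = [
    "professional_pair_session",
    "edge_jitter",
    "clock_filter_trial",
]


def professional_pair_session(
    seed: int,
    duration: float = 600.0,
    srate: float = 2000.0,
    wave_hz: float = 2.0,
    chunk_period: float = 0.020,
    clock_offset: float = 0.5,
    drift: float = 1e-5,
    timestamp_noise_std: float = 0.0002,
    net: NetworkSpec | None = None,
    cfg: SyncConfig = DEFAULT_CONFIG,
) -> RecordingBundle:
    """Simulate the two-professional-device square-wave session."""
    period = 1.0 / wave_hz
    signal = lambda t: square_wave(t, period=period, high_fraction=0.5)  # noqa: E731
    devices = [
        DeviceSpec(
            info=StreamInfo(name="A", type="EEG", nominal_srate=srate, source_id="dev-a"),
            timestamp_noise_std=timestamp_noise_std,
            signal=signal,
        ),
        DeviceSpec(
            info=StreamInfo(name="B", type="EMG", nominal_srate=srate, source_id="dev-b"),
            chunk_period=chunk_period,
            stamp_at_delivery=True,
            timestamp_noise_std=timestamp_noise_std,
            signal=signal,
        ),
    ]
    clocks = [
        VirtualClock(epoch_offset=clock_offset, drift=drift),
        VirtualClock(epoch_offset=clock_offset, drift=drift),
    ]
    if net is None:
        net = NetworkSpec()
    return simulate_session(
        devices, clocks, net, cfg=cfg, duration=duration, seed=seed
    )


def edge_jitter(
    bundle: RecordingBundle,
    stream_a: str = "A",
    stream_b: str = "B",
    handle_jitter: bool = True,
    cfg: SyncConfig = DEFAULT_CONFIG,
) -> dict:
    """Synchronize a session and measure residual rising-edge jitter.

    Returns mean offset, the standard deviation of the mean-centered paired
    edge differences (the jitter statistic), and the pair count.
    """
    cfg = cfg.replace(handle_jitter=handle_jitter)
    synchronize_recording(bundle, cfg)
    sa = bundle.stream(stream_a)
    sb = bundle.stream(stream_b)
    markers_a = extract_threshold_markers(sa.timestamps_sync, sa.values)
    markers_b = extract_threshold_markers(sb.timestamps_sync, sb.values)
    report = pairwise_offset_stats(markers_a, markers_b)
    return {
        "mean_offset": report.mean_offset,
        "jitter_std": float(np.std(report.centered_diffs)),
        "n_pairs": report.n_pairs,
    }


def clock_filter_trial(
    seed: int,
    n_bursts: int = 100,
    clock_offset: float = 0.5,
    drift: float = 1e-5,
    net: NetworkSpec | None = None,
    cfg: SyncConfig = DEFAULT_CONFIG,
) -> dict:
    """Min-RTT-filtered offset estimation against a drifting clock.

    Runs ``n_bursts`` probe bursts (default schedule) between an ideal
    recorder clock and a device clock with the given offset and drift
    through a spiky network, and reports the error of every retained offset
    against the noiseless simulated truth at its measurement time.
    """
    if net is None:
        net = NetworkSpec()
    device_clock = VirtualClock(epoch_offset=clock_offset, drift=drift)
    recorder_clock = VirtualClock()
    duration = n_bursts * cfg.time_update_interval
    series = measure_offset_series(
        device_clock, recorder_clock, net, cfg, duration, child_rng(seed, 7)
    )
    at, ofs, rtt = series.as_arrays()
    truth = device_clock.true_offset(at)
    errors = ofs - truth
    return {
        "n_bursts": len(series),
        "errors": errors,
        "max_abs_error": float(np.max(np.abs(errors))) if len(errors) else np.nan,
        "rtt": rtt,
    }
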