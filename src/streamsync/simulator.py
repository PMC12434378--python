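"""Virtual clocks, networks and devices for hardware-free recordings.

Everything downstream of acquisition — offset estimation, dejittering,
container I/O — is validated against recordings generated here, where the
ground truth (true capture times, clock parameters, device latencies) is
known exactly.

A :class:`VirtualClock` maps true time to a local clock reading with a
constant epoch offset, a linear drift and optional Gaussian read noise
(clamped so successive readings never decrease).  A :class:`NetworkSpec`
draws per-message transmission delays with exponential jitter and occasional
large spikes.  A :class:`DeviceSpec` describes one acquisition device: its
sampling grid, transmission chunking, constant setup offset ``tau`` (the
buffering/driver latency between physical capture and timestamping, possibly
negative for output transducers), timestamp noise, stamping mode and
dropout windows.

Two stamping modes are modeled: professional devices stamp each sample at
capture; consumer devices that deliver data in chunks often stamp at
delivery, which imprints a sawtooth of the chunk period on the raw
timestamps (the pattern dejittering removes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import clock_sync
from .clock_sync import ClockOffsetSeries, EmptyBurstError
from .config import SyncConfig, DEFAULT_CONFIG
from .streams import RecordedStream, RecordingBundle, StreamInfo, StreamTruth

__all__ = [
    "VirtualClock",
    "NetworkSpec",
    "DeviceSpec",
    "local_time",
    "sample_delay",
    "simulate_device",
    "measure_offset_series",
    "simulate_session",
    "ZERO_NETWORK",
    "pulse_signal",
    "square_wave",
    "child_rng",
]


def child_rng(seed: int, *labels: int) -> np.random.Generator:
    """Deterministic per-component generator derived from one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, labels)]))


@dataclass
class VirtualClock:
    """A local clock: ``epoch_offset + (1 + drift) * t_true`` plus read noise.

    ``drift`` is dimensionless (1e-5 = 10 ppm).  Readings are clamped to be
    non-decreasing per reading sequence, emulating a steady monotonic clock
    source.
    """

    epoch_offset: float = 0.0
    drift: float = 0.0
    noise_std: float = 0.0
    _last: float = field(default=-np.inf, init=False, repr=False, compare=False)

    def local_time(self, t_true, rng: np.random.Generator | None = None):
        """Read the clock at true time ``t_true`` (scalar or array).

        Array reads are clamped monotonic within the array; scalar reads are
        clamped against this clock object's previous scalar reads.
        """
        t = np.asarray(t_true, dtype=float)
        out = self.epoch_offset + (1.0 + self.drift) * t
        if self.noise_std > 0:
            if rng is None:
                raise ValueError("rng required when noise_std > 0")
            out = out + rng.normal(0.0, self.noise_std, size=t.shape)
        if t.ndim == 0:
            value = max(float(out), self._last)
            self._last = value
            return value
        return np.maximum.accumulate(out)

    def reader(self, rng: np.random.Generator | None = None) -> Callable[[float], float]:
        """Stateless reader for out-of-order queries (e.g. probe exchanges).

        Probe exchanges can overlap in true time (a delay spike pushes one
        exchange's final receipt past the next exchange's send), so probe
        readings must be pure functions of true time: clamping by call order
        would inflate early timestamps after a spike and fabricate
        artificially small round-trip times that the min-RTT filter then
        prefers.  Reads with noise can therefore regress; downstream
        consumers reject exchanges whose implied RTT is negative.
        """

        def read(t_true: float) -> float:
            value = self.epoch_offset + (1.0 + self.drift) * float(t_true)
            if self.noise_std > 0:
                if rng is None:
                    raise ValueError("rng required when noise_std > 0")
                value += rng.normal(0.0, self.noise_std)
            return value

        return read

    def true_offset(self, t_true):
        """Noiseless offset of this clock against true time."""
        return self.epoch_offset + self.drift * np.asarray(t_true, dtype=float)


def local_time(clock: VirtualClock, t_true, rng: np.random.Generator | None = None):
    """Functional form of :meth:`VirtualClock.local_time`."""
    return clock.local_time(t_true, rng)


@dataclass
class NetworkSpec:
    """Per-message transmission delay model.

    delay = base_delay +/- asymmetry/2 + Exponential(jitter_scale)
            + Bernoulli(spike_prob) * spike_magnitude, floored at 0.

    ``asymmetry`` is the constant forward-minus-backward difference; a
    symmetric path has asymmetry 0.  Defaults model a lightly loaded wired
    LAN: 0.2 ms base, 0.5 ms exponential jitter, and 50 ms spikes with
    probability 0.1.
    """

    base_delay: float = 0.0002
    jitter_scale: float = 0.0005
    spike_prob: float = 0.1
    spike_magnitude: float = 0.050
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.spike_prob <= 1.0):
            raise ValueError("spike_prob must lie in [0, 1]")
        if self.base_delay < 0 or self.jitter_scale < 0 or self.spike_magnitude < 0:
            raise ValueError("delays must be non-negative")

    def sample_delay(self, direction: str, rng: np.random.Generator) -> float:
        if direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        delay = self.base_delay + (
            self.asymmetry / 2.0 if direction == "forward" else -self.asymmetry / 2.0
        )
        if self.jitter_scale > 0:
            delay += rng.exponential(self.jitter_scale)
        if self.spike_prob > 0 and rng.random() < self.spike_prob:
            delay += self.spike_magnitude
        return max(delay, 0.0)


#: A network with no delay at all — useful for exact-recovery tests.
ZERO_NETWORK = NetworkSpec(base_delay=0.0, jitter_scale=0.0, spike_prob=0.0, spike_magnitude=0.0)


def sample_delay(net: NetworkSpec, direction: str, rng: np.random.Generator) -> float:
    """Functional form of :meth:`NetworkSpec.sample_delay`."""
    return net.sample_delay(direction, rng)


@dataclass
class DeviceSpec:
    """One simulated acquisition device.

    ``srate`` 0 marks an irregular stream whose events come from
    ``event_times``; regular streams sample ``signal`` (a callable of true
    time) on the grid ``k / srate``.  ``chunk_period`` > 0 batches samples
    into transmission chunks; with ``stamp_at_delivery`` the batched samples
    are also *timestamped* at the chunk boundary rather than at capture.
    ``setup_offset`` is tau; ``timestamp_noise_std`` is the stamping jitter
    eps.  Samples whose capture time falls inside a dropout window are lost.
    """

    info: StreamInfo
    srate: float | None = None
    chunk_period: float = 0.0
    setup_offset: float = 0.0
    timestamp_noise_std: float = 0.0
    stamp_at_delivery: bool = False
    dropout_windows: Sequence[tuple[float, float]] = ()
    signal: Callable[[np.ndarray], np.ndarray] | None = None
    event_times: Sequence[float] | None = None
    marker_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.srate is None:
            self.srate = self.info.nominal_srate
        if self.srate < 0 or self.chunk_period < 0:
            raise ValueError("srate and chunk_period must be >= 0")
        if self.srate == 0 and self.chunk_period > 0:
            raise ValueError(
                "irregular streams emit per event; chunk_period > 0 is ambiguous"
            )


def _capture_times(dev: DeviceSpec, duration: float) -> np.ndarray:
    if dev.srate > 0:
        n = int(np.floor(duration * dev.srate))
        t = np.arange(n, dtype=float) / dev.srate
    else:
        if dev.event_times is None:
            raise ValueError("irregular device needs event_times")
        t = np.asarray(dev.event_times, dtype=float)
        t = t[(t >= 0) & (t < duration)]
    if dev.dropout_windows:
        keep = np.ones(len(t), dtype=bool)
        for a, b in dev.dropout_windows:
            keep &= ~((t >= a) & (t < b))
        t = t[keep]
    return t


def _device_values(dev: DeviceSpec, t_actual: np.ndarray) -> np.ndarray:
    n = len(t_actual)
    if dev.info.channel_format == "string":
        if dev.marker_labels is not None:
            labels = list(dev.marker_labels)[:n]
            labels += [""] * (n - len(labels))
        else:
            labels = ["marker"] * n
        values = np.empty((n, dev.info.channel_count), dtype=object)
        for c in range(dev.info.channel_count):
            values[:, c] = labels
        return values
    if dev.signal is not None:
        sig = np.asarray(dev.signal(t_actual), dtype=float)
        if sig.ndim == 1:
            sig = np.tile(sig[:, None], (1, dev.info.channel_count))
        values = sig
    else:
        values = np.zeros((n, dev.info.channel_count))
    dtype = dev.info.dtype
    return values.astype(dtype) if dtype is not None else values


def simulate_device(
    dev: DeviceSpec,
    clock: VirtualClock,
    duration: float,
    rng: np.random.Generator,
) -> tuple[RecordedStream, StreamTruth]:
    """Generate one device's observed stream plus its hidden ground truth.

    Observed stamps realize ``t_obs = clock(t_basis) + tau + eps`` where the
    stamping basis ``t_basis`` is the capture time, or — for
    stamp-at-delivery devices — the end of the transmission chunk containing
    the sample.  Raw stamps are clamped non-decreasing (a monotonic stamping
    clock).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t_actual = _capture_times(dev, duration)
    if dev.stamp_at_delivery and dev.chunk_period > 0:
        # chunk emission is scheduled on the device's own clock, so its epoch
        # offset sets the chunk phase and its drift makes that phase slip
        # relative to true time (no artificial lock between chunk grid and
        # any signal period)
        local_capture = clock.epoch_offset + (1.0 + clock.drift) * t_actual
        stamps = np.ceil(local_capture / dev.chunk_period) * dev.chunk_period
        if clock.noise_std > 0:
            stamps = stamps + rng.normal(0.0, clock.noise_std, size=stamps.shape)
        stamps = np.maximum.accumulate(stamps)
    else:
        stamps = np.asarray(clock.local_time(t_actual, rng), dtype=float)
    stamps = stamps + dev.setup_offset
    if dev.timestamp_noise_std > 0:
        stamps = stamps + rng.normal(0.0, dev.timestamp_noise_std, size=stamps.shape)
    stamps = np.maximum.accumulate(stamps)
    stream = RecordedStream(
        info=dev.info,
        timestamps_raw=stamps,
        values=_device_values(dev, t_actual),
    )
    truth = StreamTruth(
        t_actual=t_actual,
        epoch_offset=clock.epoch_offset,
        drift=clock.drift,
        clock_noise_std=clock.noise_std,
        setup_offset=dev.setup_offset,
        timestamp_noise_std=dev.timestamp_noise_std,
        stamp_at_delivery=dev.stamp_at_delivery,
    )
    return stream, truth


def measure_offset_series(
    device_clock: VirtualClock,
    recorder_clock: VirtualClock,
    net: NetworkSpec,
    cfg: SyncConfig,
    duration: float,
    rng: np.random.Generator,
) -> ClockOffsetSeries:
    """Run periodic probe bursts over the whole recording.

    The recorder initiates a burst every ``time_update_interval`` seconds;
    each burst is min-RTT filtered.  A burst in which every exchange exceeds
    the RTT bound contributes nothing (the previous estimate simply stays in
    effect).
    """
    series = ClockOffsetSeries()
    initiator = recorder_clock.reader(rng)
    responder = device_clock.reader(rng)
    t = 0.0
    while t < duration:
        try:
            m = clock_sync.run_probe_burst(initiator, responder, net, cfg, rng, t_start=t)
            series.append(m)
        except EmptyBurstError:
            pass
        t += cfg.time_update_interval
    return series


def simulate_session(
    devices: Sequence[DeviceSpec],
    clocks: Sequence[VirtualClock],
    net: NetworkSpec,
    cfg: SyncConfig = DEFAULT_CONFIG,
    duration: float = 60.0,
    seed: int = 0,
    recorder_clock: VirtualClock | None = None,
) -> RecordingBundle:
    """Simulate a full multi-device recording session.

    All devices run against one recorder clock (default: an ideal clock at
    true time).  Per-component child generators make the bundle fully
    reproducible from ``seed``.
    """
    if not devices:
        raise ValueError("need at least one device")
    if len(clocks) != len(devices):
        raise ValueError("one clock per device required")
    if recorder_clock is None:
        recorder_clock = VirtualClock()
    streams: list[RecordedStream] = []
    truth: dict[str, StreamTruth] = {}
    for i, (dev, clock) in enumerate(zip(devices, clocks)):
        # fresh clock state per role so replay does not depend on call order
        stream, stream_truth = simulate_device(
            dev, replace(clock), duration, child_rng(seed, 1, i)
        )
        stream.offsets = measure_offset_series(
            replace(clock), replace(recorder_clock), net, cfg, duration,
            child_rng(seed, 2, i),
        )
        streams.append(stream)
        truth[dev.info.name] = stream_truth
    return RecordingBundle(streams=streams, truth=truth)


def square_wave(
    t, period: float, high_fraction: float = 0.5, amplitude: float = 1.0
) -> np.ndarray:
    """Periodic square wave with rising edges at exact multiples of ``period``."""
    if not (0.0 < high_fraction < 1.0):
        raise ValueError("high_fraction must lie in (0, 1)")
    phase = np.mod(np.asarray(t, dtype=float), period)
    return amplitude * (phase < high_fraction * period).astype(float)


def pulse_signal(
    period: float,
    high_fraction: float,
    srate: float,
    duration: float,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled periodic pulse train; rising edges at ``k * period`` exactly."""
    n = int(np.floor(duration * srate))
    t = np.arange(n, dtype=float) / srate
    return t, square_wave(t, period, high_fraction, amplitude)
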