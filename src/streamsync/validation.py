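"""Synchronization-accuracy measurement: markers, offsets, jitter.

The validation recipe mirrors bench practice: feed the same pulse train to
two acquisition paths, extract an event marker whenever each recorded signal
crosses halfway between its minimum and maximum, pair nearest markers across
streams, and summarize the paired differences.  The mean paired difference
is the *setup offset* (constant device-path latency tau, positive when the
instrument lags the reference marker); the standard deviation is the
residual synchronization jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SyncConfig, DEFAULT_CONFIG
from .streams import RecordedStream, RecordingBundle

__all__ = [
    "MarkerSeries",
    "OffsetReport",
    "extract_threshold_markers",
    "pairwise_offset_stats",
    "measure_setup_offset",
]


@dataclass
class MarkerSeries:
    """Strictly increasing event times in the recorder timebase."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("marker times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class OffsetReport:
    """Summary of paired marker differences between two streams."""

    mean_offset: float
    jitter_std: float
    n_pairs: int
    centered_diffs: np.ndarray = field(repr=False)
    n_unpaired_a: int = 0
    n_unpaired_b: int = 0

    def __post_init__(self) -> None:
        self.centered_diffs = np.asarray(self.centered_diffs, dtype=float)
        if len(self.centered_diffs) != self.n_pairs:
            raise ValueError("centered_diffs must have one entry per pair")


def extract_threshold_markers(timestamps, signal) -> MarkerSeries:
    """One marker per upward crossing of the half-maximum threshold.

    The threshold is ``(max + min) / 2`` of the recording; crossing times are
    linearly interpolated between the bracketing samples.  After a crossing,
    no further marker is emitted until the signal has fallen back below the
    threshold (refractory behaviour for noisy plateaus).  A signal that
    never crosses yields an empty series.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    signal = np.asarray(signal, dtype=float).reshape(len(timestamps), -1)[:, 0]
    if len(signal) < 2 or np.ptp(signal) == 0:
        return MarkerSeries(times=np.empty(0))
    threshold = (np.max(signal) + np.min(signal)) / 2.0
    above = signal >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    for i in crossings:
        v0, v1 = signal[i - 1], signal[i]
        t0, t1 = timestamps[i - 1], timestamps[i]
        frac = (threshold - v0) / (v1 - v0)
        times.append(t0 + frac * (t1 - t0))
    times = np.asarray(times)
    # interpolation against non-monotonic raw stamps can create tied or
    # reversed marker times; enforce strict increase by minimal perturbation
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            times[i] = np.nextafter(times[i - 1], np.inf)
    return MarkerSeries(times=times)


def pairwise_offset_stats(
    a: MarkerSeries, b: MarkerSeries, max_pair_distance: float | None = None
) -> OffsetReport:
    """Pair each marker in ``a`` with its nearest in ``b`` and summarize b - a.

    ``max_pair_distance`` caps the pairing distance to prevent cross-period
    mispairing; the default is half the median inter-marker period of ``a``.
    Each marker of ``b`` is used at most once.  Unpaired markers on either
    side are counted.  Raises when no pair forms.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both marker series must be non-empty")
    ta, tb = a.times, b.times
    if max_pair_distance is None:
        if len(ta) > 1:
            max_pair_distance = float(np.median(np.diff(ta))) / 2.0
        else:
            max_pair_distance = np.inf
    idx = np.searchsorted(tb, ta)
    best = np.empty(len(ta), dtype=int)
    dist = np.empty(len(ta))
    for k, (i, t) in enumerate(zip(idx, ta)):
        lo = max(i - 1, 0)
        hi = min(i, len(tb) - 1)
        if abs(tb[lo] - t) <= abs(tb[hi] - t):
            best[k], dist[k] = lo, abs(tb[lo] - t)
        else:
            best[k], dist[k] = hi, abs(tb[hi] - t)
    used: set[int] = set()
    diffs = []
    for k in np.argsort(dist):
        if dist[k] <= max_pair_distance and best[k] not in used:
            used.add(int(best[k]))
            diffs.append(tb[best[k]] - ta[k])
    if not diffs:
        raise ValueError("no marker pairs within the pairing distance")
    diffs = np.asarray(diffs)
    mean = float(np.mean(diffs))
    return OffsetReport(
        mean_offset=mean,
        jitter_std=float(np.std(diffs)),
        n_pairs=len(diffs),
        centered_diffs=diffs - mean,
        n_unpaired_a=len(ta) - len(diffs),
        n_unpaired_b=len(tb) - len(diffs),
    )


def measure_setup_offset(
    bundle: RecordingBundle,
    instrument_stream: str,
    datain_marker_stream: str,
    cfg: SyncConfig = DEFAULT_CONFIG,
    max_pair_distance: float | None = None,
) -> OffsetReport:
    """Determine a device's setup offset from a synchronized test recording.

    The reference pulse arrives twice: as an irregular marker stream
    (``datain_marker_stream``, event times = timestamps) and through the
    instrument under test (``instrument_stream``), from whose synchronized
    signal markers are re-extracted by threshold crossing.  The mean paired
    difference (instrument minus reference) is the setup offset: positive
    means the instrument lags.
    """
    instrument = bundle.stream(instrument_stream)
    datain = bundle.stream(datain_marker_stream)
    if instrument.timestamps_sync is None or datain.timestamps_sync is None:
        raise ValueError("bundle must be synchronized first")
    instrument_markers = extract_threshold_markers(
        instrument.timestamps_sync, instrument.values
    )
    datain_markers = MarkerSeries(times=datain.timestamps_sync)
    return pairwise_offset_stats(
        datain_markers, instrument_markers, max_pair_distance=max_pair_distance
    )
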