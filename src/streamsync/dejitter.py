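"""Post-hoc synchronization: clock correction, break detection, dejittering.

The observed timestamp of a sample is modeled as

    t_obs = t_actual + tau + OFS(t) + eps

with ``tau`` a constant device latency (setup offset), ``OFS`` the slowly
drifting clock offset between source and recorder, and ``eps`` zero-mean
jitter.  Post hoc, ``OFS`` is removed using the measured offset series, and
for regularly sampled streams the jitter ``eps`` is removed by regressing
timestamps on sample index within each contiguous segment ("dejittering").
Gaps larger than a threshold split a stream into segments so that dropouts
and reconnects do not distort the fits.  Irregular streams (nominal rate 0)
are never regressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .clock_sync import OffsetModel, fit_offset_model
from .config import SyncConfig, DEFAULT_CONFIG
from .streams import RecordedStream, RecordingBundle

__all__ = [
    "Segment",
    "detect_breaks",
    "regress_timestamps",
    "RlsRegressor",
    "rls_dejitter",
    "apply_clock_offsets",
    "synchronize_recording",
    "effective_srate",
    "srate_deviates",
    "diagnostics",
]


@dataclass
class Segment:
    """A contiguous run of samples ``[start, stop)`` with its fitted line.

    For regressed segments, the dejittered stamp of sample ``i`` is
    ``intercept + slope * (i - start)``; ``effective_srate`` is ``1/slope``.
    """

    start: int
    stop: int
    intercept: float | None = None
    slope: float | None = None
    effective_srate: float | None = None

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("segment must contain at least one sample")

    def __len__(self) -> int:
        return self.stop - self.start


def detect_breaks(
    timestamps: np.ndarray, nominal_srate: float, cfg: SyncConfig = DEFAULT_CONFIG
) -> list[Segment]:
    """Split a timestamp array into segments at gaps.

    A break is declared between consecutive samples when the gap exceeds
    ``max(break_threshold_seconds, break_threshold_samples/nominal_srate)``.
    Irregular streams (``nominal_srate == 0``) always form a single segment.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    n = len(timestamps)
    if n == 0:
        return []
    if nominal_srate <= 0 or n == 1:
        return [Segment(0, n)]
    threshold = max(
        cfg.break_threshold_seconds, cfg.break_threshold_samples / nominal_srate
    )
    breaks = np.flatnonzero(np.diff(timestamps) > threshold) + 1
    bounds = np.concatenate(([0], breaks, [n]))
    return [Segment(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def regress_timestamps(
    timestamps: np.ndarray, segment: Segment
) -> tuple[Segment, np.ndarray]:
    """Fit a line through a segment's timestamps and return the dejittered stamps.

    Ordinary least squares of timestamp on sample index; a single-sample
    segment passes through unchanged.
    """
    ts = np.asarray(timestamps, dtype=float)[segment.start : segment.stop]
    n = len(ts)
    if n < 2:
        segment.intercept = float(ts[0])
        segment.slope = None
        segment.effective_srate = None
        return segment, ts.copy()
    idx = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(idx, ts, 1)
    segment.intercept = float(intercept)
    segment.slope = float(slope)
    segment.effective_srate = 1.0 / slope if slope > 0 else np.inf
    return segment, intercept + slope * idx


class RlsRegressor:
    """Online least-squares line fit with exponential forgetting.

    Maintains exponentially decayed sufficient statistics of the regression
    of timestamp on sample index; with ``forgetting == 1`` the estimate is
    algebraically identical to batch OLS on all data seen so far, regardless
    of how the input was chunked.  Forgetting < 1 discounts old samples so
    the fit tracks slow drift changes.
    """

    def __init__(self, forgetting: float = 1.0) -> None:
        if not (0.0 < forgetting <= 1.0):
            raise ValueError("forgetting factor must lie in (0, 1]")
        self.forgetting = forgetting
        # decayed sums: [n, sum_x; sum_x, sum_x2] and [sum_y, sum_xy]
        self._s = np.zeros((2, 2))
        self._b = np.zeros(2)
        self.n_seen = 0
        self._idx_min = np.inf
        self._idx_max = -np.inf

    def update(self, index: float, timestamp: float) -> tuple[float, float]:
        lam = self.forgetting
        x = np.array([1.0, float(index)])
        self._s = lam * self._s + np.outer(x, x)
        self._b = lam * self._b + x * float(timestamp)
        self.n_seen += 1
        self._idx_min = min(self._idx_min, float(index))
        self._idx_max = max(self._idx_max, float(index))
        return self.estimate()

    def estimate(self) -> tuple[float, float]:
        """Current (intercept, slope); slope is 0 until two distinct indices."""
        if self.n_seen == 0:
            raise ValueError("no samples seen yet")
        if self.n_seen == 1 or self._idx_max == self._idx_min:
            return float(self._b[0] / self._s[0, 0]), 0.0
        intercept, slope = np.linalg.solve(self._s, self._b)
        return float(intercept), float(slope)


def rls_dejitter(
    pairs: Iterable[tuple[float, float]], forgetting: float = 1.0
) -> Iterator[tuple[float, float]]:
    """Running (intercept, slope) over a stream of (index, timestamp) pairs."""
    reg = RlsRegressor(forgetting)
    for index, timestamp in pairs:
        yield reg.update(index, timestamp)


def apply_clock_offsets(
    timestamps: np.ndarray, model: OffsetModel, cfg: SyncConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Map outlet timestamps into the recorder timebase.

    Subtracts the modeled offset (outlet minus recorder) evaluated at the raw
    stamps; a no-op when clock synchronization is disabled in ``cfg``.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if not cfg.handle_clock_sync:
        return timestamps.copy()
    return timestamps - model(timestamps)


def synchronize_recording(
    bundle: RecordingBundle, cfg: SyncConfig = DEFAULT_CONFIG
) -> RecordingBundle:
    """Fill ``timestamps_sync`` and ``segments`` for every stream of a bundle.

    Per stream: apply the fitted clock-offset model (when enabled and
    measurements exist), detect breaks, and — when jitter handling is enabled
    and the stream is regularly sampled — replace each segment's stamps by
    its least-squares line.  Always recomputed from the raw stamps, so the
    operation is idempotent.
    """
    for stream in bundle.streams:
        ts = stream.timestamps_raw.astype(float, copy=True)
        if cfg.handle_clock_sync and len(stream.offsets) > 0:
            model = fit_offset_model(stream.offsets, cfg.jump_threshold)
            ts = ts - model(ts)
        segments = detect_breaks(ts, stream.info.nominal_srate, cfg)
        if cfg.handle_jitter and stream.info.nominal_srate > 0:
            for seg in segments:
                seg, fitted = regress_timestamps(ts, seg)
                ts[seg.start : seg.stop] = fitted
        stream.timestamps_sync = ts
        stream.segments = segments
    return bundle


def effective_srate(stream: RecordedStream) -> float:
    """Observed sampling rate: sample count divided by recording length.

    Uses synchronized stamps when present.  Undefined (raises) for fewer
    than 2 samples.
    """
    ts = stream.timestamps
    if len(ts) < 2:
        raise ValueError("effective_srate needs at least 2 samples")
    span = float(ts[-1] - ts[0])
    if span <= 0:
        raise ValueError("recording length must be positive")
    return len(ts) / span


def srate_deviates(stream: RecordedStream, tolerance: float | None = None) -> bool:
    """True when the effective rate deviates from the nominal rate.

    Relative deviation above ``tolerance`` (default 1%) flags a misbehaving
    device — e.g. a webcam alternating between frame rates — whose
    timestamps must not be linearly smoothed.
    """
    if stream.info.nominal_srate <= 0:
        return False
    tol = DEFAULT_CONFIG.srate_tolerance if tolerance is None else tolerance
    rate = effective_srate(stream)
    return abs(rate - stream.info.nominal_srate) > tol * stream.info.nominal_srate


def diagnostics(bundle: RecordingBundle, cfg: SyncConfig = DEFAULT_CONFIG) -> dict:
    """Per-stream synchronization report (JSON-serializable)."""
    report: dict = {"streams": []}
    for stream in bundle.streams:
        entry: dict = {
            "name": stream.info.name,
            "type": stream.info.type,
            "nominal_srate": stream.info.nominal_srate,
            "n_samples": len(stream),
            "n_offset_measurements": len(stream.offsets),
            "segments": [
                {
                    "start": seg.start,
                    "stop": seg.stop,
                    "effective_srate": seg.effective_srate,
                }
                for seg in stream.segments
            ],
        }
        if len(stream) >= 2:
            rate = effective_srate(stream)
            entry["effective_srate"] = rate
            entry["srate_flag"] = srate_deviates(stream, cfg.srate_tolerance)
        if len(stream.offsets) > 0:
            model = fit_offset_model(stream.offsets, cfg.jump_threshold)
            entry["offset_model"] = [
                {
                    "start": p.start,
                    "stop": p.stop,
                    "intercept": p.intercept,
                    "slope": p.slope,
                }
                for p in model.pieces
            ]
        report["streams"].append(entry)
    return report
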