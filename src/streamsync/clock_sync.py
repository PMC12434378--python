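"""NTP-style clock-offset estimation between stream endpoints.

A probe exchange between an initiator (typically the recording side) and a
responder (the data source) yields four timestamps ``t0..t3``.  From these,
the round-trip time and instantaneous clock offset are

    RTT = (t3 - t0) - (t2 - t1)
    OFS = ((t1 - t0) + (t2 - t3)) / 2

``OFS`` estimates *responder clock minus initiator clock*; symmetric network
delays cancel.  Bursts of exchanges are filtered by keeping the measurement
with the lowest RTT, which suppresses random delay spikes.  The retained
measurements form a time series from which a piecewise-linear offset model
(intercept + drift per piece) is fitted by least squares; pieces are split at
large discontinuities such as those produced by an outlet reappearing on a
different host.

Sign convention, fixed project-wide: with the recorder as initiator, OFS
equals (outlet clock - recorder clock), so mapping outlet timestamps into the
recorder timebase *subtracts* the modeled offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "ProbeRecord",
    "OffsetMeasurement",
    "ClockOffsetSeries",
    "OffsetModel",
    "ModelPiece",
    "MalformedExchangeError",
    "EmptyBurstError",
    "compute_rtt_ofs",
    "clock_filter",
    "run_probe_burst",
    "fit_offset_model",
]


class MalformedExchangeError(ValueError):
    """A probe exchange whose implied round-trip time is negative."""


class EmptyBurstError(ValueError):
    """No measurement of a burst survived filtering; keep the previous estimate."""


@dataclass(frozen=True)
class ProbeRecord:
    """One four-timestamp probe exchange.

    ``t0``/``t3`` are read on the initiator clock (send / final receipt),
    ``t1``/``t2`` on the responder clock (receive / resend).
    """

    t0: float
    t1: float
    t2: float
    t3: float


@dataclass(frozen=True)
class OffsetMeasurement:
    """A retained (offset, round-trip) measurement.

    ``at`` is the initiator-clock time of the exchange (its ``t3``).
    """

    at: float
    ofs: float
    rtt: float


def compute_rtt_ofs(p: ProbeRecord) -> tuple[float, float]:
    """Round-trip time and clock offset of one probe exchange.

    Raises :class:`MalformedExchangeError` when the implied RTT is negative
    (inconsistent timestamps, e.g. a clock stepped mid-exchange).
    """
    rtt = (p.t3 - p.t0) - (p.t2 - p.t1)
    ofs = ((p.t1 - p.t0) + (p.t2 - p.t3)) / 2.0
    if rtt < 0:
        raise MalformedExchangeError(f"negative round-trip time {rtt:.6g} s")
    return rtt, ofs


def clock_filter(
    burst: Sequence[OffsetMeasurement], max_rtt: float
) -> OffsetMeasurement:
    """Retain the measurement with the lowest RTT among those with rtt <= max_rtt.

    Ties on RTT are broken by the earliest ``at`` so replays are
    deterministic.  Raises :class:`EmptyBurstError` when nothing survives.
    """
    survivors = [m for m in burst if m.rtt <= max_rtt]
    if not survivors:
        raise EmptyBurstError(
            f"no exchange with rtt <= {max_rtt:.6g} s in burst of {len(burst)}"
        )
    return min(survivors, key=lambda m: (m.rtt, m.at))


def run_probe_burst(
    initiator_clock: Callable[[float], float],
    responder_clock: Callable[[float], float],
    network,
    cfg,
    rng: np.random.Generator,
    t_start: float = 0.0,
) -> OffsetMeasurement:
    """Execute one burst of probe exchanges and clock-filter the result.

    ``initiator_clock`` and ``responder_clock`` map true time to the
    respective local clock reading; ``network`` provides
    ``sample_delay(direction, rng)`` for the forward and backward path.
    ``cfg`` supplies ``time_probe_count``, ``time_probe_interval`` and
    ``time_probe_max_rtt``.

    Exchanges are launched ``time_probe_interval`` apart starting at
    ``t_start`` (true time).  Malformed exchanges (negative RTT under clock
    noise) are dropped before filtering.
    """
    burst: list[OffsetMeasurement] = []
    for j in range(cfg.time_probe_count):
        t = t_start + j * cfg.time_probe_interval
        t0 = initiator_clock(t)
        d_fwd = network.sample_delay("forward", rng)
        t1 = responder_clock(t + d_fwd)
        t2 = responder_clock(t + d_fwd)
        d_bwd = network.sample_delay("backward", rng)
        t3 = initiator_clock(t + d_fwd + d_bwd)
        try:
            rtt, ofs = compute_rtt_ofs(ProbeRecord(t0, t1, t2, t3))
        except MalformedExchangeError:
            continue
        burst.append(OffsetMeasurement(at=t3, ofs=ofs, rtt=rtt))
    return clock_filter(burst, cfg.time_probe_max_rtt)


@dataclass
class ClockOffsetSeries:
    """Ordered history of retained offset measurements for one stream pair."""

    measurements: list[OffsetMeasurement] = field(default_factory=list)

    def append(self, m: OffsetMeasurement) -> None:
        if self.measurements and m.at <= self.measurements[-1].at:
            raise ValueError("measurement times must be strictly increasing")
        self.measurements.append(m)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, offsets, rtts) as float64 arrays."""
        at = np.array([m.at for m in self.measurements], dtype=float)
        ofs = np.array([m.ofs for m in self.measurements], dtype=float)
        rtt = np.array([m.rtt for m in self.measurements], dtype=float)
        return at, ofs, rtt

    @classmethod
    def from_arrays(
        cls, at: Iterable[float], ofs: Iterable[float], rtt: Iterable[float] | None = None
    ) -> "ClockOffsetSeries":
        at = list(at)
        ofs = list(ofs)
        rtt = list(rtt) if rtt is not None else [0.0] * len(at)
        series = cls()
        for a, o, r in zip(at, ofs, rtt):
            series.append(OffsetMeasurement(at=float(a), ofs=float(o), rtt=float(r)))
        return series


@dataclass(frozen=True)
class ModelPiece:
    """One linear piece of the offset model: OFS(t) = intercept + slope*(t - start)."""

    start: float
    stop: float
    intercept: float
    slope: float

    def __call__(self, t):
        t = np.clip(t, self.start, self.stop)
        return self.intercept + self.slope * (t - self.start)


@dataclass
class OffsetModel:
    """Piecewise-linear smoothed clock offset, evaluable at any time.

    Evaluation clamps the query time into the covering piece, so queries
    before the first or after the last measurement hold the boundary value
    (no extrapolation of drift beyond measured support).
    """

    pieces: list[ModelPiece]

    def __post_init__(self) -> None:
        if not self.pieces:
            raise ValueError("offset model needs at least one piece")
        starts = [p.start for p in self.pieces]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("model pieces must be ordered and non-overlapping")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tq = np.atleast_1d(t)
        starts = np.array([p.start for p in self.pieces])
        idx = np.clip(np.searchsorted(starts, tq, side="right") - 1, 0, len(self.pieces) - 1)
        out = np.empty(tq.shape, dtype=float)
        for i, piece in enumerate(self.pieces):
            mask = idx == i
            if np.any(mask):
                out[mask] = piece(tq[mask])
        return float(out[0]) if scalar else out


def _fit_line(at: np.ndarray, ofs: np.ndarray) -> tuple[float, float]:
    """OLS of ofs on (at - at[0]); a single point yields a constant."""
    if len(at) == 1:
        return float(ofs[0]), 0.0
    x = at - at[0]
    slope, intercept = np.polyfit(x, ofs, 1)
    return float(intercept), float(slope)


def fit_offset_model(series: ClockOffsetSeries, jump_threshold: float = 1.0) -> OffsetModel:
    """Fit the piecewise-linear offset model to a measurement series.

    The series is split wherever the offset steps by more than
    ``jump_threshold`` between consecutive measurements — the signature of a
    reconnect or host change, which produces offsets orders of magnitude
    beyond drift.  Each piece is fitted by ordinary least squares; robustness
    to delay spikes is delegated to the upstream min-RTT filter.
    """
    if len(series) == 0:
        raise ValueError("cannot fit an offset model to an empty series")
    at, ofs, _ = series.as_arrays()
    splits = np.flatnonzero(np.abs(np.diff(ofs)) > jump_threshold) + 1
    pieces: list[ModelPiece] = []
    bounds = np.concatenate(([0], splits, [len(at)]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg_at, seg_ofs = at[a:b], ofs[a:b]
        intercept, slope = _fit_line(seg_at, seg_ofs)
        pieces.append(
            ModelPiece(start=float(seg_at[0]), stop=float(seg_at[-1]), intercept=intercept, slope=slope)
        )
    return OffsetModel(pieces=pieces)
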