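"""In-process publish/subscribe transport with buffering and recovery.

Realizes the stream protocols — discovery by metadata query, subscription,
sample transfer, and silent reconnection — over an in-process channel with
injectable network behaviour, so that every transport property is
deterministic and testable.  Wire compatibility with real sockets is an
explicit non-goal; the semantics (FIFO delivery, bounded buffers with drop
accounting, recovery without caller-visible errors) are the contract.

Time is virtual: callers pass ``now`` (true time in seconds) explicitly to
``push``/``pull``, which makes runs replayable.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import clock_sync
from .clock_sync import ClockOffsetSeries, EmptyBurstError
from .config import SyncConfig, DEFAULT_CONFIG
from .streams import RecordedStream, RecordingBundle, StreamInfo

__all__ = [
    "Query",
    "Registry",
    "Outlet",
    "Inlet",
    "resolve",
    "record",
    "drop_and_recover",
]


@dataclass(frozen=True)
class Query:
    """Conjunction of equality predicates over StreamInfo fields.

    An empty query matches every stream.  Covers the common discovery
    patterns (``type='EEG'``, ``name='X' and type='EEG'``); full XPath is out
    of scope.
    """

    predicates: tuple[tuple[str, str], ...] = ()

    @classmethod
    def where(cls, **fields: str) -> "Query":
        return cls(tuple(sorted(fields.items())))

    def matches(self, info: StreamInfo) -> bool:
        for fieldname, value in self.predicates:
            if str(getattr(info, fieldname, None)) != str(value):
                return False
        return True


class Registry:
    """Process-local stream directory: the discovery substrate."""

    def __init__(self) -> None:
        self._outlets: dict[int, "Outlet"] = {}
        self._counter = itertools.count(1)
        self._cache: dict[Query, list[StreamInfo]] = {}

    def register(self, outlet: "Outlet") -> int:
        uid = next(self._counter)
        self._outlets[uid] = outlet
        self._cache.clear()
        return uid

    def unregister(self, outlet: "Outlet") -> None:
        self._outlets = {k: v for k, v in self._outlets.items() if v is not outlet}
        self._cache.clear()

    def active_outlets(self) -> list["Outlet"]:
        return [o for o in self._outlets.values() if o.state == "active"]

    def resolve(self, query: Query, timeout: float = 0.0) -> list[StreamInfo]:
        """All active streams satisfying the query.

        Responses are cached per identical query until the directory
        changes; an exhausted timeout simply yields an empty list.
        """
        if query in self._cache:
            return list(self._cache[query])
        result = [o.info for o in self.active_outlets() if query.matches(o.info)]
        self._cache[query] = result
        return list(result)

    def find_outlet(self, query: Query | None, source_id: str | None) -> "Outlet | None":
        """Rebind target: source_id takes precedence over the query."""
        if source_id:
            for outlet in self.active_outlets():
                if outlet.info.source_id == source_id:
                    return outlet
        if query is not None:
            for outlet in self.active_outlets():
                if query.matches(outlet.info):
                    return outlet
        return None


def resolve(query: Query, registry: Registry, timeout: float = 0.0) -> list[StreamInfo]:
    """Module-level resolve, mirroring the discovery verb."""
    return registry.resolve(query, timeout)


@dataclass
class _Buffered:
    timestamp: float
    values: tuple
    available_at: float


class Outlet:
    """Publishing endpoint with a bounded FIFO buffer.

    ``capacity_seconds`` bounds the buffer in seconds of data at the nominal
    rate (irregular streams get a fixed sample budget); overflow drops the
    oldest samples first and counts them.  ``clock`` maps true time to the
    outlet's local clock and is used both for default timestamps and as the
    probe responder during recording.
    """

    def __init__(
        self,
        info: StreamInfo,
        registry: Registry,
        capacity_seconds: float = DEFAULT_CONFIG.buffer_capacity_seconds,
        clock: Callable[[float], float] | None = None,
        chunk_period: float = 0.0,
        network_delay: Callable[[float], float] | None = None,
    ) -> None:
        self.info = info
        self.registry = registry
        self.clock = clock if clock is not None else (lambda t: t)
        self.chunk_period = chunk_period
        self.network_delay = network_delay
        if info.nominal_srate > 0:
            capacity = max(1, int(capacity_seconds * info.nominal_srate))
        else:
            capacity = max(1, int(capacity_seconds * 16))
        self.capacity = capacity
        self.buffer: deque[_Buffered] = deque()
        self.n_pushed = 0
        self.n_dropped = 0
        self.state = "active"
        self.unreachable = False
        self.registry.register(self)

    def push(
        self,
        values: Sequence,
        timestamp: float | None = None,
        now: float = 0.0,
        flush: bool = False,
    ) -> None:
        """Publish one sample.

        A missing timestamp is filled with the outlet clock at push time.
        Without ``flush``, delivery may be batched until the end of the
        current transmission chunk; ``flush`` marks the sample for immediate
        transmission.
        """
        if self.state != "active":
            raise RuntimeError("cannot push into a closed outlet")
        values = tuple(values) if not np.isscalar(values) else (values,)
        if len(values) != self.info.channel_count:
            raise ValueError(
                f"expected {self.info.channel_count} values, got {len(values)}"
            )
        if timestamp is None:
            timestamp = self.clock(now)
        available = now
        if not flush and self.chunk_period > 0:
            available = np.ceil(now / self.chunk_period) * self.chunk_period
        if self.network_delay is not None:
            available += self.network_delay(now)
        self.buffer.append(_Buffered(float(timestamp), values, float(available)))
        self.n_pushed += 1
        while len(self.buffer) > self.capacity:
            self.buffer.popleft()
            self.n_dropped += 1

    def close(self) -> None:
        self.state = "closed"
        self.registry.unregister(self)


class Inlet:
    """Subscribing endpoint.

    Bound either by a query or by a resolved StreamInfo (whose ``source_id``
    enables rebinding if the outlet is recreated).  While recovering, pulls
    deliver nothing but never raise.
    """

    def __init__(
        self,
        registry: Registry,
        query: Query | None = None,
        info: StreamInfo | None = None,
    ) -> None:
        if query is None and info is None:
            raise ValueError("an inlet needs a query or a resolved StreamInfo")
        self.registry = registry
        self.query = query
        self.source_id = info.source_id if info is not None else None
        self._outlet: Outlet | None = None
        self.n_pulled = 0
        self.received: list[tuple[float, tuple]] = []
        self._rebind()

    @property
    def state(self) -> str:
        return "connected" if self._outlet is not None and self._outlet.state == "active" else "recovering"

    @property
    def info(self) -> StreamInfo | None:
        return self._outlet.info if self._outlet is not None else None

    def _rebind(self) -> None:
        found = self.registry.find_outlet(self.query, self.source_id)
        if found is not None:
            self._outlet = found
            if found.info.source_id:
                self.source_id = found.info.source_id

    def pull(self, max_samples: int | None = None, now: float = np.inf) -> list[tuple[float, tuple]]:
        """Deliver buffered samples available by ``now``, in push order.

        Returns an empty list while disconnected or when nothing is
        available; never raises on a lost outlet (recovery is silent).
        """
        if self._outlet is None or self._outlet.state != "active":
            self._rebind()  # periodic rediscovery attempt
        outlet = self._outlet
        if outlet is None or outlet.state != "active" or outlet.unreachable:
            return []
        out: list[tuple[float, tuple]] = []
        while outlet.buffer and outlet.buffer[0].available_at <= now:
            if max_samples is not None and len(out) >= max_samples:
                break
            item = outlet.buffer.popleft()
            out.append((item.timestamp, item.values))
        self.n_pulled += len(out)
        self.received.extend(out)
        return out


def drop_and_recover(
    inlet: Inlet,
    registry: Registry,
    new_info: StreamInfo,
    **outlet_kwargs,
) -> dict:
    """Kill the inlet's outlet and recreate it under a new identity.

    Models the battery-swap scenario: the original outlet dies, a
    replacement with the same ``source_id`` appears (possibly on another
    host), and the inlet rebinds on its next pull without caller
    intervention.  Returns a small event log.
    """
    log: dict = {"events": []}
    if inlet._outlet is not None and inlet._outlet.state == "active":
        inlet._outlet.close()
        log["events"].append("outlet closed")
    inlet.pull(now=np.inf)
    log["state_during_downtime"] = inlet.state
    replacement = Outlet(new_info, registry, **outlet_kwargs)
    log["events"].append("outlet recreated")
    inlet.pull(max_samples=0, now=-np.inf)  # triggers rediscovery
    log["state_after_recovery"] = inlet.state
    log["rebound"] = inlet._outlet is replacement and inlet.state == "connected"
    return log


def record(
    inlets: Sequence[Inlet],
    duration: float,
    cfg: SyncConfig = DEFAULT_CONFIG,
    recorder_clock: Callable[[float], float] | None = None,
    probe_network=None,
    feeders: Sequence[Callable[[float, float], list]] | None = None,
    seed: int = 0,
    tick: float = 0.05,
) -> RecordingBundle:
    """Recorder: pull all inlets over ``duration`` and bundle the result.

    Steps virtual time in ``tick`` increments.  ``feeders``, when given, are
    per-inlet callables ``(t_from, t_to) -> [(timestamp, values), ...]``
    that push into the corresponding outlet each tick (driving the session
    without threads).  Probe bursts against each outlet's clock run every
    ``cfg.time_update_interval``; with ``cfg.force_default_timestamps`` the
    device-supplied stamps are discarded and samples are restamped with the
    recorder clock at receipt.
    """
    if not inlets:
        raise ValueError("need at least one inlet")
    if recorder_clock is None:
        recorder_clock = lambda t: t  # noqa: E731 - ideal recorder clock
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    collected: list[list[tuple[float, tuple]]] = [[] for _ in inlets]
    offset_series = [ClockOffsetSeries() for _ in inlets]
    next_probe = 0.0
    t = 0.0
    n_ticks = int(np.ceil(duration / tick))
    for k in range(n_ticks + 1):
        t = min(k * tick, duration)
        for i, inlet in enumerate(inlets):
            if feeders is not None and inlet._outlet is not None and t < duration:
                t_prev = max(0.0, (k - 1) * tick) if k else 0.0
                for timestamp, values in feeders[i](t_prev, t):
                    if inlet._outlet.state == "active":
                        inlet._outlet.push(values, timestamp=timestamp, now=t)
            for timestamp, values in inlet.pull(now=t):
                if cfg.force_default_timestamps:
                    timestamp = recorder_clock(t)
                collected[i].append((timestamp, values))
        if t >= next_probe:
            for i, inlet in enumerate(inlets):
                outlet = inlet._outlet
                if outlet is None or outlet.state != "active" or probe_network is None:
                    continue
                try:
                    m = clock_sync.run_probe_burst(
                        recorder_clock, outlet.clock, probe_network, cfg, rng, t_start=t
                    )
                    offset_series[i].append(m)
                except (EmptyBurstError, ValueError):
                    pass
            next_probe += cfg.time_update_interval
    streams = []
    for i, inlet in enumerate(inlets):
        info = inlet.info if inlet.info is not None else StreamInfo(name=f"stream{i}")
        samples = collected[i]
        timestamps = np.array([s[0] for s in samples], dtype=float)
        if info.channel_format == "string":
            values = np.empty((len(samples), info.channel_count), dtype=object)
            for j, (_, vals) in enumerate(samples):
                values[j, :] = vals
        else:
            values = np.array([s[1] for s in samples], dtype=float).reshape(
                len(samples), info.channel_count
            )
        streams.append(
            RecordedStream(
                info=info,
                timestamps_raw=timestamps,
                values=values,
                offsets=offset_series[i],
            )
        )
    return RecordingBundle(streams=streams)
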