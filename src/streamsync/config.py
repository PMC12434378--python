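"""Tuning configuration for stream synchronization.

Runtime behaviour (probe schedule, jitter handling, break detection) is
controlled by a :class:`SyncConfig`.  Settings can be loaded from a plaintext
``lsl_api.cfg``-style file with a ``[tuning]`` section, looked up in the
conventional order: application directory, then the user directory
(``~/lsl_api``), then the system directory (``/etc``).  The first file found
wins.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = ["SyncConfig", "load_config", "parse_config_file", "DEFAULT_CONFIG"]


@dataclass
class SyncConfig:
    """All tunable synchronization parameters.

    Attributes
    ----------
    handle_jitter:
        Replace observed timestamps of regularly sampled segments by a
        per-segment linear fit against sample index.
    handle_clock_sync:
        Map outlet timestamps into the recorder timebase using the measured
        clock-offset series.
    break_threshold_seconds, break_threshold_samples:
        A break (segment boundary) is declared between consecutive samples
        whose gap exceeds ``max(break_threshold_seconds,
        break_threshold_samples / nominal_srate)``.
    time_probe_max_rtt:
        Probe exchanges with a round-trip time above this bound are discarded
        by the clock filter (seconds).
    time_probe_interval:
        Spacing between the exchanges of one probe burst (seconds).
    time_probe_count:
        Number of exchanges per probe burst.
    time_update_interval:
        Period between probe bursts (seconds).
    multicast_min_rtt, multicast_max_rtt:
        Discovery-layer timeouts; parsed and stored for config-file
        compatibility, unused by the in-process transport.
    force_default_timestamps:
        Discard device-supplied timestamps and restamp at receipt on the
        recorder clock.
    rls_forgetting:
        Forgetting factor of the online (recursive least squares) dejitter
        estimator; 1.0 reproduces batch least squares.
    jump_threshold:
        Offset discontinuity (seconds) above which the clock-offset model is
        split into separate pieces (outlet reconnect / host change).
    srate_tolerance:
        Relative deviation between effective and nominal sampling rate above
        which a diagnostic flag is raised.
    boundary_interval:
        Approximate spacing of Boundary chunks written to container files
        (seconds of data).
    buffer_capacity_seconds:
        Default outlet/inlet buffer capacity, in seconds of data at the
        nominal rate.
    """

    handle_jitter: bool = True
    handle_clock_sync: bool = True
    break_threshold_seconds: float = 1.0
    break_threshold_samples: int = 500
    time_probe_max_rtt: float = 0.100
    time_probe_interval: float = 0.010
    time_probe_count: int = 10
    time_update_interval: float = 5.0
    multicast_min_rtt: float = 1.0
    multicast_max_rtt: float = 30.0
    force_default_timestamps: bool = False
    rls_forgetting: float = 1.0
    jump_threshold: float = 1.0
    srate_tolerance: float = 0.01
    boundary_interval: float = 10.0
    buffer_capacity_seconds: float = 360.0

    def __post_init__(self) -> None:
        if self.break_threshold_seconds <= 0 or self.break_threshold_samples <= 0:
            raise ValueError("break thresholds must be positive")
        if not (0.0 < self.rls_forgetting <= 1.0):
            raise ValueError("rls_forgetting must lie in (0, 1]")
        if self.time_probe_count < 1:
            raise ValueError("time_probe_count must be >= 1")

    def replace(self, **changes) -> "SyncConfig":
        return replace(self, **changes)


DEFAULT_CONFIG = SyncConfig()

# Keys as they appear verbatim in a [tuning] section, mapped onto SyncConfig
# fields.  HandleJitter and HandleJitterRemoval are accepted as aliases.
_KEY_MAP = {
    "TimeProbeMaxRTT": ("time_probe_max_rtt", float),
    "TimeProbeInterval": ("time_probe_interval", float),
    "TimeProbeCount": ("time_probe_count", int),
    "TimeUpdateInterval": ("time_update_interval", float),
    "MulticastMinRTT": ("multicast_min_rtt", float),
    "MulticastMaxRTT": ("multicast_max_rtt", float),
    "ForceDefaultTimestamps": ("force_default_timestamps", bool),
    "HandleJitter": ("handle_jitter", bool),
    "HandleJitterRemoval": ("handle_jitter", bool),
    "HandleClockSync": ("handle_clock_sync", bool),
    "BreakThresholdSeconds": ("break_threshold_seconds", float),
    "BreakThresholdSamples": ("break_threshold_samples", int),
}

_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}


def _coerce(raw: str, kind) -> object:
    raw = raw.strip()
    if kind is bool:
        lowered = raw.lower()
        if lowered in _TRUE:
            return True
        if lowered in _FALSE:
            return False
        raise ValueError(f"cannot interpret {raw!r} as a flag")
    return kind(raw)


def parse_config_file(path: str | Path, base: SyncConfig | None = None) -> SyncConfig:
    """Parse one ``lsl_api.cfg``-style file into a :class:`SyncConfig`.

    Unknown keys in the ``[tuning]`` section are ignored (forward
    compatibility); other sections are ignored entirely.
    """
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keys are matched case-sensitively, as printed
    with open(path, "r", encoding="utf-8") as fh:
        parser.read_file(fh)
    cfg = base if base is not None else SyncConfig()
    if not parser.has_section("tuning"):
        return cfg
    changes = {}
    for key, raw in parser.items("tuning"):
        if key in _KEY_MAP:
            field, kind = _KEY_MAP[key]
            changes[field] = _coerce(raw, kind)
    return cfg.replace(**changes) if changes else cfg


def load_config(
    app_dir: str | Path | None = None,
    user_dir: str | Path | None = None,
    system_dir: str | Path | None = None,
    filename: str = "lsl_api.cfg",
) -> SyncConfig:
    """Locate and parse the tuning config.

    Search order: application directory (default: current directory), user
    directory (default: ``~/lsl_api``), system directory (default ``/etc``).
    The first existing file is used; defaults apply when none is found.
    """
    candidates = [
        Path(app_dir) if app_dir is not None else Path.cwd(),
        Path(user_dir).expanduser() if user_dir is not None else Path("~/lsl_api").expanduser(),
        Path(system_dir) if system_dir is not None else Path("/etc"),
    ]
    for directory in candidates:
        path = directory / filename
        if path.is_file():
            return parse_config_file(path)
    return SyncConfig()
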