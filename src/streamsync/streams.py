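"""In-memory containers for streams and recordings.

A :class:`StreamInfo` declares a stream's identity and sample layout; a
:class:`RecordedStream` holds its observed samples and the clock-offset
measurements collected alongside; a :class:`RecordingBundle` groups the
streams of one recording session, optionally with the simulator's hidden
ground truth for every stream.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .clock_sync import ClockOffsetSeries

__all__ = [
    "CHANNEL_FORMATS",
    "StreamInfo",
    "RecordedStream",
    "StreamTruth",
    "RecordingBundle",
]

# channel_format -> numpy dtype (little-endian on disk); "string" is handled
# separately as variable-length text.
CHANNEL_FORMATS: dict[str, np.dtype | None] = {
    "float32": np.dtype("<f4"),
    "double64": np.dtype("<f8"),
    "int8": np.dtype("<i1"),
    "int16": np.dtype("<i2"),
    "int32": np.dtype("<i4"),
    "int64": np.dtype("<i8"),
    "string": None,
}


def _dict_to_xml(parent: ET.Element, data: dict) -> None:
    for key, value in data.items():
        child = ET.SubElement(parent, key)
        if isinstance(value, dict):
            _dict_to_xml(child, value)
        elif isinstance(value, (list, tuple)):
            # repeated elements share the parent key; each entry is a dict
            parent.remove(child)
            for entry in value:
                item = ET.SubElement(parent, key)
                if isinstance(entry, dict):
                    _dict_to_xml(item, entry)
                else:
                    item.text = str(entry)
        else:
            child.text = str(value)


def _xml_to_dict(element: ET.Element) -> Any:
    children = list(element)
    if not children:
        return element.text if element.text is not None else ""
    out: dict[str, Any] = {}
    for child in children:
        value = _xml_to_dict(child)
        if child.tag in out:
            existing = out[child.tag]
            if not isinstance(existing, list):
                out[child.tag] = [existing]
            out[child.tag].append(value)
        else:
            out[child.tag] = value
    return out


@dataclass
class StreamInfo:
    """Declared metadata of a stream.

    ``nominal_srate`` is the advertised sampling rate in Hz; 0 marks an
    irregular stream (e.g. event markers), which is never dejittered.
    ``desc`` is an attribute-free nested mapping serialized as an XML
    subtree.
    """

    name: str
    type: str = ""
    channel_count: int = 1
    nominal_srate: float = 0.0
    channel_format: str = "float32"
    source_id: str = ""
    desc: dict | None = None

    def __post_init__(self) -> None:
        if self.channel_count < 1:
            raise ValueError("channel_count must be >= 1")
        if self.nominal_srate < 0:
            raise ValueError("nominal_srate must be >= 0")
        if self.channel_format not in CHANNEL_FORMATS:
            raise ValueError(f"unknown channel_format {self.channel_format!r}")

    @property
    def dtype(self) -> np.dtype | None:
        return CHANNEL_FORMATS[self.channel_format]

    def to_xml(self) -> str:
        root = ET.Element("info")
        ET.SubElement(root, "name").text = self.name
        ET.SubElement(root, "type").text = self.type
        ET.SubElement(root, "channel_count").text = str(self.channel_count)
        ET.SubElement(root, "nominal_srate").text = repr(float(self.nominal_srate))
        ET.SubElement(root, "channel_format").text = self.channel_format
        ET.SubElement(root, "source_id").text = self.source_id
        desc = ET.SubElement(root, "desc")
        if self.desc:
            _dict_to_xml(desc, self.desc)
        return ET.tostring(root, encoding="unicode")

    @classmethod
    def from_xml(cls, xml: str) -> "StreamInfo":
        root = ET.fromstring(xml)

        def text(tag: str, default: str = "") -> str:
            node = root.find(tag)
            return node.text if node is not None and node.text is not None else default

        desc_node = root.find("desc")
        desc = None
        if desc_node is not None and len(desc_node):
            desc = _xml_to_dict(desc_node)
        return cls(
            name=text("name"),
            type=text("type"),
            channel_count=int(text("channel_count", "1")),
            nominal_srate=float(text("nominal_srate", "0")),
            channel_format=text("channel_format", "float32"),
            source_id=text("source_id"),
            desc=desc,
        )


@dataclass
class RecordedStream:
    """One stream of a recording.

    ``timestamps_raw`` are the observed outlet-clock stamps, recorded "as it
    happened"; ``timestamps_sync`` is filled by synchronization with stamps
    mapped into the recorder timebase (and, for regular streams, dejittered).
    ``values`` has shape ``(n_samples, channel_count)``; string streams use an
    object array.
    """

    info: StreamInfo
    timestamps_raw: np.ndarray
    values: np.ndarray
    offsets: ClockOffsetSeries = field(default_factory=ClockOffsetSeries)
    timestamps_sync: np.ndarray | None = None
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps_raw = np.asarray(self.timestamps_raw, dtype=float)
        self.values = np.asarray(self.values)
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, 1)
        if len(self.timestamps_raw) != len(self.values):
            raise ValueError("timestamps and values must have equal length")

    def __len__(self) -> int:
        return len(self.timestamps_raw)

    @property
    def timestamps(self) -> np.ndarray:
        """Synchronized stamps when available, raw stamps otherwise."""
        return self.timestamps_sync if self.timestamps_sync is not None else self.timestamps_raw


@dataclass
class StreamTruth:
    """Hidden per-stream ground truth of a simulated recording."""

    t_actual: np.ndarray
    epoch_offset: float = 0.0
    drift: float = 0.0
    clock_noise_std: float = 0.0
    setup_offset: float = 0.0
    timestamp_noise_std: float = 0.0
    stamp_at_delivery: bool = False

    def true_offset(self, t_true) -> np.ndarray:
        """Noiseless clock offset (device minus recorder) at true time."""
        return self.epoch_offset + self.drift * np.asarray(t_true, dtype=float)


@dataclass
class RecordingBundle:
    """All streams of one recording plus optional simulator ground truth."""

    streams: list[RecordedStream]
    truth: dict[str, StreamTruth] | None = None

    def __iter__(self):
        return iter(self.streams)

    def __len__(self) -> int:
        return len(self.streams)

    def stream(self, name: str) -> RecordedStream:
        for s in self.streams:
            if s.info.name == name:
                return s
        raise KeyError(f"no stream named {name!r}")
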