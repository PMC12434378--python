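"""Chunk-oriented binary container for multi-stream recordings (XDF dialect).

Layout, little-endian throughout:

* magic ``XDF:``
* a sequence of chunks, each ``[NumLengthBytes: uint8 in {1,4,8}]
  [Length: uint of that width] [Tag: uint16] [content]`` where ``Length``
  counts tag plus content.  The length-byte width is the smallest that fits.

Chunk tags:

=============  ===  =======================================================
FileHeader       1  XML (``<info><version>1.0</version></info>``)
StreamHeader     2  uint32 stream id + StreamInfo XML
Samples          3  uint32 stream id, varint sample count, then per sample a
                    timestamp-presence byte (0 = deduce from the nominal
                    interval, 8 = explicit float64), values in the declared
                    format (strings varint-length-prefixed)
ClockOffset      4  uint32 stream id + collection time + offset (2x float64)
Boundary         5  16 opaque bytes, written every ~10 s of data
StreamFooter     6  uint32 stream id + XML (first/last timestamp, count)
=============  ===  =======================================================

Raw (uncorrected, outlet-clock) timestamps and the offset-measurement series
are what get written: the file is a record of the session "as it happened";
synchronization is re-derived on load.  The stored offset value follows this
package's sign convention (outlet clock minus recorder clock).

The reader is deliberately tolerant: unknown tags are skipped via the length
field, and a truncated file is salvaged up to the last complete chunk with a
warning.
"""

from __future__ import annotations

import io
import struct
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .clock_sync import ClockOffsetSeries, OffsetMeasurement
from .config import SyncConfig, DEFAULT_CONFIG
from .streams import RecordedStream, RecordingBundle, StreamInfo

__all__ = [
    "TAG_FILE_HEADER",
    "TAG_STREAM_HEADER",
    "TAG_SAMPLES",
    "TAG_CLOCK_OFFSET",
    "TAG_BOUNDARY",
    "TAG_STREAM_FOOTER",
    "XdfChunk",
    "write_xdf",
    "read_xdf",
    "validate_xdf",
    "XdfFormatError",
]

MAGIC = b"XDF:"
TAG_FILE_HEADER = 1
TAG_STREAM_HEADER = 2
TAG_SAMPLES = 3
TAG_CLOCK_OFFSET = 4
TAG_BOUNDARY = 5
TAG_STREAM_FOOTER = 6
_KNOWN_TAGS = frozenset(range(1, 7))

_BOUNDARY_UUID = bytes(
    [0x43, 0xA5, 0x46, 0xDC, 0xCB, 0xF5, 0x41, 0x0F,
     0xB3, 0x0E, 0xD5, 0x46, 0x73, 0x83, 0xCB, 0xE4]
)

_SAMPLES_PER_CHUNK = 4096


class XdfFormatError(ValueError):
    """The file is not a container file this codec can read."""


@dataclass
class XdfChunk:
    """One parsed chunk: tag, stream id (where applicable), raw payload."""

    tag: int
    stream_id: int | None
    payload: bytes = field(repr=False)


def _write_varlen(fh, value: int) -> None:
    """Unsigned int preceded by a one-byte width marker (1, 4 or 8 bytes)."""
    if value < 0x100:
        fh.write(b"\x01" + struct.pack("<B", value))
    elif value < 0x1_0000_0000:
        fh.write(b"\x04" + struct.pack("<I", value))
    else:
        fh.write(b"\x08" + struct.pack("<Q", value))


def _read_varlen(fh) -> int:
    marker = fh.read(1)
    if len(marker) != 1:
        raise EOFError("end of file")
    width = marker[0]
    if width not in (1, 4, 8):
        raise XdfFormatError(f"invalid length-byte width {width}")
    raw = fh.read(width)
    if len(raw) != width:
        raise EOFError("truncated length field")
    return int.from_bytes(raw, "little")


def _write_chunk(fh, tag: int, content: bytes) -> None:
    _write_varlen(fh, len(content) + 2)
    fh.write(struct.pack("<H", tag))
    fh.write(content)


def _numeric_record_dtype(info: StreamInfo) -> np.dtype:
    """Packed per-sample layout with an explicit timestamp."""
    return np.dtype(
        [("presence", "u1"), ("ts", "<f8"), ("values", info.dtype, (info.channel_count,))]
    )


def _encode_samples(stream: RecordedStream, sid: int, start: int, stop: int) -> bytes:
    """One Samples chunk's content for samples [start, stop)."""
    info = stream.info
    buf = io.BytesIO()
    buf.write(struct.pack("<I", sid))
    _write_varlen(buf, stop - start)
    ts = stream.timestamps_raw
    values = stream.values
    if info.channel_format == "string":
        for i in range(start, stop):
            buf.write(b"\x08" + struct.pack("<d", ts[i]))
            for c in range(info.channel_count):
                encoded = str(values[i, c]).encode("utf-8")
                _write_varlen(buf, len(encoded))
                buf.write(encoded)
    else:
        records = np.empty(stop - start, dtype=_numeric_record_dtype(info))
        records["presence"] = 8
        records["ts"] = ts[start:stop]
        records["values"] = values[start:stop].astype(info.dtype, copy=False)
        buf.write(records.tobytes())
    return buf.getvalue()


def write_xdf(
    bundle: RecordingBundle,
    path,
    cfg: SyncConfig = DEFAULT_CONFIG,
    boundary_interval: float | None = None,
) -> None:
    """Write a bundle to an XDF container file.

    Samples chunks of different streams are interleaved in timestamp order,
    with a Boundary chunk roughly every ``boundary_interval`` seconds of
    data.  Timestamps are always written explicitly (8-byte floats); the
    deduced-timestamp encoding is supported on read.
    """
    boundary_interval = (
        cfg.boundary_interval if boundary_interval is None else boundary_interval
    )
    for stream in bundle.streams:
        if stream.info.channel_format not in ("string",) and stream.info.dtype is None:
            raise XdfFormatError(f"unwritable format {stream.info.channel_format}")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        header = "<?xml version=\"1.0\"?><info><version>1.0</version></info>"
        _write_chunk(fh, TAG_FILE_HEADER, header.encode("utf-8"))
        for sid, stream in enumerate(bundle.streams, start=1):
            _write_chunk(
                fh,
                TAG_STREAM_HEADER,
                struct.pack("<I", sid) + stream.info.to_xml().encode("utf-8"),
            )
        # interleave sample chunks across streams by their first timestamp
        pieces: list[tuple[float, int, int, int]] = []  # (t_first, sid, start, stop)
        for sid, stream in enumerate(bundle.streams, start=1):
            for start in range(0, len(stream), _SAMPLES_PER_CHUNK):
                stop = min(start + _SAMPLES_PER_CHUNK, len(stream))
                pieces.append((float(stream.timestamps_raw[start]), sid, start, stop))
        pieces.sort(key=lambda p: (p[0], p[1]))
        offset_cursor = {sid: 0 for sid in range(1, len(bundle.streams) + 1)}
        next_boundary = -np.inf
        for t_first, sid, start, stop in pieces:
            if boundary_interval > 0 and t_first >= next_boundary:
                _write_chunk(fh, TAG_BOUNDARY, _BOUNDARY_UUID)
                next_boundary = t_first + boundary_interval
            stream = bundle.streams[sid - 1]
            # flush offset measurements collected up to this point in time
            series = stream.offsets.measurements
            cursor = offset_cursor[sid]
            while cursor < len(series) and series[cursor].at <= t_first:
                m = series[cursor]
                _write_chunk(
                    fh,
                    TAG_CLOCK_OFFSET,
                    struct.pack("<Idd", sid, m.at, m.ofs),
                )
                cursor += 1
            offset_cursor[sid] = cursor
            _write_chunk(fh, TAG_SAMPLES, _encode_samples(stream, sid, start, stop))
        for sid, stream in enumerate(bundle.streams, start=1):
            for m in stream.offsets.measurements[offset_cursor[sid]:]:
                _write_chunk(
                    fh, TAG_CLOCK_OFFSET, struct.pack("<Idd", sid, m.at, m.ofs)
                )
            root = ET.Element("info")
            if len(stream):
                ET.SubElement(root, "first_timestamp").text = repr(
                    float(stream.timestamps_raw[0])
                )
                ET.SubElement(root, "last_timestamp").text = repr(
                    float(stream.timestamps_raw[-1])
                )
            ET.SubElement(root, "sample_count").text = str(len(stream))
            _write_chunk(
                fh,
                TAG_STREAM_FOOTER,
                struct.pack("<I", sid) + ET.tostring(root, encoding="unicode").encode("utf-8"),
            )


def _iter_chunks(fh, *, salvage: bool = True):
    """Yield (tag, payload) pairs; stop with a warning on truncation."""
    while True:
        try:
            length = _read_varlen(fh)
        except EOFError as exc:
            if str(exc) == "end of file":
                return
            if salvage:
                warnings.warn("file ends in a truncated chunk header; salvaging")
                return
            raise
        raw = fh.read(length)
        if len(raw) < length:
            if salvage:
                warnings.warn("file ends in a truncated chunk; salvaging earlier chunks")
                return
            raise XdfFormatError("truncated chunk")
        if length < 2:
            if salvage:
                warnings.warn("chunk shorter than its tag field; stopping")
                return
            raise XdfFormatError("chunk shorter than its tag field")
        tag = struct.unpack_from("<H", raw)[0]
        yield tag, raw[2:]


def _decode_samples(payload: bytes, info: StreamInfo, last_ts: float):
    """Decode one Samples chunk; returns (timestamps, rows, new_last_ts)."""
    buf = io.BytesIO(payload[4:])
    n = _read_varlen(buf)
    interval = 1.0 / info.nominal_srate if info.nominal_srate > 0 else 0.0
    timestamps = np.empty(n)
    if info.channel_format != "string":
        # fast path: fixed-width records with explicit timestamps throughout
        record_dtype = _numeric_record_dtype(info)
        body = buf.getvalue()[buf.tell():]
        if len(body) == n * record_dtype.itemsize:
            records = np.frombuffer(body, dtype=record_dtype)
            if n and np.all(records["presence"] == 8):
                ts = records["ts"].astype(float)
                return ts, records["values"].copy(), float(ts[-1])
    if info.channel_format == "string":
        rows = np.empty((n, info.channel_count), dtype=object)
    else:
        rows = np.empty((n, info.channel_count), dtype=info.dtype)
        row_size = info.dtype.itemsize * info.channel_count
    for i in range(n):
        presence = buf.read(1)[0]
        if presence == 8:
            last_ts = struct.unpack("<d", buf.read(8))[0]
        else:
            last_ts = last_ts + interval
        timestamps[i] = last_ts
        if info.channel_format == "string":
            for c in range(info.channel_count):
                size = _read_varlen(buf)
                rows[i, c] = buf.read(size).decode("utf-8")
        else:
            rows[i] = np.frombuffer(buf.read(row_size), dtype=info.dtype)
    return timestamps, rows, last_ts


def read_xdf(path, cfg: SyncConfig = DEFAULT_CONFIG) -> RecordingBundle:
    """Read a container file back into an (unsynchronized) bundle.

    Streams are reassembled by stream id; omitted timestamps are deduced as
    the previous stamp plus the nominal interval.  Unknown chunk tags are
    skipped; a truncated file is salvaged up to the last complete chunk.
    """
    infos: dict[int, StreamInfo] = {}
    sample_parts: dict[int, list] = {}
    ts_parts: dict[int, list] = {}
    last_ts: dict[int, float] = {}
    offsets: dict[int, list[tuple[float, float]]] = {}
    order: list[int] = []
    with open(path, "rb") as fh:
        if fh.read(4) != MAGIC:
            raise XdfFormatError("not an XDF file (bad magic)")
        for tag, payload in _iter_chunks(fh):
            if tag == TAG_STREAM_HEADER:
                sid = struct.unpack_from("<I", payload)[0]
                infos[sid] = StreamInfo.from_xml(payload[4:].decode("utf-8"))
                sample_parts.setdefault(sid, [])
                ts_parts.setdefault(sid, [])
                offsets.setdefault(sid, [])
                last_ts[sid] = 0.0
                order.append(sid)
            elif tag == TAG_SAMPLES:
                sid = struct.unpack_from("<I", payload)[0]
                if sid not in infos:
                    warnings.warn(f"samples for undeclared stream {sid}; skipping")
                    continue
                ts, rows, last = _decode_samples(payload, infos[sid], last_ts[sid])
                ts_parts[sid].append(ts)
                sample_parts[sid].append(rows)
                last_ts[sid] = last
            elif tag == TAG_CLOCK_OFFSET:
                sid, at, ofs = struct.unpack_from("<Idd", payload)
                if sid in offsets:
                    offsets[sid].append((at, ofs))
            elif tag in (TAG_FILE_HEADER, TAG_BOUNDARY, TAG_STREAM_FOOTER):
                continue
            else:
                continue  # unknown tag: skippable by design
    streams = []
    for sid in order:
        info = infos[sid]
        if ts_parts[sid]:
            timestamps = np.concatenate(ts_parts[sid])
            values = np.concatenate(sample_parts[sid], axis=0)
        else:
            timestamps = np.empty(0)
            if info.channel_format == "string":
                values = np.empty((0, info.channel_count), dtype=object)
            else:
                values = np.empty((0, info.channel_count), dtype=info.dtype)
        pairs = sorted(set(offsets[sid]))
        series = ClockOffsetSeries()
        for at, ofs in pairs:
            series.append(OffsetMeasurement(at=at, ofs=ofs, rtt=0.0))
        streams.append(
            RecordedStream(
                info=info, timestamps_raw=timestamps, values=values, offsets=series
            )
        )
    return RecordingBundle(streams=streams)


def validate_xdf(path) -> dict:
    """Structural report: chunk counts, per-stream totals, footer consistency.

    Violations are listed, not raised; a file with no Boundary chunks only
    gets an informational note.
    """
    chunk_counts: dict[int, int] = {}
    sample_counts: dict[int, int] = {}
    footer_counts: dict[int, int] = {}
    violations: list[str] = []
    notes: list[str] = []
    with open(path, "rb") as fh:
        if fh.read(4) != MAGIC:
            raise XdfFormatError("not an XDF file (bad magic)")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for tag, payload in _iter_chunks(fh):
                chunk_counts[tag] = chunk_counts.get(tag, 0) + 1
                if tag == TAG_STREAM_HEADER:
                    sid = struct.unpack_from("<I", payload)[0]
                    sample_counts.setdefault(sid, 0)
                elif tag == TAG_SAMPLES:
                    sid = struct.unpack_from("<I", payload)[0]
                    buf = io.BytesIO(payload[4:])
                    sample_counts[sid] = sample_counts.get(sid, 0) + _read_varlen(buf)
                elif tag == TAG_STREAM_FOOTER:
                    sid = struct.unpack_from("<I", payload)[0]
                    root = ET.fromstring(payload[4:].decode("utf-8"))
                    node = root.find("sample_count")
                    if node is not None and node.text:
                        footer_counts[sid] = int(node.text)
        for warning in caught:
            violations.append(str(warning.message))
    for sid, declared in footer_counts.items():
        observed = sample_counts.get(sid, 0)
        if observed != declared:
            violations.append(
                f"stream {sid}: footer declares {declared} samples, observed {observed}"
            )
    for sid in sample_counts:
        if sid not in footer_counts:
            notes.append(f"stream {sid}: no footer")
    if chunk_counts.get(TAG_BOUNDARY, 0) == 0:
        notes.append("no Boundary chunks present")
    return {
        "chunk_counts": {int(k): int(v) for k, v in chunk_counts.items()},
        "sample_counts": {int(k): int(v) for k, v in sample_counts.items()},
        "footer_counts": {int(k): int(v) for k, v in footer_counts.items()},
        "violations": violations,
        "notes": notes,
    }
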