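"""Container codec: round trips, tolerant reading, structural validation."""

import io
import struct

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from streamsync.clock_sync import ClockOffsetSeries
from streamsync.streams import RecordedStream, RecordingBundle, StreamInfo
from streamsync.xdf_io import (
    MAGIC,
    TAG_BOUNDARY,
    TAG_SAMPLES,
    XdfFormatError,
    _write_chunk,
    _write_varlen,
    read_xdf,
    validate_xdf,
    write_xdf,
)


def _numeric_stream(name="s1", fmt="float32", n=10, channels=3, seed=0, srate=100.0):
    rng = np.random.default_rng(seed)
    info = StreamInfo(name=name, type="EEG", channel_count=channels,
                      nominal_srate=srate, channel_format=fmt, source_id=name)
    if fmt.startswith(("int",)):
        values = rng.integers(-100, 100, size=(n, channels)).astype(info.dtype)
    else:
        values = rng.normal(size=(n, channels)).astype(info.dtype)
    ts = np.sort(rng.uniform(0, 10, size=n))
    return RecordedStream(info=info, timestamps_raw=ts, values=values)


def _marker_stream(labels, name="mk"):
    info = StreamInfo(name=name, type="Markers", nominal_srate=0.0,
                      channel_format="string", source_id=name)
    values = np.empty((len(labels), 1), dtype=object)
    values[:, 0] = labels
    return RecordedStream(
        info=info, timestamps_raw=np.arange(len(labels), dtype=float), values=values
    )


class TestRoundTrip:
    def test_numeric_stream_bit_exact(self, tmp_path):
        stream = _numeric_stream()
        stream.offsets = ClockOffsetSeries.from_arrays([1.0, 6.0], [0.5, 0.5001])
        path = tmp_path / "a.xdf"
        write_xdf(RecordingBundle(streams=[stream]), path)
        back = read_xdf(path).streams[0]
        assert np.array_equal(back.values, stream.values)
        assert np.array_equal(back.timestamps_raw, stream.timestamps_raw)
        assert back.info == stream.info
        at, ofs, _ = back.offsets.as_arrays()
        assert np.array_equal(at, [1.0, 6.0]) and np.array_equal(ofs, [0.5, 0.5001])

    def test_string_markers_round_trip_including_empty(self, tmp_path):
        stream = _marker_stream(["go", "", "stop", "…unicode…"])
        path = tmp_path / "m.xdf"
        write_xdf(RecordingBundle(streams=[stream]), path)
        back = read_xdf(path).streams[0]
        assert back.values[:, 0].tolist() == ["go", "", "stop", "…unicode…"]

    @pytest.mark.parametrize("fmt", ["float32", "double64", "int8", "int16", "int32", "int64"])
    def test_all_numeric_formats(self, fmt, tmp_path):
        stream = _numeric_stream(fmt=fmt, n=7, channels=2)
        path = tmp_path / f"{fmt}.xdf"
        write_xdf(RecordingBundle(streams=[stream]), path)
        back = read_xdf(path).streams[0]
        assert back.values.dtype == stream.values.dtype
        assert np.array_equal(back.values, stream.values)

    def test_multi_stream_reassembly(self, tmp_path):
        streams = [
            _numeric_stream(name="a", n=5000, channels=1, seed=1),
            _numeric_stream(name="b", n=200, channels=4, seed=2),
            _marker_stream(["x"] * 5, name="c"),
        ]
        path = tmp_path / "multi.xdf"
        write_xdf(RecordingBundle(streams=streams), path)
        back = read_xdf(path)
        assert [s.info.name for s in back.streams] == ["a", "b", "c"]
        for orig, rec in zip(streams, back.streams):
            assert np.array_equal(rec.timestamps_raw, orig.timestamps_raw)
            assert np.array_equal(rec.values, orig.values)

    def test_empty_stream(self, tmp_path):
        info = StreamInfo(name="e", nominal_srate=100.0, source_id="e")
        stream = RecordedStream(info=info, timestamps_raw=np.empty(0),
                                values=np.empty((0, 1), dtype=np.float32))
        path = tmp_path / "e.xdf"
        write_xdf(RecordingBundle(streams=[stream]), path)
        assert len(read_xdf(path).streams[0]) == 0

    def test_desc_metadata_round_trips(self, tmp_path):
        info = StreamInfo(
            name="d", type="EEG", nominal_srate=100.0, source_id="d",
            desc={"manufacturer": "acme", "channels": {"label": ["Fz", "Cz"]}},
        )
        stream = RecordedStream(info=info, timestamps_raw=np.arange(3.0),
                                values=np.zeros((3, 1), dtype=np.float32))
        path = tmp_path / "d.xdf"
        write_xdf(RecordingBundle(streams=[stream]), path)
        assert read_xdf(path).streams[0].info.desc == info.desc


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    fmt=st.sampled_from(["float32", "double64", "int16", "int32", "string"]),
    n=st.integers(min_value=0, max_value=40),
    channels=st.integers(min_value=1, max_value=4),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_round_trip_identity_randomized(fmt, n, channels, seed, tmp_path_factory):
    """Randomized formats, counts and payloads survive write/read unchanged."""
    tmp_path = tmp_path_factory.mktemp("xdf")
    rng = np.random.default_rng(seed)
    info = StreamInfo(name="r", type="t", channel_count=channels,
                      nominal_srate=float(rng.choice([0.0, 100.0])),
                      channel_format=fmt, source_id="r")
    ts = np.sort(rng.uniform(-100, 100, size=n))
    if fmt == "string":
        values = np.empty((n, channels), dtype=object)
        for i in range(n):
            for c in range(channels):
                length = int(rng.integers(0, 12))
                values[i, c] = "".join(map(chr, rng.integers(32, 1000, size=length)))
    elif fmt.startswith("int"):
        iinfo = np.iinfo(info.dtype)
        values = rng.integers(iinfo.min, iinfo.max, size=(n, channels), dtype=info.dtype)
    else:
        values = rng.normal(size=(n, channels)).astype(info.dtype)
    stream = RecordedStream(info=info, timestamps_raw=ts, values=values)
    path = tmp_path / "prop.xdf"
    write_xdf(RecordingBundle(streams=[stream]), path)
    back = read_xdf(path).streams[0]
    assert np.array_equal(back.timestamps_raw, ts)
    assert np.array_equal(back.values, values)


class TestTolerantReader:
    def test_bad_magic_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.bin"
        path.write_bytes(b"NOPE" + b"\x00" * 32)
        with pytest.raises(XdfFormatError):
            read_xdf(path)

    def test_truncated_file_salvaged(self, tmp_path):
        stream = _numeric_stream(n=5000, channels=1)
        path = tmp_path / "t.xdf"
        write_xdf(RecordingBundle(streams=[stream]), path)
        data = path.read_bytes()
        cut = tmp_path / "cut.xdf"
        cut.write_bytes(data[: len(data) - 2000])  # cut into the last chunks
        with pytest.warns(UserWarning):
            back = read_xdf(cut)
        n = len(back.streams[0])
        assert 0 < n < 5000
        assert np.array_equal(
            back.streams[0].timestamps_raw, stream.timestamps_raw[:n]
        )

    def test_unknown_tags_skipped(self, tmp_path):
        stream = _numeric_stream(n=4)
        path = tmp_path / "u.xdf"
        write_xdf(RecordingBundle(streams=[stream]), path)
        data = bytearray(path.read_bytes())
        # splice an unknown-tag chunk right after the magic
        extra = io.BytesIO()
        _write_chunk(extra, 999, b"mystery-payload")
        patched = tmp_path / "patched.xdf"
        patched.write_bytes(bytes(data[:4]) + extra.getvalue() + bytes(data[4:]))
        back = read_xdf(patched)
        assert np.array_equal(back.streams[0].values, stream.values)

    def test_deduced_timestamps_from_presence_byte_zero(self, tmp_path):
        # hand-build a file whose samples omit timestamps after the first:
        # the reader must space them at exactly 1/nominal_srate
        info = StreamInfo(name="d", nominal_srate=250.0, channel_count=1,
                          channel_format="float32", source_id="d")
        buf = io.BytesIO()
        buf.write(MAGIC)
        _write_chunk(buf, 2, struct.pack("<I", 1) + info.to_xml().encode())
        content = io.BytesIO()
        content.write(struct.pack("<I", 1))
        _write_varlen(content, 4)
        content.write(b"\x08" + struct.pack("<d", 5.0) + struct.pack("<f", 1.0))
        for k in range(3):
            content.write(b"\x00" + struct.pack("<f", float(k)))
        _write_chunk(buf, TAG_SAMPLES, content.getvalue())
        path = tmp_path / "deduced.xdf"
        path.write_bytes(buf.getvalue())
        back = read_xdf(path).streams[0]
        assert back.timestamps_raw == pytest.approx(5.0 + np.arange(4) * 0.004, abs=1e-12)


class TestValidate:
    def test_pristine_file_no_violations(self, tmp_path):
        path = tmp_path / "ok.xdf"
        write_xdf(RecordingBundle(streams=[_numeric_stream(n=50)]), path)
        report = validate_xdf(path)
        assert report["violations"] == []
        assert report["sample_counts"] == {1: 50}

    def test_corrupted_footer_count_reported(self, tmp_path):
        path = tmp_path / "bad.xdf"
        write_xdf(RecordingBundle(streams=[_numeric_stream(n=50)]), path)
        data = path.read_bytes()
        # footer XML carries the count in text; corrupt 50 -> 51
        patched = data.replace(b"<sample_count>50<", b"<sample_count>51<")
        assert patched != data
        path.write_bytes(patched)
        report = validate_xdf(path)
        assert any("footer declares 51" in v for v in report["violations"])

    def test_missing_boundaries_is_note_not_violation(self, tmp_path):
        path = tmp_path / "nb.xdf"
        write_xdf(
            RecordingBundle(streams=[_numeric_stream(n=10)]), path,
            boundary_interval=0.0,
        )
        report = validate_xdf(path)
        assert report["chunk_counts"].get(TAG_BOUNDARY, 0) == 0
        assert report["violations"] == []
        assert any("Boundary" in n for n in report["notes"])


def test_session_round_trip_is_deterministic(small_session, tmp_path):
    """Same seed -> same bundle -> byte-identical files across write cycles."""
    p1, p2 = tmp_path / "a.xdf", tmp_path / "b.xdf"
    write_xdf(small_session, p1)
    write_xdf(read_xdf(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()
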