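"""Self-describing archive container (.mstc).

Layout: magic ``MSTC``, one version byte, a big-endian uint32 header
length, a JSON header (mode, read lengths, counts, stream table), then the
compressed stream payloads concatenated in table order.  Each table entry
records the stream name, backend, raw and compressed byte lengths and a
CRC32, so the decoder needs no side information and corruption is detected.

Backends: ``bz2`` (a block-sorting compressor, used for text and bit
streams) and ``lzma`` (used for the pair-distance integers); ``raw`` is a
fallback when a backend would inflate a tiny stream.
"""

from __future__ import annotations

import bz2
import json
import lzma
import zlib

from .codec import StreamBundle

__all__ = ["ArchiveError", "MAGIC", "VERSION", "build_archive", "parse_archive"]

MAGIC = b"MSTC"
VERSION = 1

_TEXT_BACKEND = "bz2"
_DISTANCE_BACKEND = "lzma"


class ArchiveError(ValueError):
    """Bad magic/version, truncated payload or checksum mismatch."""


def _backend_compress(name: str, data: bytes) -> bytes:
    if name == "bz2":
        return bz2.compress(data, 9)
    if name == "lzma":
        return lzma.compress(data, preset=6)
    if name == "raw":
        return data
    raise ArchiveError(f"unknown backend {name!r}")


def _backend_decompress(name: str, data: bytes) -> bytes:
    try:
        if name == "bz2":
            return bz2.decompress(data)
        if name == "lzma":
            return lzma.decompress(data)
        if name == "raw":
            return data
    except (OSError, lzma.LZMAError, ValueError) as exc:
        raise ArchiveError(f"stream payload corrupt ({name}): {exc}") from exc
    raise ArchiveError(f"unknown backend {name!r}")


def pack_bits(bits: list[int]) -> bytes:
    """Pack bits 8 per byte, little-endian within each byte, zero padded."""
    out = bytearray((len(bits) + 7) // 8)
    for i, b in enumerate(bits):
        if b:
            out[i >> 3] |= 1 << (i & 7)
    return bytes(out)


def unpack_bits(data: bytes, count: int) -> list[int]:
    if len(data) < (count + 7) // 8:
        raise ArchiveError("bit stream shorter than its declared count")
    return [(data[i >> 3] >> (i & 7)) & 1 for i in range(count)]


def encode_varints(values: list[int]) -> bytes:
    """Unsigned LEB128."""
    out = bytearray()
    for v in values:
        if v < 0:
            raise ValueError("varint values must be non-negative")
        while True:
            byte = v & 0x7F
            v >>= 7
            if v:
                out.append(byte | 0x80)
            else:
                out.append(byte)
                break
    return bytes(out)


def decode_varints(data: bytes, count: int) -> list[int]:
    values: list[int] = []
    v = 0
    shift = 0
    for byte in data:
        v |= (byte & 0x7F) << shift
        if byte & 0x80:
            shift += 7
        else:
            values.append(v)
            v = 0
            shift = 0
            if len(values) == count:
                break
    if len(values) != count or shift:
        raise ArchiveError("varint stream truncated")
    return values


def _bundle_streams(bundle: StreamBundle) -> list[tuple[str, bytes, str]]:
    """(name, raw bytes, backend) for every non-empty stream."""
    streams: list[tuple[str, bytes, str]] = []

    def add(name: str, raw: bytes, backend: str = _TEXT_BACKEND) -> None:
        if raw:
            streams.append((name, raw, backend))

    add("s1", "\n".join(bundle.s1_lines).encode())
    add("s2", pack_bits(bundle.s2_dir_bits))
    add("s3", pack_bits(bundle.s3_rc_bits))
    add("s4", pack_bits(bundle.s4_dup_bits))
    add("s5", encode_varints([x for pair in bundle.s5_dup_counts for x in pair]))
    add("parent_ids", encode_varints(bundle.parent_ids))
    add("singleton", pack_bits(bundle.singleton_bits))
    add("pair_dist", encode_varints(bundle.pair_distances), _DISTANCE_BACKEND)
    add("pair_order", pack_bits(bundle.pair_order_bits))
    add("pair_origin", encode_varints(bundle.pair_original_order))
    return streams


def build_archive(bundle: StreamBundle, meta: dict) -> bytes:
    """Serialize a stream bundle plus metadata into archive bytes."""
    counts = {
        "s1": len(bundle.s1_lines),
        "s2": len(bundle.s2_dir_bits),
        "s3": len(bundle.s3_rc_bits),
        "s4": len(bundle.s4_dup_bits),
        "s5": len(bundle.s5_dup_counts),
        "parent_ids": len(bundle.parent_ids),
        "singleton": len(bundle.singleton_bits),
        "pair_dist": len(bundle.pair_distances),
        "pair_order": len(bundle.pair_order_bits),
        "pair_origin": len(bundle.pair_original_order),
    }
    table = []
    payloads = []
    for name, raw, backend in _bundle_streams(bundle):
        comp = _backend_compress(backend, raw)
        if len(comp) >= len(raw):
            backend, comp = "raw", raw
        table.append(
            {
                "name": name,
                "backend": backend,
                "raw_len": len(raw),
                "comp_len": len(comp),
                "crc32": zlib.crc32(comp),
            }
        )
        payloads.append(comp)
    header = dict(meta)
    header["counts"] = counts
    header["streams"] = table
    header_bytes = json.dumps(header, separators=(",", ":")).encode()
    out = bytearray()
    out += MAGIC
    out.append(VERSION)
    out += len(header_bytes).to_bytes(4, "big")
    out += header_bytes
    for p in payloads:
        out += p
    return bytes(out)


def parse_archive(data: bytes) -> tuple[dict, StreamBundle]:
    """Parse archive bytes back into metadata and a StreamBundle."""
    if len(data) < 9 or data[:4] != MAGIC:
        raise ArchiveError("not a readspan archive (bad magic)")
    if data[4] != VERSION:
        raise ArchiveError(f"unsupported archive version {data[4]}")
    hlen = int.from_bytes(data[5:9], "big")
    if len(data) < 9 + hlen:
        raise ArchiveError("archive truncated in header")
    try:
        header = json.loads(data[9 : 9 + hlen].decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ArchiveError(f"archive header corrupt: {exc}") from exc

    counts = header.get("counts", {})
    raw_streams: dict[str, bytes] = {}
    offset = 9 + hlen
    for entry in header.get("streams", []):
        comp = data[offset : offset + entry["comp_len"]]
        if len(comp) != entry["comp_len"]:
            raise ArchiveError(f"archive truncated in stream {entry['name']!r}")
        if zlib.crc32(comp) != entry["crc32"]:
            raise ArchiveError(f"checksum mismatch in stream {entry['name']!r}")
        raw = _backend_decompress(entry["backend"], comp)
        if len(raw) != entry["raw_len"]:
            raise ArchiveError(f"stream {entry['name']!r} has wrong raw length")
        raw_streams[entry["name"]] = raw
        offset += entry["comp_len"]

    def get(name: str) -> bytes:
        return raw_streams.get(name, b"")

    bundle = StreamBundle()
    n1_lines = counts.get("s1", 0)
    if n1_lines:
        text = get("s1").decode()
        bundle.s1_lines = text.split("\n")
        if len(bundle.s1_lines) != n1_lines:
            raise ArchiveError("stream 1 line count mismatch")
    bundle.s2_dir_bits = unpack_bits(get("s2"), counts.get("s2", 0))
    bundle.s3_rc_bits = unpack_bits(get("s3"), counts.get("s3", 0))
    bundle.s4_dup_bits = unpack_bits(get("s4"), counts.get("s4", 0))
    flat = decode_varints(get("s5"), 2 * counts.get("s5", 0))
    bundle.s5_dup_counts = [(flat[i], flat[i + 1]) for i in range(0, len(flat), 2)]
    bundle.parent_ids = decode_varints(get("parent_ids"), counts.get("parent_ids", 0))
    bundle.singleton_bits = unpack_bits(get("singleton"), counts.get("singleton", 0))
    bundle.pair_distances = decode_varints(get("pair_dist"), counts.get("pair_dist", 0))
    bundle.pair_order_bits = unpack_bits(get("pair_order"), counts.get("pair_order", 0))
    bundle.pair_original_order = decode_varints(
        get("pair_origin"), counts.get("pair_origin", 0)
    )
    return header, bundle
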