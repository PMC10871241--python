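"""Binary building blocks shared by the reader and writer.

Summary arithmetic, data-section encode/decode, and the compression wrapper.
All multi-byte encoding here is parameterized on a struct byte-order prefix
(``"<"`` or ``">"``); the writer always uses little-endian, the reader
detects the order from the file magic.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import BbiFormatError
from .types import SignalInterval, SummaryStats

# BigWig section-type bytes
WIG_BEDGRAPH = 1
WIG_VARIABLE_STEP = 2
WIG_FIXED_STEP = 3

_SECTION_TYPE_NAMES = {
    WIG_BEDGRAPH: "bedgraph",
    WIG_VARIABLE_STEP: "variable_step",
    WIG_FIXED_STEP: "fixed_step",
}
SECTION_TYPE_CODES = {v: k for k, v in _SECTION_TYPE_NAMES.items()}

WIG_SECTION_HEADER = "IIIIIBBH"  # chrom_id, start, end, item_step, item_span, type, reserved, count
ZOOM_RECORD_FMT = "IIIIffff"  # chrom_id, start, end, valid_count, min, max, sum, sumsq
ZOOM_RECORD_SIZE = 32


def f32(value: float) -> float:
    """Round to the nearest 32-bit float (the precision BBI sections store)."""
    return struct.unpack("<f", struct.pack("<f", value))[0]


def merge_summaries(a: SummaryStats, b: SummaryStats) -> SummaryStats:
    """Field-wise merge: counts and sums add, min/max take extrema.

    Associative and commutative; the neutral (empty) summary is the identity.
    """
    return a.merge(b)


def summarize_intervals(
    intervals: Iterable[SignalInterval], chrom: str, start: int, end: int
) -> SummaryStats:
    """Aggregate sorted non-overlapping intervals over the bin [start, end) of ``chrom``.

    valid_count counts covered bases inside the bin; sum and sum_squares
    weight each value by its overlap length.  No overlap yields the neutral
    summary.
    """
    acc = SummaryStats.neutral()
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        lo = max(iv.start, start)
        hi = min(iv.end, end)
        if lo < hi:
            acc = acc.merge(SummaryStats.from_value(iv.value, hi - lo))
    return acc


@dataclass(frozen=True)
class WigSection:
    """One BigWig data block before encoding / after decoding.

    ``items`` depends on ``section_type``:
      bedgraph      -> (start, end, value) triples
      variable_step -> (start, value) pairs, each spanning ``item_span``
      fixed_step    -> bare values at start, start+step, ... each spanning ``item_span``
    All items share one chromosome.
    """

    section_type: str
    chrom_id: int
    start: int
    end: int
    items: tuple = ()
    item_step: int = 0
    item_span: int = 0

    def intervals(self) -> list[tuple[int, int, float]]:
        """Expand to (start, end, value) triples regardless of encoding."""
        if self.section_type == "bedgraph":
            return list(self.items)
        if self.section_type == "variable_step":
            return [(s, s + self.item_span, v) for s, v in self.items]
        out = []
        pos = self.start
        for v in self.items:
            out.append((pos, pos + self.item_span, v))
            pos += self.item_step
        return out


@dataclass(frozen=True)
class BedSection:
    """One BigBed data block: (start, end, rest) records sharing one chromosome."""

    chrom_id: int
    items: tuple = ()  # (start, end, rest-string)

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.items)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.items)


def encode_wig_section(section: WigSection, order: str = "<") -> bytes:
    code = SECTION_TYPE_CODES[section.section_type]
    head = struct.pack(
        order + WIG_SECTION_HEADER,
        section.chrom_id,
        section.start,
        section.end,
        section.item_step,
        section.item_span,
        code,
        0,
        len(section.items),
    )
    if section.section_type == "bedgraph":
        body = b"".join(struct.pack(order + "IIf", s, e, v) for s, e, v in section.items)
    elif section.section_type == "variable_step":
        body = b"".join(struct.pack(order + "If", s, v) for s, v in section.items)
    else:
        body = b"".join(struct.pack(order + "f", v) for v in section.items)
    return head + body


def decode_wig_section(raw: bytes, order: str = "<") -> WigSection:
    if len(raw) < 24:
        raise BbiFormatError(f"BigWig section truncated: {len(raw)} bytes")
    chrom_id, start, end, step, span, code, _res, count = struct.unpack_from(
        order + WIG_SECTION_HEADER, raw
    )
    name = _SECTION_TYPE_NAMES.get(code)
    if name is None:
        raise BbiFormatError(f"unknown BigWig section type {code}")
    item_size = {WIG_BEDGRAPH: 12, WIG_VARIABLE_STEP: 8, WIG_FIXED_STEP: 4}[code]
    if len(raw) < 24 + count * item_size:
        raise BbiFormatError(
            f"BigWig section truncated: {count} items need {count * item_size} bytes"
        )
    if code == WIG_BEDGRAPH:
        items = tuple(struct.iter_unpack(order + "IIf", raw[24 : 24 + count * 12]))
    elif code == WIG_VARIABLE_STEP:
        items = tuple(struct.iter_unpack(order + "If", raw[24 : 24 + count * 8]))
    else:
        items = tuple(v for (v,) in struct.iter_unpack(order + "f", raw[24 : 24 + count * 4]))
    return WigSection(name, chrom_id, start, end, items, step, span)


def encode_bed_section(section: BedSection, order: str = "<") -> bytes:
    parts = []
    for s, e, rest in section.items:
        parts.append(struct.pack(order + "III", section.chrom_id, s, e))
        parts.append(rest.encode() + b"\0")
    return b"".join(parts)


def decode_bed_section(raw: bytes, order: str = "<") -> list[tuple[int, int, int, str]]:
    """Decode a BigBed block into (chrom_id, start, end, rest) tuples."""
    out = []
    pos = 0
    n = len(raw)
    while pos < n:
        if pos + 12 > n:
            raise BbiFormatError("BigBed block truncated inside a record header")
        chrom_id, start, end = struct.unpack_from(order + "III", raw, pos)
        pos += 12
        nul = raw.find(b"\0", pos)
        if nul < 0:
            raise BbiFormatError("BigBed block record missing NUL terminator")
        out.append((chrom_id, start, end, raw[pos:nul].decode()))
        pos = nul + 1
    return out


def encode_zoom_records(
    records: Sequence[tuple[int, int, int, SummaryStats]], order: str = "<"
) -> bytes:
    """Pack (chrom_id, start, end, stats) zoom records; stats floats are 32-bit."""
    parts = []
    for chrom_id, start, end, st in records:
        mn = st.min_val if st.valid_count else 0.0
        mx = st.max_val if st.valid_count else 0.0
        parts.append(
            struct.pack(
                order + ZOOM_RECORD_FMT,
                chrom_id, start, end, st.valid_count, mn, mx, st.sum, st.sum_squares,
            )
        )
    return b"".join(parts)


def decode_zoom_records(raw: bytes, order: str = "<") -> list[tuple[int, int, int, SummaryStats]]:
    if len(raw) % ZOOM_RECORD_SIZE:
        raise BbiFormatError(
            f"zoom block size {len(raw)} is not a multiple of {ZOOM_RECORD_SIZE}"
        )
    out = []
    for chrom_id, start, end, n, mn, mx, sm, ss in struct.iter_unpack(
        order + ZOOM_RECORD_FMT, raw
    ):
        stats = (
            SummaryStats(n, mn, mx, sm, ss) if n else SummaryStats.neutral()
        )
        out.append((chrom_id, start, end, stats))
    return out


def compress_block(raw: bytes, compress: bool) -> bytes:
    return zlib.compress(raw) if compress else raw


def decompress_block(data: bytes, uncompress_buf_size: int) -> bytes:
    """Inflate a data block, enforcing the file's declared maximum inflated size.

    ``uncompress_buf_size == 0`` marks an uncompressed file; the block is
    returned as-is.
    """
    if uncompress_buf_size == 0:
        return data
    d = zlib.decompressobj()
    try:
        out = d.decompress(data, uncompress_buf_size)
    except zlib.error as exc:
        raise BbiFormatError(f"corrupt compressed block: {exc}") from None
    if d.unconsumed_tail:
        raise BbiFormatError(
            f"inflated block exceeds declared buffer size {uncompress_buf_size}"
        )
    return out


@dataclass
class SectionAccumulator:
    """Collects items for the section under construction during a write."""

    chrom_id: int = -1
    items: list = field(default_factory=list)

    def flush(self) -> WigSection | None:
        if not self.items:
            return None
        sec = WigSection(
            "bedgraph",
            self.chrom_id,
            self.items[0][0],
            self.items[-1][1],
            tuple(self.items),
        )
        self.items.clear()
        return sec
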