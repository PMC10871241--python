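"""Single-pass creation of BigWig and BigBed files.

The input record stream is consumed exactly once (it may be a pipe); the
sink must be seekable because header fields are back-patched at the end.

Write pipeline:

1. **Stream stage.**  Records are validated (chromosome order per
   chrom.sizes, sortedness, overlap rules, bounds), grouped into data
   sections of ``items_per_slot`` items, encoded (optionally in parallel),
   and appended to a staging area together with R-tree bookkeeping.  At the
   same time a compact binary stream of per-base-summarizable records is
   staged for zoom building, and the total summary is accumulated.  Staging
   areas live in anonymous temporary files by default so that peak memory
   stays bounded regardless of input size; ``use_temp_files=False`` keeps
   them in RAM instead.  Both modes produce byte-identical files.
2. **Zoom stage.**  Reduction levels are planned from the observed record
   count and mean record length (unless given explicitly); each level is
   built by one sequential scan of the staged zoom stream.
3. **Assembly.**  Header, zoom headers, total summary, optional autoSql,
   chromosome B+ tree, data sections, R-trees, and the trailing magic are
   laid out into the sink, and the header is back-patched.

For BigBed files the zoom statistics summarize per-base coverage depth
(how many records cover each base), which makes a zoomed-out BigBed
renderable as a density track.
"""

from __future__ import annotations

import heapq
import struct
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from io import BytesIO
from typing import IO, Iterable, Iterator

from . import core
from .autosql import AutoSqlSchema, emit_autosql
from .btree import serialize_chrom_btree
from .errors import ValidationError
from .rtree import RTreeLeaf, serialize_rtree
from .types import (
    BBI_VERSION,
    BIGBED_MAGIC,
    BIGWIG_MAGIC,
    BbiFileMetadata,
    BedRecord,
    ChromInfo,
    ChromSizes,
    SignalInterval,
    SummaryStats,
    ZoomLevelInfo,
)

_MAIN_HEADER_FMT = "<IHHQQQHHQQIQ"
_ZOOM_STAGE_FMT = "<IIIf"  # chrom_id, start, end, value
_ZOOM_STAGE_SIZE = 16


@dataclass(frozen=True)
class WriteOptions:
    """Knobs of the write path.

    items_per_slot: records per data section (and zoom records per zoom block).
    block_size: R-tree / B+ tree branching factor.
    compress: DEFLATE each block (sets uncompress_buf_size in the header).
    zoom_levels: "auto" for the planned ladder, or an explicit increasing list.
    use_temp_files: stage sections and zoom input on disk instead of in RAM.
    max_zoom_levels: ladder length cap.
    threads: worker threads for section compression; output is identical
        for any thread count.
    clip: silently trim records that run past the chromosome end instead of
        rejecting them.
    """

    items_per_slot: int = 1024
    block_size: int = 256
    compress: bool = True
    zoom_levels: str | list[int] = "auto"
    use_temp_files: bool = True
    max_zoom_levels: int = 10
    threads: int = 1
    clip: bool = False

    def __post_init__(self):
        if self.items_per_slot < 1:
            raise ValidationError("items_per_slot must be at least 1")
        if self.block_size < 2:
            raise ValidationError("block_size must be at least 2")
        if self.threads < 1:
            raise ValidationError("threads must be at least 1")
        if not isinstance(self.zoom_levels, str):
            levels = list(self.zoom_levels)
            if any(b <= a for a, b in zip(levels, levels[1:])) or any(
                l < 1 for l in levels
            ):
                raise ValidationError("explicit zoom levels must be strictly increasing")
        elif self.zoom_levels != "auto":
            raise ValidationError('zoom_levels must be "auto" or a list of levels')


def plan_zoom_levels(
    record_count: int,
    mean_record_length: float,
    chroms: ChromSizes,
    opts: WriteOptions = WriteOptions(),
) -> list[int]:
    """Reduction-level ladder for the auto rule.

    First level: 10x the mean record length, but at least 10 bp.  Each
    subsequent level is 4x the previous.  Levels at or beyond the longest
    chromosome are dropped, and the ladder is capped at
    ``opts.max_zoom_levels`` entries.
    """
    if record_count < 1:
        return []
    if not isinstance(opts.zoom_levels, str):
        return list(opts.zoom_levels)
    longest = max((length for _, length in chroms.items()), default=0)
    level = max(int(-(-10 * mean_record_length // 1)), 10)
    levels: list[int] = []
    while level < longest and len(levels) < opts.max_zoom_levels:
        levels.append(level)
        level *= 4
    return levels


class _Staging:
    """Append-only byte area, on disk or in RAM, replayable once complete."""

    def __init__(self, use_temp_files: bool):
        self._buf: IO[bytes] = (
            tempfile.TemporaryFile() if use_temp_files else BytesIO()
        )
        self.size = 0

    def append(self, data: bytes) -> int:
        """Write and return the offset the data landed at."""
        off = self.size
        self._buf.write(data)
        self.size += len(data)
        return off

    def replay(self, chunk_size: int = 1 << 20) -> Iterator[bytes]:
        self._buf.seek(0)
        while True:
            chunk = self._buf.read(chunk_size)
            if not chunk:
                return
            yield chunk

    def close(self) -> None:
        self._buf.close()


def parallel_section_encode(
    payloads: Iterable[bytes], threads: int, compress: bool
) -> Iterator[tuple[bytes, int]]:
    """Compress section payloads, yielding (encoded bytes, raw size) in input order.

    With ``threads > 1`` a bounded window of compression jobs runs on a
    thread pool (zlib releases the GIL); ordering and bytes are identical to
    the serial path.
    """
    if threads == 1 or not compress:
        for raw in payloads:
            yield core.compress_block(raw, compress), len(raw)
        return
    with ThreadPoolExecutor(max_workers=threads) as pool:
        window: list = []
        sizes: list[int] = []
        for raw in payloads:
            window.append(pool.submit(core.compress_block, raw, True))
            sizes.append(len(raw))
            if len(window) > threads * 4:
                yield window.pop(0).result(), sizes.pop(0)
        while window:
            yield window.pop(0).result(), sizes.pop(0)


@dataclass
class _StreamState:
    """Validation and bookkeeping shared by both writers during stage 1."""

    chroms: ChromSizes
    clip: bool
    what: str = "interval"
    chrom: str | None = None
    chrom_id: int = -1
    chrom_len: int = 0
    last_start: int = -1
    last_end: int = 0
    record_count: int = 0
    total_length: int = 0

    def advance(self, chrom: str, start: int, end: int, overlap_ok: bool) -> tuple[int, int]:
        """Validate one record, returning (chrom_id, possibly clipped end)."""
        if chrom != self.chrom:
            if chrom not in self.chroms:
                raise ValidationError(f"unknown chromosome {chrom!r} (not in chrom sizes)")
            new_id = self.chroms.index(chrom)
            if new_id <= self.chrom_id:
                raise ValidationError(
                    f"{self.what}s out of order: chromosome {chrom!r} appears after "
                    f"{self.chrom!r} but precedes it in the chromosome order"
                )
            self.chrom, self.chrom_id = chrom, new_id
            self.chrom_len = self.chroms[chrom]
            self.last_start, self.last_end = -1, 0
        if start < self.last_start or (not overlap_ok and start < self.last_end):
            prev = f"{self.chrom}:{self.last_start}-{self.last_end}"
            kind = "overlaps" if start >= self.last_start else "is out of order with"
            raise ValidationError(
                f"{self.what} {chrom}:{start}-{end} {kind} previous {self.what} {prev}"
            )
        if end > self.chrom_len:
            if not self.clip:
                raise ValidationError(
                    f"{self.what} {chrom}:{start}-{end} extends past chromosome "
                    f"end {self.chrom_len}"
                )
            end = self.chrom_len
            if start >= end:
                return self.chrom_id, -1  # fully out of range, drop
        self.last_start, self.last_end = start, max(self.last_end, end)
        self.record_count += 1
        self.total_length += end - start
        return self.chrom_id, end


class _ZoomBuilder:
    """Builds one reduction level's blocks from the staged zoom stream."""

    def __init__(self, level: int, opts: WriteOptions, use_temp: bool):
        self.level = level
        self.opts = opts
        self.staging = _Staging(use_temp)
        self.leaves: list[RTreeLeaf] = []
        self.record_count = 0
        self.max_raw = 0
        self._pending: list[tuple[int, int, int, SummaryStats]] = []
        self._bin: tuple[int, int] | None = None  # (chrom_id, bin start)
        self._bin_end = 0  # clipped at the chromosome end
        self._stats = SummaryStats.neutral()

    def add(self, chrom_id: int, start: int, end: int, value: float, chrom_len: int) -> None:
        pos = start
        while pos < end:
            bin_start = pos - pos % self.level
            key = (chrom_id, bin_start)
            if key != self._bin:
                self._flush_bin()
                self._bin = key
                self._bin_end = min(bin_start + self.level, chrom_len)
            span = min(end, self._bin_end) - pos
            self._stats = self._stats.merge(SummaryStats.from_value(value, span))
            pos += span

    def _flush_bin(self) -> None:
        if self._bin is None or self._stats.valid_count == 0:
            self._stats = SummaryStats.neutral()
            return
        cid, bin_start = self._bin
        self._pending.append((cid, bin_start, self._bin_end, self._stats))
        self._stats = SummaryStats.neutral()
        self._flush_blocks(force=False)

    def _flush_blocks(self, force: bool) -> None:
        # blocks never mix chromosomes; an incomplete single-chromosome tail
        # keeps accumulating unless forced
        slot = self.opts.items_per_slot
        while self._pending:
            cid = self._pending[0][0]
            n = 0
            while n < len(self._pending) and n < slot and self._pending[n][0] == cid:
                n += 1
            if not force and n == len(self._pending) and n < slot:
                break
            batch, self._pending = self._pending[:n], self._pending[n:]
            raw = core.encode_zoom_records(batch)
            self.max_raw = max(self.max_raw, len(raw))
            data = core.compress_block(raw, self.opts.compress)
            off = self.staging.append(data)
            self.leaves.append(
                RTreeLeaf(cid, batch[0][1], cid, batch[-1][2], off, len(data))
            )
            self.record_count += len(batch)

    def finish(self) -> None:
        self._flush_bin()
        self._flush_blocks(force=True)


class _BbiAssembler:
    """Stage-and-assemble machinery shared by the BigWig and BigBed writers."""

    def __init__(self, chroms: ChromSizes, sink: IO[bytes], opts: WriteOptions):
        if len(chroms) == 0:
            raise ValidationError("chrom sizes are empty; nothing to write")
        self.chroms = chroms
        self.sink = sink
        self.opts = opts
        self.chrom_table = [
            ChromInfo(name, i, length) for i, (name, length) in enumerate(chroms.items())
        ]
        self.sections = _Staging(opts.use_temp_files)
        self.zoom_source = _Staging(opts.use_temp_files)
        self.leaves: list[RTreeLeaf] = []
        self.total = SummaryStats.neutral()
        self.max_raw_section = 0
        self.zoom_record_count = 0
        self.zoom_total_length = 0

    # -- stage 1 helpers ---------------------------------------------------

    def stage_sections(self, payloads: Iterable[tuple[tuple[int, int, int, int], bytes]]) -> None:
        """Encode and stage (bounds, payload) sections, keeping input order."""

        bounds_q: list[tuple[int, int, int, int]] = []

        def payload_iter():
            for bounds, raw in payloads:
                bounds_q.append(bounds)
                yield raw

        for data, raw_size in parallel_section_encode(
            payload_iter(), self.opts.threads, self.opts.compress
        ):
            cid, s, e_cid, e = bounds_q.pop(0)
            self.max_raw_section = max(self.max_raw_section, raw_size)
            off = self.sections.append(data)
            self.leaves.append(RTreeLeaf(cid, s, e_cid, e, off, len(data)))

    def stage_zoom_record(self, chrom_id: int, start: int, end: int, value: float) -> None:
        self.zoom_source.append(struct.pack(_ZOOM_STAGE_FMT, chrom_id, start, end, value))
        self.zoom_record_count += 1
        self.zoom_total_length += end - start

    def build_zoom_levels(self) -> list[_ZoomBuilder]:
        mean_len = (
            self.zoom_total_length / self.zoom_record_count if self.zoom_record_count else 0
        )
        levels = plan_zoom_levels(self.zoom_record_count, mean_len, self.chroms, self.opts)
        builders = []
        lengths = {c.id: c.length for c in self.chrom_table}
        for level in levels:
            zb = _ZoomBuilder(level, self.opts, self.opts.use_temp_files)
            carry = b""
            for chunk in self.zoom_source.replay():
                chunk = carry + chunk
                usable = len(chunk) - len(chunk) % _ZOOM_STAGE_SIZE
                carry = chunk[usable:]
                for cid, s, e, v in struct.iter_unpack(_ZOOM_STAGE_FMT, chunk[:usable]):
                    zb.add(cid, s, e, v, lengths[cid])
            zb.finish()
            builders.append(zb)
        return builders

    # -- assembly ----------------------------------------------------------

    def assemble(
        self,
        magic: int,
        data_count: int,
        field_count: int = 0,
        defined_field_count: int = 0,
        autosql_text: str | None = None,
    ) -> BbiFileMetadata:
        opts = self.opts
        zooms = self.build_zoom_levels()
        sink = self.sink
        base = 0
        sink.seek(base)

        n_zoom = len(zooms)
        header_end = 64 + 24 * n_zoom
        sink.write(b"\0" * header_end)  # placeholder, back-patched below

        # autoSql precedes the total summary: third-party readers recover the
        # schema length as totalSummaryOffset - autoSqlOffset
        autosql_off = 0
        if autosql_text is not None:
            autosql_off = sink.tell()
            sink.write(autosql_text.encode() + b"\0")

        total_summary_off = sink.tell()
        st = self.total
        sink.write(
            struct.pack(
                "<Qdddd",
                st.valid_count,
                st.min_val if st.valid_count else 0.0,
                st.max_val if st.valid_count else 0.0,
                st.sum,
                st.sum_squares,
            )
        )

        chrom_tree_off = sink.tell()
        sink.write(serialize_chrom_btree(self.chrom_table, chrom_tree_off, opts.block_size))

        full_data_off = sink.tell()
        sink.write(struct.pack("<Q", data_count))
        section_base = sink.tell()
        for chunk in self.sections.replay():
            sink.write(chunk)
        self.sections.close()

        full_index_off = sink.tell()
        shifted = [
            RTreeLeaf(l.start_chrom, l.start_base, l.end_chrom, l.end_base,
                      l.data_offset + section_base, l.data_size)
            for l in self.leaves
        ]
        sink.write(
            serialize_rtree(
                shifted, full_index_off, opts.block_size, opts.items_per_slot,
                end_file_offset=full_index_off,
            )
        )

        zoom_infos: list[ZoomLevelInfo] = []
        max_raw = self.max_raw_section
        for zb in zooms:
            data_off = sink.tell()
            sink.write(struct.pack("<I", zb.record_count))
            zbase = sink.tell()
            for chunk in zb.staging.replay():
                sink.write(chunk)
            zb.staging.close()
            index_off = sink.tell()
            zleaves = [
                RTreeLeaf(l.start_chrom, l.start_base, l.end_chrom, l.end_base,
                          l.data_offset + zbase, l.data_size)
                for l in zb.leaves
            ]
            sink.write(
                serialize_rtree(
                    zleaves, index_off, opts.block_size, opts.items_per_slot,
                    end_file_offset=index_off,
                )
            )
            zoom_infos.append(ZoomLevelInfo(zb.level, data_off, index_off))
            max_raw = max(max_raw, zb.max_raw)
        self.zoom_source.close()

        sink.write(struct.pack("<I", magic))

        uncompress_buf_size = max_raw if opts.compress else 0
        sink.seek(base)
        sink.write(
            struct.pack(
                _MAIN_HEADER_FMT,
                magic,
                BBI_VERSION,
                n_zoom,
                chrom_tree_off,
                full_data_off,
                full_index_off,
                field_count,
                defined_field_count,
                autosql_off,
                total_summary_off,
                uncompress_buf_size,
                0,
            )
        )
        for zi in zoom_infos:
            sink.write(
                struct.pack("<IIQQ", zi.reduction_level, 0, zi.data_offset, zi.index_offset)
            )
        sink.flush()

        return BbiFileMetadata(
            kind="bigwig" if magic == BIGWIG_MAGIC else "bigbed",
            version=BBI_VERSION,
            zoom_levels=zoom_infos,
            chrom_table=self.chrom_table,
            total_summary=self.total,
            uncompress_buf_size=uncompress_buf_size,
            field_count=field_count,
            defined_field_count=defined_field_count,
            autosql_text=autosql_text,
        )


def write_bigwig(
    intervals: Iterable[SignalInterval],
    chroms: ChromSizes,
    sink: IO[bytes],
    opts: WriteOptions = WriteOptions(),
) -> BbiFileMetadata:
    """Create a complete BigWig from a sorted, non-overlapping interval stream.

    The stream is consumed exactly once and may come from a pipe; the sink
    must be seekable.  Chromosome order must follow ``chroms``.  Returns the
    metadata of the file just written.
    """
    asm = _BbiAssembler(chroms, sink, opts)
    state = _StreamState(chroms, opts.clip, "interval")
    section_count = 0

    def sections() -> Iterator[tuple[tuple[int, int, int, int], bytes]]:
        nonlocal section_count
        acc: list[tuple[int, int, float]] = []
        acc_cid = -1

        def flush():
            nonlocal section_count
            if not acc:
                return None
            sec = core.WigSection("bedgraph", acc_cid, acc[0][0], acc[-1][1], tuple(acc))
            bounds = (acc_cid, sec.start, acc_cid, sec.end)
            acc.clear()
            section_count += 1
            return bounds, core.encode_wig_section(sec)

        for iv in intervals:
            cid, end = state.advance(iv.chrom, iv.start, iv.end, overlap_ok=False)
            if end < 0:
                continue  # clipped away entirely
            if acc and (cid != acc_cid or len(acc) >= opts.items_per_slot):
                yield flush()
            acc_cid = cid
            # summarize the value as stored (float32), so the total summary
            # describes the file's own contents exactly
            value = core.f32(iv.value)
            acc.append((iv.start, end, value))
            asm.total = asm.total.merge(SummaryStats.from_value(value, end - iv.start))
            asm.stage_zoom_record(cid, iv.start, end, value)
        last = flush()
        if last:
            yield last

    asm.stage_sections(sections())
    if state.record_count == 0:
        raise ValidationError("no data: refusing to write an empty BigWig")
    return asm.assemble(BIGWIG_MAGIC, data_count=section_count)


def write_bigbed(
    records: Iterable[BedRecord],
    chroms: ChromSizes,
    sink: IO[bytes],
    opts: WriteOptions = WriteOptions(),
    autosql: AutoSqlSchema | None = None,
    defined_field_count: int | None = None,
) -> BbiFileMetadata:
    """Create a complete BigBed from a sorted record stream (overlaps allowed).

    The field count must be constant across records and, when a schema is
    given, match its field count; the schema text is then embedded in the
    file.  Zoom statistics summarize per-base coverage depth.
    """
    asm = _BbiAssembler(chroms, sink, opts)
    state = _StreamState(chroms, opts.clip, "record")
    field_count = 0

    # Coverage-depth sweep over the (start-sorted, possibly overlapping)
    # records of one chromosome: a heap of active record ends, advanced to
    # each new start, emits maximal constant-depth runs for the summaries.
    sweep_cid = -1
    sweep_pos = 0
    sweep_ends: list[int] = []

    def _record_depth(cid: int, start: int, end: int, depth: int) -> None:
        asm.total = asm.total.merge(SummaryStats.from_value(float(depth), end - start))
        asm.stage_zoom_record(cid, start, end, float(depth))

    def _emit_runs(upto: int) -> None:
        nonlocal sweep_pos
        while sweep_ends and sweep_ends[0] <= upto:
            boundary = sweep_ends[0]
            if boundary > sweep_pos:
                _record_depth(sweep_cid, sweep_pos, boundary, len(sweep_ends))
                sweep_pos = boundary
            while sweep_ends and sweep_ends[0] == boundary:
                heapq.heappop(sweep_ends)
        if upto > sweep_pos:
            if sweep_ends:
                _record_depth(sweep_cid, sweep_pos, upto, len(sweep_ends))
            sweep_pos = upto

    def depth_add(cid: int, start: int, end: int) -> None:
        nonlocal sweep_cid, sweep_pos
        if cid != sweep_cid:
            if sweep_ends:
                _emit_runs(max(sweep_ends))
            sweep_cid, sweep_pos = cid, start
            sweep_ends.clear()
        _emit_runs(start)
        heapq.heappush(sweep_ends, end)

    def depth_finish() -> None:
        if sweep_ends:
            _emit_runs(max(sweep_ends))

    def sections() -> Iterator[tuple[tuple[int, int, int, int], bytes]]:
        nonlocal field_count
        acc: list[tuple[int, int, str]] = []
        acc_cid = -1

        def flush():
            if not acc:
                return None
            sec = core.BedSection(acc_cid, tuple(acc))
            bounds = (acc_cid, sec.start, acc_cid, sec.end)
            payload = core.encode_bed_section(sec)
            acc.clear()
            return bounds, payload

        for rec in records:
            n = rec.field_count
            if field_count == 0:
                field_count = n
            elif n != field_count:
                raise ValidationError(
                    f"field count drift: record {rec.chrom}:{rec.start}-{rec.end} has "
                    f"{n} fields, previous records had {field_count}"
                )
            cid, end = state.advance(rec.chrom, rec.start, rec.end, overlap_ok=True)
            if end < 0:
                continue
            if acc and (cid != acc_cid or len(acc) >= opts.items_per_slot):
                yield flush()
            acc_cid = cid
            acc.append((rec.start, end, rec.rest))
            depth_add(cid, rec.start, end)
        last = flush()
        if last:
            yield last
        depth_finish()

    asm.stage_sections(sections())
    if state.record_count == 0:
        raise ValidationError("no data: refusing to write an empty BigBed")
    if autosql is not None and autosql.field_count != field_count:
        raise ValidationError(
            f"autoSql schema has {autosql.field_count} fields but records have {field_count}"
        )
    defined = defined_field_count if defined_field_count is not None else min(field_count, 12)
    if defined > field_count:
        raise ValidationError(
            f"defined field count {defined} exceeds field count {field_count}"
        )
    return asm.assemble(
        BIGBED_MAGIC,
        data_count=state.record_count,
        field_count=field_count,
        defined_field_count=defined,
        autosql_text=emit_autosql(autosql) if autosql is not None else None,
    )
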