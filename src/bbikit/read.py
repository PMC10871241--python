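"""Reading BigWig and BigBed files from any seekable byte source.

``open_bbi`` accepts a filesystem path or any object with ``read``/``seek``
(local file handles and in-memory buffers alike; a remote transport exposing
the same contract would work unchanged).  The file kind and byte order are
detected from the magic number; both little- and big-endian files are read.

Queries go through the file's R-tree indexes, so only the data blocks whose
bounds overlap the request are read and decompressed.  The reader keeps two
instrumentation counters, ``sections_decoded`` and ``max_section_items``,
used by the efficiency and memory-contract tests.
"""

from __future__ import annotations

import math
import struct
from pathlib import Path
from typing import IO, Iterator

import numpy as np

from . import core, rtree
from .btree import read_chrom_btree
from .errors import (
    BbiFormatError,
    ChromNotFoundError,
    ValidationError,
    WrongFileKindError,
)
from .types import (
    BIGBED_MAGIC,
    BIGWIG_MAGIC,
    BbiFileMetadata,
    BedRecord,
    SignalInterval,
    SummaryStats,
    ZoomLevelInfo,
    ZoomRecord,
)

_MAIN_HEADER_FMT = "IHHQQQHHQQIQ"
_ZOOM_HEADER_FMT = "IIQQ"
_TOTAL_SUMMARY_FMT = "Qdddd"

STATISTICS = ("mean", "min", "max", "coverage", "sum")


def open_bbi(source: str | Path | IO[bytes]) -> "BbiFile":
    """Open a BBI file, returning a :class:`BigWigFile` or :class:`BigBedFile`."""
    if isinstance(source, (str, Path)):
        handle: IO[bytes] = open(source, "rb")
        owns = True
    else:
        handle = source
        owns = False
    try:
        handle.seek(0)
        magic_raw = handle.read(4)
        if len(magic_raw) < 4:
            raise BbiFormatError("not a BBI file: shorter than a magic number")
        for order in ("<", ">"):
            magic = struct.unpack(order + "I", magic_raw)[0]
            if magic == BIGWIG_MAGIC:
                return BigWigFile(handle, order, owns)
            if magic == BIGBED_MAGIC:
                return BigBedFile(handle, order, owns)
        raise BbiFormatError(f"not a BBI file: unknown magic {magic_raw.hex()}")
    except Exception:
        if owns:
            handle.close()
        raise


class BbiFile:
    """Common header parsing and block access for both file kinds."""

    kind = "bbi"

    def __init__(self, source: IO[bytes], order: str, owns_source: bool):
        self._source = source
        self._order = order
        self._owns = owns_source
        self.sections_decoded = 0
        self.max_section_items = 0
        self._parse_header()

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        if self._owns:
            self._source.close()

    def __enter__(self) -> "BbiFile":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- header ------------------------------------------------------------

    def _read_at(self, offset: int, size: int, what: str) -> bytes:
        self._source.seek(offset)
        data = self._source.read(size)
        if len(data) < size:
            raise BbiFormatError(f"truncated file: {what} at offset {offset}")
        return data

    def _parse_header(self) -> None:
        o = self._order
        head = self._read_at(0, 64, "main header")
        (
            _magic,
            version,
            n_zoom,
            chrom_tree_off,
            self._full_data_off,
            self._full_index_off,
            field_count,
            defined_field_count,
            autosql_off,
            total_summary_off,
            uncompress_buf_size,
            _reserved,
        ) = struct.unpack(o + _MAIN_HEADER_FMT, head)

        zoom_levels = []
        zoom_raw = self._read_at(64, 24 * n_zoom, "zoom headers")
        for i in range(n_zoom):
            red, _res, d_off, i_off = struct.unpack_from(o + _ZOOM_HEADER_FMT, zoom_raw, i * 24)
            zoom_levels.append(ZoomLevelInfo(red, d_off, i_off))

        # every declared structure must lie inside the file: catches truncation
        # up front instead of on first touch
        self._source.seek(0, 2)
        file_size = self._source.tell()
        declared = {
            "chromosome index": chrom_tree_off,
            "data section": self._full_data_off,
            "data index": self._full_index_off,
            "autoSql": autosql_off,
            "total summary": total_summary_off,
        }
        for z in zoom_levels:
            declared[f"zoom level {z.reduction_level} data"] = z.data_offset
            declared[f"zoom level {z.reduction_level} index"] = z.index_offset
        for what, off in declared.items():
            if off and off >= file_size:
                raise BbiFormatError(
                    f"truncated file: {what} declared at offset {off} but the "
                    f"file holds {file_size} bytes"
                )
        if any(
            b.reduction_level <= a.reduction_level
            for a, b in zip(zoom_levels, zoom_levels[1:])
        ):
            raise BbiFormatError("zoom levels are not strictly increasing")

        total = SummaryStats.neutral()
        if total_summary_off:
            n, mn, mx, sm, ss = struct.unpack(
                o + _TOTAL_SUMMARY_FMT, self._read_at(total_summary_off, 40, "total summary")
            )
            if n:
                total = SummaryStats(n, mn, mx, sm, ss)

        autosql_text = None
        if autosql_off:
            autosql_text = self._read_nul_string(autosql_off)

        self._btree = read_chrom_btree(self._source, chrom_tree_off, o)
        self.metadata = BbiFileMetadata(
            kind=self.kind,
            version=version,
            zoom_levels=zoom_levels,
            chrom_table=self._btree.table_by_id(),
            total_summary=total,
            uncompress_buf_size=uncompress_buf_size,
            field_count=field_count,
            defined_field_count=defined_field_count,
            autosql_text=autosql_text,
        )
        self._chrom_names = {c.id: c.name for c in self.metadata.chrom_table}

    def _read_nul_string(self, offset: int) -> str:
        self._source.seek(offset)
        chunks = []
        while True:
            chunk = self._source.read(4096)
            if not chunk:
                raise BbiFormatError("unterminated embedded string")
            nul = chunk.find(b"\0")
            if nul >= 0:
                chunks.append(chunk[:nul])
                break
            chunks.append(chunk)
        return b"".join(chunks).decode()

    # -- shared query plumbing ---------------------------------------------

    def chroms(self) -> dict[str, int]:
        """Chromosome name -> length, in chromosome-id order."""
        return {c.name: c.length for c in self.metadata.chrom_table}

    def _resolve(self, chrom: str, start: int | None, end: int | None) -> tuple[int, int, int]:
        found = self._btree.lookup(chrom)
        if found is None:
            raise ChromNotFoundError(chrom)
        cid, length = found
        start = 0 if start is None else start
        end = length if end is None else end
        if start < 0 or start >= end:
            raise ValidationError(f"invalid query range {chrom}:{start}-{end}")
        return cid, start, end

    def _blocks(self, index_off: int, cid: int, start: int, end: int) -> Iterator[bytes]:
        for off, size in rtree.query_rtree(self._source, index_off, cid, start, end, self._order):
            raw = self._read_at(off, size, "data block")
            self.sections_decoded += 1
            yield core.decompress_block(raw, self.metadata.uncompress_buf_size)

    # -- zoom --------------------------------------------------------------

    def zoom_query(
        self, chrom: str, start: int | None = None, end: int | None = None,
        reduction_level: int | None = None,
    ) -> list[ZoomRecord]:
        """Zoom records of one reduction level overlapping the query range."""
        available = [z.reduction_level for z in self.metadata.zoom_levels]
        matches = [z for z in self.metadata.zoom_levels if z.reduction_level == reduction_level]
        if not matches:
            raise ValidationError(
                f"no zoom level with reduction {reduction_level}; available: {available}"
            )
        level = matches[0]
        cid, start, end = self._resolve(chrom, start, end)
        out = []
        for raw in self._blocks(level.index_offset, cid, start, end):
            for rec_cid, s, e, stats in core.decode_zoom_records(raw, self._order):
                if rec_cid == cid and s < end and e > start:
                    out.append(ZoomRecord(rec_cid, s, e, stats))
        return out


class BigWigFile(BbiFile):
    kind = "bigwig"

    # -- intervals ---------------------------------------------------------

    def intervals(
        self, chrom: str, start: int | None = None, end: int | None = None,
        clip: bool = False,
    ) -> Iterator[SignalInterval]:
        """Lazily yield the signal intervals overlapping [start, end).

        Records are returned whole by default; ``clip=True`` trims them to
        the query range instead.
        """
        cid, start, end = self._resolve(chrom, start, end)
        for raw in self._blocks(self._full_index_off, cid, start, end):
            section = core.decode_wig_section(raw, self._order)
            triples = section.intervals()
            self.max_section_items = max(self.max_section_items, len(triples))
            if section.chrom_id != cid:
                continue
            for s, e, v in triples:
                if s < end and e > start:
                    if clip:
                        s, e = max(s, start), min(e, end)
                    yield SignalInterval(chrom, s, e, v)

    def iter_all(self, clip: bool = False) -> Iterator[SignalInterval]:
        """All intervals of the file in (chromosome id, start) order."""
        for info in self.metadata.chrom_table:
            yield from self.intervals(info.name, 0, info.length, clip=clip)

    # -- dense values ------------------------------------------------------

    def values(
        self, chrom: str, start: int | None = None, end: int | None = None,
        bins: int | None = None,
    ) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are NaN.

        With ``bins``, the range is split into equal bins and each bin holds
        the mean of its covered bases (NaN when none).  Bases past the
        chromosome end count as missing.
        """
        cid, start, end = self._resolve(chrom, start, end)
        arr = np.full(end - start, np.nan, dtype=np.float64)
        for iv in self.intervals(chrom, start, end, clip=True):
            arr[iv.start - start : iv.end - start] = iv.value
        if bins is None:
            return arr
        if bins < 1:
            raise ValidationError("bins must be at least 1")
        edges = np.linspace(0, end - start, bins + 1)
        out = np.full(bins, np.nan, dtype=np.float64)
        for i in range(bins):
            lo, hi = int(edges[i]), int(edges[i + 1])
            chunk = arr[lo:hi]
            covered = ~np.isnan(chunk)
            if covered.any():
                out[i] = chunk[covered].mean()
        return out

    # -- statistics --------------------------------------------------------

    def stats(
        self, chrom: str, start: int | None = None, end: int | None = None,
        statistic: str = "mean", bins: int = 1, exact: bool = True,
    ) -> list[float]:
        """Per-bin summary statistic over [start, end).

        ``exact=True`` aggregates full-resolution intervals.  ``exact=False``
        may serve the request from the largest zoom level whose reduction is
        at most half the bin width (guaranteeing >= 2 zoom bins per output
        bin), falling back to exact data when no level qualifies.  Partially
        overlapping zoom bins contribute proportionally to their overlap.
        """
        if statistic not in STATISTICS:
            raise ValidationError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
        cid, start, end = self._resolve(chrom, start, end)
        if bins < 1:
            raise ValidationError("bins must be at least 1")
        edges = [start + round(i * (end - start) / bins) for i in range(bins + 1)]
        if any(a >= b for a, b in zip(edges, edges[1:])):
            raise ValidationError(f"zero-length bin: range {end - start} < {bins} bins")

        bin_width = (end - start) / bins
        level = None
        if not exact:
            usable = [
                z.reduction_level
                for z in self.metadata.zoom_levels
                if z.reduction_level <= bin_width / 2
            ]
            if usable:
                level = max(usable)

        if level is None:
            summaries = self._exact_bin_summaries(chrom, edges)
        else:
            summaries = self._zoom_bin_summaries(chrom, edges, level)

        out = []
        for (lo, hi), st in zip(zip(edges, edges[1:]), summaries):
            if statistic == "coverage":
                out.append(st.valid_count / (hi - lo))
            elif statistic == "sum":
                out.append(st.sum)
            elif st.valid_count == 0:
                out.append(math.nan)
            elif statistic == "mean":
                out.append(st.mean)
            elif statistic == "min":
                out.append(st.min_val)
            else:
                out.append(st.max_val)
        return out

    def _exact_bin_summaries(self, chrom: str, edges: list[int]) -> list[SummaryStats]:
        sums = [SummaryStats.neutral() for _ in range(len(edges) - 1)]
        i = 0
        for iv in self.intervals(chrom, edges[0], edges[-1], clip=True):
            while edges[i + 1] <= iv.start:
                i += 1
            j = i
            while j < len(sums) and edges[j] < iv.end:
                lo, hi = max(iv.start, edges[j]), min(iv.end, edges[j + 1])
                if lo < hi:
                    sums[j] = sums[j].merge(SummaryStats.from_value(iv.value, hi - lo))
                j += 1
        return sums

    def _zoom_bin_summaries(
        self, chrom: str, edges: list[int], level: int
    ) -> list[SummaryStats]:
        sums = [SummaryStats.neutral() for _ in range(len(edges) - 1)]
        for rec in self.zoom_query(chrom, edges[0], edges[-1], reduction_level=level):
            if rec.stats.valid_count == 0:
                continue
            rec_len = rec.end - rec.start
            for j in range(len(sums)):
                lo, hi = max(rec.start, edges[j]), min(rec.end, edges[j + 1])
                if lo >= hi:
                    continue
                frac = (hi - lo) / rec_len
                part = SummaryStats(
                    max(1, round(rec.stats.valid_count * frac)),
                    rec.stats.min_val,
                    rec.stats.max_val,
                    rec.stats.sum * frac,
                    rec.stats.sum_squares * frac,
                )
                sums[j] = sums[j].merge(part)
        return sums


class BigBedFile(BbiFile):
    kind = "bigbed"

    def records(
        self, chrom: str, start: int | None = None, end: int | None = None,
    ) -> Iterator[BedRecord]:
        """Lazily yield BED records overlapping [start, end), whole, sorted by start.

        Overlapping records are all returned; a record stored in one block
        appears exactly once.
        """
        cid, start, end = self._resolve(chrom, start, end)
        for raw in self._blocks(self._full_index_off, cid, start, end):
            decoded = core.decode_bed_section(raw, self._order)
            self.max_section_items = max(self.max_section_items, len(decoded))
            for rec_cid, s, e, rest in decoded:
                if rec_cid == cid and s < end and e > start:
                    yield BedRecord(chrom, s, e, rest)

    def iter_all(self) -> Iterator[BedRecord]:
        for info in self.metadata.chrom_table:
            yield from self.records(info.name, 0, info.length)

    def autosql(self):
        """Parsed embedded schema, or None when the file carries none."""
        from .autosql import parse_autosql

        if self.metadata.autosql_text is None:
            return None
        return parse_autosql(self.metadata.autosql_text)


def _require_bigwig(f: BbiFile) -> BigWigFile:
    if not isinstance(f, BigWigFile):
        raise WrongFileKindError(f"expected a BigWig file, got {f.kind}")
    return f


def _require_bigbed(f: BbiFile) -> BigBedFile:
    if not isinstance(f, BigBedFile):
        raise WrongFileKindError(f"expected a BigBed file, got {f.kind}")
    return f
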