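"""Library backing of the command-line tools.

Each function here is the pure, streaming core of one CLI command so it can
be tested (and instrumented) without a shell.  Memory contracts: the merge
and region-average paths hold a bounded number of records at a time,
independent of chromosome length — merge keeps one active value per input
plus one pending run, region averaging holds at most one decoded data
section.
"""

from __future__ import annotations

import heapq
import logging
from typing import IO, Iterable, Iterator

from .errors import ValidationError
from .read import BigBedFile, BigWigFile
from .text import format_value
from .types import BedRecord, SignalInterval

logger = logging.getLogger("bbikit")


# ---------------------------------------------------------------------------
# bigwigmerge


def merge_bigwigs(
    readers: list[BigWigFile],
    adjust: float = 0.0,
    threshold: float = 0.0,
    max_mode: bool = False,
    telemetry: dict | None = None,
) -> Iterator[SignalInterval]:
    """Combine BigWigs per base — sum, or max with ``max_mode`` — lazily.

    Yields maximal runs of constant combined value; covered runs whose value
    (after adding ``adjust``) is at or below ``threshold`` are omitted,
    matching the omit-zero default of the classic merge tool.  Chromosomes
    shared between inputs must agree in length.

    The merge is an ordered sweep over interval edges: memory holds one
    pending interval per input regardless of chromosome length.  When given,
    ``telemetry`` records the peak number of simultaneously active
    intervals under ``"peak_active"``.
    """
    if len(readers) < 2:
        raise ValidationError("merging needs at least two inputs")
    lengths: dict[str, int] = {}
    order: list[str] = []
    for r in readers:
        for name, length in r.chroms().items():
            if name in lengths:
                if lengths[name] != length:
                    raise ValidationError(
                        f"conflicting lengths for chromosome {name!r}: "
                        f"{lengths[name]} vs {length}"
                    )
            else:
                lengths[name] = length
                order.append(name)
    if telemetry is not None:
        telemetry.setdefault("peak_active", 0)

    for chrom in order:
        streams = [
            r.intervals(chrom) for r in readers if chrom in r.chroms()
        ]
        yield from _sweep_chrom(chrom, streams, adjust, threshold, max_mode, telemetry)


def _sweep_chrom(
    chrom: str,
    streams: list[Iterator[SignalInterval]],
    adjust: float,
    threshold: float,
    max_mode: bool,
    telemetry: dict | None,
) -> Iterator[SignalInterval]:
    # event stream per input: (pos, kind, value); ends (kind 0) sort before
    # starts (kind 1) at the same position
    def events(stream):
        for iv in stream:
            yield (iv.start, 1, iv.value)
            yield (iv.end, 0, iv.value)

    # each input's events are already position-sorted (intervals are sorted
    # and non-overlapping), so a k-way heap merge keeps global order
    merged = heapq.merge(*(events(s) for s in streams))

    active: list[float] = []  # multiset of currently overlapping values
    pos: int | None = None
    run: tuple[int, int, float] | None = None  # pending maximal constant run

    for epos, kind, value in merged:
        if pos is not None and epos > pos:
            if active:
                v = (max(active) if max_mode else sum(active)) + adjust
                if run is not None and run[2] == v and run[1] == pos:
                    run = (run[0], epos, v)  # extend
                else:
                    if run is not None and run[2] > threshold:
                        yield SignalInterval(chrom, run[0], run[1], run[2])
                    run = (pos, epos, v)
            elif run is not None:  # coverage gap closes the pending run
                if run[2] > threshold:
                    yield SignalInterval(chrom, run[0], run[1], run[2])
                run = None
        if kind == 1:
            active.append(value)
            if telemetry is not None:
                telemetry["peak_active"] = max(telemetry["peak_active"], len(active))
        else:
            active.remove(value)
        pos = epos
    if run is not None and run[2] > threshold:
        yield SignalInterval(chrom, run[0], run[1], run[2])


# ---------------------------------------------------------------------------
# bigwigaverageoverbed


def average_over_bed(
    reader: BigWigFile, regions: Iterable[BedRecord]
) -> Iterator[tuple[str, int, int, float, float, float]]:
    """Per-region coverage summary rows: (name, size, covered, sum, mean0, mean).

    ``mean0`` divides by the region size (uncovered bases count as zero),
    ``mean`` by covered bases only (0 when nothing is covered).  Region
    names (column 4, or ``chrom:start-end`` when absent) must be unique.
    Bases past a chromosome end, and whole regions on chromosomes absent
    from the BigWig, count as uncovered rather than failing.
    """
    chroms = reader.chroms()
    seen: set[str] = set()
    for rec in regions:
        name = rec.rest.split("\t", 1)[0] if rec.rest else f"{rec.chrom}:{rec.start}-{rec.end}"
        if name in seen:
            raise ValidationError(f"duplicate region name {name!r}")
        seen.add(name)
        size = rec.end - rec.start
        covered = 0
        total = 0.0
        if rec.chrom not in chroms:
            logger.warning("region %s: chromosome %s absent from BigWig", name, rec.chrom)
        else:
            end = min(rec.end, chroms[rec.chrom])
            if rec.start < end:
                for iv in reader.intervals(rec.chrom, rec.start, end, clip=True):
                    covered += iv.end - iv.start
                    total += iv.value * (iv.end - iv.start)
        mean0 = total / size if size else 0.0
        mean = total / covered if covered else 0.0
        yield name, size, covered, total, mean0, mean


# ---------------------------------------------------------------------------
# info


def bigwig_info(reader: BigWigFile) -> str:
    md = reader.metadata
    ts = md.total_summary
    lines = [
        f"version: {md.version}",
        f"isCompressed: {'yes' if md.compressed else 'no'}",
        f"zoomLevels: {len(md.zoom_levels)}",
        "reductionLevels: " + ",".join(str(z.reduction_level) for z in md.zoom_levels),
        f"chromCount: {len(md.chrom_table)}",
        f"basesCovered: {ts.valid_count}",
        f"mean: {_fmt(ts.mean if ts.valid_count else 0.0)}",
        f"min: {_fmt(ts.min_val if ts.valid_count else 0.0)}",
        f"max: {_fmt(ts.max_val if ts.valid_count else 0.0)}",
        f"std: {_fmt(ts.std if ts.valid_count else 0.0)}",
    ]
    return "\n".join(lines) + "\n"


def bigbed_info(reader: BigBedFile) -> str:
    md = reader.metadata
    ts = md.total_summary
    lines = [
        f"version: {md.version}",
        f"isCompressed: {'yes' if md.compressed else 'no'}",
        f"fieldCount: {md.field_count}",
        f"definedFieldCount: {md.defined_field_count}",
        f"hasAutoSql: {'yes' if md.autosql_text else 'no'}",
        f"zoomLevels: {len(md.zoom_levels)}",
        "reductionLevels: " + ",".join(str(z.reduction_level) for z in md.zoom_levels),
        f"chromCount: {len(md.chrom_table)}",
        f"basesCovered: {ts.valid_count}",
        f"meanDepth: {_fmt(ts.mean if ts.valid_count else 0.0)}",
        f"minDepth: {_fmt(ts.min_val if ts.valid_count else 0.0)}",
        f"maxDepth: {_fmt(ts.max_val if ts.valid_count else 0.0)}",
    ]
    return "\n".join(lines) + "\n"


def _fmt(x: float) -> str:
    return f"{x:.6f}".rstrip("0").rstrip(".") or "0"


# ---------------------------------------------------------------------------
# bigwigtobedgraph


def export_bedgraph(
    reader: BigWigFile,
    sink: IO[str],
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> int:
    """Dump (a region of) a BigWig as bedGraph text; returns the line count.

    Regional exports clip intervals to the requested range.
    """
    if chrom is None:
        if start is not None or end is not None:
            raise ValidationError("start/end restriction requires a chromosome")
        source = reader.iter_all()
    else:
        if chrom not in reader.chroms():
            return 0  # exporting a chromosome the file lacks is an empty, valid export
        source = reader.intervals(chrom, start, end, clip=True)
    n = 0
    for iv in source:
        sink.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{format_value(iv.value)}\n")
        n += 1
    return n
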