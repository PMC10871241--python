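"""Parsers and emitters for the text formats around BBI files.

bedGraph, Wiggle (fixedStep/variableStep), BED, and chrom.sizes.  All
parsers are lazy single-pass generators over a line iterable: peak resident
record count does not grow with file size.  Input lines may be delimited by
any run of tabs and/or spaces; emitters always write tabs.

``track``, ``browser``, and ``#`` comment lines are skipped (they are
display metadata, not data), as are blank lines.
"""

from __future__ import annotations

from typing import IO, Iterable, Iterator

import numpy as np

from .errors import ParseError, ValidationError
from .types import BedRecord, ChromSizes, SignalInterval

_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(lines: Iterable[str]) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(_SKIP_PREFIXES):
            continue
        yield lineno, line


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{what} is not an integer: {token!r}", line=lineno) from None


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{what} is not a number: {token!r}", line=lineno) from None


def parse_bedgraph(lines: Iterable[str]) -> Iterator[SignalInterval]:
    """Lazily parse bedGraph text: ``chrom start end value``, 0-based half-open."""
    for lineno, line in _data_lines(lines):
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(
                f"expected 4 fields (chrom start end value), got {len(fields)}",
                line=lineno,
            )
        chrom, s, e, v = fields
        start = _parse_int(s, "start", lineno)
        end = _parse_int(e, "end", lineno)
        value = _parse_float(v, "value", lineno)
        if start < 0:
            raise ParseError(f"negative start {start}", line=lineno)
        if start >= end:
            raise ValidationError(
                f"line {lineno}: empty or inverted interval {chrom}:{start}-{end}"
            )
        yield SignalInterval(chrom, start, end, value)


def parse_wiggle(lines: Iterable[str]) -> Iterator[SignalInterval]:
    """Lazily parse Wiggle text (fixedStep and variableStep dialects).

    Wiggle starts are 1-based inclusive; emitted intervals are 0-based
    half-open.  ``span`` defaults to 1.  Adjacent equal-valued steps are not
    coalesced.
    """
    mode: str | None = None
    chrom = ""
    pos = 0  # next 0-based start for fixedStep
    step = 0
    span = 1

    def attrs(fields: list[str], lineno: int) -> dict[str, str]:
        out = {}
        for f in fields:
            if "=" not in f:
                raise ParseError(f"malformed attribute {f!r}", line=lineno)
            k, v = f.split("=", 1)
            out[k] = v
        return out

    for lineno, line in _data_lines(lines):
        fields = line.split()
        head = fields[0]
        if head == "fixedStep":
            a = attrs(fields[1:], lineno)
            for req in ("chrom", "start", "step"):
                if req not in a:
                    raise ParseError(f"fixedStep missing {req}=", line=lineno)
            mode = "fixed"
            chrom = a["chrom"]
            start1 = _parse_int(a["start"], "start", lineno)
            if start1 < 1:
                raise ParseError(f"fixedStep start {start1} is not 1-based", line=lineno)
            pos = start1 - 1
            step = _parse_int(a["step"], "step", lineno)
            span = _parse_int(a["span"], "span", lineno) if "span" in a else 1
            if step <= 0 or span <= 0:
                raise ParseError("step and span must be positive", line=lineno)
            if span > step:
                raise ParseError(f"span {span} exceeds step {step}", line=lineno)
        elif head == "variableStep":
            a = attrs(fields[1:], lineno)
            if "chrom" not in a:
                raise ParseError("variableStep missing chrom=", line=lineno)
            mode = "variable"
            chrom = a["chrom"]
            span = _parse_int(a["span"], "span", lineno) if "span" in a else 1
            if span <= 0:
                raise ParseError("span must be positive", line=lineno)
        elif mode == "fixed":
            if len(fields) != 1:
                raise ParseError("fixedStep data line must hold one value", line=lineno)
            value = _parse_float(fields[0], "value", lineno)
            yield SignalInterval(chrom, pos, pos + span, value)
            pos += step
        elif mode == "variable":
            if len(fields) != 2:
                raise ParseError(
                    "variableStep data line must hold position and value", line=lineno
                )
            start1 = _parse_int(fields[0], "position", lineno)
            if start1 < 1:
                raise ParseError(f"position {start1} is not 1-based", line=lineno)
            value = _parse_float(fields[1], "value", lineno)
            yield SignalInterval(chrom, start1 - 1, start1 - 1 + span, value)
        else:
            raise ParseError(
                "data line before any fixedStep/variableStep declaration", line=lineno
            )


def parse_bed(
    lines: Iterable[str], field_count: int | None = None
) -> Iterator[BedRecord]:
    """Lazily parse BED text with a constant column count.

    The count is taken from the first record when ``field_count`` is None;
    any later drift is a :class:`ValidationError` naming both counts.
    """
    expected = field_count
    for lineno, line in _data_lines(lines):
        fields = line.split()
        n = len(fields)
        if n < 3:
            raise ParseError(f"BED line has {n} fields, need at least 3", line=lineno)
        if expected is None:
            expected = n
        elif n != expected:
            raise ValidationError(
                f"line {lineno}: column count drift: expected {expected} fields, got {n}"
            )
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        if start < 0:
            raise ParseError(f"negative start {start}", line=lineno)
        if start >= end:
            raise ValidationError(
                f"line {lineno}: empty or inverted record {fields[0]}:{start}-{end}"
            )
        yield BedRecord(fields[0], start, end, "\t".join(fields[3:]))


def parse_chrom_sizes(lines: Iterable[str]) -> ChromSizes:
    """Parse a two-column ``name length`` chrom.sizes file, preserving order."""
    sizes = ChromSizes()
    for lineno, line in _data_lines(lines):
        fields = line.split()
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 fields (name length), got {len(fields)}", line=lineno
            )
        length = _parse_int(fields[1], "length", lineno)
        try:
            sizes.add(fields[0], length)
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    return sizes


def format_value(value: float) -> str:
    """Shortest decimal string that round-trips through a 32-bit float.

    BBI stores values as float32, so this is the canonical text rendering of
    what the binary file actually holds.
    """
    return str(np.float32(value))


def emit_bedgraph(intervals: Iterable[SignalInterval], sink: IO[str]) -> int:
    """Write intervals as bedGraph lines; returns the line count.

    Input must be sorted and non-overlapping per chromosome, with each
    chromosome's intervals contiguous in the stream.
    """
    n = 0
    prev_chrom: str | None = None
    prev_end = 0
    seen: set[str] = set()
    for iv in intervals:
        if iv.chrom != prev_chrom:
            if iv.chrom in seen:
                raise ValidationError(
                    f"chromosome {iv.chrom!r} intervals are not contiguous"
                )
            seen.add(iv.chrom)
            prev_chrom = iv.chrom
            prev_end = 0
        if iv.start < prev_end:
            raise ValidationError(
                f"unsorted or overlapping intervals at {iv.chrom}:{iv.start}"
                f" (previous end {prev_end})"
            )
        prev_end = iv.end
        sink.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{format_value(iv.value)}\n")
        n += 1
    return n
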