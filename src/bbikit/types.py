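"""Core value types shared across the package.

Coordinates are 0-based half-open throughout ([start, end)), matching the
BED/bedGraph convention and the on-disk BBI encoding.  The only 1-based
format, Wiggle text, is converted at parse time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import ParseError, ValidationError

MAX_CHROM_LEN = 2**32 - 1

BIGWIG_MAGIC = 0x888FFC26
BIGBED_MAGIC = 0x8789F2EB
CHROM_BTREE_MAGIC = 0x78CA8C91
RTREE_MAGIC = 0x2468ACE0
BBI_VERSION = 4


@dataclass(frozen=True, slots=True)
class SignalInterval:
    """One step of a BigWig track: a constant float value over [start, end)."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )


@dataclass(frozen=True, slots=True)
class BedRecord:
    """One BigBed feature.  Fields beyond chrom/start/end live verbatim in ``rest``."""

    chrom: str
    start: int
    end: int
    rest: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid record {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def field_count(self) -> int:
        return 3 + (self.rest.count("\t") + 1 if self.rest else 0)

    @property
    def fields(self) -> list[str]:
        base = [self.chrom, str(self.start), str(self.end)]
        return base + (self.rest.split("\t") if self.rest else [])


class ChromSizes:
    """Ordered mapping of chromosome name -> length in bases.

    Iteration order is insertion (file line) order; that order also defines
    the chromosome ids a writer assigns and the chromosome order it expects
    of its input stream.
    """

    def __init__(self, items: Iterable[tuple[str, int]] = ()):
        self._sizes: dict[str, int] = {}
        for name, length in items:
            self.add(name, length)

    def add(self, name: str, length: int) -> None:
        if name in self._sizes:
            raise ValidationError(f"duplicate chromosome name: {name!r}")
        if not isinstance(length, int) or isinstance(length, bool):
            raise ParseError(f"chromosome length must be an integer, got {length!r}")
        if length <= 0 or length > MAX_CHROM_LEN:
            raise ValidationError(
                f"chromosome {name!r} length {length} out of range (1..2^32-1)"
            )
        self._sizes[name] = length

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChromSizes):
            return NotImplemented
        return list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"ChromSizes({list(self._sizes.items())!r})"

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self._sizes.items())

    def names(self) -> list[str]:
        return list(self._sizes)

    def index(self, name: str) -> int:
        """Position of ``name`` in file order (also its chromosome id when writing)."""
        try:
            return list(self._sizes).index(name)
        except ValueError:
            raise KeyError(name) from None


@dataclass(frozen=True, slots=True)
class SummaryStats:
    """The five-field mergeable aggregate behind zoom records and total summaries.

    ``valid_count`` counts bases with data; ``sum`` and ``sum_squares`` are
    sums of the per-base value and its square.  The empty aggregate uses
    +/-inf min/max sentinels so that merging is a monoid; serialization maps
    the sentinels to 0 (consumers must gate on ``valid_count``).
    """

    valid_count: int = 0
    min_val: float = math.inf
    max_val: float = -math.inf
    sum: float = 0.0
    sum_squares: float = 0.0

    @classmethod
    def neutral(cls) -> "SummaryStats":
        return cls()

    @classmethod
    def from_value(cls, value: float, length: int) -> "SummaryStats":
        """Summary of a constant value covering ``length`` bases."""
        if length <= 0:
            return cls()
        return cls(length, value, value, value * length, value * value * length)

    def merge(self, other: "SummaryStats") -> "SummaryStats":
        if self.valid_count == 0:
            return other
        if other.valid_count == 0:
            return self
        return SummaryStats(
            self.valid_count + other.valid_count,
            min(self.min_val, other.min_val),
            max(self.max_val, other.max_val),
            self.sum + other.sum,
            self.sum_squares + other.sum_squares,
        )

    @property
    def mean(self) -> float:
        return self.sum / self.valid_count if self.valid_count else math.nan

    @property
    def std(self) -> float:
        """Sample standard deviation from the sufficient statistics."""
        n = self.valid_count
        if n < 2:
            return 0.0 if n == 1 else math.nan
        var = (self.sum_squares - self.sum * self.sum / n) / (n - 1)
        return math.sqrt(max(var, 0.0))


@dataclass(frozen=True, slots=True)
class ZoomRecord:
    """A SummaryStats bound to an aligned bin of one reduction level."""

    chrom_id: int
    start: int
    end: int
    stats: SummaryStats


@dataclass(frozen=True, slots=True)
class ZoomLevelInfo:
    reduction_level: int
    data_offset: int
    index_offset: int


@dataclass(frozen=True, slots=True)
class ChromInfo:
    name: str
    id: int
    length: int


@dataclass(slots=True)
class BbiFileMetadata:
    """Parsed header state of an open (or freshly written) BBI file."""

    kind: str  # "bigwig" | "bigbed"
    version: int
    zoom_levels: list[ZoomLevelInfo] = field(default_factory=list)
    chrom_table: list[ChromInfo] = field(default_factory=list)
    total_summary: SummaryStats = field(default_factory=SummaryStats)
    uncompress_buf_size: int = 0
    field_count: int = 0
    defined_field_count: int = 0
    autosql_text: str | None = None

    @property
    def compressed(self) -> bool:
        return self.uncompress_buf_size > 0
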