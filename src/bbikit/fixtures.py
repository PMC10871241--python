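"""Seeded synthetic data: genomes, signal tracks, feature sets, corrupt files.

Everything here is a pure function of its spec (seed included), built on a
single ``numpy.random.default_rng`` stream, so fixtures regenerate
identically anywhere.  Small genomes come with a per-base oracle map that
tests aggregate against.

What these tracks emulate: step-function coverage signal with gaps (missing
data) and BED-style feature annotations with optional overlap — enough to
exercise every container feature.  They are not read pileups: values are
uniform, not count-distributed, and interval lengths have no fragment-size
structure.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .types import BedRecord, ChromSizes, SignalInterval

ORACLE_MAX_CHROM = 10_000  # per-base maps are only built for chroms this size or smaller

CORRUPT_MODES = ("bad_magic", "truncated", "bad_section_size", "bad_node_magic")


def default_genome(n_chroms: int = 3, chrom_len: int = 5_000) -> ChromSizes:
    return ChromSizes((f"chr{i + 1}", chrom_len) for i in range(n_chroms))


@dataclass(frozen=True)
class TrackSpec:
    """Recipe for a random step-function signal track."""

    seed: int
    chroms: ChromSizes = field(default_factory=default_genome)
    interval_count: int = 100
    length_range: tuple[int, int] = (1, 50)
    value_range: tuple[float, float] = (-10.0, 10.0)
    gap_probability: float = 0.3

    def __post_init__(self):
        if not 0 <= self.gap_probability <= 1:
            raise ValidationError("gap_probability must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"bad length range {self.length_range}")
        genome = sum(l for _, l in self.chroms.items())
        if self.interval_count * lo > genome:
            raise ValidationError(
                f"infeasible: {self.interval_count} intervals of >= {lo} bp "
                f"cannot fit a {genome} bp genome"
            )


@dataclass(frozen=True)
class FeatureSpec:
    """Recipe for a random BED feature set (bedN+P layout)."""

    seed: int
    chroms: ChromSizes = field(default_factory=default_genome)
    record_count: int = 100
    length_range: tuple[int, int] = (5, 200)
    bed_n: int = 6  # defined BED columns (3..12 subset supported: 3..6)
    extra_fields: int = 0  # the +P part
    overlap_allowed: bool = True

    def __post_init__(self):
        if not 3 <= self.bed_n <= 6:
            raise ValidationError("bed_n must be between 3 and 6")
        if self.extra_fields < 0:
            raise ValidationError("extra_fields must be non-negative")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"bad length range {self.length_range}")
        if not self.overlap_allowed:
            genome = sum(l for _, l in self.chroms.items())
            if self.record_count * lo > genome:
                raise ValidationError(
                    f"infeasible: {self.record_count} disjoint records of >= {lo} bp "
                    f"cannot fit a {genome} bp genome"
                )


def _split_count(rng: np.random.Generator, total: int, chroms: ChromSizes) -> dict[str, int]:
    """Distribute a record budget over chromosomes proportionally to length."""
    names = chroms.names()
    lengths = np.array([chroms[n] for n in names], dtype=float)
    if total == 0:
        return {n: 0 for n in names}
    counts = rng.multinomial(total, lengths / lengths.sum())
    return dict(zip(names, counts.tolist()))


def gen_signal_track(
    spec: TrackSpec,
) -> tuple[list[SignalInterval], dict[str, np.ndarray]]:
    """Generate a sorted, non-overlapping, in-bounds signal track.

    Returns the intervals plus a per-base oracle map (chrom -> float array,
    NaN where uncovered) for every chromosome of at most
    ``ORACLE_MAX_CHROM`` bases.
    """
    rng = np.random.default_rng(spec.seed)
    per_chrom = _split_count(rng, spec.interval_count, spec.chroms)
    lo, hi = spec.length_range
    vlo, vhi = spec.value_range
    out: list[SignalInterval] = []
    oracle: dict[str, np.ndarray] = {}
    for chrom, length in spec.chroms.items():
        want = per_chrom[chrom]
        arr = (
            np.full(length, np.nan, dtype=np.float64)
            if length <= ORACLE_MAX_CHROM
            else None
        )
        if want == 0:
            if arr is not None:
                oracle[chrom] = arr
            continue
        # draw lengths first, then spread the leftover space as gaps so the
        # track covers the whole chromosome rather than clumping at its start
        lengths = rng.integers(lo, hi + 1, size=want)
        while lengths.sum() > length and len(lengths) > 1:
            lengths = lengths[:-1]
        slack = int(length - lengths.sum())
        gap_mask = rng.random(len(lengths)) < spec.gap_probability
        weights = np.where(gap_mask, rng.random(len(lengths)), 0.0)
        if weights.sum() > 0:
            gaps = np.floor(weights / weights.sum() * slack).astype(int)
        else:
            gaps = np.zeros(len(lengths), dtype=int)
        pos = 0
        for ln, gap in zip(lengths.tolist(), gaps.tolist()):
            pos += gap
            end = min(pos + ln, length)
            if end <= pos:
                break
            # float32 so the value survives the binary round trip bit-exactly
            value = float(np.float32(rng.uniform(vlo, vhi)))
            out.append(SignalInterval(chrom, pos, end, value))
            if arr is not None:
                arr[pos:end] = value
            pos = end
        if arr is not None:
            oracle[chrom] = arr
    _check_track(out, spec.chroms)
    return out, oracle


def _check_track(intervals: list[SignalInterval], chroms: ChromSizes) -> None:
    """Generation self-check: sorted, non-overlapping, in bounds."""
    last: dict[str, int] = {}
    order = {n: i for i, n in enumerate(chroms.names())}
    prev_order = -1
    for iv in intervals:
        if iv.chrom not in order:
            raise AssertionError(f"generated unknown chrom {iv.chrom}")
        if order[iv.chrom] != prev_order:
            if order[iv.chrom] < prev_order:
                raise AssertionError("generated chroms out of order")
            prev_order = order[iv.chrom]
        if iv.start < last.get(iv.chrom, 0) or iv.end > chroms[iv.chrom]:
            raise AssertionError(f"generated interval out of contract: {iv}")
        last[iv.chrom] = iv.end


def gen_features(spec: FeatureSpec) -> list[BedRecord]:
    """Generate a sorted BED feature set; disjoint per chromosome when asked."""
    rng = np.random.default_rng(spec.seed)
    per_chrom = _split_count(rng, spec.record_count, spec.chroms)
    lo, hi = spec.length_range
    strands = np.array(["+", "-", "."])
    out: list[BedRecord] = []
    counter = 0
    for chrom, length in spec.chroms.items():
        want = per_chrom[chrom]
        if want == 0:
            continue
        if spec.overlap_allowed:
            starts = np.sort(rng.integers(0, max(1, length - lo), size=want))
            ends = [min(int(s) + int(rng.integers(lo, hi + 1)), length) for s in starts]
            pairs = [(int(s), e) for s, e in zip(starts, ends) if e > s]
        else:
            pairs = []
            pos = 0
            while len(pairs) < want and pos < length:
                pos += int(rng.integers(0, hi))  # gap
                ln = int(rng.integers(lo, hi + 1))
                end = min(pos + ln, length)
                if end <= pos:
                    break
                pairs.append((pos, end))
                pos = end
        for start, end in pairs:
            counter += 1
            extras = []
            if spec.bed_n >= 4:
                extras.append(f"feat{counter}")
            if spec.bed_n >= 5:
                extras.append(str(int(rng.integers(0, 1001))))
            if spec.bed_n >= 6:
                extras.append(str(rng.choice(strands)))
            extras += [f"x{counter}.{j}" for j in range(spec.extra_fields)]
            out.append(BedRecord(chrom, start, end, "\t".join(extras)))
    if not spec.overlap_allowed:
        by_chrom: dict[str, int] = {}
        for r in out:
            if r.start < by_chrom.get(r.chrom, 0):
                raise AssertionError("generated overlapping records with overlap_allowed=False")
            by_chrom[r.chrom] = r.end
    return out


def depth_oracle(records: list[BedRecord], chroms: ChromSizes) -> dict[str, np.ndarray]:
    """Per-base coverage depth of a feature set, for small chromosomes."""
    out = {}
    for chrom, length in chroms.items():
        if length > ORACLE_MAX_CHROM:
            continue
        arr = np.zeros(length, dtype=np.int64)
        for r in records:
            if r.chrom == chrom:
                arr[r.start : r.end] += 1
        out[chrom] = arr
    return out


def gen_corrupt_bbi(base: bytes, mode: str) -> bytes:
    """A minimally corrupted copy of a valid BBI byte string.

    Modes: ``bad_magic`` (clobber the file magic), ``truncated`` (cut at
    half length), ``bad_section_size`` (halve the declared decompression
    buffer so inflated sections overflow it), ``bad_node_magic`` (clobber
    the full-data R-tree magic).
    """
    if mode not in CORRUPT_MODES:
        raise ValidationError(f"unknown corruption mode {mode!r}; choose from {CORRUPT_MODES}")
    data = bytearray(base)
    if mode == "bad_magic":
        data[:4] = b"\xde\xad\xbe\xef"
    elif mode == "truncated":
        data = data[: len(data) // 2]
    elif mode == "bad_section_size":
        (buf_size,) = struct.unpack_from("<I", data, 52)
        if buf_size == 0:
            raise ValidationError("bad_section_size needs a compressed file")
        struct.pack_into("<I", data, 52, max(1, buf_size // 8))
    elif mode == "bad_node_magic":
        (full_index_off,) = struct.unpack_from("<Q", data, 24)
        struct.pack_into("<I", data, full_index_off, 0x0BADF00D)
    return bytes(data)
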