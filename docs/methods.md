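# Methods

This note records how bbikit models the BBI container, the choices made
where the format or its surrounding conventions leave room, and what the
synthetic fixtures do and do not establish.

## The container model

A BBI file is a 64-byte header; an array of zoom-level headers; an optional
embedded autoSql schema (BigBed); a total-summary block; a chromosome
B+ tree mapping fixed-width name keys to (id, length); the primary data as
a run of optionally DEFLATE-compressed sections; an R-tree over those
sections; and, per zoom level, reduced data with its own R-tree. The file
ends with the magic number repeated. BigWig magic is `0x888FFC26`, BigBed
`0x8789F2EB`, the chromosome tree `0x78CA8C91`, R-trees `0x2468ACE0`;
multi-byte fields are little-endian as written here, and the reader accepts
either byte order by testing the magic both ways.

Details the public format description leaves loose were fixed by dissecting
files produced by an independent implementation (libBigWig, via pyBigWig)
and confirmed by cross-reading in both directions in the test suite:

- the primary data area begins with a u64 count (sections for BigWig,
  records for BigBed); each zoom level's data begins with a u32 count of
  32-byte zoom records whose statistics are float32;
- third-party readers recover the embedded autoSql text as the byte span
  between `autoSqlOffset` and `totalSummaryOffset`, so the writer places
  the schema immediately before the total summary;
- the R-tree header is 48 bytes; leaf items are 32 bytes (bounds, data
  offset, size), internal items 24 bytes; bounds are half-open
  (chromosome id, base) pairs compared lexicographically.

## Summary statistics

Every aggregate — zoom record, total summary, region statistic — is the
five-field tuple (validCount, min, max, Σx, Σx²) over per-base values.
It forms a commutative monoid under field-wise merging, with the empty
summary (±inf sentinels, zero sums) as identity; the sentinels are
serialized as 0 and consumers gate on validCount. Derived statistics:
mean = Σx/n, coverage = n/width, sample std = √((Σx² − (Σx)²/n)/(n−1)).

The writer rounds every value to float32 *before* summarizing, because
float32 is what the data sections store. The total summary therefore
describes the file's actual contents, the coarsest zoom level folds to the
total summary exactly (up to float addition order), and
BigWig → bedGraph → BigWig is byte-identical. Summarizing at input
precision instead would bake unrecoverable float64 information into the
summary doubles.

## Writing in one pass

The input stream is consumed exactly once, so pipes work. Records are
validated on the fly (chromosome order must follow the chrom.sizes file,
which also assigns chromosome ids; starts sorted; BigWig intervals
non-overlapping; bounds checked, with an opt-in clip). Sections of
`items_per_slot` records (default 1024) are encoded, compressed, and
appended to a staging area together with their R-tree bookkeeping; a
compact 16-byte-per-record stream of (chrom id, start, end, value) is
staged in parallel for zoom building. With `use_temp_files=True` (default)
both staging areas are anonymous temporary files and peak memory is
bounded by a constant; with `False` they are in-memory buffers. The two
modes produce byte-identical output, as do all thread counts: compression
jobs run in a bounded window on a thread pool and are written back in
submission order.

Zoom levels are planned once the stream is exhausted (its length and mean
record length are then known): the first reduction is max(10 × mean record
length, 10) bp, each next level 4× coarser, stopping at the longest
chromosome or after `max_zoom_levels` (default 10) levels. Each level is
then built in one sequential scan of the staged zoom stream; bins are
aligned to the reduction level, clipped at chromosome ends, and empty bins
are omitted. Finally header, schema, summary, trees, staged bytes, and
indexes are laid out and the header back-patched — hence sinks must be
seekable even when sources are not.

Choices worth naming:

- **BigWig sections always use the bedgraph encoding** (explicit
  start/end/value triples). The fixed-step and variable-step encodings are
  implemented in the codec for reading third-party files; emitting them is
  a possible size optimization, not a correctness matter.
- **BigBed zoom statistics aggregate per-base coverage depth** (how many
  records cover each base, computed by a heap-based sweep over the sorted,
  possibly overlapping records). Depth is what makes a zoomed-out BigBed
  renderable as a density track, and it is well-defined where raw BED
  records carry no value. The total summary likewise summarizes depth.
- **The chromosome table contains every chrom.sizes entry**, data or not,
  so the coordinate system round-trips through metadata. (The classic
  tools keep only chromosomes with data; both are valid files.) B+ tree
  keys are stored name-sorted for search; ids keep chrom.sizes order.
- **Sections never span chromosomes**; a section is flushed at a
  chromosome change or when full.
- An empty input stream is an error ("no data") rather than a data-free
  file.

## Reading

`open_bbi` detects kind and byte order from the magic and parses all
metadata up front, including a check that every header-declared offset
lies inside the file — truncation fails at open, not via a wrong answer
later. Queries resolve the chromosome, walk the relevant R-tree (touching
O(log n + k) nodes), and decode only the selected blocks, enforcing the
header's declared maximum inflated block size. Interval/record queries
return overlapping records whole, sorted by start; `clip=True` trims to
the query range. Dense `values()` arrays mark missing data as NaN —
missing is not zero — and binned values average covered bases per bin.

`stats(..., exact=False)` may serve a request from the largest zoom level
whose reduction is at most half the output bin width (guaranteeing at
least two zoom bins per output bin; the format gives no selection rule, so
this one is stated explicitly). Zoom bins partially overlapping an output
bin contribute proportionally to the overlap fraction, so approximate
means deviate from exact ones by at most about max|value| ×
(reduction/bin width), a bound the tests check empirically. Statistics for
regions running past a chromosome end treat the out-of-range bases as
missing.

## Command-line tools

Each tool is a thin shell over a streaming library function. Flags follow
the single-dash `-flag=value` convention of the classic tools; extensions
use an `-x-` prefix (`-x-threads`, `-x-uncompressed`, `-x-no-temp-files`)
so they cannot collide. Exit codes: 0 success, 1 usage/validation,
2 corrupt binary input.

- `bigwigmerge` performs an ordered k-way sweep over interval edges,
  holding one pending interval per input — memory is independent of
  chromosome length. It emits maximal constant-value runs of the per-base
  sum (or max with `-max`, plus `-adjust`), omitting runs at or below
  `-threshold` (default 0, so zero-sum runs are dropped). It stays
  single-threaded: the ordered sweep is inherently sequential. bedGraph
  output is the default; a `.bw` output name plus `-sizes=chrom.sizes`
  writes BigWig directly.
- `bigwigaverageoverbed` streams one decoded section at a time per region
  and reports name, size, covered, sum, mean0 (sum/size) and mean
  (sum/covered, 0 if uncovered). Regions on chromosomes absent from the
  BigWig produce a zero row and a warning, not a failure.
- `bedtobigbed` embeds an autoSql schema only when `-as` is given (the
  classic tool always embeds a generated default; `bbikit.bed_schema`
  provides one for callers who want that). `-type=bedN[+[P]]` fixes the
  defined/total column counts and is cross-checked against the input and
  any schema.

## Synthetic data, and what the tests show

`bbikit.fixtures` generates everything from explicit seeds through one
`numpy` PRNG stream: genomes, step-function tracks (interval lengths drawn
first, leftover space spread as gaps across the chromosome so data covers
the whole sequence; `gap_probability=0` tiles contiguously), bedN+P
feature sets with or without overlap, and minimally corrupted copies of
valid files (bad magic, truncation, understated decompression buffer, bad
index magic). Tracks on chromosomes ≤ 10 kb come with a per-base oracle
array that all aggregation tests compare against. Values are uniform
floats rounded to float32; lengths are uniform. These tracks exercise
every container feature, but they are not read pileups: no count noise, no
fragment-length structure, no chromosome-scale coverage waves. Passing
tests establish format correctness and query/summary arithmetic, not
biological realism.

Problem sizes: the test suite and the acceptance script use genomes up to
10 chromosomes × 100 kb with up to 100k records for identity, determinism
and index-efficiency checks, and ≤ 10 kb chromosomes wherever a dense
per-base oracle is compared. Three tiny golden files (committed
base64-encoded, with a manifest of their generation parameters) pin the
writer's exact bytes against regression.

## Known limitations

- Later-version format extras (extended headers, extra indexes) are out of
  scope; files are written as version 4 with a total summary always.
- The reader accepts any seek/read byte source but ships no remote
  transport.
- `query_rtree` recursion depth equals tree height (≥ 2 branching), which
  is fine for any realistic file but means a pathological branching-2 tree
  over millions of blocks would recurse deeply.
- autoSql is tokenized, not type-checked against field contents, and only
  the `table` form is supported.
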