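# bbikit

Reading, writing, and command-line manipulation of **BigWig** and **BigBed**
(collectively *BBI*, Big Binary Indexed) files, in pure Python.

BigWig files store a quantitative step function over a reference genome — a
float value per base, with gaps for missing data — and BigBed files store
BED-like interval features, possibly overlapping, with extra columns
described by an embedded [autoSql](https://genomewiki.ucsc.edu/index.php/AutoSql)
schema. Both keep the primary data, a sparse R-tree spatial index, and
multi-resolution "zoom" summaries inside one compressed, seekable container,
which is why they are the workhorse formats for coverage tracks, peak calls,
and annotations in epigenomics and regulatory genomics.

bbikit implements the whole container, both directions:

- **Read** from any seekable byte source (path, file handle, or in-memory
  buffer; both byte orders): metadata, interval queries, dense per-base
  values, zoom records, and exact or zoom-accelerated region statistics.
  Queries go through the R-tree, so only the data blocks overlapping the
  request are read and decompressed.
- **Write** BigWig and BigBed in a *single pass* of the input stream — which
  may be a pipe — building compressed data sections, every zoom level, the
  chromosome B+ tree, R-trees, and the total summary, with temporary-file
  staging so peak memory stays bounded regardless of input size (and an
  in-memory mode that produces byte-identical files). Section compression
  can run on multiple threads; the output bytes are identical for any
  thread count.
- **Text formats**: lazy, single-pass parsers and emitters for bedGraph,
  Wiggle (fixedStep/variableStep), BED, chrom.sizes, and autoSql.
- **CLI tools**, drop-in compatible with the classic UCSC utilities, as one
  multitool (`bbikit <cmd>`) and as individual entry points:
  `bedgraphtobigwig`, `bedtobigbed`, `bigwigaverageoverbed`, `bigwigmerge`,
  `bigwiginfo`, `bigbedinfo`, `bigwigtobedgraph`.
- **Synthetic fixtures** (`bbikit.fixtures`): seeded generators for genomes,
  signal tracks, feature sets, and minimally corrupted files, so everything
  is testable without downloads.

The summary machinery is built on one mergeable five-field aggregate per
span — (validCount, min, max, Σx, Σx²) — from which mean, coverage
(validCount/width) and sample standard deviation
√((Σx² − (Σx)²/n)/(n−1)) follow. Zoom levels are ladders of aligned bins
(each level 4× coarser than the last, starting near 10× the mean record
length) holding these aggregates; BigBed zoom aggregates per-base coverage
depth. Files written here are read by independent implementations
(verified against pyBigWig/libBigWig in the test suite) and vice versa.

## Worked example

```python
from io import BytesIO
from bbikit import ChromSizes, SignalInterval, open_bbi, write_bigwig

chroms = ChromSizes([("chr1", 1000), ("chr2", 500)])
track = [
    SignalInterval("chr1", 0, 10, 1.5),
    SignalInterval("chr1", 10, 20, 2.5),
    SignalInterval("chr2", 5, 30, 3.5),
]
buf = BytesIO()
meta = write_bigwig(iter(track), chroms, buf)
print(meta.total_summary)

f = open_bbi(buf)
print(f.values("chr1", 0, 25))
print(f.stats("chr1", 0, 20, "mean"))
```

prints

```
SummaryStats(valid_count=45, min_val=1.5, max_val=3.5, sum=127.5, sum_squares=391.25)
[1.5 1.5 1.5 1.5 1.5 1.5 1.5 1.5 1.5 1.5 2.5 2.5 2.5 2.5 2.5 2.5 2.5 2.5
 2.5 2.5 nan nan nan nan nan]
[2.0]
```

— 45 bases carry data (10 + 10 + 25), their values sum to 127.5, uncovered
bases come back as NaN rather than zero, and the mean over chr1:0-20 is
(10·1.5 + 10·2.5)/20 = 2.0.

The same from a shell:

```sh
$ printf 'chr1\t0\t100\t2\nchr1\t100\t150\t3.5\n' > in.bedGraph
$ printf 'chr1\t1000\n' > chrom.sizes
$ bbikit bedgraphtobigwig in.bedGraph chrom.sizes out.bw
$ bbikit bigwiginfo out.bw
version: 4
isCompressed: yes
zoomLevels: 1
reductionLevels: 750
chromCount: 1
basesCovered: 150
mean: 2.5
min: 2
max: 3.5
std: 0.709476
```

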