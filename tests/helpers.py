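"""Shared test utilities: brute-force oracles and a whole-file byte swapper.

The oracles here deliberately avoid the library's own query code paths:
they expand intervals into dense per-base arrays and aggregate with numpy,
so agreement with the library is meaningful.
"""

from __future__ import annotations

import struct

import numpy as np

from bbikit import ChromSizes


def per_base_map(intervals, chroms: ChromSizes) -> dict[str, np.ndarray]:
    """chrom -> per-base float array (NaN = no data), built by brute force."""
    out = {name: np.full(length, np.nan) for name, length in chroms.items()}
    for iv in intervals:
        out[iv.chrom][iv.start : iv.end] = iv.value
    return out


def oracle_summary(arr: np.ndarray, start: int, end: int):
    """(valid, min, max, sum, sumsq) over arr[start:end], NaN-aware."""
    chunk = arr[start:end]
    covered = chunk[~np.isnan(chunk)]
    if covered.size == 0:
        return 0, None, None, 0.0, 0.0
    return (
        int(covered.size),
        float(covered.min()),
        float(covered.max()),
        float(covered.sum()),
        float((covered**2).sum()),
    )


def bin_edges(start: int, end: int, bins: int) -> list[int]:
    """Same integer bin-edge rule the reader's stats() uses."""
    return [start + round(i * (end - start) / bins) for i in range(bins + 1)]


def swap_uncompressed_bigwig(data: bytes) -> bytes:
    """Byte-swap every multi-byte field of an uncompressed little-endian BigWig.

    Produces the big-endian twin of the file so the reader's byte-order
    detection can be exercised without a big-endian writer.
    """
    out = bytearray(data)

    def swap(fmt: str, offset: int) -> tuple:
        vals = struct.unpack_from("<" + fmt, data, offset)
        struct.pack_into(">" + fmt, out, offset, *vals)
        return vals

    hdr = swap("IHHQQQHHQQIQ", 0)
    (_magic, _ver, n_zoom, chrom_off, data_off, index_off,
     _fc, _dfc, autosql_off, summary_off, buf_size, _res) = hdr
    assert buf_size == 0, "swapper only handles uncompressed files"
    assert autosql_off == 0

    zoom_headers = []
    for i in range(n_zoom):
        zoom_headers.append(swap("IIQQ", 64 + 24 * i))
    swap("Qdddd", summary_off)

    # chromosome B+ tree
    _m, _bs, key_size, _vs, _n, _r = swap("IIIIQQ", chrom_off)

    def swap_btree_node(off: int) -> None:
        is_leaf, _res2, count = struct.unpack_from("<BBH", data, off)
        swap("BBH", off)
        pos = off + 4
        for _ in range(count):
            if is_leaf:
                swap("II", pos + key_size)
            else:
                (child,) = swap("Q", pos + key_size)
                swap_btree_node(child)
            pos += key_size + 8

    swap_btree_node(chrom_off + 32)

    # full data: u64 section count, then uncompressed BigWig sections
    (n_sections,) = swap("Q", data_off)
    pos = data_off + 8
    for _ in range(n_sections):
        _cid, _s, _e, _step, _span, stype, _r2, count = struct.unpack_from(
            "<IIIIIBBH", data, pos
        )
        swap("IIIIIBBH", pos)
        pos += 24
        item_fmt = {1: "IIf", 2: "If", 3: "f"}[stype]
        for _ in range(count):
            swap(item_fmt, pos)
            pos += struct.calcsize(item_fmt)

    def swap_rtree(off: int) -> None:
        swap("IIQIIIIQII", off)

        def node(noff: int) -> None:
            is_leaf, _r3, count = struct.unpack_from("<BBH", data, noff)
            swap("BBH", noff)
            p = noff + 4
            for _ in range(count):
                if is_leaf:
                    swap("IIIIQQ", p)
                    p += 32
                else:
                    vals = swap("IIIIQ", p)
                    node(vals[4])
                    p += 24

        node(off + 48)

    swap_rtree(index_off)

    # zoom levels: u32 record count, raw zoom records, then that level's R-tree
    for red, _r4, z_data, z_index in zoom_headers:
        (_n_recs,) = swap("I", z_data)
        pos = z_data + 4
        while pos < z_index:
            swap("IIIIffff", pos)
            pos += 32
        swap_rtree(z_index)

    swap("I", len(data) - 4)  # trailing magic
    return bytes(out)
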