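"""R-tree spatial index over (chromosome id, base) ranges.

Leaf items map a bounding range to the file offset and size of one data
block; internal nodes hold child bounds so a query touches O(log n + k)
nodes.  Bounds compare lexicographically as (chrom_id, base) pairs, and a
block's range [(s_chrom, s_base), (e_chrom, e_base)) is half-open like the
intervals it covers.

The packed layout is bottom-up: consecutive runs of ``block_size`` children
form each parent, which keeps leaves in (chrom, start) file order.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

from .errors import BbiFormatError, ValidationError
from .types import RTREE_MAGIC

_HEADER_FMT = "IIQIIIIQII"
# magic, block_size, item_count, start_chrom, start_base, end_chrom, end_base,
# end_file_offset, items_per_slot, reserved
HEADER_SIZE = 48
_NODE_HEADER_FMT = "BBH"
_LEAF_ITEM_FMT = "IIIIQQ"  # bounds + data offset + data size
_INTERNAL_ITEM_FMT = "IIIIQ"  # bounds + child offset


@dataclass(frozen=True, slots=True)
class RTreeLeaf:
    """Bounds and location of one data block."""

    start_chrom: int
    start_base: int
    end_chrom: int
    end_base: int
    data_offset: int
    data_size: int


def serialize_rtree(
    leaf_items: list[RTreeLeaf],
    base_offset: int,
    block_size: int = 256,
    items_per_slot: int = 1024,
    end_file_offset: int = 0,
) -> bytes:
    """Serialize a packed R-tree as it will appear at ``base_offset``."""
    if block_size < 2:
        raise ValidationError("R-tree branching factor must be at least 2")
    keys = [(it.start_chrom, it.start_base) for it in leaf_items]
    if keys != sorted(keys):
        raise ValidationError("R-tree leaf items must be sorted by (chrom_id, start)")

    # level 0: leaf nodes, each holding up to block_size leaf items
    def bounds(children) -> tuple[int, int, int, int]:
        scs = min((c[0], c[1]) for c in children)
        ecs = max((c[2], c[3]) for c in children)
        return (*scs, *ecs)

    item_tuples = [
        (it.start_chrom, it.start_base, it.end_chrom, it.end_base, it.data_offset, it.data_size)
        for it in leaf_items
    ]
    leaf_nodes = [
        item_tuples[i : i + block_size] for i in range(0, len(item_tuples), block_size)
    ]
    # each level is a list of nodes; a node is (bounds, children, is_leaf)
    levels: list[list[tuple]] = [[(bounds(n), n, True) for n in leaf_nodes]]
    while len(levels[-1]) > 1:
        prev = levels[-1]
        groups = [prev[i : i + block_size] for i in range(0, len(prev), block_size)]
        levels.append(
            [(bounds([g[0] for g in grp]), grp, False) for grp in groups]
        )
    levels.reverse()  # root first

    def node_size(node) -> int:
        _b, children, is_leaf = node
        return 4 + len(children) * (32 if is_leaf else 24)

    offsets: dict[int, int] = {}
    pos = base_offset + HEADER_SIZE
    for level in levels:
        for node in level:
            offsets[id(node)] = pos
            pos += node_size(node)

    root_bounds = levels[0][0][0] if leaf_items else (0, 0, 0, 0)
    out = bytearray()
    out += struct.pack(
        "<" + _HEADER_FMT,
        RTREE_MAGIC,
        block_size,
        len(leaf_items),
        *root_bounds,
        end_file_offset,
        items_per_slot,
        0,
    )
    for level in levels:
        for node in level:
            _b, children, is_leaf = node
            out += struct.pack("<" + _NODE_HEADER_FMT, 1 if is_leaf else 0, 0, len(children))
            if is_leaf:
                for c in children:
                    out += struct.pack("<" + _LEAF_ITEM_FMT, *c)
            else:
                for child in children:
                    out += struct.pack(
                        "<" + _INTERNAL_ITEM_FMT, *child[0], offsets[id(child)]
                    )
    return bytes(out)


def rtree_size(n_items: int, block_size: int = 256) -> int:
    """Byte size of the serialized index for ``n_items`` leaf items."""
    size = HEADER_SIZE
    count = n_items
    is_leaf = True
    while True:
        nodes = max(1, -(-count // block_size))
        size += nodes * 4 + count * (32 if is_leaf else 24)
        if nodes == 1:
            break
        count, is_leaf = nodes, False
    return size


def query_rtree(
    source, index_offset: int, chrom_id: int, start: int, end: int
    , order: str = "<"
) -> list[tuple[int, int]]:
    """(data offset, size) of every leaf block overlapping [start, end) on ``chrom_id``.

    Reads only the nodes on the traversal path; results come back in file
    (chrom, start) order.
    """
    source.seek(index_offset)
    head = source.read(HEADER_SIZE)
    if len(head) < HEADER_SIZE:
        raise BbiFormatError(f"truncated R-tree header at offset {index_offset}")
    magic = struct.unpack(order + "I", head[:4])[0]
    if magic != RTREE_MAGIC:
        raise BbiFormatError(f"bad R-tree magic {magic:#x} at offset {index_offset}")

    qlo = (chrom_id, start)
    qhi = (chrom_id, end)

    def overlaps(sc: int, sb: int, ec: int, eb: int) -> bool:
        return (sc, sb) < qhi and (ec, eb) > qlo

    hits: list[tuple[int, int]] = []

    def visit(node_offset: int) -> None:
        source.seek(node_offset)
        nh = source.read(4)
        if len(nh) < 4:
            raise BbiFormatError(f"truncated R-tree node at offset {node_offset}")
        is_leaf, _res, count = struct.unpack(order + _NODE_HEADER_FMT, nh)
        size = count * (32 if is_leaf else 24)
        body = source.read(size)
        if len(body) < size:
            raise BbiFormatError(f"truncated R-tree node at offset {node_offset}")
        if is_leaf:
            for sc, sb, ec, eb, off, sz in struct.iter_unpack(order + _LEAF_ITEM_FMT, body):
                if overlaps(sc, sb, ec, eb):
                    hits.append((off, sz))
        else:
            children = [
                child
                for *b, child in struct.iter_unpack(order + _INTERNAL_ITEM_FMT, body)
                if overlaps(*b)
            ]
            for child in children:
                visit(child)

    visit(index_offset + HEADER_SIZE)
    return hits
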