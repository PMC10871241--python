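"""Chromosome B+ tree: fixed-width name keys -> (chrom id, chrom length).

Keys are chromosome names padded with NULs to the longest name's length and
stored in ascending key order, so node-level binary search works for any
reader.  Chromosome ids are NOT key order: they are assigned by the writer
in chrom.sizes order and stored as values.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

from .errors import BbiFormatError, ValidationError
from .types import CHROM_BTREE_MAGIC, ChromInfo

_HEADER_FMT = "IIIIQQ"  # magic, block_size, key_size, val_size, item_count, reserved
_HEADER_SIZE = 32
_NODE_HEADER_FMT = "BBH"  # is_leaf, reserved, count


def serialize_chrom_btree(
    chrom_table: list[ChromInfo], base_offset: int, block_size: int = 256
) -> bytes:
    """Serialize the chromosome index as it will appear at ``base_offset``.

    Child pointers are absolute file offsets, hence the base offset argument.
    """
    if not chrom_table:
        raise ValidationError("cannot build a chromosome index with no chromosomes")
    key_size = max(len(c.name.encode()) for c in chrom_table)
    items = sorted(chrom_table, key=lambda c: c.name.encode())

    # group leaves bottom-up into levels of at most block_size entries
    leaves = [items[i : i + block_size] for i in range(0, len(items), block_size)]
    levels: list[list[list]] = [leaves]
    while len(levels[-1]) > 1:
        prev = levels[-1]
        levels.append([prev[i : i + block_size] for i in range(0, len(prev), block_size)])
    levels.reverse()  # root level first

    def node_size(count: int, is_leaf: bool) -> int:
        return 4 + count * (key_size + (8 if is_leaf else 8))

    # assign offsets in level order
    offsets: dict[int, int] = {}
    pos = base_offset + _HEADER_SIZE
    for level in levels:
        for node in level:
            offsets[id(node)] = pos
            pos += node_size(len(node), True)

    def key_bytes(name: str) -> bytes:
        return name.encode().ljust(key_size, b"\0")

    out = bytearray()
    out += struct.pack(
        "<" + _HEADER_FMT, CHROM_BTREE_MAGIC, block_size, key_size, 8, len(items), 0
    )
    for depth, level in enumerate(levels):
        is_leaf = depth == len(levels) - 1
        for node in level:
            out += struct.pack("<" + _NODE_HEADER_FMT, 1 if is_leaf else 0, 0, len(node))
            for entry in node:
                if is_leaf:
                    out += key_bytes(entry.name) + struct.pack("<II", entry.id, entry.length)
                else:
                    first = entry
                    while isinstance(first, list):
                        first = first[0]
                    out += key_bytes(first.name) + struct.pack("<Q", offsets[id(entry)])
    return bytes(out)


@dataclass
class ChromBTree:
    """Parsed chromosome index with lookup by name."""

    key_size: int
    items: list[ChromInfo]

    def __post_init__(self):
        self._by_name = {c.name: c for c in self.items}

    def lookup(self, name: str) -> tuple[int, int] | None:
        """(id, length) for ``name``, or None when absent."""
        info = self._by_name.get(name)
        return (info.id, info.length) if info else None

    def table_by_id(self) -> list[ChromInfo]:
        return sorted(self.items, key=lambda c: c.id)


def read_chrom_btree(source, offset: int, order: str = "<") -> ChromBTree:
    """Parse the whole chromosome index (it is small) from a seekable source."""
    source.seek(offset)
    head = source.read(_HEADER_SIZE)
    if len(head) < _HEADER_SIZE:
        raise BbiFormatError("truncated chromosome index header")
    magic, _block_size, key_size, val_size, item_count, _ = struct.unpack(
        order + _HEADER_FMT, head
    )
    if magic != CHROM_BTREE_MAGIC:
        raise BbiFormatError(
            f"bad chromosome index magic {magic:#x} at offset {offset}"
        )
    if val_size != 8:
        raise BbiFormatError(f"unexpected chromosome index value size {val_size}")

    items: list[ChromInfo] = []

    def walk(node_offset: int) -> None:
        source.seek(node_offset)
        nh = source.read(4)
        if len(nh) < 4:
            raise BbiFormatError(f"truncated index node at offset {node_offset}")
        is_leaf, _res, count = struct.unpack(order + _NODE_HEADER_FMT, nh)
        entry_size = key_size + (8 if is_leaf else 8)
        body = source.read(count * entry_size)
        if len(body) < count * entry_size:
            raise BbiFormatError(f"truncated index node at offset {node_offset}")
        for i in range(count):
            entry = body[i * entry_size : (i + 1) * entry_size]
            key = entry[:key_size].rstrip(b"\0").decode()
            if is_leaf:
                cid, length = struct.unpack(order + "II", entry[key_size:])
                items.append(ChromInfo(key, cid, length))
            else:
                (child,) = struct.unpack(order + "Q", entry[key_size:])
                walk(child)

    walk(offset + _HEADER_SIZE)
    if len(items) != item_count:
        raise BbiFormatError(
            f"chromosome index declares {item_count} items, found {len(items)}"
        )
    return ChromBTree(key_size, items)
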