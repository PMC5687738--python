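"""Persistence: binary point file, memory-bounded cache, SQLite metadata.

A store on disk is a directory holding two files:

``points.bin``
    Immutable fixed-record binary file. Header: 8-byte magic ``MZPTREE\\0``,
    u32 format version, u64 point count, u32 record width; then one
    24-byte record (little-endian f64 mz, rt, intensity) per point, in
    leaf order. Record ``i`` starts at ``HEADER_SIZE + i * RECORD_WIDTH``,
    so lookup by id is one seek, and each leaf's records occupy one
    contiguous byte range readable with a single seek.

``meta.sqlite``
    Relational persistence of the tree nodes, their summary point-id
    lists, and the mutable segmentation metadata (point -> trace,
    trace -> envelope). Coordinates never live here: segmentation edits
    cannot alter mz/rt/intensity.

Point ids are assigned at write time as record indices; the builder's
provisional ids are remapped so the constant-time offset formula is exact.

The point cache is an LRU hashmap from point id to point object with a
user-set byte budget; by default 80% of the memory limit (itself
defaulting to 1 GiB) is given to the cache. Results are identical with
the cache enabled, disabled, or cold.
"""

from __future__ import annotations

import os
import sqlite3
import struct
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import DataBounds, MsPoint, QueryWindow
from .summarize import DEFAULT_STRIDE
from .tree import BuildParams, QueryStats, TreeNode, build_tree, iter_leaves, query

__all__ = [
    "MAGIC",
    "FORMAT_VERSION",
    "HEADER_SIZE",
    "RECORD_WIDTH",
    "DEFAULT_MEMORY_LIMIT",
    "CACHE_FRACTION",
    "CorruptionError",
    "PointFile",
    "write_point_file",
    "PointCache",
    "cache_fetch",
    "MetadataStore",
    "MzStore",
]

MAGIC = b"MZPTREE\x00"
FORMAT_VERSION = 1
_HEADER = struct.Struct("<8sIQI")
_RECORD = struct.Struct("<ddd")
HEADER_SIZE = _HEADER.size  # 24
RECORD_WIDTH = _RECORD.size  # 24

SCHEMA_VERSION = 1
#: Default process memory limit (bytes); the store refuses nothing above it,
#: it only sizes the cache.
DEFAULT_MEMORY_LIMIT = 1 << 30  # 1 GiB
#: Share of the memory limit given to the point cache.
CACHE_FRACTION = 0.8


class CorruptionError(RuntimeError):
    """The point file's header or byte ranges are inconsistent."""


class PointFile:
    """Read-only random access to the fixed-record point file."""

    def __init__(self, path: os.PathLike):
        self.path = Path(path)
        self._fh = open(self.path, "rb")
        header = self._fh.read(HEADER_SIZE)
        if len(header) != HEADER_SIZE:
            raise CorruptionError(f"{self.path}: truncated header")
        magic, version, count, width = _HEADER.unpack(header)
        if magic != MAGIC:
            raise CorruptionError(f"{self.path}: bad magic {magic!r}")
        if version != FORMAT_VERSION:
            raise CorruptionError(f"{self.path}: unsupported format version {version}")
        if width != RECORD_WIDTH:
            raise CorruptionError(f"{self.path}: unexpected record width {width}")
        self.count = count
        size = self.path.stat().st_size
        if size < HEADER_SIZE + count * RECORD_WIDTH:
            raise CorruptionError(
                f"{self.path}: file holds fewer than {count} records"
            )

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "PointFile":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def read_point(self, point_id: int) -> MsPoint:
        """Decode one record by direct offset (no scan)."""
        if not (0 <= point_id < self.count):
            raise IndexError(f"point id {point_id} out of range [0, {self.count})")
        self._fh.seek(HEADER_SIZE + point_id * RECORD_WIDTH)
        mz, rt, intensity = _RECORD.unpack(self._fh.read(RECORD_WIDTH))
        return MsPoint(id=point_id, mz=mz, rt=rt, intensity=intensity)

    def read_block(self, offset: int, count: int, first_id: int) -> List[MsPoint]:
        """Read ``count`` contiguous records with a single seek."""
        end = offset + count * RECORD_WIDTH
        if (
            offset < HEADER_SIZE
            or (offset - HEADER_SIZE) % RECORD_WIDTH != 0
            or end > HEADER_SIZE + self.count * RECORD_WIDTH
        ):
            raise CorruptionError(
                f"{self.path}: leaf block ({offset}, {count}) outside file"
            )
        self._fh.seek(offset)
        raw = self._fh.read(count * RECORD_WIDTH)
        if len(raw) != count * RECORD_WIDTH:
            raise CorruptionError(f"{self.path}: short read at offset {offset}")
        return [
            MsPoint(id=first_id + i, mz=mz, rt=rt, intensity=inten)
            for i, (mz, rt, inten) in enumerate(_RECORD.iter_unpack(raw))
        ]

    def read_leaf_block(self, leaf: TreeNode) -> List[MsPoint]:
        if leaf.leaf_block is None:
            raise ValueError(f"node {leaf.node_id} has no leaf block")
        offset, count = leaf.leaf_block
        first_id = (offset - HEADER_SIZE) // RECORD_WIDTH
        return self.read_block(offset, count, first_id)


def write_point_file(
    leaves: Sequence[Sequence[MsPoint]], path: os.PathLike
) -> Tuple[Dict[int, int], List[Tuple[int, int]]]:
    """Write leaf partitions left-to-right as one fixed-record file.

    Point ids are assigned as final record indices. Returns the old-id ->
    new-id map and each leaf's (byte offset, count).
    """
    if not leaves or all(len(leaf) == 0 for leaf in leaves):
        raise ValueError("nothing to persist: empty leaf list")
    total = sum(len(leaf) for leaf in leaves)
    id_map: Dict[int, int] = {}
    blocks: List[Tuple[int, int]] = []
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, FORMAT_VERSION, total, RECORD_WIDTH))
        next_id = 0
        for leaf in leaves:
            blocks.append((HEADER_SIZE + next_id * RECORD_WIDTH, len(leaf)))
            # one write per leaf: the partition lands as a contiguous block
            fh.write(
                b"".join(_RECORD.pack(p.mz, p.rt, p.intensity) for p in leaf)
            )
            for p in leaf:
                id_map[p.id] = next_id
                next_id += 1
    return id_map, blocks


class PointCache:
    """LRU point cache with a byte budget (record width per entry).

    Capacity 0 disables caching entirely; every fetch is then served from
    the backing file, with identical results.
    """

    def __init__(self, capacity_bytes: int):
        if capacity_bytes < 0:
            raise ValueError("capacity must be non-negative")
        self.capacity_bytes = capacity_bytes
        self.capacity_points = capacity_bytes // RECORD_WIDTH
        self._map: "OrderedDict[int, MsPoint]" = OrderedDict()
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self._map)

    @property
    def resident_bytes(self) -> int:
        return len(self._map) * RECORD_WIDTH

    def get(self, point_id: int) -> Optional[MsPoint]:
        p = self._map.get(point_id)
        if p is None:
            self.misses += 1
            return None
        self.hits += 1
        self._map.move_to_end(point_id)
        return p

    def put(self, p: MsPoint) -> None:
        if self.capacity_points == 0:
            return
        self._map[p.id] = p
        self._map.move_to_end(p.id)
        while len(self._map) > self.capacity_points:
            self._map.popitem(last=False)


def cache_fetch(
    cache: Optional[PointCache], ids: Sequence[int], backing: PointFile
) -> List[MsPoint]:
    """Fetch points by id through the cache; misses load from ``backing``."""
    if cache is None:
        return [backing.read_point(i) for i in ids]
    out: List[MsPoint] = []
    for i in ids:
        p = cache.get(i)
        if p is None:
            p = backing.read_point(i)
            cache.put(p)
        out.append(p)
    return out


_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta(key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS nodes(
    node_id INTEGER PRIMARY KEY,
    parent_id INTEGER,
    child_index INTEGER NOT NULL DEFAULT 0,
    min_mz REAL NOT NULL, max_mz REAL NOT NULL,
    min_rt REAL NOT NULL, max_rt REAL NOT NULL,
    is_leaf INTEGER NOT NULL,
    leaf_offset INTEGER, leaf_count INTEGER
);
CREATE TABLE IF NOT EXISTS node_points(
    node_id INTEGER NOT NULL REFERENCES nodes(node_id),
    position INTEGER NOT NULL,
    point_id INTEGER NOT NULL,
    PRIMARY KEY(node_id, position)
);
CREATE TABLE IF NOT EXISTS traces(
    trace_id INTEGER PRIMARY KEY,
    envelope_id INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS point_trace(
    point_id INTEGER PRIMARY KEY,
    trace_id INTEGER NOT NULL REFERENCES traces(trace_id)
);
"""


class MetadataStore:
    """SQLite persistence of nodes, summaries, and segmentation.

    Segmentation is normalized: a point maps to a trace, a trace to an
    envelope; a point's envelope is inherited through its trace. Id 0 is
    the "unassigned" sentinel on both levels and is never stored as a row.
    """

    def __init__(self, path: os.PathLike):
        self.path = Path(path)
        # single-writer store; the HTTP server serializes requests, so
        # cross-thread use of one connection is safe
        self._db = sqlite3.connect(self.path, check_same_thread=False)
        self._db.executescript(_SCHEMA)
        row = self._db.execute(
            "SELECT value FROM meta WHERE key = 'schema_version'"
        ).fetchone()
        if row is None:
            self._db.execute(
                "INSERT INTO meta(key, value) VALUES ('schema_version', ?)",
                (str(SCHEMA_VERSION),),
            )
            self._db.commit()
        elif int(row[0]) != SCHEMA_VERSION:
            raise RuntimeError(
                f"metadata schema version {row[0]} != supported {SCHEMA_VERSION}"
            )

    def close(self) -> None:
        self._db.close()

    # -- store-level config ------------------------------------------------

    def set_meta(self, key: str, value: str) -> None:
        self._db.execute(
            "INSERT INTO meta(key, value) VALUES (?, ?) "
            "ON CONFLICT(key) DO UPDATE SET value = excluded.value",
            (key, value),
        )
        self._db.commit()

    def get_meta(self, key: str) -> Optional[str]:
        row = self._db.execute("SELECT value FROM meta WHERE key = ?", (key,)).fetchone()
        return row[0] if row else None

    @property
    def point_count(self) -> int:
        v = self.get_meta("point_count")
        return int(v) if v is not None else 0

    # -- tree persistence --------------------------------------------------

    def save_tree(self, root: TreeNode) -> None:
        db = self._db
        db.execute("DELETE FROM nodes")
        db.execute("DELETE FROM node_points")
        node_rows, point_rows = [], []

        def walk(node: TreeNode, parent_id: Optional[int], child_index: int) -> None:
            offset, count = node.leaf_block if node.leaf_block else (None, None)
            b = node.bounds
            node_rows.append(
                (
                    node.node_id, parent_id, child_index,
                    b.min_mz, b.max_mz, b.min_rt, b.max_rt,
                    int(node.is_leaf), offset, count,
                )
            )
            point_rows.extend(
                (node.node_id, pos, pid) for pos, pid in enumerate(node.point_ids)
            )
            for ci, child in enumerate(node.children):
                walk(child, node.node_id, ci)

        walk(root, None, 0)
        db.executemany("INSERT INTO nodes VALUES (?,?,?,?,?,?,?,?,?,?)", node_rows)
        db.executemany("INSERT INTO node_points VALUES (?,?,?)", point_rows)
        db.commit()

    def load_tree(self) -> TreeNode:
        rows = self._db.execute(
            "SELECT node_id, parent_id, child_index, min_mz, max_mz, min_rt, max_rt,"
            " is_leaf, leaf_offset, leaf_count FROM nodes"
        ).fetchall()
        if not rows:
            raise RuntimeError("metadata store holds no tree")
        nodes: Dict[int, TreeNode] = {}
        parents: Dict[int, Tuple[Optional[int], int]] = {}
        root_id = None
        for (nid, parent, cidx, mn_mz, mx_mz, mn_rt, mx_rt, is_leaf, off, cnt) in rows:
            node = TreeNode(
                node_id=nid,
                bounds=DataBounds(mn_mz, mx_mz, mn_rt, mx_rt),
                leaf_block=(off, cnt) if is_leaf else None,
            )
            nodes[nid] = node
            parents[nid] = (parent, cidx)
            if parent is None:
                root_id = nid
        if root_id is None:
            raise RuntimeError("metadata store has no root node")
        for pid, pos, point_id in self._db.execute(
            "SELECT node_id, position, point_id FROM node_points ORDER BY node_id, position"
        ):
            nodes[pid].point_ids.append(point_id)
        children: Dict[int, List[Tuple[int, TreeNode]]] = {}
        for nid, (parent, cidx) in parents.items():
            if parent is not None:
                children.setdefault(parent, []).append((cidx, nodes[nid]))
        for parent, kids in children.items():
            kids.sort()
            nodes[parent].children = [n for _, n in kids]
        return nodes[root_id]

    # -- segmentation ------------------------------------------------------

    def _check_point_ids(self, point_ids: Sequence[int]) -> None:
        count = self.point_count
        bad = [i for i in point_ids if not (0 <= i < count)]
        if bad:
            raise KeyError(f"unknown point ids: {sorted(bad)}")

    def assign_trace(self, point_ids: Sequence[int], trace_id: int) -> int:
        """Assign points to a trace; trace 0 clears the assignment."""
        if trace_id < 0:
            raise ValueError("trace_id must be non-negative")
        self._check_point_ids(point_ids)
        db = self._db
        if trace_id == 0:
            db.executemany(
                "DELETE FROM point_trace WHERE point_id = ?",
                [(i,) for i in point_ids],
            )
        else:
            db.execute(
                "INSERT OR IGNORE INTO traces(trace_id, envelope_id) VALUES (?, 0)",
                (trace_id,),
            )
            db.executemany(
                "INSERT INTO point_trace(point_id, trace_id) VALUES (?, ?) "
                "ON CONFLICT(point_id) DO UPDATE SET trace_id = excluded.trace_id",
                [(i, trace_id) for i in point_ids],
            )
        db.commit()
        return len(point_ids)

    def assign_envelope(self, trace_ids: Sequence[int], envelope_id: int) -> int:
        """Attach traces to an envelope; envelope 0 detaches them."""
        if envelope_id < 0:
            raise ValueError("envelope_id must be non-negative")
        if not trace_ids:
            return 0
        known = {
            r[0]
            for r in self._db.execute(
                "SELECT trace_id FROM traces WHERE trace_id IN (%s)"
                % ",".join("?" * len(trace_ids)),
                list(trace_ids),
            )
        }
        bad = sorted(set(trace_ids) - known)
        if bad:
            raise KeyError(f"unknown trace ids: {bad}")
        self._db.executemany(
            "UPDATE traces SET envelope_id = ? WHERE trace_id = ?",
            [(envelope_id, t) for t in trace_ids],
        )
        self._db.commit()
        return len(trace_ids)

    def segmentation_for(self, point_ids: Sequence[int]) -> Dict[int, Tuple[int, int]]:
        """point id -> (trace_id, envelope_id); unassigned ids are absent."""
        out: Dict[int, Tuple[int, int]] = {}
        ids = list(point_ids)
        for i in range(0, len(ids), 500):
            chunk = ids[i : i + 500]
            for pid, tid, eid in self._db.execute(
                "SELECT pt.point_id, pt.trace_id, t.envelope_id "
                "FROM point_trace pt JOIN traces t USING (trace_id) "
                "WHERE pt.point_id IN (%s)" % ",".join("?" * len(chunk)),
                chunk,
            ):
                out[pid] = (tid, eid)
        return out


@dataclass
class StoreConfig:
    """User-facing store limits. ``memory_limit`` bounds the point cache at
    ``CACHE_FRACTION`` of its value; at least 1 GiB is the assumed default."""

    memory_limit: int = DEFAULT_MEMORY_LIMIT
    use_cache: bool = True

    @property
    def cache_bytes(self) -> int:
        return int(self.memory_limit * CACHE_FRACTION) if self.use_cache else 0


class MzStore:
    """A built store: point file + metadata + index + cache, queryable."""

    POINTS_NAME = "points.bin"
    META_NAME = "meta.sqlite"

    def __init__(
        self,
        directory: os.PathLike,
        config: StoreConfig = StoreConfig(),
        stride_length: int = DEFAULT_STRIDE,
    ):
        self.directory = Path(directory)
        self.config = config
        self.stride_length = stride_length
        self.points = PointFile(self.directory / self.POINTS_NAME)
        self.meta = MetadataStore(self.directory / self.META_NAME)
        self.root = self.meta.load_tree()
        self.cache = PointCache(config.cache_bytes) if config.use_cache else None

    # -- construction ------------------------------------------------------

    @classmethod
    def build(
        cls,
        points: Iterable[MsPoint],
        directory: os.PathLike,
        params: BuildParams = BuildParams(),
        config: StoreConfig = StoreConfig(),
    ) -> "MzStore":
        """Index a point cloud and persist it under ``directory``.

        Provisional ids are remapped to final record indices; points
        carrying non-zero trace/envelope ids seed the segmentation tables.
        """
        pts = [p.with_id(i) for i, p in enumerate(points)]
        if not pts:
            raise ValueError("cannot build a store from zero points")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        root = build_tree(pts, params)
        leaves = iter_leaves(root)
        by_id = {p.id: p for p in pts}
        id_map, blocks = write_point_file(
            [[by_id[i] for i in leaf.point_ids] for leaf in leaves],
            directory / cls.POINTS_NAME,
        )
        for leaf, block in zip(leaves, blocks):
            leaf.leaf_block = block
        for node in _all_nodes(root):
            node.point_ids = [id_map[i] for i in node.point_ids]

        meta_path = directory / cls.META_NAME
        if meta_path.exists():
            meta_path.unlink()
        meta = MetadataStore(meta_path)
        meta.set_meta("point_count", str(len(pts)))
        meta.set_meta("leaf_capacity", str(params.leaf_capacity))
        meta.set_meta("branching", str(params.branching))
        meta.set_meta("stride_length", str(params.stride_length))
        meta.save_tree(root)

        by_trace: Dict[int, List[int]] = {}
        trace_env: Dict[int, int] = {}
        for p in pts:
            if p.trace_id > 0:
                by_trace.setdefault(p.trace_id, []).append(id_map[p.id])
                if p.envelope_id > 0:
                    trace_env[p.trace_id] = p.envelope_id
        for tid, ids in by_trace.items():
            meta.assign_trace(ids, tid)
        for tid, eid in trace_env.items():
            meta.assign_envelope([tid], eid)
        meta.close()
        store = cls(directory, config)
        store.stride_length = params.stride_length
        return store

    @classmethod
    def open(
        cls, directory: os.PathLike, config: StoreConfig = StoreConfig()
    ) -> "MzStore":
        store = cls(directory, config)
        stride = store.meta.get_meta("stride_length")
        if stride is not None:
            store.stride_length = int(stride)
        return store

    def close(self) -> None:
        self.points.close()
        self.meta.close()

    def __enter__(self) -> "MzStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- queries -----------------------------------------------------------

    @property
    def bounds(self) -> DataBounds:
        return self.root.bounds

    def _resolve(self, ids: Sequence[int]) -> List[MsPoint]:
        return cache_fetch(self.cache, ids, self.points)

    def query(
        self, window: QueryWindow, stats: Optional[QueryStats] = None
    ) -> List[MsPoint]:
        """Window query with current segmentation attached to each point."""
        raw = query(
            self.root, window, self._resolve,
            stride_length=self.stride_length, stats=stats,
        )
        seg = self.meta.segmentation_for([p.id for p in raw])
        return [
            p.with_segmentation(*seg[p.id]) if p.id in seg else p for p in raw
        ]

    # -- segmentation passthrough ------------------------------------------

    def assign_trace(self, point_ids: Sequence[int], trace_id: int) -> int:
        return self.meta.assign_trace(point_ids, trace_id)

    def assign_envelope(self, trace_ids: Sequence[int], envelope_id: int) -> int:
        return self.meta.assign_envelope(trace_ids, envelope_id)


def _all_nodes(root: TreeNode) -> List[TreeNode]:
    out = [root]
    for i, node in enumerate(out):
        out.extend(node.children)
    return out
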