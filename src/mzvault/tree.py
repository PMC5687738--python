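"""Alternating-axis spatial index over LC-MS points.

The tree is bulk-loaded in the Sort-Tile-Recursive style: a node holding
more than ``leaf_capacity`` points sorts its data on the current axis
(levels alternate RT <-> m/z, starting with RT so the first level can be
assembled scan by scan), splits it into ``branching`` contiguous chunks of
equal cardinality (equal point volume, not equal data range), and recurses
with the axis flipped. A node holding at most ``leaf_capacity`` points is
a leaf and keeps all of its point ids. Every internal node stores a
weighted-striding summary (at most ``leaf_capacity`` point ids) drawn from
its children's point-id lists, so each level of the tree is a progressively
coarser, deterministic sketch of the data underneath it.

Budgeted queries descend breadth-first, level by level, counting the
in-window points among the intersecting nodes' summaries, and stop at the
first level that can supply the requested cardinality (or at the leaves,
where every in-window point is returned). The gathered candidates are then
weighted-strided down to the budget, so repeated queries always return the
identical set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .model import DataBounds, MsPoint, QueryWindow, extent
from .summarize import DEFAULT_STRIDE, weighted_stride

__all__ = [
    "BuildParams",
    "TreeNode",
    "QueryStats",
    "build_tree",
    "partition",
    "query",
    "iter_leaves",
    "iter_nodes",
]

AXIS_RT = True  # sort flag: True = RT, False = m/z


@dataclass(frozen=True)
class BuildParams:
    """Bulk-load parameters.

    ``leaf_capacity`` (p) is both the maximum points per leaf and the
    summary size of internal nodes; ``branching`` (b) the fan-out;
    ``initial_sort`` the axis of the first split (RT by default).
    Defaults p=1000, b=4 give a five-level tree on a million-point run.
    """

    leaf_capacity: int = 1000
    branching: int = 4
    initial_sort: bool = AXIS_RT
    stride_length: int = DEFAULT_STRIDE

    def __post_init__(self) -> None:
        if self.leaf_capacity < 1:
            raise ValueError("leaf_capacity must be >= 1")
        if self.branching < 2:
            raise ValueError("branching must be >= 2")


@dataclass
class TreeNode:
    """Rectangular (m/z x RT) region with children or a leaf block.

    ``point_ids`` holds every point of the partition for a leaf, and a
    weighted-striding summary of at most ``leaf_capacity`` ids for an
    internal node. ``leaf_block`` is the (byte offset, count) of the leaf's
    contiguous record range in the point file, set at persistence time.
    """

    node_id: int
    bounds: DataBounds
    children: List["TreeNode"] = field(default_factory=list)
    point_ids: List[int] = field(default_factory=list)
    leaf_block: Optional[Tuple[int, int]] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class QueryStats:
    """Instrumentation for one query: nodes examined during traversal."""

    nodes_visited: int = 0


def partition(sorted_points: Sequence, branching: int) -> List[Sequence]:
    """Split an axis-sorted sequence into <= b contiguous equal-size chunks.

    Chunk size is ceil(n / b); the last chunk may be smaller. Concatenating
    the chunks reproduces the input.
    """
    if branching < 2:
        raise ValueError("branching must be >= 2")
    n = len(sorted_points)
    size = -(-n // branching)  # ceil
    return [sorted_points[i : i + size] for i in range(0, n, size)]


def _sort_key(axis_rt: bool) -> Callable[[MsPoint], Tuple[float, float, int]]:
    if axis_rt:
        return lambda p: (p.rt, p.mz, p.id)
    return lambda p: (p.mz, p.rt, p.id)


def build_tree(points: Sequence[MsPoint], params: BuildParams = BuildParams()) -> TreeNode:
    """Bulk-load the index over ``points`` (each with a unique id).

    Node ids are assigned in depth-first construction order, root = 0, so
    the tree shape and every summary are a pure function of the input and
    parameters.
    """
    pts = list(points)
    if not pts:
        raise ValueError("cannot build an index over an empty point set")
    ids = set()
    for p in pts:
        if p.id in ids:
            raise ValueError(f"duplicate point id {p.id}")
        ids.add(p.id)

    by_id: Dict[int, MsPoint] = {p.id: p for p in pts}
    counter = [0]

    def divide(data: Sequence[MsPoint], axis_rt: bool) -> TreeNode:
        node = TreeNode(node_id=counter[0], bounds=extent(data))
        counter[0] += 1
        if len(data) <= params.leaf_capacity:
            node.point_ids = [p.id for p in data]
            return node
        ordered = sorted(data, key=_sort_key(axis_rt))
        bounds = None
        for chunk in partition(ordered, params.branching):
            child = divide(chunk, not axis_rt)
            bounds = child.bounds if bounds is None else bounds.union(child.bounds)
            node.children.append(child)
        node.bounds = bounds
        pooled = [by_id[i] for c in node.children for i in c.point_ids]
        node.point_ids = [
            p.id
            for p in weighted_stride(pooled, params.leaf_capacity, params.stride_length)
        ]
        return node

    return divide(pts, params.initial_sort)


def iter_nodes(root: TreeNode):
    """Yield every node, breadth-first."""
    frontier = [root]
    while frontier:
        nxt: List[TreeNode] = []
        for node in frontier:
            yield node
            nxt.extend(node.children)
        frontier = nxt


def iter_leaves(root: TreeNode) -> List[TreeNode]:
    """Leaves in left-to-right order (the point file's layout order)."""
    out: List[TreeNode] = []

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            out.append(node)
        else:
            for c in node.children:
                walk(c)

    walk(root)
    return out


Resolver = Callable[[Sequence[int]], List[MsPoint]]


def _result_key(p: MsPoint) -> Tuple[float, float, int]:
    return (p.mz, p.rt, p.id)


def query(
    root: TreeNode,
    window: QueryWindow,
    resolver: Resolver,
    stride_length: int = DEFAULT_STRIDE,
    stats: Optional[QueryStats] = None,
) -> List[MsPoint]:
    """Answer a window query, optionally bounded to ``window.n`` points.

    Without a budget the result is exactly the stored points inside the
    window. With a budget the traversal is level-synchronous breadth-first:
    only in-window summary points count toward the budget, leaves
    encountered early stay in the frontier with their full point lists, and
    the first level supplying >= n candidates is resampled down to n with
    weighted striding. Results are sorted ascending (mz, rt, id).
    """
    if stats is None:
        stats = QueryStats()
    if not window.intersects(root.bounds):
        return []

    if window.n is None:
        hits: List[MsPoint] = []
        frontier = [root]
        stats.nodes_visited += 1
        while frontier:
            nxt: List[TreeNode] = []
            for node in frontier:
                if node.is_leaf:
                    hits.extend(
                        p for p in resolver(node.point_ids) if window.contains(p)
                    )
                else:
                    for c in node.children:
                        if window.intersects(c.bounds):
                            stats.nodes_visited += 1
                            nxt.append(c)
            frontier = nxt
        hits.sort(key=_result_key)
        return hits

    budget = window.n
    frontier = [root]
    stats.nodes_visited += 1
    while True:
        candidates: List[MsPoint] = []
        for node in frontier:
            candidates.extend(
                p for p in resolver(node.point_ids) if window.contains(p)
            )
        all_leaves = all(node.is_leaf for node in frontier)
        if len(candidates) >= budget or all_leaves:
            break
        nxt = []
        for node in frontier:
            if node.is_leaf:
                nxt.append(node)  # keeps contributing its full point list
            else:
                for c in node.children:
                    if window.intersects(c.bounds):
                        stats.nodes_visited += 1
                        nxt.append(c)
        frontier = nxt

    candidates.sort(key=_result_key)
    if len(candidates) > budget:
        candidates = weighted_stride(candidates, budget, stride_length)
    return candidates
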