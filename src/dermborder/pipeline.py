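"""Shingled partitioning, iterative min-id label negotiation, and merging.

This is the parallel redesign of the serial scanner as a set of independent
per-partition computations:

1. **Shingled partitioning** — the image is tiled by non-overlapping *core*
   rectangles; each partition's working view extends ``2*eps + 1`` pixels
   past its core to the right and bottom (the *lap* region), clipped at the
   image boundary.  Every pixel within ε of a core boundary therefore has
   its complete ε-neighbourhood visible in at least one partition.

2. **Label negotiation** — inside each partition every node starts with its
   own global pid as cluster id C and repeatedly adopts the minimum C among
   the locally dense members of its ε-neighbourhood (a dense node includes
   itself).  The sweep is Jacobi-style: all reads see the previous
   iteration, so one scan is deterministic and schedule-independent.  The
   loop stops when a scan leaves the labels (and hence their checksum)
   unchanged; on a path-shaped cluster the number of scans is governed by
   ``ceil(longest_path_pixels / eps)`` plus the confirming scan.

3. **Transitive merge** — pixels inside lap regions are observed by several
   partitions.  For every *globally dense* pixel, all cluster ids it
   received are unified with union-find (smallest id wins); border pixels
   are attributed afterwards to the adjacent cluster with the smallest
   canonical id.  Restricting unification to dense pixels is what keeps two
   clusters that merely share a border node from being merged, so the final
   labeling is identical to :func:`dermborder.density.dbscan_serial`.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .density import (
    BIG,
    NO_LABEL,
    NOISE,
    ClusterMap,
    diamond_footprint,
    finalize_cluster_map,
    neighbor_counts,
)
from .image import Params

__all__ = [
    "GlobalNodeList",
    "LocalNodeList",
    "Partition",
    "create_partitions",
    "initial_state",
    "merge_partitions",
    "process_partition",
    "run_pipeline",
    "run_pipeline_detailed",
    "scan_once",
]


@dataclass
class Partition:
    """One shingle: a core rectangle plus its right/bottom lap region.

    ``view`` is the node mask restricted to core + lap; ``x_off``/``y_off``
    are the global coordinates of the core origin, so global pids of view
    pixels can be reconstructed from ``img_w``.
    """

    x_off: int
    y_off: int
    core_w: int
    core_h: int
    view: np.ndarray
    img_w: int
    img_h: int
    eps: int

    @property
    def view_h(self) -> int:
        return self.view.shape[0]

    @property
    def view_w(self) -> int:
        return self.view.shape[1]

    def pid_grid(self) -> np.ndarray:
        """Global pids of every view pixel."""
        ys = self.y_off + np.arange(self.view_h, dtype=np.int64)
        xs = self.x_off + np.arange(self.view_w, dtype=np.int64)
        return ys[:, None] * self.img_w + xs[None, :]


def create_partitions(
    mask: np.ndarray,
    core_width: int,
    core_height: int,
    eps: int,
    lap: int | None = None,
) -> list[Partition]:
    """Tile a mask into ceil(w/cw) x ceil(h/ch) shingles, row-major.

    The core rectangles tile the image exactly; each view extends ``lap``
    (default ``2*eps + 1``) pixels past the core to the right and bottom,
    clipped to the image.  ``lap`` is overridable only to demonstrate that
    narrower laps break serial equivalence; production code uses the
    default.
    """
    if core_width < 1 or core_height < 1:
        raise ValueError("core partition size must be positive")
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if lap is None:
        lap = 2 * int(eps) + 1
    parts = []
    for row in range(math.ceil(h / core_height)):
        for col in range(math.ceil(w / core_width)):
            x0, y0 = col * core_width, row * core_height
            cw, ch = min(core_width, w - x0), min(core_height, h - y0)
            x1, y1 = min(w, x0 + cw + lap), min(h, y0 + ch + lap)
            parts.append(
                Partition(
                    x_off=x0,
                    y_off=y0,
                    core_w=cw,
                    core_h=ch,
                    view=mask[y0:y1, x0:x1].copy(),
                    img_w=w,
                    img_h=h,
                    eps=int(eps),
                )
            )
    return parts


@dataclass
class LocalNodeList:
    """Per-partition negotiation state: one cluster id C per node pixel.

    ``labels`` holds the current C per view pixel (``BIG`` on non-nodes),
    ``dense`` flags the locally dense nodes, and ``iterations`` is the
    number of scans the negotiation loop ran (including the final scan that
    confirmed convergence).
    """

    partition: Partition
    labels: np.ndarray
    dense: np.ndarray
    iterations: int = 0

    @property
    def checksum(self) -> int:
        """Sum of C over all nodes — the convergence checksum."""
        return int(self.labels[self.partition.view].sum())

    @property
    def node_pids(self) -> np.ndarray:
        return self.partition.pid_grid()[self.partition.view]

    @property
    def node_labels(self) -> np.ndarray:
        return self.labels[self.partition.view]

    @property
    def node_dense(self) -> np.ndarray:
        return self.dense[self.partition.view]


def initial_state(part: Partition, params: Params) -> LocalNodeList:
    """State with C = own global pid for every node in the view."""
    dense = part.view & (neighbor_counts(part.view, params.eps) >= params.min_pts)
    labels = np.where(part.view, part.pid_grid(), BIG)
    return LocalNodeList(partition=part, labels=labels, dense=dense)


def scan_once(part: Partition, state: LocalNodeList, params: Params) -> LocalNodeList:
    """One Jacobi sweep of the minimum-id negotiation.

    Every node with at least one locally dense ε-neighbour adopts the
    minimum C among those dense neighbours (dense nodes see themselves, so
    their own C participates); nodes with no dense neighbour are unchanged.
    All reads are against ``state``, never the values written this sweep.
    """
    dense_labels = np.where(state.dense, state.labels, BIG)
    nbr_min = ndimage.minimum_filter(
        dense_labels,
        footprint=diamond_footprint(params.eps),
        mode="constant",
        cval=BIG,
    )
    new = np.where(part.view & (nbr_min < BIG), nbr_min, state.labels)
    return replace(state, labels=new)


def process_partition(part: Partition, params: Params) -> LocalNodeList:
    """Iterate the scan until the checksum and labels stop changing.

    On return every density-connected group within the partition shares
    C = minimum pid of its locally dense members.  Termination is
    guaranteed: dense labels are pointwise non-increasing and bounded below
    by each region's minimum pid.  The reported iteration count includes
    the final confirming scan (the while-sums-differ loop counts the scan
    that detects the fixed point).
    """
    state = initial_state(part, params)
    iterations = 0
    while True:
        new = scan_once(part, state, params)
        iterations += 1
        # checksum comparison per the original scheme, hardened with
        # elementwise equality (sums can collide across labelings)
        if new.checksum == state.checksum and np.array_equal(new.labels, state.labels):
            state = new
            break
        state = new
    return replace(state, iterations=iterations)


class _DSU:
    """Union-find over cluster ids; the smallest id of a class is its root."""

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, a: int) -> int:
        parent = self.parent
        root = a
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(a, a) != a:  # path compression
            parent[a], a = root, parent[a]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        lo, hi = (ra, rb) if ra < rb else (rb, ra)
        self.parent[hi] = lo


@dataclass
class GlobalNodeList:
    """Merged labeling of the whole image, flat over pids.

    ``labels[pid]`` is the cluster id (minimum dense-member pid of the
    merged cluster), ``NOISE`` or ``NO_LABEL``; ``observers[pid]`` counts
    how many partitions observed the pixel (>1 inside lap regions).
    """

    labels: np.ndarray
    observers: np.ndarray
    img_w: int
    img_h: int

    def label_grid(self) -> np.ndarray:
        return self.labels.reshape(self.img_h, self.img_w)


def merge_partitions(
    locals_: list[LocalNodeList],
    parts: list[Partition] | None = None,
    eps: int | None = None,
) -> GlobalNodeList:
    """Fold per-partition labelings into one global labeling.

    A pixel is globally dense if any partition saw it as dense (the
    partition whose view contains its full neighbourhood always does).  All
    cluster ids observed for a globally dense pixel are unified; the
    transitive closure is taken by union-find with min-id roots.  Border
    pixels (non-dense, within ε of a dense pixel) are then attributed on
    the merged labeling to the adjacent cluster with the smallest canonical
    id — attribution must wait until after unification because a
    partition-local minimum compares pre-merge ids, whose order can differ
    from the canonical order.  The result is independent of the order of
    ``locals_``.
    """
    if not locals_:
        raise ValueError("no partitions to merge")
    del parts  # partition geometry travels with each LocalNodeList
    p0 = locals_[0].partition
    if eps is None:
        eps = p0.eps
    n = p0.img_w * p0.img_h

    observers = np.zeros(n, dtype=np.int16)
    dense_any = np.zeros(n, dtype=bool)
    nonnode_seen = np.zeros(n, dtype=bool)
    for lnl in locals_:
        pids = lnl.node_pids
        np.add.at(observers, pids, 1)
        dense_any[pids[lnl.node_dense]] = True
        part = lnl.partition
        nonnode_seen[part.pid_grid()[~part.view]] = True
    if np.any(nonnode_seen[observers > 0]):
        raise AssertionError(
            "partitioning bug: pixel observed as node in one view, non-node in another"
        )

    dsu = _DSU()
    first = np.full(n, -1, dtype=np.int64)
    for lnl in locals_:
        pids = lnl.node_pids
        labs = lnl.node_labels
        gd = dense_any[pids]
        for p, c in zip(pids[gd].tolist(), labs[gd].tolist()):
            if first[p] < 0:
                first[p] = c
                dsu.parent.setdefault(c, c)
            else:
                dsu.union(int(first[p]), c)

    labels = np.full(n, NO_LABEL, dtype=np.int64)
    labels[observers > 0] = NOISE
    dense_pids = np.nonzero(first >= 0)[0]
    canon = np.full(n, BIG, dtype=np.int64)
    canon[dense_pids] = np.fromiter(
        (dsu.find(int(first[p])) for p in dense_pids), dtype=np.int64, count=len(dense_pids)
    )
    labels[dense_pids] = canon[dense_pids]
    # border attribution on the merged labeling: smallest canonical id
    # among the clusters of dense ε-neighbours (same rule as the serial path)
    adj = ndimage.minimum_filter(
        canon.reshape(p0.img_h, p0.img_w),
        footprint=diamond_footprint(int(eps)),
        mode="constant",
        cval=BIG,
    ).reshape(n)
    border = (observers > 0) & ~dense_any & (adj < BIG)
    labels[border] = adj[border]
    return GlobalNodeList(labels=labels, observers=observers, img_w=p0.img_w, img_h=p0.img_h)


@dataclass
class PipelineDetails:
    """Run log of one partitioned execution."""

    grid: tuple[int, int]
    iterations: list[int] = field(default_factory=list)
    n_clusters: int = 0


def run_pipeline_detailed(
    mask: np.ndarray,
    params: Params,
    core_width: int = 256,
    core_height: int = 256,
    workers: int = 1,
    lap: int | None = None,
) -> tuple[ClusterMap, PipelineDetails]:
    """Partition, negotiate, merge — returning the run log alongside.

    Partition processing is embarrassingly parallel; with ``workers > 1`` a
    thread pool is used.  Results are collected by partition index, so the
    output is byte-identical for any worker count or execution order.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    parts = create_partitions(mask, core_width, core_height, params.eps, lap=lap)
    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            locals_ = list(pool.map(lambda p: process_partition(p, params), parts))
    else:
        locals_ = [process_partition(p, params) for p in parts]
    gnl = merge_partitions(locals_)
    cmap = finalize_cluster_map(ClusterMap(gnl.label_grid().copy()), params.min_pts)
    details = PipelineDetails(
        grid=(math.ceil(w / core_width), math.ceil(h / core_height)),
        iterations=[lnl.iterations for lnl in locals_],
        n_clusters=cmap.n_clusters,
    )
    return cmap, details


def run_pipeline(
    mask: np.ndarray,
    params: Params,
    core_width: int = 256,
    core_height: int = 256,
    workers: int = 1,
    lap: int | None = None,
) -> ClusterMap:
    """Full partitioned clustering; output equals :func:`dbscan_serial`."""
    cmap, _ = run_pipeline_detailed(
        mask, params, core_width=core_width, core_height=core_height, workers=workers, lap=lap
    )
    return cmap
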