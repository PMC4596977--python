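"""Manhattan-metric density clustering: region queries and the serial scanner.

The serial scanner is the reference algorithm for the whole package: the
partitioned pipeline in :mod:`dermborder.pipeline` must reproduce its output
exactly.  Clustering follows the classic density-based scheme:

* a node is *dense* (a core point) when its Manhattan ε-neighbourhood —
  a diamond of ``eps**2 + (eps + 1)**2`` cells — contains at least
  ``min_pts`` nodes, the node itself included;
* clusters are the connected components of dense nodes under ε-adjacency;
* a non-dense node within ε of a dense node joins a cluster as a border
  point; anything else is noise.

Border attribution is order-dependent in textbook implementations.  Here it
is made deterministic: a border node joins the candidate cluster with the
smallest canonical id (the minimum pid over the cluster's dense members).
The same rule governs the partitioned pipeline, so serial and partitioned
labelings are bit-comparable.

Cluster ids are canonicalized to the smallest pid of any member, noise is
the sentinel ``NOISE`` (-1) and non-node pixels carry ``NO_LABEL`` (-2).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import Params

__all__ = [
    "BIG",
    "NOISE",
    "NO_LABEL",
    "ClusterMap",
    "canonicalize_labels",
    "dbscan_serial",
    "diamond_footprint",
    "finalize_cluster_map",
    "manhattan_distance",
    "neighbor_counts",
    "region_query",
]

NOISE = -1
NO_LABEL = -2
#: sentinel larger than any pid; used as +infinity in minimum scans
BIG = np.int64(2**62)


def manhattan_distance(p, q) -> int:
    """|Δx| + |Δy| between two pixels given as (x, y[, pid]) tuples."""
    return abs(int(p[0]) - int(q[0])) + abs(int(p[1]) - int(q[1]))


def diamond_footprint(eps: int) -> np.ndarray:
    """Boolean (2·eps+1)² stencil of the Manhattan disc of radius eps."""
    r = np.arange(-eps, eps + 1)
    return (np.abs(r[:, None]) + np.abs(r[None, :])) <= eps


def diamond_offsets(eps: int, include_center: bool = False) -> list[tuple[int, int]]:
    """(dx, dy) offsets of the Manhattan disc, row-major order."""
    return [
        (dx, dy)
        for dy in range(-eps, eps + 1)
        for dx in range(-(eps - abs(dy)), eps - abs(dy) + 1)
        if include_center or (dx, dy) != (0, 0)
    ]


def neighbor_counts(mask: np.ndarray, eps: int) -> np.ndarray:
    """Per-pixel count of node pixels within Manhattan distance eps.

    Counts include the pixel itself when it is a node; pixels beyond the
    raster boundary contribute nothing (the disc is clipped).
    """
    mask = np.asarray(mask, dtype=bool)
    return ndimage.correlate(
        mask.astype(np.int32),
        diamond_footprint(int(eps)).astype(np.int32),
        mode="constant",
        cval=0,
    )


def region_query(center, mask: np.ndarray, eps: int) -> np.ndarray:
    """Pids of node pixels within Manhattan distance eps of ``center``.

    ``center`` is an (x, y[, pid]) tuple; it may itself be a non-node, in
    which case it is simply absent from the result.  Pids are returned in
    ascending (row-major) order.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    x, y = int(center[0]), int(center[1])
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"center ({x}, {y}) outside {w}x{h} raster")
    eps = int(eps)
    y0, y1 = max(0, y - eps), min(h, y + eps + 1)
    x0, x1 = max(0, x - eps), min(w, x + eps + 1)
    win = mask[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    hit = win & ((np.abs(xx - x) + np.abs(yy - y)) <= eps)
    return (yy[hit] * w + xx[hit]).astype(np.int64)


@dataclass
class ClusterMap:
    """Per-pixel cluster labels over a raster.

    ``labels[y, x]`` is the cluster id of a clustered node, ``NOISE`` for a
    noise node and ``NO_LABEL`` for a non-node pixel.  After
    :func:`canonicalize_labels` every cluster id equals the smallest pid
    among the cluster's members.
    """

    labels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def node_mask(self) -> np.ndarray:
        return self.labels != NO_LABEL

    def cluster_ids(self) -> np.ndarray:
        """Sorted distinct cluster ids (noise excluded)."""
        lab = self.labels[self.labels >= 0]
        return np.unique(lab)

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels >= 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids())

    def to_frame(self) -> pd.DataFrame:
        """Tabulate node pixels as columns x, y, pid, cluster_id."""
        h, w = self.labels.shape
        ys, xs = np.nonzero(self.node_mask)
        return pd.DataFrame(
            {
                "x": xs,
                "y": ys,
                "pid": ys * w + xs,
                "cluster_id": self.labels[ys, xs],
            }
        )


def _pid_grid(h: int, w: int) -> np.ndarray:
    return (np.arange(h, dtype=np.int64)[:, None] * w + np.arange(w, dtype=np.int64)[None, :])


def canonicalize_labels(cmap: ClusterMap) -> ClusterMap:
    """Relabel every cluster to the minimum pid among its members.

    Idempotent; noise and non-node pixels are untouched.
    """
    labels = cmap.labels.copy()
    clustered = labels >= 0
    if clustered.any():
        pid = _pid_grid(*labels.shape)
        uniq, inv = np.unique(labels[clustered], return_inverse=True)
        minpid = np.full(len(uniq), BIG, dtype=np.int64)
        np.minimum.at(minpid, inv, pid[clustered])
        labels[clustered] = minpid[inv]
    return ClusterMap(labels)


def finalize_cluster_map(cmap: ClusterMap, min_pts: int) -> ClusterMap:
    """Shared final step of both clustering routes.

    Demotes clusters with fewer than ``min_pts`` members to noise (the
    ClusterCount rule of the node-classification stage, applied here so both
    routes expose the same noise set) and canonicalizes the surviving labels
    to minimum member pid.
    """
    labels = cmap.labels.copy()
    clustered = labels >= 0
    if clustered.any():
        uniq, inv = np.unique(labels[clustered], return_inverse=True)
        sizes = np.bincount(inv)
        demote = sizes[inv] < min_pts
        vals = labels[clustered]
        vals[demote] = NOISE
        labels[clustered] = vals
    return canonicalize_labels(ClusterMap(labels))


def dbscan_serial(mask: np.ndarray, params: Params) -> ClusterMap:
    """Serial density-based clustering of a node mask.

    Unvisited nodes are visited in ascending pid order; a dense node starts
    a cluster that is grown by breadth-first expansion (every node within ε
    of a dense member joins; only dense members expand further).  Nodes
    provisionally treated as noise are re-promoted to border points when a
    later expansion reaches them.  Border nodes are then re-attributed to
    the candidate cluster with the smallest canonical id, sub-``min_pts``
    clusters are demoted, and labels are canonicalized.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    eps, min_pts = params.eps, params.min_pts
    dense = mask & (neighbor_counts(mask, eps) >= min_pts)
    offs = diamond_offsets(eps)

    cluster_of = np.full((h, w), -1, dtype=np.int64)
    n_clusters = 0
    ys, xs = np.nonzero(mask)  # row-major => ascending pid visit order
    for y0, x0 in zip(ys.tolist(), xs.tolist()):
        if not dense[y0, x0] or cluster_of[y0, x0] != -1:
            continue
        cid = n_clusters
        n_clusters += 1
        cluster_of[y0, x0] = cid
        queue = deque([(x0, y0)])
        while queue:
            x, y = queue.popleft()
            if not dense[y, x]:
                continue  # border members join but do not expand
            for dx, dy in offs:
                nx, ny = x + dx, y + dy
                if 0 <= nx < w and 0 <= ny < h and mask[ny, nx] and cluster_of[ny, nx] == -1:
                    cluster_of[ny, nx] = cid
                    queue.append((nx, ny))

    pid = _pid_grid(h, w)
    labels = np.full((h, w), NO_LABEL, dtype=np.int64)
    labels[mask] = NOISE
    if n_clusters:
        core_min = np.full(n_clusters, BIG, dtype=np.int64)
        np.minimum.at(core_min, cluster_of[dense], pid[dense])
        canon = np.full((h, w), BIG, dtype=np.int64)
        canon[dense] = core_min[cluster_of[dense]]
        # min canonical id among dense ε-neighbours: the border attribution rule
        adj = ndimage.minimum_filter(
            canon, footprint=diamond_footprint(eps), mode="constant", cval=BIG
        )
        border = mask & ~dense & (adj < BIG)
        labels[dense] = canon[dense]
        labels[border] = adj[border]
    return finalize_cluster_map(ClusterMap(labels), min_pts)
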