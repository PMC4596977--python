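"""Core/border/noise node classification and border overlay rendering.

The classification follows the three node categories of density scanning:
a *core* node has a dense ε-neighbourhood (>= min_pts nodes, itself
included); a *border* node sits inside the neighbourhood of a core node
without being dense itself; a *noise* node is neither.  The tests are
applied in the order of the reference procedure: a node whose cluster holds
fewer than ``min_pts`` members is noise regardless of its own density, then
neighbourhood density separates border from core.

Border nodes traced around the detected lesion are the delivered "border";
rendering paints them onto a copy of the dermoscopy image in a
high-contrast colour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .density import NOISE, ClusterMap, neighbor_counts
from .image import Params

__all__ = [
    "NodeClassification",
    "classification_to_frame",
    "classify_nodes",
    "lesion_region_mask",
    "read_label_png",
    "render_overlay",
    "write_label_png",
]


@dataclass
class NodeClassification:
    """Disjoint boolean rasters partitioning the node set."""

    core: np.ndarray
    border: np.ndarray
    noise: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {
            "core": int(self.core.sum()),
            "border": int(self.border.sum()),
            "noise": int(self.noise.sum()),
        }

    def class_grid(self) -> np.ndarray:
        """Per-pixel class codes: '' outside, else core/border/noise."""
        grid = np.full(self.core.shape, "", dtype=object)
        grid[self.core] = "core"
        grid[self.border] = "border"
        grid[self.noise] = "noise"
        return grid


def classify_nodes(cmap: ClusterMap, mask: np.ndarray, params: Params) -> NodeClassification:
    """Classify every node as core, border or noise.

    For each node: cluster size < min_pts -> noise; else neighbourhood count
    < min_pts -> border; else core.  Nodes already labelled noise in the
    cluster map stay noise (their "cluster" is a singleton).
    """
    mask = np.asarray(mask, dtype=bool)
    if cmap.labels.shape != mask.shape:
        raise ValueError("cluster map and mask dimensions disagree")
    labels = cmap.labels
    counts = neighbor_counts(mask, params.eps)

    size_of = np.zeros(mask.shape, dtype=np.int64)
    clustered = labels >= 0
    if clustered.any():
        uniq, inv = np.unique(labels[clustered], return_inverse=True)
        size_of[clustered] = np.bincount(inv)[inv]

    noise = mask & ((labels == NOISE) | (clustered & (size_of < params.min_pts)))
    border = mask & ~noise & (counts < params.min_pts)
    core = mask & ~noise & ~border
    return NodeClassification(core=core, border=border, noise=noise)


def render_overlay(
    image: np.ndarray,
    cls: NodeClassification,
    border_color: tuple[int, int, int] = (0, 255, 0),
    core_color: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Copy of the image with border (and optionally core) nodes painted.

    Noise pixels are never touched.  Pure green default gives high contrast
    against the browns and reds of dermoscopy imagery.
    """
    image = np.asarray(image)
    if image.shape[:2] != cls.core.shape:
        raise ValueError(
            f"image shape {image.shape[:2]} does not match classification {cls.core.shape}"
        )
    out = image.copy()
    if core_color is not None:
        out[cls.core] = core_color
    out[cls.border] = border_color
    return out


def lesion_region_mask(
    cls: NodeClassification, cmap: ClusterMap, mode: str = "largest_cluster"
) -> np.ndarray:
    """Binary mask of the detected lesion region: core ∪ border pixels.

    ``largest_cluster`` keeps only the cluster with the most members (ties
    broken by smaller cluster id) — dermoscopy images contain one dominant
    lesion; ``all_clusters`` keeps every cluster.
    """
    if mode not in {"largest_cluster", "all_clusters"}:
        raise ValueError(f"unknown mode {mode!r}")
    region = cls.core | cls.border
    if mode == "all_clusters" or not region.any():
        return region
    ids, sizes = np.unique(cmap.labels[region], return_counts=True)
    best = ids[np.lexsort((ids, -sizes))[0]]  # max size, then min id
    return region & (cmap.labels == best)


def classification_to_frame(cls: NodeClassification, cmap: ClusterMap) -> pd.DataFrame:
    """Tabulate nodes as x, y, pid, cluster_id, class (CSV-ready)."""
    frame = cmap.to_frame()
    grid = cls.class_grid()
    frame["class"] = [grid[y, x] for x, y in zip(frame["x"], frame["y"])]
    return frame


def write_label_png(path: str | Path, cmap: ClusterMap) -> None:
    """Store cluster labels losslessly as a 32-bit-per-pixel PNG.

    PNG grayscale tops out at 16 bits and has no signed variant, so each
    int32 label (including the negative noise/non-node sentinels) is packed
    little-endian into the four RGBA bytes of one pixel.
    """
    packed = cmap.labels.astype("<i4").view(np.uint8)
    h, w = cmap.labels.shape
    Image.fromarray(packed.reshape(h, w, 4), mode="RGBA").save(Path(path))


def read_label_png(path: str | Path) -> ClusterMap:
    arr = np.asarray(Image.open(Path(path)).convert("RGBA"), dtype=np.uint8)
    labels = arr.reshape(arr.shape[0], -1).view("<i4").astype(np.int64)
    return ClusterMap(labels)
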