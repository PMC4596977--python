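"""Deterministic synthetic fixtures: masks, lesion images, adversarial shapes.

Everything the pipeline consumes can be generated here with no external
data.  All generators are pure functions of a :class:`FixtureSpec` — the
same spec always yields bit-identical output.

* ``random_mask`` — i.i.d. Bernoulli node raster, for oracle-equivalence
  sweeps.
* ``lesion_blob`` — a dermoscopy-like image: one dark, irregular, connected
  lesion on lighter skin plus isolated dark salt pixels, together with the
  clean lesion mask as ground truth.  The generator models only what the
  method consumes (a dark connected region and isolated noise), not
  photorealism.
* ``serpentine_path`` — a one-pixel-wide winding path, the worst case for
  the iterative minimum-id negotiation: with ε = 1 the label must crawl the
  whole path, one pixel per scan.
* ``split_cluster`` — a single cluster crossing every partition boundary,
  forcing maximal merge activity.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FixtureSpec",
    "make_lesion_image",
    "make_random_mask",
    "make_serpentine",
    "make_split_cluster",
    "serpentine_width",
]

#: extract_nodes threshold at which lesion_blob images decompose exactly
#: into ground-truth blob plus salt (blue <= this on nodes, > on skin)
LESION_THRESHOLD = 128
#: minimum Manhattan separation of salt pixels from the blob and each other;
#: keeps them isolated (neighbourhood count 1) for any eps <= 4
_SALT_GAP = 5


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture; identical spec => identical bytes."""

    kind: str
    seed: int = 0
    width: int = 64
    height: int = 64
    density: float = 0.5
    irregularity: float = 0.5
    noise_rate: float = 0.0
    path_length: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


def make_random_mask(spec: FixtureSpec) -> np.ndarray:
    """Each pixel is independently a node with probability ``density``."""
    if not 0.0 <= spec.density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {spec.density}")
    rng = np.random.default_rng(spec.seed)
    return rng.random((spec.height, spec.width)) < spec.density


def make_lesion_image(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic dermoscopy image plus its ground-truth lesion mask.

    The lesion is the largest 4-connected component of a thresholded field
    (radial bump plus smoothed noise scaled by ``irregularity``), opened
    with a 3x3 cross so every lesion pixel keeps a dense neighbourhood, and
    hole-filled.  Lesion pixels get low blue values, skin high ones, so
    ``extract_nodes(image, "B", 128)`` recovers blob ∪ salt exactly.  Salt
    pixels are kept at Manhattan distance >= 5 from the blob and from each
    other, so each is an isolated node (count 1) for the default ε.
    """
    if spec.irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy = h / 2 + rng.uniform(-h / 16, h / 16)
    cx = w / 2 + rng.uniform(-w / 16, w / 16)
    r = np.hypot((yy - cy) / (h / 2), (xx - cx) / (w / 2))
    field = 1.0 - r
    noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 10)
    std = noise.std()
    if std > 0:
        field = field + spec.irregularity * 0.5 * (noise / std)

    blob = field >= np.quantile(field, 0.75)  # ~25% of the frame is lesion
    cross = ndimage.generate_binary_structure(2, 1)  # 3x3 cross (4-connectivity)
    blob = ndimage.binary_opening(blob, structure=cross)
    labeled, n = ndimage.label(blob, structure=cross)
    if n > 1:
        sizes = ndimage.sum_labels(blob, labeled, index=np.arange(1, n + 1))
        blob = labeled == (1 + int(np.argmax(sizes)))
    blob = ndimage.binary_fill_holes(blob)

    # paint: skin-toned background, dark lesion; blue channel carries the signal
    image = np.empty((h, w, 3), dtype=np.uint8)
    jitter = rng.integers(-10, 11, size=(h, w, 3))
    image[:, :, 0] = np.clip(200 + jitter[:, :, 0], 0, 255)
    image[:, :, 1] = np.clip(160 + jitter[:, :, 1], 0, 255)
    image[:, :, 2] = np.clip(175 + jitter[:, :, 2], LESION_THRESHOLD + 20, 255)
    lesion_rgb = np.stack(
        [
            np.clip(110 + jitter[:, :, 0], 0, 255),
            np.clip(70 + jitter[:, :, 1], 0, 255),
            np.clip(80 + jitter[:, :, 2], 0, LESION_THRESHOLD - 20),
        ],
        axis=-1,
    )
    image[blob] = lesion_rgb[blob]

    if spec.noise_rate > 0:
        far = ndimage.distance_transform_cdt(~blob, metric="taxicab") >= _SALT_GAP
        cand = np.flatnonzero(far)
        rng.shuffle(cand)
        target = int(round(spec.noise_rate * h * w))
        chosen: list[tuple[int, int]] = []
        for idx in cand.tolist():
            if len(chosen) >= target:
                break
            y, x = divmod(idx, w)
            if all(abs(y - cy_) + abs(x - cx_) >= _SALT_GAP for cy_, cx_ in chosen):
                chosen.append((y, x))
        for y, x in chosen:
            image[y, x] = (90, 60, 70)

    return image, blob


def serpentine_width(path_length: int) -> int:
    """Default coil width: a near-square winding like the worst-case figure."""
    return max(2, round(math.sqrt(path_length)))


def make_serpentine(spec: FixtureSpec) -> np.ndarray:
    """One-pixel-wide boustrophedon path of exactly ``path_length`` nodes.

    Horizontal runs of ``spec.width`` pixels on even rows, joined by single
    connector pixels on odd rows at alternating ends.  Consecutive path
    pixels are 4-adjacent; non-consecutive pixels are at Manhattan distance
    >= 2, so with ε = 1 a label can only travel along the path.  The path
    starts at (0, 0): pid 0 is the minimum pid and sits at one end.
    """
    length = spec.path_length
    if length < 1:
        raise ValueError("path_length must be >= 1")
    run = spec.width
    if run < 1:
        raise ValueError("serpentine needs width >= 1")
    pts: list[tuple[int, int]] = []
    y, rightward = 0, True
    while len(pts) < length:
        cols = range(run) if rightward else range(run - 1, -1, -1)
        for x in cols:
            pts.append((y, x))
            if len(pts) == length:
                break
        if len(pts) < length:
            pts.append((y + 1, pts[-1][1]))  # connector below the run's last pixel
            y += 2
            rightward = not rightward
    max_y = max(p[0] for p in pts)
    if max_y >= spec.height or run > spec.width:
        raise ValueError(
            f"path of {length} pixels does not fit a {spec.width}x{spec.height} raster"
        )
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for py, px in pts:
        mask[py, px] = True
    return mask


def make_split_cluster(
    spec: FixtureSpec, core_width: int, core_height: int, eps: int
) -> np.ndarray:
    """A single connected cluster crossing every partition boundary.

    A two-pixel-thick plus sign spanning the full image crosses each
    vertical boundary (via the horizontal bar) and each horizontal boundary
    (via the vertical bar); seeded bumps along the bars vary the local
    labels every partition must reconcile.
    """
    h, w = spec.height, spec.width
    if w <= core_width and h <= core_height:
        raise ValueError("raster must be larger than one partition")
    del eps  # the plus shape crosses boundaries regardless of lap width
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((h, w), dtype=bool)
    mask[h // 2 : h // 2 + 2, :] = True
    mask[:, w // 2 : w // 2 + 2] = True
    for _ in range(max(4, (h + w) // 16)):  # bumps attached to the bars
        if rng.random() < 0.5:
            x = int(rng.integers(0, max(1, w - 3)))
            y0 = h // 2 - 2 if rng.random() < 0.5 else h // 2 + 2
            mask[max(0, y0) : max(0, y0) + 2, x : x + 3] = True
        else:
            y = int(rng.integers(0, max(1, h - 3)))
            x0 = w // 2 - 2 if rng.random() < 0.5 else w // 2 + 2
            mask[y : y + 3, max(0, x0) : max(0, x0) + 2] = True
    return mask
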