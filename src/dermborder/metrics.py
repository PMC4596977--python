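"""Segmentation accuracy: XOR border error, precision and recall.

The disagreement measure is the XOR border error

    error = 100 * |A ⊕ M| / |M|

where A is the automatic lesion mask, M the manual (ground-truth) mask and
⊕ the pixelwise symmetric difference: the area mis-segmented in either
direction, normalised by the manual lesion area.  It is zero only when the
masks are identical and can exceed 100% under gross over-segmentation.
Precision and recall are the usual pixelwise tp/(tp+fp) and tp/(tp+fn)
with the manual mask as truth, computed on filled lesion *regions* rather
than one-pixel contours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EvalReport", "batch_report", "evaluate_masks"]


@dataclass(frozen=True)
class EvalReport:
    """Pixelwise confusion counts and the derived accuracy measures."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def border_error_pct(self) -> float:
        return 100.0 * (self.fp + self.fn) / (self.tp + self.fn)

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn)


def evaluate_masks(auto: np.ndarray, manual: np.ndarray) -> EvalReport:
    """Compare an automatic lesion mask against a manual one.

    Raises on dimension mismatch and on an empty manual mask (the border
    error is undefined without a reference lesion area).
    """
    auto = np.asarray(auto, dtype=bool)
    manual = np.asarray(manual, dtype=bool)
    if auto.shape != manual.shape:
        raise ValueError(f"mask shapes differ: {auto.shape} vs {manual.shape}")
    if not manual.any():
        raise ValueError("manual mask is empty: border error undefined")
    tp = int(np.count_nonzero(auto & manual))
    fp = int(np.count_nonzero(auto & ~manual))
    fn = int(np.count_nonzero(~auto & manual))
    tn = int(auto.size - tp - fp - fn)
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn)


def batch_report(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-image rows (id, border error, precision, recall) plus means.

    The final row, labelled ``mean``, carries the unweighted means of the
    three measures across images.
    """
    if not pairs:
        raise ValueError("batch_report needs at least one (auto, manual) pair")
    if ids is None:
        ids = [str(i + 1) for i in range(len(pairs))]
    rows = []
    for image_id, (auto, manual) in zip(ids, pairs):
        rep = evaluate_masks(auto, manual)
        rows.append(
            {
                "image_id": image_id,
                "border_error_pct": rep.border_error_pct,
                "precision": rep.precision,
                "recall": rep.recall,
            }
        )
    frame = pd.DataFrame(rows)
    means = frame[["border_error_pct", "precision", "recall"]].mean()
    frame.loc[len(frame)] = {"image_id": "mean", **means.to_dict()}
    return frame
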