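"""Voxel-overlap metrics and surface-deviation analysis.

The three overlap metrics compare the ground-truth voxel set ``V_gt`` with
the segmented voxel set ``V_seg``::

    DSC = 2 |V_gt ∩ V_seg| / (|V_gt| + |V_seg|)
    SEN =   |V_gt ∩ V_seg| / |V_gt|
    IOU =   |V_gt ∩ V_seg| / |V_gt ∪ V_seg|

Higher is better for all three. Degenerate cases follow a documented
convention: two empty masks agree perfectly (all metrics 1); an empty ground
truth against a non-empty segmentation reports SEN = 0 with ``gt_empty`` set.

Surface deviation is computed point-cloud-to-point-cloud between boundary
voxel centers, signed by ground-truth interior membership (positive outside
the ground-truth solid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import BinaryMask

__all__ = [
    "MetricReport",
    "DeviationReport",
    "overlap_metrics",
    "surface_deviation",
    "compare_arms",
]


@dataclass(frozen=True)
class MetricReport:
    dsc: float
    sen: float
    iou: float
    n_gt: int
    n_seg: int
    n_intersection: int
    n_union: int
    gt_empty: bool = False

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "sen": self.sen,
            "iou": self.iou,
            "n_gt": self.n_gt,
            "n_seg": self.n_seg,
            "n_intersection": self.n_intersection,
            "n_union": self.n_union,
            "gt_empty": self.gt_empty,
        }


@dataclass(frozen=True)
class DeviationReport:
    """Signed distances (mm) from predicted-surface points to the ground-truth surface."""

    distances: np.ndarray
    band_mm: float
    mean: float
    sd: float
    pct_within_band: float


def overlap_metrics(gt: BinaryMask, seg: BinaryMask) -> MetricReport:
    """Exact voxel-count DSC / SEN / IOU between two masks on the same grid."""
    if not gt.same_grid(seg):
        raise ValueError("overlap_metrics requires masks on identical grids")
    g = gt.as_bool()
    s = seg.as_bool()
    n_gt = int(g.sum())
    n_seg = int(s.sum())
    n_int = int(np.logical_and(g, s).sum())
    n_union = n_gt + n_seg - n_int
    if n_gt == 0 and n_seg == 0:
        return MetricReport(1.0, 1.0, 1.0, 0, 0, 0, 0)
    if n_gt == 0:
        dsc = 2.0 * n_int / (n_gt + n_seg)
        iou = n_int / n_union
        return MetricReport(dsc, 0.0, iou, n_gt, n_seg, n_int, n_union, gt_empty=True)
    dsc = 2.0 * n_int / (n_gt + n_seg)
    sen = n_int / n_gt
    iou = n_int / n_union
    return MetricReport(dsc, sen, iou, n_gt, n_seg, n_int, n_union)


def _surface_voxels(mask: BinaryMask) -> np.ndarray:
    """(N, 3) indices of foreground voxels with a face-adjacent background neighbor."""
    fg = mask.as_bool()
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(fg, structure=structure, border_value=0)
    return np.argwhere(fg & ~interior)


def surface_deviation(pred: BinaryMask, gt: BinaryMask, band_mm: float) -> DeviationReport:
    """Signed surface distances from prediction to ground truth.

    For every predicted boundary-voxel center, the distance to the nearest
    ground-truth boundary-voxel center, with positive sign when the predicted
    point lies outside the ground-truth solid and negative inside. The band
    is a reporting window only; no points are discarded.
    """
    if not pred.same_grid(gt):
        raise ValueError("surface_deviation requires masks on identical grids")
    if pred.count == 0 or gt.count == 0:
        raise ValueError("surface_deviation requires two non-empty masks")
    p_idx = _surface_voxels(pred)
    g_idx = _surface_voxels(gt)
    p_world = p_idx * pred.voxel_size + pred.origin
    g_world = g_idx * gt.voxel_size + gt.origin
    tree = cKDTree(g_world)
    dist, _ = tree.query(p_world, k=1)
    inside = gt.as_bool()[tuple(p_idx.T)]
    signed = np.where(inside, -dist, dist)
    within = np.abs(signed) <= band_mm
    return DeviationReport(
        distances=signed,
        band_mm=float(band_mm),
        mean=float(signed.mean()),
        sd=float(signed.std()),
        pct_within_band=float(100.0 * within.mean()),
    )


def compare_arms(reports_a, reports_b, paired: bool = True) -> dict:
    """Tabulate per-metric means ± sd for two arms and their paired differences.

    ``reports_a`` and ``reports_b`` are equal-length lists of
    :class:`MetricReport` (e.g., micro-CT-guided arm vs degraded-label arm).
    No hypothesis tests are computed.
    """
    if len(reports_a) != len(reports_b):
        raise ValueError(
            f"arm report lists differ in length: {len(reports_a)} vs {len(reports_b)}"
        )
    out: dict = {"n": len(reports_a), "paired": paired, "metrics": {}}
    for metric in ("dsc", "sen", "iou"):
        a = np.array([getattr(r, metric) for r in reports_a], dtype=float)
        b = np.array([getattr(r, metric) for r in reports_b], dtype=float)
        entry = {
            "arm_a_mean": float(a.mean()) if a.size else float("nan"),
            "arm_a_sd": float(a.std()) if a.size else float("nan"),
            "arm_b_mean": float(b.mean()) if b.size else float("nan"),
            "arm_b_sd": float(b.std()) if b.size else float("nan"),
        }
        if paired and a.size:
            d = a - b
            entry["diff_mean"] = float(d.mean())
            entry["diff_sd"] = float(d.std())
        out["metrics"][metric] = entry
    return out
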