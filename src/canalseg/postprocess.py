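"""Connected-component analysis and false-positive removal for canal predictions.

Predicted canal masks occasionally contain spurious objects disconnected from
the true canal system (typically in the coronal dentin under the enamel).
This module separates a mask into individual 3D objects and removes
components by one of three policies:

* ``keep_largest_k(k)`` — retain only the k largest components;
* ``min_size(v)`` — drop components smaller than v voxels;
* ``keep_in_region(region)`` — retain components whose centroid lies inside
  a region mask (default surrogate: the tooth below its widest axial
  cross-section, a cervical-plane proxy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask

__all__ = [
    "ComponentSet",
    "connected_components",
    "remove_false_positives",
    "cervical_region",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ComponentSet:
    """Labeled components of a mask, with per-component geometry."""

    labels: np.ndarray          # int label map, 0 = background
    n_components: int
    sizes: np.ndarray           # voxel counts, index c-1 for component c
    centroids: np.ndarray       # (n, 3) world mm
    z_extents: np.ndarray       # (n, 2) index [zmin, zmax] inclusive
    voxel_size: np.ndarray
    origin: np.ndarray


def connected_components(mask: BinaryMask, connectivity: int = 26) -> ComponentSet:
    """Flood-fill labeling of a mask under face (6) or full (26) connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, n = ndimage.label(mask.as_bool(), structure=_STRUCTURES[connectivity])
    if n == 0:
        return ComponentSet(
            labels, 0, np.zeros(0, int), np.zeros((0, 3)), np.zeros((0, 2), int),
            mask.voxel_size.copy(), mask.origin.copy(),
        )
    ids = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, ids).astype(int)
    cent_idx = np.asarray(ndimage.center_of_mass(np.ones_like(labels), labels, ids))
    cent_idx = cent_idx.reshape(n, 3)
    centroids = cent_idx * mask.voxel_size + mask.origin
    z_extents = np.zeros((n, 2), int)
    objs = ndimage.find_objects(labels)
    for c, sl in enumerate(objs):
        z_extents[c] = (sl[0].start, sl[0].stop - 1)
    return ComponentSet(labels, n, sizes, centroids, z_extents,
                        mask.voxel_size.copy(), mask.origin.copy())


def remove_false_positives(
    mask: BinaryMask,
    policy: str,
    *,
    k: int | None = None,
    min_voxels: int | None = None,
    region: BinaryMask | None = None,
    connectivity: int = 26,
) -> BinaryMask:
    """Zero out components failing the policy; the output is a subset of the input.

    Parameters
    ----------
    policy : {"keep_largest_k", "min_size", "keep_in_region"}
    k : number of components to keep (keep_largest_k); must be >= 1.
    min_voxels : minimum component size (min_size).
    region : region mask on the same grid (keep_in_region); a component is
        kept when the voxel containing its centroid is inside the region.
    """
    comps = connected_components(mask, connectivity)
    if comps.n_components == 0:
        return BinaryMask(np.zeros(mask.shape, np.uint8), mask.voxel_size.copy(),
                          mask.origin.copy())
    if policy == "keep_largest_k":
        if k is None or k < 1:
            raise ValueError("keep_largest_k requires k >= 1")
        order = np.argsort(comps.sizes)[::-1]
        keep = set((order[:k] + 1).tolist())
    elif policy == "min_size":
        if min_voxels is None or min_voxels < 1:
            raise ValueError("min_size requires min_voxels >= 1")
        keep = set((np.nonzero(comps.sizes >= min_voxels)[0] + 1).tolist())
    elif policy == "keep_in_region":
        if region is None:
            raise ValueError("keep_in_region requires a region mask")
        if not mask.same_grid(region):
            raise ValueError("region mask must share the input grid")
        if region.count == 0:
            raise ValueError("keep_in_region requires a non-empty region mask")
        reg = region.as_bool()
        keep = set()
        for c in range(comps.n_components):
            idx = np.clip(
                np.rint((comps.centroids[c] - mask.origin) / mask.voxel_size),
                0, np.asarray(mask.shape) - 1,
            ).astype(int)
            if reg[tuple(idx)]:
                keep.add(c + 1)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    out = np.isin(comps.labels, sorted(keep)) & mask.as_bool()
    return BinaryMask(out.astype(np.uint8), mask.voxel_size.copy(), mask.origin.copy())


def cervical_region(tooth_mask: BinaryMask) -> BinaryMask:
    """Tooth region at and below its widest axial cross-section.

    The widest axial slice of a tooth approximates the cervical plane; canal
    components whose centroid sits above it (in the crown-side dentin) are
    the typical false positives.
    """
    fg = tooth_mask.as_bool()
    if not fg.any():
        raise ValueError("cervical_region requires a non-empty tooth mask")
    areas = fg.reshape(fg.shape[0], -1).sum(axis=1)
    z_widest = int(np.argmax(areas))
    out = np.zeros_like(fg)
    out[: z_widest + 1] = fg[: z_widest + 1]
    return BinaryMask(out.astype(np.uint8), tooth_mask.voxel_size.copy(),
                      tooth_mask.origin.copy())
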