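"""Separate a batch scan into per-walnut sub-volumes.

The cleaned foreground mask is labelled by 3D voxel connectivity into nuts
numbered 1..n (deterministically, in scan order of each component's first
voxel).  Touching nuts can optionally be split by a distance-transform
watershed.  Each labelled nut is then cropped to a tight bounding box with
neighbouring material masked out, ready for part segmentation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from ._geometry import hull_vertices_mm
from .volume_io import BinaryMask, LabelMap, Volume3D

__all__ = [
    "label_walnuts",
    "split_touching",
    "component_masks",
    "convex_hull_mask",
    "crop_subvolumes",
]

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _renumber_scan_order(labels: np.ndarray) -> np.ndarray:
    """Relabel positive labels 1..n by first occurrence in raster order."""
    flat = labels.ravel()
    positive = flat[flat > 0]
    if positive.size == 0:
        return labels
    first = np.full(int(flat.max()) + 1, np.iinfo(np.int64).max, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # reversed so the smallest raster index wins
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable") + 1
    remap = np.zeros(first.size, dtype=labels.dtype)
    remap[order] = np.arange(1, order.size + 1, dtype=labels.dtype)
    return remap[labels]


def label_walnuts(mask: BinaryMask, connectivity: int = 26) -> LabelMap:
    """Connected-component labelling of the foreground into nuts 1..n."""
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labels, _ = ndimage.label(mask.data, structure=_CONNECTIVITY_STRUCTS[connectivity])
    labels = _renumber_scan_order(labels.astype(np.int32))
    return LabelMap(data=labels, voxel_size_mm=mask.voxel_size_mm)


def split_touching(
    labelmap: LabelMap,
    min_seed_distance_mm: float = 10.0,
    peak_rel_threshold: float = 0.5,
) -> LabelMap:
    """Split fused components with a watershed on the negated distance map.

    A component is considered a fusion of several nuts when its Euclidean
    distance transform has two or more strong maxima (each at least
    ``peak_rel_threshold`` of the global maximum) separated by more than
    ``min_seed_distance_mm``.  Other components pass through untouched, so
    a bumpy single nut is not over-split.
    """
    vox = labelmap.voxel_size_mm
    out = np.zeros_like(labelmap.data)
    next_label = 1
    objects = ndimage.find_objects(labelmap.data)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        comp = labelmap.data[slc] == lab
        dist = ndimage.distance_transform_edt(comp)
        min_dist_vox = max(1, int(round(min_seed_distance_mm / vox / 2)))
        peaks = peak_local_max(
            dist,
            min_distance=min_dist_vox,
            threshold_rel=peak_rel_threshold,
            exclude_border=False,
        )
        # greedy thinning: keep strongest peaks pairwise > min_seed_distance apart
        kept: list[np.ndarray] = []
        for p in peaks[np.argsort(dist[tuple(peaks.T)])[::-1]]:
            if all(np.linalg.norm((p - q) * vox) > min_seed_distance_mm for q in kept):
                kept.append(p)
        if len(kept) >= 2:
            markers = np.zeros(comp.shape, dtype=np.int32)
            for i, p in enumerate(kept, start=1):
                markers[tuple(p)] = i
            ws = watershed(-dist, markers=markers, mask=comp)
            for i in range(1, len(kept) + 1):
                out[slc][ws == i] = next_label
                next_label += 1
        else:
            out[slc][comp] = next_label
            next_label += 1
    return LabelMap(data=_renumber_scan_order(out), voxel_size_mm=vox)


def component_masks(labelmap: LabelMap) -> list[BinaryMask]:
    """One disjoint mask per positive label; union equals the foreground."""
    return [
        BinaryMask(data=labelmap.data == lab, voxel_size_mm=labelmap.voxel_size_mm)
        for lab in range(1, labelmap.n_labels + 1)
    ]


def convex_hull_mask(mask: BinaryMask) -> tuple[BinaryMask, np.ndarray]:
    """Filled convex hull of a voxel set, plus hull vertices in mm.

    Vertices are convex-hull extreme points of the foreground voxel centres;
    the hull mask marks every voxel whose centre lies inside that hull (so
    it always contains the input).
    """
    if not mask.data.any():
        raise ValueError("cannot take the convex hull of an empty mask")
    verts = hull_vertices_mm(mask.data, mask.voxel_size_mm)
    tri = Delaunay(verts)
    coords = np.argwhere(mask.data)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    grids = np.meshgrid(
        *[np.arange(lo[i], hi[i] + 1) for i in range(3)], indexing="ij"
    )
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(float) * mask.voxel_size_mm
    inside = tri.find_simplex(pts) >= 0
    hull = np.zeros(mask.shape, dtype=bool)
    hull[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = inside.reshape(
        [hi[i] - lo[i] + 1 for i in range(3)]
    )
    hull |= mask.data  # guard against boundary ties in find_simplex
    return BinaryMask(data=hull, voxel_size_mm=mask.voxel_size_mm), verts


def crop_subvolumes(
    vol: Volume3D,
    labelmap: LabelMap,
    margin_mm: float = 1.0,
    air_level: float | None = None,
    mask_dilation_vox: int = 3,
) -> list[Volume3D]:
    """Export each labelled nut as its own sub-volume.

    The crop is the tight bounding box of the nut's label plus ``margin_mm``;
    every voxel outside the nut's own (slightly dilated) mask is set to the
    background air level (estimated as a low percentile of the unlabelled
    voxels when not given), which removes foam and any neighbouring nut that
    intrudes into the box.  The dilation keeps true boundary voxels that the
    morphological cleaning of the foreground mask may have shaved off — a
    pinhole punched into the shell here would wrongly fail the nut's
    shell-integrity check downstream.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if labelmap.shape != vol.shape:
        raise ValueError("label map and volume shapes differ")
    vox = vol.voxel_size_mm
    if air_level is None:
        background = vol.data[labelmap.data == 0]
        air_level = float(np.percentile(background, 1)) if background.size else 0.0
    margin_vox = int(np.ceil(margin_mm / vox))
    subvols: list[Volume3D] = []
    for lab, slc in enumerate(ndimage.find_objects(labelmap.data), start=1):
        if slc is None:
            continue
        ext = tuple(
            slice(max(s.start - margin_vox, 0), min(s.stop + margin_vox, n))
            for s, n in zip(slc, vol.shape)
        )
        crop = np.array(vol.data[ext], dtype=np.float64)
        owner = labelmap.data[ext] == lab
        if mask_dilation_vox > 0:
            owner = ndimage.binary_dilation(
                owner,
                structure=ndimage.generate_binary_structure(3, 1),
                iterations=mask_dilation_vox,
            )
        crop[~owner] = air_level
        subvols.append(Volume3D(data=crop, voxel_size_mm=vox))
    return subvols
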