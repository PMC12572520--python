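"""Body and bone segmentation of CT-like volumes.

Pipeline: concatenate CT series into one volume, strip the scanner bed,
threshold the body at a fraction of the intensity range, and threshold
bone HU inside the body.  Bed removal and bone segmentation are
classical (connected components, HU thresholds) by design: the module
boundary accepts any segmenter with the same signature, so a learned
model can be dropped in without touching downstream code.

Connectivity conventions (fixed so voxel counts reproduce): 26-connected
components in 3D, 8-connected hole fill within axial (z) slices.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, EmptySceneError, GeometryError
from .volume import Mask, Volume

__all__ = [
    "concatenate_series",
    "remove_bed",
    "segment_body",
    "segment_bone",
    "combine_masks",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def concatenate_series(volumes: list[Volume], z_tol: float = 0.5) -> Volume:
    """Concatenate CT series along the z (stacking) axis into one volume.

    Series must share in-plane shape and spacing; slices are placed on a
    common z grid (step = first series' z spacing) by world coordinate.
    Where series overlap, the later series wins.  The x/y origin comes
    from the first series; the output z origin is the lowest slice.

    ``z_tol``: tolerance in voxels for off-grid slice positions.
    """
    if len(volumes) == 0:
        raise GeometryError("need at least one volume to concatenate")
    first = volumes[0]
    dz = first.spacing[2]
    for i, v in enumerate(volumes[1:], start=1):
        if v.shape[:2] != first.shape[:2]:
            raise GeometryError(
                f"series {i} in-plane shape {v.shape[:2]} != series 0 shape {first.shape[:2]}"
            )
        if not np.allclose(v.spacing, first.spacing, atol=1e-6):
            raise GeometryError(
                f"series {i} spacing {v.spacing} != series 0 spacing {first.spacing}"
            )
        if not np.allclose(v.origin[:2], first.origin[:2], atol=1e-6):
            raise GeometryError(
                f"series {i} in-plane origin {v.origin[:2]} != series 0 origin {first.origin[:2]}"
            )
    if len(volumes) == 1:
        return first

    # Map every slice of every series onto integer indices of a common z grid.
    slices: dict[int, np.ndarray] = {}
    for i, v in enumerate(volumes):
        for k in range(v.shape[2]):
            zw = v.origin[2] + k * v.spacing[2]
            pos = (zw - first.origin[2]) / dz
            idx = int(round(pos))
            if abs(pos - idx) > z_tol:
                raise GeometryError(
                    f"series {i} slice {k} lies {abs(pos - idx):.2f} voxels off the "
                    f"common z grid (tolerance {z_tol})"
                )
            slices[idx] = v.data[:, :, k]  # later series wins on overlap

    keys = sorted(slices)
    lo, hi = keys[0], keys[-1]
    if len(keys) != hi - lo + 1:
        missing = sorted(set(range(lo, hi + 1)) - set(keys))
        raise GeometryError(f"z gap between series at grid indices {missing[:5]}")
    data = np.stack([slices[k] for k in range(lo, hi + 1)], axis=2)
    origin = first.origin.copy()
    origin[2] = first.origin[2] + lo * dz
    return Volume(data=data, spacing=first.spacing.copy(), origin=origin,
                  meta={"kind": "concatenated", "n_series": len(volumes)})


def _above_air_threshold(volume: Volume, percentile: float = 0.20) -> float:
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi <= lo:
        raise DegenerateInputError("volume has constant intensity; cannot threshold")
    return lo + percentile * (hi - lo)


def remove_bed(volume: Volume) -> Volume:
    """Suppress the scanner bed: keep only the largest above-air component.

    Voxels of above-air connected components other than the largest (the
    body) are set to the scene's air value (median of the below-threshold
    voxels).  Idempotent; a bed-free volume passes through unchanged.
    """
    t = _above_air_threshold(volume)
    fg = volume.data >= t
    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    if n == 0:
        raise EmptySceneError("no above-air component found")
    if n == 1:
        return volume
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    air_value = float(np.median(volume.data[~fg])) if (~fg).any() else float(volume.data.min())
    data = volume.data.copy()
    data[fg & (labels != keep)] = air_value
    return Volume(data=data, spacing=volume.spacing.copy(), origin=volume.origin.copy(),
                  meta={**volume.meta, "bed_removed": True})


def segment_body(volume: Volume, percentile: float = 0.20, method: str = "range") -> Mask:
    """Threshold-based body mask.

    The threshold is ``t = min + percentile * (max - min)`` over the
    volume intensities (``method="range"``; ``method="histogram"``
    instead uses the intensity distribution's percentile).  The mask is
    the largest 26-connected component above ``t``, morphologically
    closed, with per-axial-slice hole filling.  ``t`` is recorded in
    ``mask.meta["threshold"]``.
    """
    if not (0.0 < percentile < 1.0):
        raise DegenerateInputError(f"percentile must be in (0, 1), got {percentile}")
    if method == "range":
        t = _above_air_threshold(volume, percentile)
    elif method == "histogram":
        if volume.data.max() <= volume.data.min():
            raise DegenerateInputError("volume has constant intensity; cannot threshold")
        t = float(np.quantile(volume.data, percentile))
    else:
        raise DegenerateInputError(f"unknown threshold method {method!r}")

    fg = volume.data >= t
    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    if n == 0:
        raise EmptySceneError("nothing above the body threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    mask = ndimage.binary_closing(mask, structure=_STRUCT_26)
    for k in range(mask.shape[2]):
        mask[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k], structure=_STRUCT_8)
    return Mask.like(volume, mask, kind="body", threshold=t, percentile=percentile, method=method)


def segment_bone(
    volume: Volume,
    hu_threshold: float = 150.0,
    body: Mask | None = None,
    min_component_voxels: int = 50,
) -> Mask:
    """HU-threshold bone mask inside the body.

    Voxels at or above ``hu_threshold`` within the body mask (computed
    via :func:`segment_body` when not supplied), with 26-connected
    components below ``min_component_voxels`` removed.
    """
    if body is None:
        body = segment_body(volume)
    elif not volume.same_geometry(body):
        raise GeometryError("body mask geometry does not match volume")
    bone = (volume.data >= hu_threshold) & body.data
    if min_component_voxels > 1 and bone.any():
        labels, n = ndimage.label(bone, structure=_STRUCT_26)
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_component_voxels)
        bone[np.isin(labels, small[small > 0])] = False
    return Mask.like(volume, bone, kind="bone", hu_threshold=hu_threshold,
                     min_component_voxels=min_component_voxels)


def combine_masks(a: Mask, b: Mask) -> Mask:
    """Voxelwise OR of two masks with identical geometry."""
    if not a.same_geometry(b):
        raise GeometryError("cannot combine masks with differing geometry")
    return Mask.like(a, a.data | b.data, kind="combined",
                     sources=(a.meta.get("kind"), b.meta.get("kind")))
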