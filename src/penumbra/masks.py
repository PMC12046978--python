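"""Mask geometry: WM thresholding, NAWM derivation, penumbra rings, frequency maps.

Distances are Euclidean, computed with the sampled distance transform so that
anisotropic grids are handled in millimetres rather than voxels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volume import GridMismatchError, VolumeMap, check_same_grid

__all__ = [
    "ball_footprint",
    "wm_mask_from_probability",
    "derive_nawm",
    "penumbra_rings",
    "lesion_frequency_map",
]


def ball_footprint(radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Binary ball structuring element of physical radius ``radius_mm``.

    The radius is converted to voxels per axis, so the footprint is an
    ellipsoid in index space but a ball in millimetres.
    """
    spacing = np.asarray(voxel_size_mm, dtype=float)
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    half = np.floor(radius_mm / spacing).astype(int)
    grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm**2 + 1e-9


def wm_mask_from_probability(
    prob: VolumeMap, threshold: float = 0.5, erode_mm: float = 1.0
) -> np.ndarray:
    """Threshold a WM probability map and erode by a physical radius.

    Voxels with probability strictly above ``threshold`` are kept, then the
    mask is eroded with a ball of radius ``erode_mm`` (converted to voxels per
    axis).  If the radius is smaller than the spacing along some axis the
    erosion cannot act along that axis; a warning is emitted.
    """
    values = np.asarray(prob.values)
    if values.min() < 0 or values.max() > 1:
        raise ValueError("probability values must lie in [0, 1]")
    mask = values > threshold
    if erode_mm <= 0:
        return mask
    spacing = np.asarray(prob.voxel_size_mm, dtype=float)
    noop_axes = [i for i, s in enumerate(spacing) if erode_mm < s]
    if noop_axes:
        warnings.warn(
            f"erosion radius {erode_mm} mm is below the voxel spacing along "
            f"axes {noop_axes}; erosion is a no-op along those axes",
            stacklevel=2,
        )
    footprint = ball_footprint(erode_mm, spacing)
    if footprint.size == 1:
        return mask
    return ndimage.binary_erosion(mask, structure=footprint)


def derive_nawm(wm: np.ndarray, wmh: np.ndarray, lacunes: np.ndarray) -> np.ndarray:
    """Normal-appearing WM: white matter minus lesions minus lacunes."""
    check_same_grid({"wm": wm, "wmh": wmh, "lacunes": lacunes})
    return np.asarray(wm, bool) & ~np.asarray(wmh, bool) & ~np.asarray(lacunes, bool)


def penumbra_rings(
    wmh: np.ndarray,
    nawm: np.ndarray,
    voxel_size_mm,
    step_mm: float = 2.0,
    max_mm: float = 10.0,
) -> np.ndarray:
    """Label NAWM shells around the lesion mask by distance from its boundary.

    Ring ``k`` (1-based) holds voxels whose Euclidean distance ``d`` to the
    nearest lesion voxel satisfies ``step*(k-1) <= d < step*k``, intersected
    with NAWM.  Voxels beyond ``max_mm`` are unlabeled (0).

    Returns an int16 label volume.
    """
    check_same_grid({"wmh": wmh, "nawm": nawm})
    wmh = np.asarray(wmh, bool)
    nawm = np.asarray(nawm, bool)
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    n_rings = max_mm / step_mm
    if abs(n_rings - round(n_rings)) > 1e-9:
        raise ValueError(f"max_mm ({max_mm}) must be a multiple of step_mm ({step_mm})")
    n_rings = int(round(n_rings))
    if not wmh.any():
        raise ValueError("WMH mask is empty: no lesion boundary to measure distances from")

    dist = ndimage.distance_transform_edt(~wmh, sampling=voxel_size_mm)
    labels = np.floor(dist / step_mm).astype(np.int16) + 1
    valid = nawm & (dist > 0) & (dist < max_mm)
    return np.where(valid, labels, np.int16(0))


def lesion_frequency_map(masks: list, voxel_size_mm=None) -> VolumeMap:
    """Per-voxel lesion frequency (percent of subjects) across binary masks.

    Accepts a list of boolean arrays or :class:`VolumeMap` objects on a
    shared grid; returns percentages in [0, 100].
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask to build a frequency map")
    arrays = []
    for m in masks:
        if isinstance(m, VolumeMap):
            if voxel_size_mm is None:
                voxel_size_mm = m.voxel_size_mm
            arrays.append(np.asarray(m.values, bool))
        else:
            arrays.append(np.asarray(m, bool))
    check_same_grid({f"mask[{i}]": a for i, a in enumerate(arrays)})
    if voxel_size_mm is None:
        raise ValueError("voxel_size_mm required when masks are plain arrays")
    count = np.zeros(arrays[0].shape, dtype=np.float64)
    for a in arrays:
        count += a
    freq = 100.0 * count / len(arrays)
    return VolumeMap(freq, voxel_size_mm, units="%")
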