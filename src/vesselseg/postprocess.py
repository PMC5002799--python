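"""Outlier removal on segmentation masks.

Non-vessel structures with vessel-like intensities (fat rings, isolated
blobs) survive intensity-driven segmentation.  The connectivity filter
removes them by shape: vesselness is computed on the *raw* volume (before
segmentation, where the shape information is still intact), voxels of the
mask whose vesselness clears a seed threshold become seeds, and only the
connected components of the mask reachable from a seed are kept — a region
growth over vessel connectivity.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi

from .volume_io import BinaryMask3D

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, "
                         f"got {connectivity}")
    return ndi.generate_binary_structure(3, _STRUCTURES[connectivity])


def _like(mask: BinaryMask3D, data: np.ndarray) -> BinaryMask3D:
    return BinaryMask3D(data, spacing=mask.spacing, origin=mask.origin)


def connectivity_filter(mask: BinaryMask3D, vesselness: np.ndarray,
                        seed_threshold: float = 0.65,
                        connectivity: int = 26) -> BinaryMask3D:
    """Keep only mask components containing a high-vesselness seed voxel.

    Seeds are mask voxels with ``vesselness >= seed_threshold``.  An empty
    seed set yields an empty mask with a warning (not an error).
    """
    vesselness = np.asarray(vesselness)
    if vesselness.shape != mask.shape:
        raise ValueError(f"vesselness shape {vesselness.shape} != mask shape {mask.shape}")
    seeds = mask.data & (vesselness >= seed_threshold)
    if not seeds.any():
        warnings.warn("connectivity filter found 0 seed voxels; returning an "
                      "empty mask", RuntimeWarning)
        return _like(mask, np.zeros_like(mask.data))
    labels, _ = ndi.label(mask.data, structure=_structure(connectivity))
    keep = np.unique(labels[seeds])
    keep = keep[keep > 0]
    return _like(mask, np.isin(labels, keep))


def remove_small_components(mask: BinaryMask3D, min_voxels: int,
                            connectivity: int = 26) -> BinaryMask3D:
    """Drop connected components smaller than ``min_voxels`` (safety net)."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    if min_voxels == 0 or not mask.data.any():
        return _like(mask, mask.data.copy())
    labels, n = ndi.label(mask.data, structure=_structure(connectivity))
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.flatnonzero(sizes >= min_voxels)
    keep = keep[keep > 0]
    return _like(mask, np.isin(labels, keep))
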