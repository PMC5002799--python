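"""Dice evaluation and the model-comparison / parameter-sweep harnesses."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .levelset import MODES, LevelSetParams, segment
from .vesselness import multiscale_vesselness
from .volume_io import BinaryMask3D, Volume3D


def dice(m: BinaryMask3D, g: BinaryMask3D) -> float:
    """Dice similarity coefficient on the 0-100 scale.

    DSC = 2 |M ∩ G| / (|M| + |G|) × 100; 100 iff the masks are equal
    (nonempty), 0 iff they share no voxel.  Undefined when both are empty.
    """
    md = np.asarray(m.data, dtype=bool) if not isinstance(m, BinaryMask3D) else m.data
    gd = np.asarray(g.data, dtype=bool) if not isinstance(g, BinaryMask3D) else g.data
    if md.shape != gd.shape:
        raise ValueError(f"mask shapes differ: {md.shape} vs {gd.shape}")
    nm = int(np.count_nonzero(md))
    ng = int(np.count_nonzero(gd))
    if nm + ng == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int(np.count_nonzero(md & gd))
    return 200.0 * inter / (nm + ng)


def compare_variants(volume: Volume3D, gt: BinaryMask3D,
                     params: LevelSetParams | None = None,
                     postprocess: bool = True,
                     modes: tuple[str, ...] = MODES) -> pd.DataFrame:
    """Run every model variant with shared parameters and score against ``gt``.

    The vesselness response (used for initialization, seeding and the
    outlier filter) is computed once on the volume and shared, so variants
    differ only in their region terms.  Returns a table with columns
    ``mode``, ``dsc``, ``iterations``, ``mask_voxels``.
    """
    params = params or LevelSetParams()
    vness = multiscale_vesselness(volume, scales=params.vessel_scales,
                                  mode=params.vesselness_mode).response
    rows = []
    for mode in modes:
        mask, diag = segment(volume, params=params, mode=mode,
                             vesselness=vness, postprocess=postprocess)
        rows.append({
            "mode": mode,
            "dsc": dice(mask, gt),
            "iterations": diag["iterations"],
            "mask_voxels": mask.count(),
        })
    return pd.DataFrame(rows)


def ratio_sweep(volume: Volume3D, gt: BinaryMask3D,
                params: LevelSetParams | None = None,
                ratios: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
                postprocess: bool = True) -> pd.DataFrame:
    """Sensitivity of the hybrid model to the local/global weight ratio.

    alpha1 stays at ``params.alpha1``; alpha2 = ratio * alpha1 for each
    requested ratio.  Returns a table with columns ``ratio``, ``dsc``,
    ``iterations`` (one row per ratio, in the given order).
    """
    params = params or LevelSetParams()
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    vness = multiscale_vesselness(volume, scales=params.vessel_scales,
                                  mode=params.vesselness_mode).response
    rows = []
    for ratio in ratios:
        from dataclasses import replace

        p = replace(params, alpha2=float(ratio) * params.alpha1)
        mask, diag = segment(volume, params=p, mode="hybrid",
                             vesselness=vness, postprocess=postprocess)
        rows.append({"ratio": float(ratio), "dsc": dice(mask, gt),
                     "iterations": diag["iterations"]})
    return pd.DataFrame(rows)
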