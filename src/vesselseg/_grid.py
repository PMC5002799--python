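"""Finite-difference primitives on regular 3D grids.

All operators use central differences with replicate (zero-flux) boundary
handling, in voxel units.  These are the building blocks shared by the
level-set evolution and the edge map; they deliberately avoid ``np.gradient``
so that the boundary treatment is uniform across every operator.
"""

from __future__ import annotations

import numpy as np

# Regularizer added under the square root of |grad phi| so that normalized
# gradients are defined on flat regions: |g| -> sqrt(|g|^2 + ETA^2), ETA=1e-8.
ETA = 1.0e-8
ETA2 = ETA * ETA


def _pad_axis(f: np.ndarray, axis: int) -> np.ndarray:
    pad = [(1, 1) if a == axis else (0, 0) for a in range(f.ndim)]
    return np.pad(f, pad, mode="edge")


def _hi_lo(p: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    hi = [slice(None)] * p.ndim
    lo = [slice(None)] * p.ndim
    hi[axis] = slice(2, None)
    lo[axis] = slice(None, -2)
    return p[tuple(hi)], p[tuple(lo)]


def central_diff(f: np.ndarray, axis: int) -> np.ndarray:
    """First derivative along ``axis``: (f[i+1] - f[i-1]) / 2, replicated ends."""
    hi, lo = _hi_lo(_pad_axis(f, axis), axis)
    return 0.5 * (hi - lo)


def first_and_second_diff(f: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Central first derivative and second difference from a single padding pass."""
    hi, lo = _hi_lo(_pad_axis(f, axis), axis)
    return 0.5 * (hi - lo), hi - 2.0 * f + lo


def gradient(f: np.ndarray) -> list[np.ndarray]:
    return [central_diff(f, a) for a in range(3)]


def gradient_norm(grads: list[np.ndarray], regularized: bool = True) -> np.ndarray:
    s = grads[0] * grads[0] + grads[1] * grads[1] + grads[2] * grads[2]
    if regularized:
        s = s + ETA2
    return np.sqrt(s)


def laplacian(f: np.ndarray) -> np.ndarray:
    out = None
    for a in range(3):
        hi, lo = _hi_lo(_pad_axis(f, a), a)
        d2 = hi - 2.0 * f + lo
        out = d2 if out is None else out + d2
    return out


def divergence(field: list[np.ndarray]) -> np.ndarray:
    out = None
    for a in range(3):
        d = central_diff(field[a], a)
        out = d if out is None else out + d
    return out
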