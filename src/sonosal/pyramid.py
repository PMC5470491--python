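"""Gaussian pyramid construction and the per-level intensity / blackness-ratio
feature maps.

The pyramid uses a 6-tap separable binomial-like kernel ``[1,5,10,10,5,1]/32``
applied along rows then columns, followed by factor-2 decimation keeping the
even-indexed rows/cols.  Level 1 is the input; level sigma has resolution
``ceil(original / 2**(sigma-1))`` so nine levels never produce an empty array.

Features are extracted *per pyramid level* from the pyramided channel planes:
the channels are smoothed/decimated once, and the intensity and blackness-ratio
maps are computed at every level.  Intensity (a linear feature) commutes with
the smoothing; the blackness ratio does not, so this ordering is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.ndimage import correlate1d

from .io import ValidationError

__all__ = [
    "KERNEL_1D",
    "N_LEVELS",
    "EPSILON",
    "FeaturePyramid",
    "intensity_map",
    "blackness_ratio_map",
    "gaussian_reduce",
    "build_pyramid",
    "feature_pyramids",
]

#: 6-tap separable smoothing kernel; sums to 1 exactly.
KERNEL_1D = np.array([1, 5, 10, 10, 5, 1], dtype=np.float64) / 32.0

#: Number of pyramid levels (sigma = 1..9; sigma=1 is the input).
N_LEVELS = 9

#: Regularizer in the blackness-ratio denominator.
EPSILON = 1e-3


@dataclass
class FeaturePyramid:
    """An ordered set of 2-D maps at halving resolutions, sigma = 1..N_LEVELS."""

    feature_name: str
    levels: Dict[int, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, sigma: int) -> np.ndarray:
        return self.levels[sigma]

    def shape(self, sigma: int) -> tuple:
        return self.levels[sigma].shape


def _check_planes(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> tuple:
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if not (r.shape == g.shape == b.shape):
        raise ValidationError(
            f"channel planes have mismatched shapes {r.shape}, {g.shape}, {b.shape}"
        )
    return r, g, b


def intensity_map(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel channel mean (r + g + b) / 3."""
    r, g, b = _check_planes(r, g, b)
    return (r + g + b) / 3.0


def blackness_ratio_map(r: np.ndarray, g: np.ndarray, b: np.ndarray,
                        epsilon: float = EPSILON) -> np.ndarray:
    """Blackness ratio 1 - min(r,g,b) / ((r+g+b)/3 + epsilon).

    Emphasizes dark (hypoechoic) regions: pure black maps to ~1, bright
    uniform gray to ~0.  With equal channels the value lies in [0, 1].
    """
    if epsilon <= 0:
        raise ValidationError(f"epsilon must be positive, got {epsilon}")
    r, g, b = _check_planes(r, g, b)
    mn = np.minimum(np.minimum(r, g), b)
    return 1.0 - mn / ((r + g + b) / 3.0 + epsilon)


def gaussian_reduce(level: np.ndarray, kernel: np.ndarray = KERNEL_1D) -> np.ndarray:
    """Separably smooth with the pyramid kernel, then decimate by two.

    Boundary handling is reflective (symmetric), which avoids dark halos at
    the frame that would otherwise show up as spurious edge saliency.
    Output dimensions are ceil(input / 2).
    """
    arr = np.asarray(level, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(f"gaussian_reduce needs a 2-D array >= 2x2, got {arr.shape}")
    sm = correlate1d(arr, kernel, axis=0, mode="reflect")
    sm = correlate1d(sm, kernel, axis=1, mode="reflect")
    return sm[::2, ::2]


def build_pyramid(base: np.ndarray, feature_name: str = "raw",
                  n_levels: int = N_LEVELS) -> FeaturePyramid:
    """Build an ``n_levels``-level half-resolution pyramid; level 1 is ``base``."""
    arr = np.asarray(base, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValidationError(f"pyramid input must be 2-D and >= 2x2, got {arr.shape}")
    pyr = FeaturePyramid(feature_name=feature_name, levels={1: arr})
    current = arr
    for sigma in range(2, n_levels + 1):
        if min(current.shape) >= 2:
            current = gaussian_reduce(current)
        # a 1-pixel side can no longer be reduced; carry it unchanged
        pyr.levels[sigma] = current
    return pyr


def feature_pyramids(r: np.ndarray, g: np.ndarray, b: np.ndarray,
                     epsilon: float = EPSILON) -> tuple:
    """Pyramid the channel planes once, then extract both features per level.

    Returns (intensity_pyramid, blackness_ratio_pyramid).
    """
    r, g, b = _check_planes(r, g, b)
    pr, pg, pb = (build_pyramid(p) for p in (r, g, b))
    mi = FeaturePyramid("intensity")
    mbr = FeaturePyramid("blackness_ratio")
    for sigma in pr.levels:
        mi.levels[sigma] = intensity_map(pr[sigma], pg[sigma], pb[sigma])
        mbr.levels[sigma] = blackness_ratio_map(pr[sigma], pg[sigma], pb[sigma],
                                               epsilon=epsilon)
    return mi, mbr
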