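"""Center-surround contrast maps, iterative nonlinear normalization, and the
per-feature saliency maps.

Center-surround receptive fields are emulated by across-scale subtraction:
the surround level (coarse) is upsampled to the center level (fine) and the
absolute difference taken.  Center levels c in {3,4,5} pair with surrounds
s = c+3, c+4, giving six contrast maps per feature.  Each is passed through
the competition operator N{.}, resampled to the level-5 working resolution,
summed, normalized once more, and scaled to [0, 1].

N{.} realizes local spatial competition with a difference-of-Gaussians:
per iteration the map is convolved with an excitatory (narrow) minus
inhibitory (broad) Gaussian pair, the response added back, and negatives
clamped to zero.  Maps with a single dominant peak keep it; fields of many
comparable peaks are mutually suppressed.  The operator is positively
homogeneous, so it behaves identically across feature scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io import ValidationError
from .pyramid import FeaturePyramid

__all__ = [
    "WORKING_LEVEL",
    "CENTER_LEVELS",
    "SURROUND_DELTAS",
    "NormalizeParams",
    "resize_bilinear",
    "across_scale_subtract",
    "normalize_iterative",
    "channel_saliency",
]

WORKING_LEVEL = 5
CENTER_LEVELS = (3, 4, 5)
SURROUND_DELTAS = (3, 4)


@dataclass
class NormalizeParams:
    """Constants of the DoG competition operator N{.}.

    Sigmas are fractions of the map width; weights are the excitatory and
    inhibitory amplitudes.  Defaults follow the standard published
    realization of the operator, with 3 iterations (midpoint of the 1-5
    range the method uses).
    """

    iterations: int = 3
    ex_sigma_frac: float = 0.02
    ex_weight: float = 0.5
    inh_sigma_frac: float = 0.25
    inh_weight: float = 1.5


def resize_bilinear(arr: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Bilinear resampling on a corner-aligned grid (used for both up- and
    down-sampling between pyramid levels)."""
    arr = np.asarray(arr, dtype=np.float64)
    h_out, w_out = out_shape
    h_in, w_in = arr.shape
    if (h_in, w_in) == (h_out, w_out):
        return arr.copy()
    rows = (np.linspace(0.0, h_in - 1.0, h_out) if h_out > 1
            else np.array([(h_in - 1) / 2.0]))
    cols = (np.linspace(0.0, w_in - 1.0, w_out) if w_out > 1
            else np.array([(w_in - 1) / 2.0]))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(arr, [rr, cc], order=1, mode="nearest")


def across_scale_subtract(pyramid: FeaturePyramid, c: int, s: int) -> np.ndarray:
    """Contrast map |level c - upsample(level s)| at the level-c resolution."""
    if c not in CENTER_LEVELS or s not in (c + SURROUND_DELTAS[0], c + SURROUND_DELTAS[1]):
        raise ValidationError(f"invalid center-surround pair (c={c}, s={s})")
    if c not in pyramid.levels or s not in pyramid.levels:
        raise ValidationError(f"pyramid is missing level {c} or {s}")
    center = pyramid[c]
    surround = resize_bilinear(pyramid[s], center.shape)
    return np.abs(center - surround)


def normalize_iterative(values: np.ndarray,
                        params: NormalizeParams | None = None) -> np.ndarray:
    """Apply the iterative DoG competition operator N{.} to a nonnegative map."""
    params = params or NormalizeParams()
    if not 1 <= params.iterations <= 5:
        raise ValidationError(f"iterations must be in 1..5, got {params.iterations}")
    m = np.asarray(values, dtype=np.float64)
    if m.min() < 0:
        raise ValidationError("normalize_iterative requires a nonnegative map")
    width = m.shape[1]
    sig_ex = max(params.ex_sigma_frac * width, 0.5)
    sig_inh = max(params.inh_sigma_frac * width, 1.0)
    m = m.copy()
    for _ in range(params.iterations):
        dog = (params.ex_weight * gaussian_filter(m, sig_ex, mode="reflect")
               - params.inh_weight * gaussian_filter(m, sig_inh, mode="reflect"))
        m = np.clip(m + dog, 0.0, None)
    return m


def channel_saliency(pyramid: FeaturePyramid,
                     norm_params: NormalizeParams | None = None) -> np.ndarray:
    """Fuse the six normalized contrast maps of one feature into a saliency map.

    Each (c, s) contrast map is normalized, resampled to the level-5 working
    resolution, summed, normalized once more, and finally divided by its
    global maximum so the three feature maps share a [0, 1] scale.
    """
    needed = max(c + max(SURROUND_DELTAS) for c in CENTER_LEVELS)
    if any(sigma not in pyramid.levels for sigma in range(1, needed + 1)):
        raise ValidationError(f"pyramid must contain levels 1..{needed}")
    work_shape = pyramid.shape(WORKING_LEVEL)
    total = np.zeros(work_shape, dtype=np.float64)
    for c in CENTER_LEVELS:
        for delta in SURROUND_DELTAS:
            contrast = across_scale_subtract(pyramid, c, c + delta)
            contrast = normalize_iterative(contrast, norm_params)
            total += resize_bilinear(contrast, work_shape)
    total = normalize_iterative(total, norm_params)
    peak = total.max()
    # a peak at roundoff scale is a constant feature map, not structure
    if peak <= 1e-9:
        return np.zeros(work_shape)
    return total / peak
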