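"""Saliency-map fusion, winner-take-all focus selection, inhibition of
return, and the end-to-end localization loop.

The three feature saliency maps (intensity, blackness ratio, superpixel
contrast), all on the level-5 working grid and individually scaled to
[0, 1], are averaged into the combined map S.  The focus of attention (FOA)
is the global maximum of S — the steady-state winner of the
integrate-and-fire winner-take-all network, computed directly as an argmax
(row-major first maximum on ties).  Working-grid coordinates are mapped
back to the original image on the corner-aligned grid.

The post-processing loop guards against plausible-looking dark regions in
the fat layer or at the image border: the FOA seeds a Chan-Vese
segmentation, and if the segmented region touches the frame (junction count
Lj > 0) the fixation is rejected, its saliency inhibited to zero, and
attention shifts to the next winner.  By default the inhibited area is the
segmented region itself (the region whose saliency the rejection is about);
a fixed-radius FOA-disk mode is available via configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Optional

import numpy as np
from scipy.ndimage import binary_dilation

from .chanvese import ChanVeseParams, SegmentationResult, chan_vese, junction_count
from .io import ValidationError, validate_gray
from .pyramid import feature_pyramids
from .saliency import NormalizeParams, channel_saliency, resize_bilinear
from .superpixel import slic_segment, superpixel_saliency

__all__ = [
    "NoSalientRegionError",
    "FocusOfAttention",
    "LocalizationResult",
    "combine",
    "winner_take_all",
    "inhibit_return",
    "inhibit_mask",
    "compute_saliency_maps",
    "localize",
]

#: Saliency below this is treated as "nothing left to attend to".
SALIENCE_FLOOR = 1e-9


class NoSalientRegionError(RuntimeError):
    """Raised when the combined saliency map contains no salient location."""


@dataclass
class FocusOfAttention:
    """One fixation: a circle in original-image coordinates."""

    row: int
    col: int
    radius: float
    saliency_value: float
    accepted: bool = False
    rejection_reason: Optional[str] = None   # None | "edge_junction"
    lj: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LocalizationResult:
    fixations: List[FocusOfAttention] = field(default_factory=list)
    final_accepted: Optional[int] = None
    combined_map: Optional[np.ndarray] = field(default=None, repr=False)
    accepted_mask: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def accepted_foa(self) -> Optional[FocusOfAttention]:
        if self.final_accepted is None:
            return None
        return self.fixations[self.final_accepted]

    def to_dict(self) -> dict:
        return {
            "fixations": [f.to_dict() for f in self.fixations],
            "final_accepted": self.final_accepted,
        }


def combine(s_intensity: np.ndarray, s_blackness: np.ndarray,
            s_superpixel: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the three working-resolution saliency maps."""
    maps = [np.asarray(m, dtype=np.float64)
            for m in (s_intensity, s_blackness, s_superpixel)]
    if not (maps[0].shape == maps[1].shape == maps[2].shape):
        raise ValidationError(
            f"saliency maps have mismatched shapes: {[m.shape for m in maps]}"
        )
    return (maps[0] + maps[1] + maps[2]) / 3.0


def _work_to_orig(idx: int, n_work: int, n_orig: int) -> int:
    if n_work <= 1:
        return (n_orig - 1) // 2
    return int(round(idx * (n_orig - 1) / (n_work - 1)))


def _orig_to_work_scale(n_work: int, n_orig: int) -> float:
    if n_orig <= 1:
        return 1.0
    return (n_work - 1) / (n_orig - 1)


def winner_take_all(saliency: np.ndarray, orig_shape: tuple,
                    radius_frac: float = 0.125) -> FocusOfAttention:
    """Select the most salient location as the focus of attention.

    The winner is the global maximum (row-major first on ties), mapped back
    to original-image coordinates; the FOA radius is ``radius_frac`` of the
    shorter image side.  Raises NoSalientRegionError on an all-zero map.
    """
    s = np.asarray(saliency, dtype=np.float64)
    if s.size == 0:
        raise ValidationError("empty saliency map")
    peak = s.max()
    if peak <= SALIENCE_FLOOR:
        raise NoSalientRegionError("saliency map has no salient region")
    flat_idx = int(np.argmax(s))
    r_w, c_w = np.unravel_index(flat_idx, s.shape)
    h, w = orig_shape
    return FocusOfAttention(
        row=_work_to_orig(int(r_w), s.shape[0], h),
        col=_work_to_orig(int(c_w), s.shape[1], w),
        radius=radius_frac * min(h, w),
        saliency_value=float(peak),
    )


def inhibit_return(saliency: np.ndarray, foa: FocusOfAttention,
                   orig_shape: tuple) -> np.ndarray:
    """Zero the saliency inside the FOA disk (in working-grid coordinates)."""
    s = np.asarray(saliency, dtype=np.float64).copy()
    h, w = orig_shape
    sr = _orig_to_work_scale(s.shape[0], h)
    sc = _orig_to_work_scale(s.shape[1], w)
    r_w, c_w = foa.row * sr, foa.col * sc
    rad_w = max(foa.radius * 0.5 * (sr + sc), 1.0)
    rr, cc = np.indices(s.shape)
    s[(rr - r_w) ** 2 + (cc - c_w) ** 2 <= rad_w ** 2] = 0.0
    return s


def inhibit_mask(saliency: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the saliency over a full-resolution region mask (downsampled to
    the working grid and dilated by one cell for safety)."""
    s = np.asarray(saliency, dtype=np.float64).copy()
    frac = resize_bilinear(np.asarray(mask, dtype=np.float64), s.shape)
    region = binary_dilation(frac > 0.25)
    s[region] = 0.0
    return s


def compute_saliency_maps(r: np.ndarray, g: np.ndarray, b: np.ndarray, *,
                          epsilon: float = 1e-3,
                          norm_params: NormalizeParams | None = None,
                          slic_k: int = 400, slic_m: float = 40.0,
                          slic_iter: int = 10, delta: float = 0.05):
    """Run the feature half of the pipeline; returns (SI, SBR, SSP, combined)."""
    mi, mbr = feature_pyramids(r, g, b, epsilon=epsilon)
    s_int = channel_saliency(mi, norm_params)
    s_bla = channel_saliency(mbr, norm_params)
    gray = (np.asarray(r, float) + np.asarray(g, float) + np.asarray(b, float)) / 3.0
    part = slic_segment(gray, k=slic_k, m=slic_m, max_iter=slic_iter)
    ssp = superpixel_saliency(part, delta=delta)
    s_sp = resize_bilinear(ssp.rendered, s_int.shape)
    return s_int, s_bla, s_sp, combine(s_int, s_bla, s_sp)


def localize(r: np.ndarray, g: np.ndarray, b: np.ndarray, *,
             epsilon: float = 1e-3,
             norm_params: NormalizeParams | None = None,
             slic_k: int = 400, slic_m: float = 40.0, slic_iter: int = 10,
             delta: float = 0.05,
             radius_frac: float = 0.125,
             max_attempts: int = 3,
             post_processing: bool = True,
             ior_mode: str = "mask",
             cv_params: ChanVeseParams | None = None) -> LocalizationResult:
    """Full localization: saliency fusion, WTA, and the Lj rejection loop.

    With ``post_processing`` off the first winner is accepted outright
    (no segmentation check) — the behavior the rejection loop improves on.
    ``ior_mode`` selects what gets inhibited after a rejection: the
    Chan-Vese ``"mask"`` (default) or the fixed-radius FOA ``"disk"``.
    """
    gray = validate_gray((np.asarray(r, float) + np.asarray(g, float)
                          + np.asarray(b, float)) / 3.0)
    if ior_mode not in ("mask", "disk"):
        raise ValidationError(f"ior_mode must be 'mask' or 'disk', got {ior_mode!r}")
    s_int, s_bla, s_sp, s = compute_saliency_maps(
        r, g, b, epsilon=epsilon, norm_params=norm_params, slic_k=slic_k,
        slic_m=slic_m, slic_iter=slic_iter, delta=delta)
    result = LocalizationResult(combined_map=s.copy())
    current = s
    for _ in range(max_attempts):
        try:
            foa = winner_take_all(current, gray.shape, radius_frac=radius_frac)
        except NoSalientRegionError:
            break
        if not post_processing:
            foa.accepted = True
            result.fixations.append(foa)
            result.final_accepted = len(result.fixations) - 1
            break
        seg: SegmentationResult = chan_vese(gray, (foa.row, foa.col),
                                            foa.radius, cv_params)
        lj = junction_count(seg.mask)
        foa.lj = lj
        if lj > 0:
            foa.accepted = False
            foa.rejection_reason = "edge_junction"
            result.fixations.append(foa)
            if ior_mode == "mask" and seg.mask.any():
                current = inhibit_mask(current, seg.mask)
                # also clear the fixation itself in case the downsampled
                # mask missed the winning cell
                current = inhibit_return(current, foa, gray.shape)
            else:
                current = inhibit_return(current, foa, gray.shape)
        else:
            foa.accepted = True
            result.fixations.append(foa)
            result.final_accepted = len(result.fixations) - 1
            result.accepted_mask = seg.mask
            break
    return result
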