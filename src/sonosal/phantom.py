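"""Synthetic B-mode-like phantoms with exact ground truth.

A phantom is a piecewise-mean image — mid-gray background, a dark rotated
ellipse (the hypoechoic lesion), optional bright artifact bands/blobs and an
optional dark band glued to the top edge standing in for the subcutaneous
fat layer — multiplied by a unit-mean speckle field.  The speckle is a
squared-Rayleigh-style (exponential) random field, Gaussian-smoothed to a
short correlation length and renormalized to mean 1 with a configurable
standard deviation.  Defaults emulate display-domain (log-compressed)
speckle contrast.  Masks are constructed analytically, never thresholded,
so ground truth is exact; the lesion is required to lie strictly inside the
frame, mirroring the anatomy (real lesions sit in the mammary layer and do
not touch the image border).

Not modeled: attenuation and time-gain compensation, the probe's point
spread function, shadowing below the lesion, scan-cone geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import ValidationError

__all__ = ["Artifact", "FatBand", "PhantomSpec", "Phantom",
           "generate", "generate_cohort"]

SPECKLE_STD_DEFAULT = 0.25        # std of the unit-mean multiplicative field
SPECKLE_CORR_DEFAULT = 1.5        # smoothing sigma of the speckle field, px


@dataclass
class Artifact:
    """A bright distractor: a band (full-width horizontal strip) or a blob."""

    kind: str                      # "band" | "blob"
    row: int
    col: int = 0
    height: int = 10               # band thickness / blob semi-axis (rows)
    width: int = 10                # blob semi-axis (cols); ignored for bands
    gray: float = 225.0


@dataclass
class FatBand:
    """Dark low-echo band touching the top edge."""

    height: int = 35
    gray: float = 55.0


@dataclass
class PhantomSpec:
    height: int = 256
    width: int = 256
    lesion_center: Tuple[float, float] = (128.0, 128.0)   # (row, col)
    lesion_axes: Tuple[float, float] = (35.0, 28.0)       # semi-axes (row, col)
    lesion_rotation: float = 0.0                          # radians
    lesion_gray: float = 45.0
    background_gray: float = 155.0
    speckle: float = SPECKLE_STD_DEFAULT
    speckle_corr: float = SPECKLE_CORR_DEFAULT
    artifacts: List[Artifact] = field(default_factory=list)
    fat_band: Optional[FatBand] = None
    seed: int = 0


@dataclass
class Phantom:
    image: np.ndarray
    lesion_mask: np.ndarray
    spec: PhantomSpec


def _ellipse_mask(shape: Tuple[int, int], center: Tuple[float, float],
                  axes: Tuple[float, float], rotation: float) -> np.ndarray:
    rr, cc = np.indices(shape)
    dr, dc = rr - center[0], cc - center[1]
    cos_t, sin_t = np.cos(rotation), np.sin(rotation)
    u = cos_t * dr + sin_t * dc
    v = -sin_t * dr + cos_t * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _speckle_field(shape: Tuple[int, int], std: float, corr: float,
                   rng: np.random.Generator) -> np.ndarray:
    if std == 0:
        return np.ones(shape)
    raw = rng.exponential(scale=1.0, size=shape)       # squared-Rayleigh law
    raw = gaussian_filter(raw, corr, mode="reflect")
    raw = (raw - raw.mean()) / raw.std()
    return np.clip(1.0 + std * raw, 0.0, None)


def generate(spec: PhantomSpec) -> Phantom:
    """Render a phantom; deterministic for a fixed spec (including seed)."""
    h, w = spec.height, spec.width
    if h < 32 or w < 32:
        raise ValidationError("phantom must be at least 32x32")
    cr, cc = spec.lesion_center
    a, b = spec.lesion_axes
    reach = max(a, b)
    if (cr - reach < 1 or cr + reach > h - 2 or cc - reach < 1
            or cc + reach > w - 2):
        raise ValidationError("lesion must lie strictly inside the image frame")

    base = np.full((h, w), float(spec.background_gray))
    if spec.fat_band is not None:
        base[: spec.fat_band.height, :] = spec.fat_band.gray
    for art in spec.artifacts:
        if art.kind == "band":
            base[art.row: art.row + art.height, :] = art.gray
        elif art.kind == "blob":
            blob = _ellipse_mask((h, w), (art.row, art.col),
                                 (art.height, art.width), 0.0)
            base[blob] = art.gray
        else:
            raise ValidationError(f"unknown artifact kind {art.kind!r}")
    lesion_mask = _ellipse_mask((h, w), spec.lesion_center, spec.lesion_axes,
                                spec.lesion_rotation)
    if spec.lesion_gray >= spec.background_gray:
        raise ValidationError("lesion must be darker than the background")
    base[lesion_mask] = spec.lesion_gray

    rng = np.random.default_rng(spec.seed)
    image = np.clip(base * _speckle_field((h, w), spec.speckle,
                                          spec.speckle_corr, rng), 0.0, 255.0)
    return Phantom(image=image, lesion_mask=lesion_mask, spec=spec)


def generate_cohort(n: int, seed: int, difficulty: str = "easy",
                    height: int = 256, width: int = 256) -> List[Phantom]:
    """Generate ``n`` phantoms with randomized lesion size class, position,
    eccentricity and rotation.

    ``easy``: clean background, lesion/background contrast >= 60 gray levels.
    ``hard``: additionally a dark fat band at the top edge and, usually,
    bright artifact bands/blobs — the distractor scenarios the rejection
    loop exists for.
    Size classes (small / medium / large semi-axes) are cycled so each third
    of the cohort covers one class.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    if difficulty not in ("easy", "hard"):
        raise ValidationError(f"difficulty must be 'easy' or 'hard', got {difficulty!r}")
    rng = np.random.default_rng(seed)
    size_classes = [(12.0, 20.0), (25.0, 40.0), (42.0, 58.0)]
    phantoms: List[Phantom] = []
    for i in range(n):
        lo, hi = size_classes[i % 3]
        a = rng.uniform(lo, hi)
        b = a * rng.uniform(0.6, 1.0)
        rotation = rng.uniform(0.0, np.pi)
        lesion_gray = rng.uniform(35.0, 60.0)
        background_gray = rng.uniform(140.0, 180.0)

        fat_band = None
        artifacts: List[Artifact] = []
        top_margin = 2.0
        if difficulty == "hard":
            # the distractor the rejection loop exists for: a low-echo band
            # darker (hence more salient) than the lesion itself
            fat_band = FatBand(height=int(rng.integers(28, 50)),
                               gray=float(rng.uniform(15.0, lesion_gray - 8.0)))
            top_margin = fat_band.height + 4.0
            if rng.random() < 0.7:
                artifacts.append(Artifact(
                    kind="band",
                    row=int(rng.integers(height - 40, height - 15)),
                    height=int(rng.integers(6, 14)),
                    gray=float(rng.uniform(210.0, 240.0))))
            if rng.random() < 0.4:
                artifacts.append(Artifact(
                    kind="blob",
                    row=int(rng.integers(height // 2, height - 30)),
                    col=int(rng.integers(25, width - 25)),
                    height=int(rng.integers(6, 12)),
                    width=int(rng.integers(10, 20)),
                    gray=float(rng.uniform(205.0, 235.0))))

        reach = max(a, b)
        cr = rng.uniform(top_margin + reach + 2.0, height - reach - 3.0)
        ccol = rng.uniform(reach + 2.0, width - reach - 3.0)
        spec = PhantomSpec(
            height=height, width=width,
            lesion_center=(cr, ccol), lesion_axes=(a, b),
            lesion_rotation=rotation, lesion_gray=lesion_gray,
            background_gray=background_gray,
            artifacts=artifacts, fat_band=fat_band,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        phantoms.append(generate(spec))
    return phantoms
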