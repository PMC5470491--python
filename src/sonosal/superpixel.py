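"""SLIC superpixel partitioning and the global superpixel-contrast saliency map.

SLIC here is grid-seeded local k-means in joint (gray, space) coordinates:
cluster centers start on a regular grid at spacing S = sqrt(N/K); each center
competes for pixels within a 2S x 2S window under the combined distance

    D = sqrt(d_gray^2 + (d_xy / S)^2 * m^2)

where m is the compactness (larger m -> squarer regions).  After a fixed
number of assignment/update rounds, connectivity is enforced: connected
components smaller than N/(4K) pixels are merged into their largest
4-adjacent neighbor.  Gray values are used raw (0-255); images are
single-channel so no color-space conversion applies.

The saliency of region r_k is its size-, distance- and contrast-weighted
dissimilarity to all other regions,

    SSP(r_k) = W(r_k) * sum_{i != k} (n_i / N) * exp(-d_ki^2 / (2 delta^2)) * |g_k - g_i|

with W the darkness weight (darkest region -> 1, brightest -> 0), d_ki the
centroid distance normalized by the image diagonal, and delta (default 0.05)
limiting the reach of far regions.  Dark, large, locally contrasting regions
— hypoechoic lesions — score highest; thin bright bands score low because of
their small area fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _cc_label

from .io import ValidationError

__all__ = [
    "SuperpixelPartition",
    "SuperpixelSaliency",
    "slic_segment",
    "region_distance",
    "region_weight",
    "superpixel_saliency",
]

DELTA_DEFAULT = 0.05
SLIC_K_DEFAULT = 400
SLIC_M_DEFAULT = 40.0
SLIC_ITER_DEFAULT = 10


@dataclass
class SuperpixelPartition:
    """Per-pixel label image plus per-region statistics."""

    labels: np.ndarray            # int array, contiguous labels starting at 0
    k_requested: int
    compactness: float
    sizes: np.ndarray             # n_k, pixel counts
    mean_gray: np.ndarray         # g_k in [0, 255]
    centroids: np.ndarray         # (K, 2) array of (row, col) means

    @property
    def n_regions(self) -> int:
        return int(self.sizes.shape[0])

    @property
    def n_pixels(self) -> int:
        return int(self.labels.size)


@dataclass
class SuperpixelSaliency:
    """Per-region raw scores and the [0,1]-rescaled rendered map."""

    region_scores: np.ndarray     # raw SSP(r_k), before rescaling
    rendered: np.ndarray          # per-pixel map, rescaled to [0, 1]
    partition: SuperpixelPartition = field(repr=False, default=None)


def _region_stats(labels: np.ndarray, image: np.ndarray):
    k = labels.max() + 1
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=k).astype(np.float64)
    gray = np.bincount(flat, weights=image.ravel(), minlength=k) / sizes
    rr, cc = np.indices(labels.shape)
    rows = np.bincount(flat, weights=rr.ravel(), minlength=k) / sizes
    cols = np.bincount(flat, weights=cc.ravel(), minlength=k) / sizes
    return sizes, gray, np.stack([rows, cols], axis=1)


def _enforce_connectivity(labels: np.ndarray, min_size: float) -> np.ndarray:
    """Split disconnected superpixels, then merge small components into their
    largest 4-adjacent neighbor."""
    comp = _cc_label(labels + 1, connectivity=1) - 1
    n_comp = comp.max() + 1
    sizes = np.bincount(comp.ravel(), minlength=n_comp)
    # adjacency via horizontal/vertical neighbor pairs
    pairs = set()
    a, b = comp[:, :-1].ravel(), comp[:, 1:].ravel()
    mask = a != b
    pairs.update(zip(a[mask].tolist(), b[mask].tolist()))
    a, b = comp[:-1, :].ravel(), comp[1:, :].ravel()
    mask = a != b
    pairs.update(zip(a[mask].tolist(), b[mask].tolist()))
    neighbors = {i: set() for i in range(n_comp)}
    for i, j in pairs:
        neighbors[i].add(j)
        neighbors[j].add(i)
    # merge smallest-first so chains of orphans collapse into real regions
    target = np.arange(n_comp)

    def resolve(i: int) -> int:
        while target[i] != i:
            i = target[i]
        return i

    order = np.argsort(sizes, kind="stable")
    current_sizes = sizes.astype(np.int64).copy()
    for i in order:
        if current_sizes[resolve(i)] >= min_size:
            continue
        ri = resolve(i)
        cands = {resolve(j) for j in neighbors[i]} - {ri}
        if not cands:
            continue
        best = max(cands, key=lambda j: (current_sizes[j], -j))
        target[ri] = best
        current_sizes[best] += current_sizes[ri]
    merged = np.array([resolve(i) for i in range(n_comp)])
    _, contiguous = np.unique(merged, return_inverse=True)
    return contiguous[comp]


def slic_segment(image: np.ndarray, k: int = SLIC_K_DEFAULT,
                 m: float = SLIC_M_DEFAULT,
                 max_iter: int = SLIC_ITER_DEFAULT) -> SuperpixelPartition:
    """Partition a gray image into ~k compact superpixels."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValidationError("slic_segment expects a 2-D gray image")
    h, w = img.shape
    n = h * w
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds pixel count {n}")
    if m <= 0:
        raise ValidationError(f"compactness m must be positive, got {m}")
    s = math.sqrt(n / k)

    # grid seeding: gr x gc centers with gr*gc >= k, aspect following the image
    gr = max(1, round(math.sqrt(k * h / w)))
    gc = max(1, math.ceil(k / gr))
    cr = (np.arange(gr) + 0.5) * h / gr
    cc = (np.arange(gc) + 0.5) * w / gc
    centers_rc = np.array([(r, c) for r in cr for c in cc])
    centers_g = img[np.clip(np.rint(centers_rc[:, 0]).astype(int), 0, h - 1),
                    np.clip(np.rint(centers_rc[:, 1]).astype(int), 0, w - 1)]
    n_centers = centers_rc.shape[0]

    labels = np.zeros((h, w), dtype=np.int64)
    for _ in range(max_iter):
        best = np.full((h, w), np.inf)
        labels.fill(0)
        for ci in range(n_centers):
            r0, c0 = centers_rc[ci]
            rlo, rhi = max(0, int(r0 - 2 * s)), min(h, int(r0 + 2 * s) + 1)
            clo, chi = max(0, int(c0 - 2 * s)), min(w, int(c0 + 2 * s) + 1)
            if rlo >= rhi or clo >= chi:
                continue
            win = img[rlo:rhi, clo:chi]
            rr = np.arange(rlo, rhi)[:, None] - r0
            cc2 = np.arange(clo, chi)[None, :] - c0
            d2 = (win - centers_g[ci]) ** 2 + (rr ** 2 + cc2 ** 2) * (m / s) ** 2
            sub_best = best[rlo:rhi, clo:chi]
            upd = d2 < sub_best
            sub_best[upd] = d2[upd]
            labels[rlo:rhi, clo:chi][upd] = ci
        # update centers to cluster means; empty clusters stay put
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=n_centers).astype(np.float64)
        nonzero = counts > 0
        sum_g = np.bincount(flat, weights=img.ravel(), minlength=n_centers)
        rr_idx, cc_idx = np.indices((h, w))
        sum_r = np.bincount(flat, weights=rr_idx.ravel(), minlength=n_centers)
        sum_c = np.bincount(flat, weights=cc_idx.ravel(), minlength=n_centers)
        centers_g[nonzero] = sum_g[nonzero] / counts[nonzero]
        centers_rc[nonzero, 0] = sum_r[nonzero] / counts[nonzero]
        centers_rc[nonzero, 1] = sum_c[nonzero] / counts[nonzero]

    labels = _enforce_connectivity(labels, min_size=n / (4.0 * n_centers))
    sizes, gray, centroids = _region_stats(labels, img)
    return SuperpixelPartition(labels=labels, k_requested=k, compactness=m,
                               sizes=sizes, mean_gray=gray, centroids=centroids)


def region_distance(centroid_a: np.ndarray, centroid_b: np.ndarray,
                    image_diag: float) -> float:
    """Euclidean centroid distance normalized by the image diagonal (-> [0,1])."""
    d = float(np.hypot(centroid_a[0] - centroid_b[0], centroid_a[1] - centroid_b[1]))
    return d / image_diag


def region_weight(mean_gray: np.ndarray) -> np.ndarray:
    """Darkness weight W(r_k) = (max(g) - g_k) / (max(g) - min(g)).

    The darkest region gets 1, the brightest 0.  If all regions share one
    gray value there is nothing salient and every weight is 0.
    """
    g = np.asarray(mean_gray, dtype=np.float64)
    if g.size == 0:
        raise ValidationError("region_weight needs at least one region")
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.zeros_like(g)
    return (hi - g) / (hi - lo)


def superpixel_saliency(partition: SuperpixelPartition,
                        delta: float = DELTA_DEFAULT) -> SuperpixelSaliency:
    """Global-contrast saliency per region, rendered as a [0,1] pixel map."""
    if delta <= 0:
        raise ValidationError(f"delta must be positive, got {delta}")
    k = partition.n_regions
    n = float(partition.sizes.sum())  # == n_pixels for any valid partition
    h, w = partition.labels.shape
    diag = math.hypot(h - 1, w - 1)
    weights = region_weight(partition.mean_gray)

    cen = partition.centroids
    diff = cen[:, None, :] - cen[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2)) / diag
    gray_contrast = np.abs(partition.mean_gray[:, None] - partition.mean_gray[None, :])
    area = partition.sizes / n
    kernel = np.exp(-d ** 2 / (2.0 * delta ** 2))
    terms = area[None, :] * kernel * gray_contrast
    np.fill_diagonal(terms, 0.0)
    scores = weights * terms.sum(axis=1)

    rendered = scores[partition.labels]
    peak = rendered.max()
    if peak > 0:
        rendered = rendered / peak
    return SuperpixelSaliency(region_scores=scores, rendered=rendered,
                              partition=partition)
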