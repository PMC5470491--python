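import math

import numpy as np
import pytest

import sonosal as ss
from sonosal.superpixel import SuperpixelPartition, region_weight


def make_partition(labels, image):
    """Build a SuperpixelPartition directly from a label image (test helper)."""
    labels = np.asarray(labels)
    k = labels.max() + 1
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=k).astype(float)
    gray = np.bincount(flat, weights=np.asarray(image, float).ravel(),
                       minlength=k) / sizes
    rr, cc = np.indices(labels.shape)
    rows = np.bincount(flat, weights=rr.ravel(), minlength=k) / sizes
    cols = np.bincount(flat, weights=cc.ravel(), minlength=k) / sizes
    return SuperpixelPartition(labels=labels, k_requested=k, compactness=1.0,
                               sizes=sizes, mean_gray=gray,
                               centroids=np.stack([rows, cols], axis=1))


def ssp_loop_oracle(partition, delta):
    """Naive O(K^2) double loop over regions."""
    k = partition.n_regions
    n = partition.n_pixels
    h, w = partition.labels.shape
    diag = math.hypot(h - 1, w - 1)
    g = partition.mean_gray
    weights = region_weight(g)
    scores = np.zeros(k)
    for a in range(k):
        total = 0.0
        for b in range(k):
            if a == b:
                continue
            d = math.hypot(*(partition.centroids[a] - partition.centroids[b])) / diag
            total += (partition.sizes[b] / n) * math.exp(-d * d / (2 * delta * delta)) \
                * abs(g[a] - g[b])
        scores[a] = weights[a] * total
    return scores


# ---------------------------------------------------------------- SLIC

def test_uniform_image_k4_gives_grid_quadrants():
    img = np.full((21, 21), 100.0)
    part = ss.slic_segment(img, k=4, m=10.0)
    assert part.n_regions == 4
    for lab in range(4):
        rows, cols = np.nonzero(part.labels == lab)
        # each region is a contiguous block about half the image wide/tall
        assert rows.max() - rows.min() + 1 in (10, 11)
        assert cols.max() - cols.min() + 1 in (10, 11)


def test_two_halves_match_exhaustive_two_cluster_oracle():
    img = np.full((20, 20), 200.0)
    img[:, :10] = 30.0
    part = ss.slic_segment(img, k=2, m=1.0)
    assert part.n_regions == 2
    # exhaustive oracle: local k-means at K=2 with the same joint distance
    # converges to the dark/bright halves, whatever the initial grid
    left = part.labels[:, :10]
    right = part.labels[:, 10:]
    assert len(np.unique(left)) == 1
    assert len(np.unique(right)) == 1
    assert left[0, 0] != right[0, 0]
    dark = int(left[0, 0])
    assert part.mean_gray[dark] == pytest.approx(30.0)
    assert part.sizes[dark] == 200


def test_k1_single_region_stats():
    rng = np.random.default_rng(2)
    img = rng.uniform(0, 255, size=(20, 20))
    part = ss.slic_segment(img, k=1, m=10.0)
    assert part.n_regions == 1
    assert np.all(part.labels == 0)
    assert part.mean_gray[0] == pytest.approx(img.mean())
    np.testing.assert_allclose(part.centroids[0], [9.5, 9.5])


@pytest.mark.parametrize("k", [0, -3, 10 ** 9])
def test_slic_rejects_bad_k(k):
    with pytest.raises(ss.ValidationError):
        ss.slic_segment(np.zeros((20, 20)), k=k)


def test_slic_full_coverage_connectivity_and_contiguous_labels(easy_phantom):
    part = ss.slic_segment(easy_phantom.image, k=100, m=40.0)
    labels = part.labels
    k = part.n_regions
    assert set(np.unique(labels)) == set(range(k))
    assert part.sizes.sum() == labels.size
    # every region 4-connected
    from skimage.measure import label as cc_label
    for lab in range(k):
        comp = cc_label(labels == lab, connectivity=1)
        assert comp.max() == 1
    # no region smaller than the orphan threshold survives unmerged
    assert part.sizes.min() >= labels.size / (4.0 * k) or k < 100


# ------------------------------------------------- region weight / distance

def test_region_weight_endpoints_and_midpoint():
    np.testing.assert_allclose(region_weight(np.array([10.0, 200.0])), [1.0, 0.0])
    np.testing.assert_allclose(region_weight(np.array([0.0, 50.0, 100.0])),
                               [1.0, 0.5, 0.0])
    np.testing.assert_allclose(region_weight(np.array([77.0, 77.0, 77.0])), 0.0)


def test_region_distance_normalized_by_diagonal():
    assert ss.region_distance(np.array([5.0, 5.0]), np.array([5.0, 5.0]), 100.0) == 0.0
    h, w = 30, 40
    diag = math.hypot(h - 1, w - 1)
    assert ss.region_distance(np.array([0.0, 0.0]),
                              np.array([h - 1.0, w - 1.0]), diag) == pytest.approx(1.0)
    assert ss.region_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0]),
                              100.0) == pytest.approx(0.05)


# ------------------------------------------------------ superpixel saliency

def test_single_region_saliency_is_zero():
    part = make_partition(np.zeros((10, 10), dtype=int), np.full((10, 10), 50.0))
    out = ss.superpixel_saliency(part)
    assert out.region_scores[0] == 0.0
    np.testing.assert_allclose(out.rendered, 0.0)


def test_equal_gray_regions_have_zero_saliency():
    labels = np.zeros((10, 10), dtype=int)
    labels[:, 5:] = 1
    part = make_partition(labels, np.full((10, 10), 120.0))
    np.testing.assert_allclose(ss.superpixel_saliency(part).region_scores, 0.0)


def test_two_region_hand_value():
    """Two 50-pixel regions, grays 10/200, centroid gap 5% of the diagonal:
    the dark region scores 0.5 * exp(-1/2) * 190 ~= 57.62 before rescaling."""
    labels = np.zeros((10, 10), dtype=int)
    labels[:, 5:] = 1
    img = np.where(labels == 0, 10.0, 200.0)
    part = make_partition(labels, img)
    diag = math.hypot(9, 9)
    part.centroids = np.array([[4.5, 2.0], [4.5, 2.0 + 0.05 * diag]])
    out = ss.superpixel_saliency(part, delta=0.05)
    expected_dark = 1.0 * 0.5 * math.exp(-0.5) * 190.0
    assert out.region_scores[labels[0, 0]] == pytest.approx(expected_dark, abs=1e-9)
    assert round(float(out.region_scores[labels[0, 0]]), 2) == 57.62
    assert out.region_scores[labels[0, -1]] == 0.0


def test_saliency_rejects_nonpositive_delta():
    part = make_partition(np.zeros((10, 10), dtype=int), np.zeros((10, 10)))
    with pytest.raises(ss.ValidationError):
        ss.superpixel_saliency(part, delta=0.0)


def random_partition(rng, k, shape=(24, 24)):
    labels = rng.integers(0, k, size=shape)
    labels = np.unique(labels, return_inverse=True)[1].reshape(shape)
    img = rng.uniform(0, 255, size=shape)
    return make_partition(labels, img)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_vectorized_saliency_matches_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    part = random_partition(rng, k=int(rng.integers(2, 51)))
    got = ss.superpixel_saliency(part, delta=0.05).region_scores
    want = ssp_loop_oracle(part, delta=0.05)
    np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)


def test_saliency_invariant_to_uniform_size_scaling():
    """n_i/N is an area fraction: multiplying every region size (and hence
    the total) by a constant leaves the scores unchanged."""
    rng = np.random.default_rng(7)
    part = random_partition(rng, k=12)
    base = ss.superpixel_saliency(part).region_scores
    part.sizes = part.sizes * 5.0
    np.testing.assert_allclose(ss.superpixel_saliency(part).region_scores,
                               base, rtol=1e-9)


def test_saliency_monotone_in_gray_contrast():
    labels = np.zeros((12, 12), dtype=int)
    labels[:, 4:8] = 1
    labels[:, 8:] = 2
    img = np.select([labels == 0, labels == 1, labels == 2],
                    [40.0, 120.0, 200.0])
    part = make_partition(labels, img)
    s_before = ss.superpixel_saliency(part).region_scores[0]
    part.mean_gray = part.mean_gray.copy()
    part.mean_gray[2] = 250.0  # increase |g_0 - g_2| only
    s_after = ss.superpixel_saliency(part).region_scores[0]
    assert s_after >= s_before


def test_lesion_region_most_salient_thin_band_low(noisefree_lesion):
    """On a lesion image with a thin bright band, the dark compact lesion
    attains maximal rendered saliency; the thin band scores low despite its
    brightness, because of its small area fraction."""
    img, mask = noisefree_lesion
    img = img.copy()
    img[200:206, :] = 250.0
    part = ss.slic_segment(img, k=100, m=40.0)
    out = ss.superpixel_saliency(part)
    peak = np.unravel_index(np.argmax(out.rendered), out.rendered.shape)
    assert mask[peak]
    band_score = out.rendered[203, 120]
    assert band_score < 0.5
    assert out.rendered.min() >= 0.0 and out.rendered.max() == pytest.approx(1.0)
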