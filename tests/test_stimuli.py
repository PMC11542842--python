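"""Stimulus metrics: color similarity, CIELAB operations, Procrustes shapes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from skimage import color as skcolor

import memcolor as mc


def uniform_image(rgb, h=8, w=8):
    px = np.tile(np.asarray(rgb, dtype=float), (h, w, 1))
    return mc.StimulusImage(px, np.ones((h, w), dtype=bool))


# --------------------------------------------------------------------- color


def test_color_similarity_closed_forms():
    """Identical -> 1; black vs white -> 0; pure red vs green -> 1 - sqrt(2/3)."""
    a = uniform_image((10, 200, 30))
    assert mc.color_similarity(a, a) == pytest.approx(1.0, abs=1e-12)
    black = uniform_image((0, 0, 0))
    white = uniform_image((255, 255, 255))
    assert mc.color_similarity(black, white) == pytest.approx(0.0, abs=1e-12)
    red = uniform_image((255, 0, 0))
    green = uniform_image((0, 255, 0))
    assert mc.color_similarity(red, green) == pytest.approx(1 - np.sqrt(2 / 3), abs=1e-12)


@given(
    st.tuples(*[st.integers(0, 255)] * 3),
    st.tuples(*[st.integers(0, 255)] * 3),
)
def test_color_similarity_symmetric_bounded(rgb1, rgb2):
    a, b = uniform_image(rgb1), uniform_image(rgb2)
    s = mc.color_similarity(a, b)
    assert 0.0 <= s <= 1.0
    assert s == pytest.approx(mc.color_similarity(b, a), abs=1e-12)
    assert (s == pytest.approx(1.0, abs=1e-12)) == (rgb1 == rgb2)


def test_empty_foreground_rejected():
    img = mc.StimulusImage(np.zeros((4, 4, 3)), np.zeros((4, 4), dtype=bool))
    with pytest.raises(ValueError, match="foreground"):
        mc.color_similarity(img, img)


# ------------------------------------------------------------------- CIELAB


@pytest.fixture
def photo():
    rng = np.random.default_rng(0)
    px = rng.uniform(40, 220, size=(16, 16, 3))
    mask = np.zeros((16, 16), dtype=bool)
    mask[4:12, 4:12] = True
    return mc.StimulusImage(px, mask)


def test_equiluminant_grayscale(photo):
    out = mc.equiluminant_grayscale(photo, target_L=42.4)
    lab = out.lab()
    assert lab[..., 0][out.foreground_mask].mean() == pytest.approx(42.4, abs=0.5)
    assert np.abs(lab[..., 1:]).max() < 0.5  # achromatic
    # an achromatic input keeps its lightness ordering
    gray = mc.equiluminant_grayscale(photo, target_L=60.0)
    gray2 = mc.equiluminant_grayscale(gray, target_L=42.4)
    L1 = gray.lab()[..., 0][gray.foreground_mask]
    L2 = gray2.lab()[..., 0][gray.foreground_mask]
    assert sps.spearmanr(L1, L2).statistic == pytest.approx(1.0, abs=1e-9)


def test_hue_swap_targets_and_luminance(photo):
    target = (30.0, 20.0)  # a moderate in-gamut chroma
    mid = mc.equiluminant_grayscale(photo, target_L=50.0)
    out = mc.hue_swap(mid, target)
    lab = out.lab()
    fg = out.foreground_mask
    assert lab[..., 1][fg].mean() == pytest.approx(target[0], abs=0.5)
    assert lab[..., 2][fg].mean() == pytest.approx(target[1], abs=0.5)
    # per-pixel L* preserved
    assert np.allclose(lab[..., 0][fg], mid.lab()[..., 0][fg], atol=0.5)
    # double swap red -> green -> red equals the single red version
    red, green = (45.0, 35.0), (-25.0, 30.0)
    once = mc.hue_swap(mid, red)
    twice = mc.hue_swap(mc.hue_swap(mid, green), red)
    # equality up to gamut-clipping error (< 2 of 255 levels)
    assert np.abs(once.pixels - twice.pixels).max() < 2.0


def test_foreground_stats(photo):
    count, hist = mc.foreground_stats(photo)
    assert count == 64
    assert hist.sum() == 64
    empty = mc.StimulusImage(photo.pixels, np.zeros_like(photo.foreground_mask))
    count0, hist0 = mc.foreground_stats(empty)
    assert count0 == 0 and hist0.sum() == 0
    full = mc.StimulusImage(np.zeros((100, 100, 3)), np.ones((100, 100), dtype=bool))
    assert mc.foreground_stats(full)[0] == 10_000
    # identical L* distributions -> histogram intersection 1
    _, h1 = mc.foreground_stats(photo)
    assert mc.histogram_intersection(h1, h1) == pytest.approx(1.0)


# ---------------------------------------------------------------- Procrustes


def circle(n=120, r=1.0, cx=0.0, cy=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return mc.ShapeBoundary(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def blob(seed, n=90):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 1.0 + 0.3 * np.sin(3 * t + rng.uniform(0, np.pi)) + 0.15 * np.cos(5 * t)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def transform(pts, angle=0.0, scale=1.0, shift=(0.0, 0.0), mirror=False):
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    out = pts @ R.T * scale + np.asarray(shift)
    if mirror:
        out = out * np.array([1.0, -1.0])
    return out


@pytest.mark.parametrize("mirror", [False, True])
def test_procrustes_invariances(mirror):
    """Similarity transforms (and reflection) leave the distance at zero."""
    pts = blob(1)
    b1 = mc.ShapeBoundary(pts)
    b2 = mc.ShapeBoundary(transform(pts, angle=0.7, scale=2.3, shift=(4, -2), mirror=mirror))
    assert mc.shape_dissimilarity(b1, b2, n_resample=100) == pytest.approx(0.0, abs=1e-9)


def _brute_force_disparity(a, b):
    """Dense rotation/reflection search over the same resampled points."""
    best = np.inf
    thetas = np.linspace(0, 2 * np.pi, 36000, endpoint=False)
    cos, sin = np.cos(thetas), np.sin(thetas)
    for flip in (1.0, -1.0):
        bf = b * np.array([1.0, flip])
        # inner product <a, b R(theta)> is A cos + B sin over the grid
        A = (a * bf).sum()
        B = (a[:, 0] * bf[:, 1] - a[:, 1] * bf[:, 0]).sum()
        inner = A * cos + B * sin
        best = min(best, 1.0 - float(inner.max()) ** 2)
    return max(best, 0.0)


def test_procrustes_matches_brute_force_oracle():
    """Circle vs square (and random blobs) agree with an independent search."""
    sq = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)
    pairs = [
        (circle().points, sq),
        (blob(2), blob(3)),
        (blob(4), transform(blob(4), angle=1.2, scale=0.5)),
    ]
    from memcolor.stimuli import _standardize, resample_boundary

    for p1, p2 in pairs:
        b1, b2 = mc.ShapeBoundary(p1), mc.ShapeBoundary(p2)
        got = mc.shape_dissimilarity(b1, b2, n_resample=100)
        a = _standardize(resample_boundary(b1, 100))
        raw = resample_boundary(b2, 100)
        want = np.inf
        for direction in (raw, raw[::-1]):
            base = _standardize(direction)
            for offset in range(100):
                want = min(want, _brute_force_disparity(a, np.roll(base, offset, axis=0)))
        assert got == pytest.approx(want, abs=1e-6)
        assert 0.0 <= got <= 1.0


def test_degenerate_boundary_rejected():
    with pytest.raises(ValueError):
        mc.ShapeBoundary(np.zeros((2, 2)))
    b = mc.ShapeBoundary(np.ones((5, 2)))
    with pytest.raises(ValueError, match="degenerate"):
        mc.shape_dissimilarity(b, circle())


def test_boundary_from_mask_and_matrix():
    mask = np.zeros((20, 20), dtype=bool)
    mask[5:15, 5:15] = True
    boundary = mc.boundary_from_mask(mask)
    assert boundary.n_points >= 3
    # square mask outline vs explicit square: near-identical shapes
    sq = mc.ShapeBoundary(np.array([[0, 0], [0, 9], [9, 9], [9, 0]], dtype=float))
    assert mc.shape_dissimilarity(boundary, sq, n_resample=80) < 0.01

    items = {"circle": [circle(r=1.0), circle(r=2.0)], "square": [sq]}
    m = mc.average_similarity_matrix(
        items, lambda x, y: mc.shape_similarity(x, y, n_resample=60)
    )
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 1.0)
    assert 0.0 <= m.loc["circle", "square"] < 1.0
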