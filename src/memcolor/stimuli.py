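"""Stimulus-level metrics: color similarity, Procrustes shape distance,
equiluminant grayscale conversion, hue swapping and foreground statistics.

Color similarity between two images is one minus the Euclidean distance
of their foreground-mean RGB vectors, normalized by the RGB-cube
diagonal sqrt(3 * 255^2), so it lives in [0, 1] and equals 1 iff the mean
colors coincide.  Shape dissimilarity is the full Procrustes distance
between arc-length-resampled outlines (translation, uniform scaling,
rotation and reflection removed).  RGB <-> CIELAB conversions assume
sRGB primaries and D65 white.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color as skcolor
from skimage import measure as skmeasure

_RGB_DIAGONAL = np.sqrt(3.0) * 255.0


@dataclass
class StimulusImage:
    """An RGB stimulus with a boolean foreground mask.

    Pixels are stored as float64 in [0, 255] (8-bit convention without
    forced quantization, so CIELAB round trips stay exact for in-gamut
    colors); uint8 input is accepted.
    """

    pixels: np.ndarray
    foreground_mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.foreground_mask = np.asarray(self.foreground_mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.foreground_mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape does not match pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")

    def mean_rgb(self) -> np.ndarray:
        if not self.foreground_mask.any():
            raise ValueError("empty foreground mask")
        return self.pixels[self.foreground_mask].mean(axis=0)

    def lab(self) -> np.ndarray:
        return skcolor.rgb2lab(self.pixels / 255.0)


def _lab_to_image(lab: np.ndarray, mask: np.ndarray) -> StimulusImage:
    rgb = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0) * 255.0
    return StimulusImage(rgb, mask)


def color_similarity(img1: StimulusImage, img2: StimulusImage) -> float:
    """Foreground mean-RGB similarity in [0, 1] (1 = identical mean color)."""
    d = np.linalg.norm(img1.mean_rgb() - img2.mean_rgb())
    return float(1.0 - d / _RGB_DIAGONAL)


def equiluminant_grayscale(img: StimulusImage, target_L: float = 42.4) -> StimulusImage:
    """Achromatic version of an image recentered at the target lightness.

    The CIELAB L* distribution is shifted so the foreground mean equals
    ``target_L`` while its original spread (SD) is preserved; a* and b*
    are set to 0; the result is converted back to RGB with out-of-gamut
    values clipped.
    """
    lab = img.lab()
    shift = target_L - lab[..., 0][img.foreground_mask].mean()
    out = np.zeros_like(lab)
    out[..., 0] = np.clip(lab[..., 0] + shift, 0.0, 100.0)
    return _lab_to_image(out, img.foreground_mask)


def hue_swap(
    img: StimulusImage, target_ab: tuple[float, float], source_hue: object = None
) -> StimulusImage:
    """Replace every foreground pixel's chromaticity, keeping its lightness.

    ``target_ab`` is a CIE (a*, b*) pair, e.g. (60.0, 47.0) for the red
    used on strawberries; per-pixel L* is untouched (up to gamut
    clipping on back-conversion).  ``source_hue`` is accepted for
    symmetry with swap bookkeeping but does not alter the result: the
    whole foreground is recolored.
    """
    lab = img.lab()
    a, b = float(target_ab[0]), float(target_ab[1])
    out = lab.copy()
    out[..., 1][img.foreground_mask] = a
    out[..., 2][img.foreground_mask] = b
    return _lab_to_image(out, img.foreground_mask)


def foreground_stats(
    img: StimulusImage, bins: np.ndarray | None = None
) -> tuple[int, np.ndarray]:
    """Foreground pixel count and its L* histogram (fixed 0..100 binning)."""
    if bins is None:
        bins = np.linspace(0.0, 100.0, 21)
    count = int(img.foreground_mask.sum())
    if count == 0:
        return 0, np.zeros(len(bins) - 1)
    L = img.lab()[..., 0][img.foreground_mask]
    hist, _ = np.histogram(L, bins=bins)
    return count, hist


def histogram_intersection(h1: np.ndarray, h2: np.ndarray) -> float:
    """Normalized overlap of two histograms (1 = identical shapes)."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.sum() == 0 or h2.sum() == 0:
        return 0.0
    return float(np.minimum(h1 / h1.sum(), h2 / h2.sum()).sum())


# --------------------------------------------------------------------------
# shape boundaries and Procrustes distance


@dataclass
class ShapeBoundary:
    """Ordered (x, y) points tracing a closed object outline."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be N x 2")
        if len(self.points) < 3:
            raise ValueError("a boundary needs at least 3 points")
        # drop a duplicated closing point; adjacency is implied
        if np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]

    @property
    def n_points(self) -> int:
        return len(self.points)


def boundary_from_mask(mask: np.ndarray) -> ShapeBoundary:
    """Outline of the largest connected foreground component."""
    contours = skmeasure.find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise ValueError("mask has no foreground boundary")
    longest = max(contours, key=len)
    return ShapeBoundary(longest[:, ::-1])  # (row, col) -> (x, y)


def resample_boundary(boundary: ShapeBoundary, n: int = 200) -> np.ndarray:
    """``n`` points equally spaced along the closed contour's arc length."""
    pts = boundary.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        raise ValueError("degenerate boundary: all points identical")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


def _standardize(pts: np.ndarray) -> np.ndarray:
    """Center and scale to unit Frobenius norm (degenerate -> error)."""
    out = pts - pts.mean(axis=0)
    norm = np.linalg.norm(out)
    if norm == 0:
        raise ValueError("degenerate boundary: all points identical")
    return out / norm


def _procrustes_disparity(a: np.ndarray, b: np.ndarray, scaling: bool = True) -> float:
    """Squared full-Procrustes distance of two standardized point sets.

    The optimal orthogonal map (rotation or reflection) comes from the
    SVD of a^T b; with scaling the disparity is 1 - (sum of singular
    values)^2, which lives in [0, 1].
    """
    u, s, vt = np.linalg.svd(a.T @ b)
    trace = s.sum()
    if scaling:
        return float(max(0.0, 1.0 - trace ** 2))
    return float(max(0.0, 2.0 - 2.0 * trace))


def shape_dissimilarity(
    b1: ShapeBoundary,
    b2: ShapeBoundary,
    n_resample: int = 200,
    scaling: bool = True,
) -> float:
    """Full Procrustes distance between two object outlines, in [0, 1].

    Both contours are resampled to ``n_resample`` equal-arc-length
    points; because the starting point and orientation of a traced
    outline are arbitrary, the disparity is minimized over all cyclic
    start offsets and over traversal direction.  Translation, rotation
    and reflection are always factored out; uniform scaling is too by
    default (``scaling=False`` keeps size differences).
    """
    a = _standardize(resample_boundary(b1, n_resample))
    raw_b = resample_boundary(b2, n_resample)
    best = np.inf
    for direction in (raw_b, raw_b[::-1]):
        base = _standardize(direction)
        for offset in range(n_resample):
            rolled = np.roll(base, offset, axis=0)
            best = min(best, _procrustes_disparity(a, rolled, scaling))
    return float(best)


def shape_similarity(
    b1: ShapeBoundary, b2: ShapeBoundary, n_resample: int = 200, scaling: bool = True
) -> float:
    return 1.0 - shape_dissimilarity(b1, b2, n_resample, scaling)


def average_similarity_matrix(
    items: dict[str, list], pair_similarity
) -> pd.DataFrame:
    """Object-level similarity matrix averaged over all image/shape pairs.

    ``items`` maps object labels to lists of exemplars (images or
    boundaries); ``pair_similarity(x, y)`` scores one pair.  Off-diagonal
    entries average over all cross-object pairs; the diagonal is unit by
    convention (an object is identical to itself).  The result is
    symmetric.
    """
    labels = list(items)
    out = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if j <= i:
                continue
            pairs = [
                pair_similarity(x, y) for x in items[la] for y in items[lb]
            ]
            val = float(np.mean(pairs))
            out.iloc[i, j] = val
            out.iloc[j, i] = val
    return out
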