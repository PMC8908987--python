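"""Multi-view peripheral sum curvature scale space (PSCSS).

Spiculated (malignant-like) nodule boundaries show many curvature-sign
reversals along their 2D cross-section contours; smooth boundaries show none.
For every view plane and every Gaussian scale sigma the binary cross-section is
smoothed, Canny edges are detected and traced into the longest closed contour,
and the curvature along the contour

    k(t) = (x' y'' - x'' y') / (x'^2 + y'^2)^(3/2)

is estimated with symmetric finite differences at a pixel ``gap`` (wrap-around
indexing).  Reversal points are indices where the curvature sign flips
(zero-curvature runs carry the previous sign).  The descriptor is the per-sigma
sum of reversal counts over all views, a scale-indexed complexity profile that
decays to zero as smoothing turns the section into a near-circle.  Because
curvature is intrinsic to the contour, the aggregated profile is approximately
rotation invariant.

Edges are computed on the mask cross-sections, not on HU intensities, so the
feature measures shape rather than texture.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature

from ..volume import NoduleMask, extract_views
from .base import DescriptorVector, NoduleDescriptor

__all__ = [
    "DEFAULT_SIGMAS",
    "detect_edges",
    "curvature_at",
    "curvature_profile",
    "reversal_count",
    "pscss_descriptor",
    "PSCSSExtractor",
]

DEFAULT_SIGMAS = (8.0, 12.0, 16.0, 24.0, 32.0)
_NBR8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_closed(points: np.ndarray) -> np.ndarray:
    """Order 8-connected edge pixels into a closed loop.

    Greedy nearest-neighbour walk with a minimal-turn preference; falls back to
    a polar-angle sort around the centroid (valid for star-shaped contours)
    when the walk cannot close the loop.  Returns an empty array on failure.
    """
    pts = {tuple(p) for p in points}
    if len(pts) < 3:
        return np.empty((0, 2))
    start = min(pts)
    order = [start]
    pts.remove(start)
    prev_dir = None
    while pts:
        y, x = order[-1]
        cands = [(y + dy, x + dx) for dy, dx in _NBR8 if (y + dy, x + dx) in pts]
        if not cands:
            break
        if prev_dir is None:
            nxt = min(cands)
        else:
            def turn(c):
                d = (c[0] - y, c[1] - x)
                n = np.hypot(*d)
                return -(d[0] * prev_dir[0] + d[1] * prev_dir[1]) / n
            nxt = min(cands, key=turn)
        d = (nxt[0] - y, nxt[1] - x)
        prev_dir = (d[0] / np.hypot(*d), d[1] / np.hypot(*d))
        order.append(nxt)
        pts.remove(nxt)
    closed = max(abs(order[-1][0] - start[0]), abs(order[-1][1] - start[1])) <= 1
    if closed and not pts and len(order) >= 3:
        return np.asarray(order, dtype=float)
    # fallback: star-shaped ordering by polar angle about the centroid
    arr = np.asarray(points, dtype=float)
    c = arr.mean(axis=0)
    ang = np.arctan2(arr[:, 0] - c[0], arr[:, 1] - c[1])
    return arr[np.argsort(ang)]


def _resample_arclength(contour: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a closed contour to uniform arc-length spacing.

    The traced 8-connected chain mixes steps of length 1 and sqrt(2); with
    index-based finite differences that non-uniform parametrisation alone
    injects spurious curvature-sign flips, so the contour is re-parametrised
    before any curvature is computed.
    """
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return contour
    n = max(int(round(total / spacing)), 8)
    t = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(t, s, closed[:, 0]), np.interp(t, s, closed[:, 1])])


def detect_edges(view_pixels, sigma: float, resample_px: float | None = 1.0) -> np.ndarray:
    """Longest closed Canny contour of a (float) mask cross-section.

    The section is Gaussian-smoothed at ``sigma`` before edge detection; the
    edge pixels of the largest connected component are traced into an ordered
    closed contour ``(n, 2)`` and resampled to uniform arc length
    (``resample_px`` pixels per step; None disables).  Returns an empty array
    when no contour exists (empty section, or one erased by heavy smoothing).
    """
    img = np.asarray(view_pixels, dtype=np.float64)
    if img.max() < 0.5:
        return np.empty((0, 2))
    smooth = ndimage.gaussian_filter(img, sigma)
    edges = skfeature.canny(smooth, sigma=0.0)
    if not edges.any():
        return np.empty((0, 2))
    labels, n = ndimage.label(edges, structure=np.ones((3, 3)))
    if n == 0:
        return np.empty((0, 2))
    largest = np.argmax(ndimage.sum_labels(edges, labels, index=np.arange(1, n + 1))) + 1
    points = np.argwhere(labels == largest)
    contour = _trace_closed(points)
    if len(contour) < 3:
        return np.empty((0, 2))
    # consistent counter-clockwise orientation (positive shoelace area)
    y, x = contour[:, 0], contour[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    contour = contour if area > 0 else contour[::-1]
    if resample_px:
        contour = _resample_arclength(contour, resample_px)
    return contour


def curvature_profile(contour: np.ndarray, gap: int) -> np.ndarray:
    """Curvature at every contour index, derivatives at the given pixel gap.

    First derivatives use the symmetric difference over +/-gap, second
    derivatives the three-point stencil at the same spacing, both with
    wrap-around indexing.  Degenerate points (|x'| = |y'| = 0) get curvature 0.
    """
    n = len(contour)
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if n <= 2 * gap:
        raise ValueError(f"contour of length {n} too short for gap {gap}")
    y = contour[:, 0]
    x = contour[:, 1]
    xp = (np.roll(x, -gap) - np.roll(x, gap)) / (2.0 * gap)
    yp = (np.roll(y, -gap) - np.roll(y, gap)) / (2.0 * gap)
    xpp = (np.roll(x, -gap) - 2 * x + np.roll(x, gap)) / float(gap**2)
    ypp = (np.roll(y, -gap) - 2 * y + np.roll(y, gap)) / float(gap**2)
    denom = (xp**2 + yp**2) ** 1.5
    k = np.zeros(n)
    ok = denom > 0
    k[ok] = (xp[ok] * ypp[ok] - xpp[ok] * yp[ok]) / denom[ok]
    return k


def curvature_at(contour: np.ndarray, t: int, gap: int) -> float:
    """Curvature at one contour index (see :func:`curvature_profile`)."""
    return float(curvature_profile(np.asarray(contour, float), gap)[t])


def reversal_count(contour: np.ndarray, gap: int) -> int:
    """Number of curvature-sign changes along the closed contour.

    Zero-curvature points do not count; the sign is carried through them.
    """
    k = curvature_profile(np.asarray(contour, float), gap)
    signs = np.sign(k)
    nz = signs[signs != 0]
    if nz.size < 2:
        return 0
    return int(np.sum(nz != np.roll(nz, 1)))


def pscss_descriptor(
    mask: NoduleMask,
    n_views: int = 5,
    gap: int = 15,
    sigmas=DEFAULT_SIGMAS,
    in_plane_spacing: float = 0.25,
    presmooth_px: float = 0.0,
) -> DescriptorVector:
    """Per-sigma reversal counts summed over the view pencil.

    Views are resampled at ``in_plane_spacing`` mm/pixel (finer than the voxel
    grid) so the default pixel gap of 15 spans a sensible arc length on
    desk-scale nodules.  The default sigma grid starts near the curvature
    stencil scale (8 px = 2 mm): below the voxel scale edges only show the
    interpolation staircase of the binary mask, and below the stencil scale
    spicule clusters narrower than the +/-gap window can *gain* resolved
    undulations under smoothing, breaking scale-space monotonicity.  An
    optional fixed Gaussian ``presmooth_px`` can be applied to every
    cross-section before the sweep when a finer sigma grid is requested.  A
    view whose contour is empty or shorter than ``2 * gap + 1`` contributes
    zero at that scale.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    sigmas = tuple(float(s) for s in sigmas)
    if any(b <= a for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError("sigmas must be strictly increasing")
    views = extract_views(mask, n_views, in_plane_spacing=in_plane_spacing)
    counts = np.zeros(len(sigmas))
    for view in views:
        pixels = ndimage.gaussian_filter(view.pixels, presmooth_px) if presmooth_px else view.pixels
        for i, s in enumerate(sigmas):
            contour = detect_edges(pixels, s)
            if len(contour) > 2 * gap:
                counts[i] += reversal_count(contour, gap)
    names = [f"pscss_sigma{s:g}" for s in sigmas]
    return DescriptorVector(values=counts, tag="pscss", names=names)


class PSCSSExtractor(NoduleDescriptor):
    """Multi-view PSCSS as a scikit-learn transformer over nodule records."""

    tag = "pscss"

    def __init__(self, n_views: int = 5, gap: int = 15, sigmas=DEFAULT_SIGMAS,
                 in_plane_spacing: float = 0.25, presmooth_px: float = 0.0):
        self.n_views = n_views
        self.gap = gap
        self.sigmas = sigmas
        self.in_plane_spacing = in_plane_spacing
        self.presmooth_px = presmooth_px

    def describe(self, record) -> DescriptorVector:
        return pscss_descriptor(
            record.mask, n_views=self.n_views, gap=self.gap, sigmas=self.sigmas,
            in_plane_spacing=self.in_plane_spacing, presmooth_px=self.presmooth_px,
        )
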