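"""Multi-view Analytical Local Binary Pattern (ALBP).

The traditional LBP thresholds the neighbours on a circle of radius R at the
central pixel value:

    LBP_{N,R} = sum_{i=1..N} 2^(i-1) f(g_i - c),   f(x) = 1 iff x >= 0,

with neighbour i at offset (-R sin(2 pi i / N), R cos(2 pi i / N)), bilinearly
interpolated off-grid.  The hard threshold makes it noise-sensitive.

The analytical variant replaces per-pixel comparison with statistics of whole
neighbourhood *levels*: for each level R = 1..R_max the circle is resampled
(``full_n``: 8R points, ``single_n``: 8 points, ``average_n``: the 8R points
averaged over 8 contiguous arcs) and summarised by five statistics (median,
mean, population sd, min, max).  Each statistic m is thresholded at its own
mean mu(m) over the levels:

    ALBP(m) = sum_{i=1..R_max} 2^(i-1) f(m(G_i) - mu(m)),

giving five code maps with codes in [0, 2^R_max - 1].  The descriptor is the
per-statistic code histogram over the nodule's cross-section in each of the
``n_views`` planes, all histograms normalised to sum 1 and concatenated
(views x 5 statistics x 2^R_max bins; the default 5 views / 3 levels /
average_n gives length 200).

Codes are shift-invariant: adding a constant to the image moves every
statistic and its threshold together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..volume import NoduleMask, ViewSlice, VoxelVolume, extract_views
from .base import DescriptorVector, NoduleDescriptor

__all__ = [
    "STATS",
    "LevelSamples",
    "StatVector",
    "ALBPCodeMaps",
    "traditional_lbp",
    "resample_level",
    "level_stats",
    "albp_codes",
    "multiview_albp",
    "ALBPExtractor",
]

STATS = ("median", "mean", "sd", "min", "max")
SCHEMES = ("full_n", "single_n", "average_n")


class GeometryError(ValueError):
    """View too small for the requested neighbourhood geometry."""


@dataclass
class LevelSamples:
    """Gray values sampled on the circle of radius ``level`` around one pixel."""

    level: int
    gray_values: np.ndarray

    def __post_init__(self) -> None:
        self.gray_values = np.asarray(self.gray_values, dtype=np.float64).ravel()
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.gray_values.size == 0:
            raise ValueError("empty sample set")


@dataclass
class StatVector:
    median: float
    mean: float
    sd: float
    min: float
    max: float

    def as_array(self) -> np.ndarray:
        return np.array([self.median, self.mean, self.sd, self.min, self.max])


@dataclass
class ALBPCodeMaps:
    """Per-statistic integer code images plus the valid-interior mask."""

    maps: dict
    r_max: int
    valid: np.ndarray


def _pixels(view) -> np.ndarray:
    return view.pixels if isinstance(view, ViewSlice) else np.asarray(view, dtype=np.float64)


def _float_tol(img: np.ndarray) -> float:
    """Threshold slack absorbing bilinear round-off on flat regions.

    The codes use f(x) = 1 iff x >= 0; interpolating a constant patch can
    return values off by a few ulp, which must not flip a bit.
    """
    return 1e-9 * max(1.0, float(np.abs(img).max()))


def _circle_offsets(n: int, radius: float) -> np.ndarray:
    """Neighbour i = 1..n at (-R sin(2 pi i / n), R cos(2 pi i / n))."""
    i = np.arange(1, n + 1)
    ang = 2.0 * np.pi * i / n
    return np.stack([-radius * np.sin(ang), radius * np.cos(ang)], axis=1)


def _sample_offsets(img: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Bilinear samples of ``img`` at every pixel shifted by every offset.

    Returns an array of shape ``(len(offsets),) + img.shape``.  Coordinates
    outside the grid are clamped to the nearest edge pixel; callers restrict
    statistics to interior pixels where no clamping occurs.
    """
    r0, r1 = np.meshgrid(
        np.arange(img.shape[0], dtype=float), np.arange(img.shape[1], dtype=float), indexing="ij"
    )
    out = np.empty((len(offsets),) + img.shape)
    for k, (dy, dx) in enumerate(offsets):
        out[k] = ndimage.map_coordinates(img, [r0 + dy, r1 + dx], order=1, mode="nearest")
    return out


def _interior(shape: tuple, margin: int) -> np.ndarray:
    valid = np.zeros(shape, dtype=bool)
    if shape[0] > 2 * margin and shape[1] > 2 * margin:
        valid[margin:shape[0] - margin, margin:shape[1] - margin] = True
    return valid


def traditional_lbp(view, n_neighbors: int = 8, radius: int = 1, support=None) -> np.ndarray:
    """Classic LBP code histogram (length ``2**n_neighbors``) over interior pixels.

    ``support`` optionally restricts the histogram to a boolean pixel mask
    (e.g. the nodule cross-section).
    """
    img = _pixels(view)
    if n_neighbors < 1 or radius < 1:
        raise ValueError("n_neighbors and radius must be >= 1")
    if min(img.shape) <= 2 * radius:
        raise GeometryError(f"view of shape {img.shape} too small for radius {radius}")
    samples = _sample_offsets(img, _circle_offsets(n_neighbors, radius))
    bits = samples - img[None] >= -_float_tol(img)
    weights = (2 ** np.arange(n_neighbors))[:, None, None]
    codes = (bits * weights).sum(axis=0)
    valid = _interior(img.shape, int(np.ceil(radius)))
    if support is not None:
        valid &= np.asarray(support, dtype=bool)
    hist = np.bincount(codes[valid].ravel(), minlength=2**n_neighbors).astype(float)
    return hist


def _level_sample_stack(img: np.ndarray, level: int, scheme: str) -> np.ndarray:
    """Per-pixel circle samples for one level, shape (n_samples, H, W)."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "single_n":
        return _sample_offsets(img, _circle_offsets(8, level))
    full = _sample_offsets(img, _circle_offsets(8 * level, level))
    if scheme == "full_n":
        return full
    # average_n: 8 contiguous arcs of `level` consecutive samples, arc 0 at index 0
    return full.reshape(8, level, *img.shape).mean(axis=1)


def resample_level(view, center, level: int, scheme: str = "average_n") -> LevelSamples:
    """Circle samples around one pixel ``center = (row, col)``.

    ``full_n`` yields 8*level samples, ``single_n`` 8, ``average_n`` the 8*level
    samples reduced to 8 arc means.
    """
    img = _pixels(view)
    cy, cx = center
    if level < 1:
        raise ValueError("level must be >= 1")
    if not (level <= cy <= img.shape[0] - 1 - level and level <= cx <= img.shape[1] - 1 - level):
        raise GeometryError(f"circle of radius {level} at {center} leaves the view")
    if scheme == "single_n":
        offs = _circle_offsets(8, level)
    else:
        offs = _circle_offsets(8 * level, level)
    coords = offs + np.array([cy, cx])
    vals = ndimage.map_coordinates(img, [coords[:, 0], coords[:, 1]], order=1, mode="nearest")
    if scheme == "average_n":
        vals = vals.reshape(8, level).mean(axis=1)
    return LevelSamples(level=level, gray_values=vals)


def level_stats(samples: LevelSamples) -> StatVector:
    """Median, mean, population sd, min and max of the level's gray values."""
    g = samples.gray_values
    return StatVector(
        median=float(np.median(g)),
        mean=float(np.mean(g)),
        sd=float(np.std(g)),  # population normalisation
        min=float(np.min(g)),
        max=float(np.max(g)),
    )


def _stat_stack(samples: np.ndarray) -> np.ndarray:
    """(5, H, W) stack of the five statistics over axis 0 of ``samples``."""
    return np.stack(
        [
            np.median(samples, axis=0),
            samples.mean(axis=0),
            samples.std(axis=0),
            samples.min(axis=0),
            samples.max(axis=0),
        ]
    )


def albp_codes(view, r_max: int = 3, scheme: str = "average_n") -> ALBPCodeMaps:
    """Five per-statistic code maps with codes in ``[0, 2**r_max - 1]``.

    For every pixel: statistics are computed at each level 1..r_max, the
    per-statistic mean over levels is the threshold, and level i contributes
    bit 2^(i-1) when the statistic at level i reaches its threshold.
    """
    img = _pixels(view)
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    per_level = np.stack([_stat_stack(_level_sample_stack(img, r, scheme)) for r in range(1, r_max + 1)])
    mu = per_level.mean(axis=0)  # (5, H, W)
    bits = per_level - mu[None] >= -_float_tol(img)  # (r_max, 5, H, W)
    weights = (2 ** np.arange(r_max))[:, None, None, None]
    codes = (bits * weights).sum(axis=0)  # (5, H, W)
    maps = {stat: codes[k].astype(np.int64) for k, stat in enumerate(STATS)}
    return ALBPCodeMaps(maps=maps, r_max=r_max, valid=_interior(img.shape, r_max))


def _code_histograms(code_maps: ALBPCodeMaps, support: np.ndarray) -> np.ndarray:
    """(5, 2**r_max) normalised histograms; all-zero when the support is empty."""
    n_bins = 2**code_maps.r_max
    sel = code_maps.valid & support
    out = np.zeros((len(STATS), n_bins))
    if sel.any():
        for k, stat in enumerate(STATS):
            h = np.bincount(code_maps.maps[stat][sel].ravel(), minlength=n_bins).astype(float)
            out[k] = h / h.sum()
    return out


def multiview_albp(
    volume: VoxelVolume,
    mask: NoduleMask,
    n_views: int = 5,
    r_max: int = 3,
    scheme: str = "average_n",
    in_plane_spacing: float | None = None,
) -> DescriptorVector:
    """Concatenated per-view, per-statistic ALBP histograms over the nodule.

    Histograms are restricted to the nodule's 2D cross-section in each view; a
    view with an empty cross-section contributes all-zero histograms.  Default
    configuration (5 views, 3 levels, average_n) yields a length-200 vector.
    """
    center = mask.centroid
    vol_views = extract_views(volume, n_views, center=center, in_plane_spacing=in_plane_spacing)
    mask_views = extract_views(mask, n_views, center=center, in_plane_spacing=in_plane_spacing)
    n_bins = 2**r_max
    values, names = [], []
    for vv, mv in zip(vol_views, mask_views):
        cross = mv.pixels >= 0.5
        hists = _code_histograms(albp_codes(vv, r_max=r_max, scheme=scheme), cross)
        values.append(hists.ravel())
        names += [
            f"albp_{vv.view_index}_{stat}_{b}" for stat in STATS for b in range(n_bins)
        ]
    return DescriptorVector(values=np.concatenate(values), tag="albp", names=names)


class ALBPExtractor(NoduleDescriptor):
    """Multi-view ALBP as a scikit-learn transformer over nodule records."""

    tag = "albp"

    def __init__(self, n_views: int = 5, r_max: int = 3, scheme: str = "average_n",
                 in_plane_spacing: float | None = None):
        self.n_views = n_views
        self.r_max = r_max
        self.scheme = scheme
        self.in_plane_spacing = in_plane_spacing

    def describe(self, record) -> DescriptorVector:
        return multiview_albp(
            record.voi, record.mask, n_views=self.n_views, r_max=self.r_max,
            scheme=self.scheme, in_plane_spacing=self.in_plane_spacing,
        )
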