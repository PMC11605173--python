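"""Colour extraction from transmitted-light capsule micrographs.

The measurement chain is: two-cluster segmentation of the RGB image into
capsule and background, selection of a small disc at the capsule centre,
per-channel means over that disc and over the (eroded) background, and the
derived colour metrics

    R        - raw red-channel mean of the centre region,
    R - bg   - red mean minus the red background mean,
    R - B    - red mean minus the blue mean of the centre region.

Under transmitted illumination the capsule is darker than the background,
so the darker of the two clusters is taken as the capsule; the mask is
cleaned to its largest connected component with holes filled (the optically
clear core is a hole in the dark shell ring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .errors import (
    DomainError,
    NoCapsuleError,
    RegionSelectionError,
    UnitError,
)

__all__ = [
    "CapsuleImage",
    "SegmentationResult",
    "ColourStats",
    "segment_capsule",
    "centre_region",
    "extract_colour_stats",
    "measure_radius",
]

logger = logging.getLogger(__name__)

#: Luminance weights (ITU-R BT.601) used only to pick deterministic k-means seeds
#: and to label the darker cluster.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class CapsuleImage:
    """An 8-bit RGB micrograph of a single capsule plus its metadata.

    ``scale`` is micrometres per pixel and may be absent when only colour
    (not geometry) is needed.
    """

    pixels: np.ndarray
    sample_id: str = ""
    conc: float = float("nan")
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DomainError(f"expected an HxWx3 RGB array, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise DomainError(f"image must be at least 32x32, got {px.shape[:2]}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise DomainError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class SegmentationResult:
    """Disjoint capsule/background masks that jointly cover the image."""

    capsule_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        cap = np.asarray(self.capsule_mask, dtype=bool)
        bg = np.asarray(self.background_mask, dtype=bool)
        if cap.shape != bg.shape:
            raise DomainError("capsule and background masks must have the same shape")
        if np.any(cap & bg) or not np.all(cap | bg):
            raise DomainError("masks must be disjoint and jointly cover the image")
        self.capsule_mask = cap
        self.background_mask = bg


@dataclass
class ColourStats:
    """Centre-region and background channel means plus derived metrics.

    The derived metrics are defined (and therefore exact) as
    ``metric_R = R_mean``, ``metric_R_minus_bg = R_mean - R_bg`` and
    ``metric_R_minus_B = R_mean - B_mean``.
    """

    R_mean: float
    G_mean: float
    B_mean: float
    R_bg: float
    G_bg: float
    B_bg: float
    metric_R: float = field(init=False)
    metric_R_minus_bg: float = field(init=False)
    metric_R_minus_B: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("R_mean", "G_mean", "B_mean", "R_bg", "G_bg", "B_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise DomainError(f"{name}={v} outside [0, 255]")
        self.metric_R = self.R_mean
        self.metric_R_minus_bg = self.R_mean - self.R_bg
        self.metric_R_minus_B = self.R_mean - self.B_mean


def _two_means(flat: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means on RGB rows; returns boolean labels (True = cluster 1).

    Initialised from the pixel values at the minimum- and maximum-luminance
    pixels (first occurrence on ties), which for transmitted-light images are
    the two most separated colours; the result is then invariant to a global
    brightness offset that does not clip.
    """
    luma = flat @ _LUMA
    c0 = flat[int(np.argmin(luma))].astype(float)
    c1 = flat[int(np.argmax(luma))].astype(float)
    if np.all(c0 == c1):
        raise NoCapsuleError("image has no colour contrast to cluster")
    labels = np.zeros(len(flat), dtype=bool)
    for _ in range(max_iter):
        d0 = np.einsum("ij,ij->i", flat - c0, flat - c0)
        d1 = np.einsum("ij,ij->i", flat - c1, flat - c1)
        new = d1 < d0
        if np.array_equal(new, labels):
            break
        labels = new
        if not labels.any() or labels.all():
            raise NoCapsuleError("two-cluster segmentation collapsed to one cluster")
        c0 = flat[~labels].mean(axis=0)
        c1 = flat[labels].mean(axis=0)
    return labels


def segment_capsule(
    image: CapsuleImage,
    min_capsule_fraction: float = 0.005,
    min_cluster_separation: float = 10.0,
) -> SegmentationResult:
    """Partition the image into a capsule mask and a background mask.

    Pixels are clustered in RGB space (k = 2, deterministic initialisation);
    the darker-mean cluster is the capsule.  The capsule mask is reduced to
    its largest connected component and its holes are filled (the clear core
    appears as a hole inside the dark shell ring).  Raises
    :class:`NoCapsuleError` when the image has no two-cluster structure or
    the capsule cluster covers less than ``min_capsule_fraction`` of the
    pixels.
    """
    px = image.pixels.astype(float)
    flat = px.reshape(-1, 3)
    labels = _two_means(flat)

    mean0 = flat[~labels].mean(axis=0)
    mean1 = flat[labels].mean(axis=0)
    if float(np.linalg.norm(mean0 - mean1)) < min_cluster_separation:
        raise NoCapsuleError(
            "cluster means are closer than the separation threshold; "
            "the image appears to be a single uniform field"
        )
    # darker cluster (by luminance of the cluster mean) is the capsule
    dark_is_1 = mean1 @ _LUMA < mean0 @ _LUMA
    capsule = (labels if dark_is_1 else ~labels).reshape(image.shape)

    if capsule.mean() < min_capsule_fraction:
        raise NoCapsuleError(
            f"capsule cluster covers {capsule.mean():.2%} of pixels "
            f"(< {min_capsule_fraction:.2%})"
        )

    cc = measure.label(capsule, connectivity=2)
    sizes = np.bincount(cc.ravel())
    sizes[0] = 0
    if sizes.max() == 0:
        raise NoCapsuleError("capsule cluster is empty after labelling")
    n_large = int(np.sum(sizes > 0.25 * sizes.max()))
    if n_large > 1:
        logger.warning(
            "image %s: %d capsule-sized components found; keeping the largest",
            image.sample_id or "<unnamed>",
            n_large,
        )
    largest = cc == int(np.argmax(sizes))
    filled = ndi.binary_fill_holes(largest)
    if filled.mean() < min_capsule_fraction:
        raise NoCapsuleError("capsule component too small after cleanup")
    return SegmentationResult(capsule_mask=filled, background_mask=~filled)


def centre_region(seg: SegmentationResult, fraction: float = 0.1) -> np.ndarray:
    """Disc mask at the capsule centroid with radius = fraction x equivalent radius.

    The equivalent radius is sqrt(area/pi) of the capsule mask.  Raises
    :class:`RegionSelectionError` if the disc is not entirely inside the
    capsule mask (highly eccentric or hollow masks).
    """
    if not 0 < fraction <= 0.5:
        raise DomainError(f"fraction must lie in (0, 0.5], got {fraction}")
    cap = seg.capsule_mask
    area = int(cap.sum())
    if area == 0:
        raise RegionSelectionError("capsule mask is empty")
    ys, xs = np.nonzero(cap)
    cy, cx = ys.mean(), xs.mean()
    r_eq = np.sqrt(area / np.pi)
    r = fraction * r_eq
    yy, xx = np.ogrid[: cap.shape[0], : cap.shape[1]]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not disc.any():
        raise RegionSelectionError("centre disc contains no pixels")
    if np.any(disc & ~cap):
        raise RegionSelectionError(
            "centre disc extends outside the capsule mask; "
            "the mask is too eccentric for centre sampling"
        )
    return disc


def extract_colour_stats(
    image: CapsuleImage,
    centre: np.ndarray,
    seg: SegmentationResult,
    background_erosion: int = 5,
) -> ColourStats:
    """Channel means over the centre disc and the background, plus metrics.

    The background is the background mask with a margin of
    ``background_erosion`` pixels around the capsule excluded (dilation of
    the capsule mask), so halo pixels at the capsule rim do not bias the
    background estimate.  Means are computed in floating point.
    """
    centre = np.asarray(centre, dtype=bool)
    if not centre.any():
        raise DomainError("centre mask is empty")
    bg = seg.background_mask
    if background_erosion < 0:
        raise DomainError("background_erosion must be non-negative")
    if background_erosion > 0:
        halo = ndi.binary_dilation(
            seg.capsule_mask, structure=morphology.disk(background_erosion)
        )
        eroded = bg & ~halo
        if eroded.any():
            bg = eroded
        else:
            logger.warning("background erosion left no pixels; using full background")
    if not bg.any():
        raise DomainError("background mask is empty")
    px = image.pixels.astype(float)
    cR, cG, cB = (float(px[..., k][centre].mean()) for k in range(3))
    bR, bG, bB = (float(px[..., k][bg].mean()) for k in range(3))
    return ColourStats(R_mean=cR, G_mean=cG, B_mean=cB, R_bg=bR, G_bg=bG, B_bg=bB)


def measure_radius(seg: SegmentationResult, scale: Optional[float]) -> float:
    """Outer (equivalent-circle) radius of the capsule mask, micrometres."""
    if scale is None or not scale > 0:
        raise UnitError(f"a positive micrometres-per-pixel scale is required, got {scale}")
    area = int(seg.capsule_mask.sum())
    if area == 0:
        raise DomainError("capsule mask is empty")
    return float(np.sqrt(area / np.pi) * scale)
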