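"""Fundus preprocessing: eye mask, optic-disc mask, analysis-channel selection.

Wide-field pediatric fundus photographs have an illuminated circular field
surrounded by a ring of saturated pixels (the camera optics overexpose the
field boundary) and darkness outside it.  The optic disc (OD) is annotated
manually with the two endpoints of its major axis; everything downstream is
anchored to the circle derived from those endpoints.

Coordinate convention: (row, col), 0-based, throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "FundusImage",
    "GrayImage",
    "ODGeometry",
    "compute_eye_mask",
    "compute_od_mask",
    "select_channel",
]


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph plus provenance metadata.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
    id : str
        Stable identifier used in feature tables and reports.
    path : str
        Source path, or "" for in-memory (synthetic) images.
    """

    pixels: np.ndarray
    id: str = ""
    path: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected an H x W x 3 raster, got shape {p.shape}")
        if p.shape[0] < 64 or p.shape[1] < 64:
            raise ValueError("fundus image must be at least 64 x 64")
        self.pixels = p.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GrayImage:
    """A single selected channel (or derived intensity plane)."""

    pixels: np.ndarray
    channel: str = "green"


@dataclass
class ODGeometry:
    """Optic-disc circle derived from two annotated major-axis endpoints.

    The OD is not strictly circular, but a circle through the major-axis
    endpoints is a sufficient exclusion zone and the anchor for all
    diagnostic regions.
    """

    endpoint_a: tuple[float, float]
    endpoint_b: tuple[float, float]
    centroid: tuple[float, float] = field(init=False)
    radius: float = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.endpoint_a, dtype=float)
        b = np.asarray(self.endpoint_b, dtype=float)
        self.centroid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
        self.radius = float(np.linalg.norm(a - b) / 2.0)
        if self.radius <= 0:
            raise ValueError("OD major-axis endpoints coincide: zero radius")


def _intensity(image: FundusImage) -> np.ndarray:
    return image.pixels.astype(np.float64).mean(axis=2)


def compute_eye_mask(image: FundusImage, margin: int = 5,
                     threshold: float | None = None) -> np.ndarray:
    """Mask of the illuminated field, excluding the saturated outer ring.

    Procedure: contrast-stretch the mean-channel intensity between its 1st
    and 99th percentiles, threshold globally (Otsu unless ``threshold``
    overrides it), fill holes, keep the largest connected component, drop
    the saturated population (pixels at or above the 99th-percentile
    stretch limit — the ring), and finally erode by ``margin`` pixels for
    safety.

    Parameters
    ----------
    image : FundusImage
    margin : int
        Erosion radius in pixels applied after ring removal.
    threshold : float, optional
        Override for the global threshold, on the stretched [0, 1] scale.

    Returns
    -------
    ndarray of bool, shape (H, W)

    Raises
    ------
    DegenerateInputError
        If the image has no contrast to stretch or the mask comes out empty.
    """
    inten = _intensity(image)
    p1, p99 = np.percentile(inten, [1, 99])
    if p99 <= p1:
        raise DegenerateInputError("no intensity contrast between the 1st and "
                                   "99th percentiles; cannot build an eye mask")
    stretched = np.clip((inten - p1) / (p99 - p1), 0.0, 1.0)

    t = threshold_otsu(stretched) if threshold is None else float(threshold)
    mask = stretched > t
    if not mask.any():
        raise DegenerateInputError("eye-mask threshold produced an empty mask")

    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))

    # The saturated ring sits at the top stretch limit; remove that
    # population rather than relying on a large erosion.
    mask &= inten < p99
    if margin > 0:
        mask = ndimage.binary_erosion(mask, structure=disk(margin))
    if not mask.any():
        raise DegenerateInputError("eye mask empty after ring removal/erosion")
    return mask


def compute_od_mask(od: ODGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Circular optic-disc mask, clipped to the image bounds.

    OD-interior pixels never contribute to vessel features; this mask is
    subtracted from every region of interest.
    """
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = od.centroid
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= od.radius**2


def select_channel(image: FundusImage, eye_mask: np.ndarray,
                   mean_cutoff: float = 64.0) -> GrayImage:
    """Pick the analysis channel by masked mean/variance statistics.

    Channels whose mean intensity over the eye mask is at or below
    ``mean_cutoff`` (the 25th percentile of the 8-bit range by default) are
    discarded as underexposed; among the survivors the channel with least
    variance — the most uniform background illumination — is selected.
    If no channel survives the mean rule, the channel with the greatest
    mean is used as a fallback (logged).  Ties break green, blue, red:
    green and blue are the channels that show usable vessel contrast in
    practice.
    """
    if not np.any(eye_mask):
        raise DegenerateInputError("eye mask is empty")
    names = ("red", "green", "blue")
    tie_rank = {"green": 0, "blue": 1, "red": 2}
    stats = []
    for i, name in enumerate(names):
        vals = image.pixels[..., i][eye_mask].astype(np.float64)
        stats.append((name, i, vals.mean(), vals.var()))

    survivors = [s for s in stats if s[2] > mean_cutoff]
    if survivors:
        name, i, _, _ = min(survivors, key=lambda s: (s[3], tie_rank[s[0]]))
    else:
        name, i, _, _ = max(stats, key=lambda s: (s[2], -tie_rank[s[0]]))
        logger.warning("no channel mean exceeds %.0f; falling back to the "
                       "brightest channel (%s)", mean_cutoff, name)
    return GrayImage(pixels=image.pixels[..., i].copy(), channel=name)
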