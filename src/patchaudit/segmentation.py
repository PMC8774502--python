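"""Coloured-patch artefact segmentation.

Detects colour-calibration patches by SLIC superpixel segmentation followed
by thresholding each superpixel's mean colour distance to an estimated
average skin tone, measured jointly in RGB and HSV (with the hue treated
circularly).  The resulting mask is cleaned of small regions and dilated
with an elliptical structuring element so that inpainting fully covers the
artefact instead of "repairing" it from leftover patch pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_objects
from skimage.segmentation import slic


def elliptical_kernel(size: int = 9) -> np.ndarray:
    """Filled-ellipse (disc, for square size) structuring element.

    ``size`` is the full width in pixels and must be odd so the element is
    centred; the 9x9 default matches the dilation used for patch masks.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    r = size // 2
    if r == 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy / r) ** 2 + (xx / r) ** 2 <= 1.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the superpixel colour-distance segmenter.

    Defaults were chosen on the synthetic generator at 128x128 and are
    recorded here as configuration, not as values taken from any external
    source.  ``colour_distance_threshold`` applies to the Euclidean
    distance over concatenated RGB and hue-circular HSV coordinates
    (7 dimensions, each channel in [0, 1] scale).

    ``dilation_kernel_size`` should scale with image resolution: the
    conventional 9x9 elliptical element used on 224x224 dermoscopy images
    corresponds to 5x5 at this package's default 128x128 working size
    (9/224 ~ 5/128); pass 9 when working at 224.
    """

    n_superpixels: int = 200
    compactness: float = 10.0
    colour_distance_threshold: float = 1.4
    hue_weight: float = 2.0
    dilation_kernel_size: int = 5
    min_region_area: int = 25

    def __post_init__(self) -> None:
        if self.n_superpixels < 2:
            raise ValueError("n_superpixels must be >= 2")
        if self.colour_distance_threshold <= 0:
            raise ValueError("colour_distance_threshold must be > 0")
        if self.dilation_kernel_size < 1 or self.dilation_kernel_size % 2 == 0:
            raise ValueError("dilation_kernel_size must be odd and >= 1")


def _colour_features(rgb: np.ndarray, hue_weight: float = 2.0) -> np.ndarray:
    """Map N x 3 RGB rows to 7-dim [r, g, b, w*s*cos h, w*s*sin h, s, v].

    The hue angle is embedded on the circle, scaled by saturation so that
    the (meaningless) hue of near-grey colours does not dominate, and
    weighted by ``hue_weight``: calibration patches differ from skin
    chiefly in hue, whereas pigmented lesions differ chiefly in value, so
    up-weighting hue separates the two kinds of off-skin region.
    """
    rgb = np.atleast_2d(rgb)
    hsv = rgb2hsv(rgb.reshape(-1, 1, 3)).reshape(-1, 3)
    h, s, v = hsv[:, 0], hsv[:, 1], hsv[:, 2]
    ang = 2 * np.pi * h
    w = hue_weight
    return np.column_stack(
        [rgb, w * s * np.cos(ang), w * s * np.sin(ang), s, v]
    )


def estimate_skin_tone(
    image: np.ndarray, exclude_mask: np.ndarray | None = None
) -> np.ndarray:
    """Robust average skin colour as an RGB triple (per-channel median).

    Pixels under ``exclude_mask`` (e.g. a lesion mask) are ignored.  The
    median is used rather than the mean so that a dark lesion or a bright
    artefact cannot drag the estimate off the actual skin tone.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    flat = image.reshape(-1, image.shape[-1])
    if exclude_mask is not None:
        if exclude_mask.shape != image.shape[:2]:
            raise ValueError("exclude_mask shape must match image")
        keep = ~exclude_mask.reshape(-1)
        if not keep.any():
            raise ValueError("exclude_mask covers all pixels")
        flat = flat[keep]
    return np.median(flat, axis=0)


def segment_patches(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Binary mask of coloured-patch artefacts in an RGB [0, 1] image.

    Superpixels whose mean colour is further than
    ``colour_distance_threshold`` from the estimated skin tone (in the
    joint RGB+HSV feature space) are flagged; connected regions smaller
    than ``min_region_area`` pixels are dropped.  Returns an all-False
    mask when nothing exceeds the threshold.  The output is *not*
    dilated; apply :func:`dilate_mask` before inpainting.
    """
    if config is None:
        config = SegmentationConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB image")

    labels = slic(
        image,
        n_segments=config.n_superpixels,
        compactness=config.compactness,
        start_label=0,
    )
    n = labels.max() + 1
    flat = image.reshape(-1, 3)
    lab = labels.reshape(-1)
    sums = np.zeros((n, 3))
    np.add.at(sums, lab, flat)
    counts = np.bincount(lab, minlength=n).astype(float)
    means = sums / counts[:, None]

    skin = estimate_skin_tone(image)
    dist = np.linalg.norm(
        _colour_features(means, config.hue_weight)
        - _colour_features(skin[None, :], config.hue_weight),
        axis=1,
    )
    selected = dist > config.colour_distance_threshold
    mask = selected[labels]

    # Pixel-level refinement: superpixels straddling a patch edge dilute
    # their mean below threshold, which can strand saturated pixels at the
    # image border where dilation cannot reach them.  Attach any connected
    # component of per-pixel off-skin colour that touches the detected mask.
    if mask.any():
        pix_dist = np.linalg.norm(
            _colour_features(flat, config.hue_weight)
            - _colour_features(skin[None, :], config.hue_weight),
            axis=1,
        ).reshape(labels.shape)
        off_skin = pix_dist > config.colour_distance_threshold
        components, n_comp = ndimage.label(off_skin | mask)
        touching = np.unique(components[mask])
        mask = np.isin(components, touching[touching > 0])

    if config.min_region_area > 1:
        mask = remove_small_objects(mask, max_size=config.min_region_area - 1)
    return mask


def dilate_mask(mask: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Morphological dilation of a binary mask (single application).

    ``kernel`` defaults to the elliptical structuring element at the
    default config size.  The operation is extensive (output contains
    input) and increasing.
    """
    mask = np.asarray(mask, dtype=bool)
    if kernel is None:
        kernel = elliptical_kernel(SegmentationConfig().dilation_kernel_size)
    return ndimage.binary_dilation(mask, structure=np.asarray(kernel, dtype=bool))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)
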