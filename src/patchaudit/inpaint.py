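"""Inpainting backends, random validity-check masks and SSIM.

The audit only requires that masked regions be replaced by *uninformative*
skin-like pixels; whether a particular backend achieves this is an
empirical question answered by :func:`validity_check`, which inpaints
random elliptical regions of patch-free images and verifies that the
classifier's output distribution does not shift.  The reference backend is
classical biharmonic (smooth-interpolation) inpainting; learned backends
can be registered through the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from skimage.metrics import structural_similarity
from skimage.restoration import inpaint_biharmonic


class InpaintBackend(Protocol):
    """Contract for inpainting backends.

    ``fill(image, mask)`` returns an image of identical shape in which
    pixels outside the mask are bit-exactly unchanged and filled pixels
    lie in [0, 1].
    """

    name: str

    def fill(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray: ...


class BiharmonicBackend:
    """Classical smooth-interpolation inpainter (biharmonic equation).

    Fills the masked region by solving the biharmonic equation with the
    surrounding pixels as boundary data, which extends the local skin
    texture base tone smoothly into the hole.
    """

    name = "biharmonic"

    def fill(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return image.copy()
        filled = inpaint_biharmonic(image.astype(float), mask, channel_axis=-1)
        out = image.copy()
        out[mask] = np.clip(filled[mask], 0.0, 1.0).astype(image.dtype)
        return out


class IdentityBackend:
    """No-op backend returning the input unchanged (diagnostic baseline)."""

    name = "identity"

    def fill(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return np.asarray(image).copy()


_BACKENDS: dict[str, InpaintBackend] = {}


def register_backend(backend: InpaintBackend) -> None:
    _BACKENDS[backend.name] = backend


def get_backend(name: str) -> InpaintBackend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"unknown inpainting backend {name!r}; registered: "
            f"{sorted(_BACKENDS)}"
        ) from None


def registered_backends() -> dict[str, InpaintBackend]:
    return dict(_BACKENDS)


register_backend(BiharmonicBackend())
register_backend(IdentityBackend())


def inpaint(
    image: np.ndarray, mask: np.ndarray, backend: InpaintBackend | str = "biharmonic"
) -> np.ndarray:
    """Fill ``mask`` in ``image`` with the given backend.

    Pixels outside the mask are returned bit-exactly unchanged; an empty
    mask returns a copy of the input.
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match image height and width")
    return backend.fill(image, mask)


@dataclass(frozen=True)
class RandomMaskParams:
    """Geometry of random elliptical validity-check masks.

    Semi-axes are drawn uniformly from ``axes_range`` (as fractions of the
    image side); the centre is drawn uniformly subject to lying within
    ``boundary_ring`` (fraction of the side) of an image edge, mirroring
    where real calibration patches occur; rotation is uniform.  Defaults
    mirror the synthetic generator's patch geometry.
    """

    axes_range: tuple[float, float] = (0.10, 0.25)
    boundary_ring: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.axes_range
        if not 0 < lo <= hi < 0.5:
            raise ValueError("axes_range must satisfy 0 < min <= max < 0.5")
        if not 0 < self.boundary_ring <= 0.5:
            raise ValueError("boundary_ring must be in (0, 0.5]")


def random_elliptical_mask(
    image_shape: tuple[int, int],
    params: RandomMaskParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """A filled, rotated ellipse near the image boundary (clipped at edges)."""
    if params is None:
        params = RandomMaskParams()
    rng = np.random.default_rng(rng)
    h, w = image_shape[:2]
    side = min(h, w)
    band = params.boundary_ring * side
    while True:
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        if min(cy, h - cy) <= band or min(cx, w - cx) <= band:
            break
    a, b = rng.uniform(params.axes_range[0], params.axes_range[1], 2) * side
    angle = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def ssim(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Structural similarity index between two [0, 1] images.

    Uses the standard Gaussian-weighted 11x11 window (sigma 1.5) with
    K1 = 0.01, K2 = 0.03, population (non-sample) window statistics, and
    channel averaging for RGB inputs.  Symmetric; 1.0 for identical
    images; values lie in (-1, 1].
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    channel_axis = -1 if a.ndim == 3 else None
    return float(
        structural_similarity(
            a,
            b,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            channel_axis=channel_axis,
        )
    )


@dataclass
class ValidityReport:
    """Distributional summary of the inpainting validity check.

    ``delta_p`` is P(malignant | inpainted) - P(malignant | original) per
    image.  ``frac_large_dev`` is the fraction with |delta_p| > the outlier
    threshold (default 0.2); ``outlier_ids`` lists those images for manual
    inspection rather than silently dropping them.
    """

    n: int
    ssim_mean: float
    ssim_median: float
    ssim_sd: float
    delta_p_mean: float
    delta_p_sd: float
    delta_p_quantiles: dict[str, float]
    frac_large_dev: float
    outlier_threshold: float
    outlier_ids: list[str] = field(default_factory=list)
    ids: list[str] = field(default_factory=list)
    delta_p: list[float] = field(default_factory=list)
    ssim_values: list[float] = field(default_factory=list)

    def delta_p_histogram_csv(self, path, bins: int = 40) -> None:
        """Write the delta-P histogram as CSV (bin_left, bin_right, count)."""
        import csv

        counts, edges = np.histogram(self.delta_p, bins=bins, range=(-1.0, 1.0))
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bin_left", "bin_right", "count"])
            for left, right, c in zip(edges[:-1], edges[1:], counts):
                w.writerow([left, right, int(c)])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "ssim_mean": self.ssim_mean,
            "ssim_median": self.ssim_median,
            "ssim_sd": self.ssim_sd,
            "delta_p_mean": self.delta_p_mean,
            "delta_p_sd": self.delta_p_sd,
            "delta_p_quantiles": self.delta_p_quantiles,
            "frac_large_dev": self.frac_large_dev,
            "outlier_threshold": self.outlier_threshold,
            "outlier_ids": list(self.outlier_ids),
        }


def validity_check(
    classifier,
    images: Sequence,
    mask_params: RandomMaskParams | None = None,
    backend: InpaintBackend | str = "biharmonic",
    rng: np.random.Generator | int | None = None,
    outlier_threshold: float = 0.2,
) -> ValidityReport:
    """Inpaint one random elliptical region per patch-free image and
    measure the classifier's prediction shift and the SSIM to the original.

    A well-behaved backend leaves the prediction distribution centred on
    zero shift; images with |delta_p| above ``outlier_threshold`` are
    flagged for inspection.  All input images must be patch-free (the
    check is about inpainting itself, not about artefact removal).
    """
    if len(images) == 0:
        raise ValueError("empty image set")
    for im in images:
        if getattr(im, "has_patch", False):
            raise ValueError(f"image {im.id} has a patch; validity check "
                             "requires patch-free images")
    if isinstance(backend, str):
        backend = get_backend(backend)
    rng = np.random.default_rng(rng)

    originals = [im.pixels for im in images]
    inpainted = []
    ssims = []
    for im in images:
        mask = random_elliptical_mask(im.pixels.shape[:2], mask_params, rng)
        alt = inpaint(im.pixels, mask, backend)
        inpainted.append(alt)
        ssims.append(ssim(im.pixels, alt))

    p_orig = np.array([r.p_malignant for r in classifier.predict_proba(originals)])
    p_alt = np.array([r.p_malignant for r in classifier.predict_proba(inpainted)])
    dp = p_alt - p_orig
    ids = [im.id for im in images]
    large = np.abs(dp) > outlier_threshold
    qs = {q: float(np.quantile(dp, float(q))) for q in ("0.05", "0.25", "0.5", "0.75", "0.95")}
    ssims = np.asarray(ssims)
    return ValidityReport(
        n=len(images),
        ssim_mean=float(ssims.mean()),
        ssim_median=float(np.median(ssims)),
        ssim_sd=float(ssims.std()),
        delta_p_mean=float(dp.mean()),
        delta_p_sd=float(dp.std()),
        delta_p_quantiles=qs,
        frac_large_dev=float(large.mean()),
        outlier_threshold=outlier_threshold,
        outlier_ids=[i for i, flag in zip(ids, large) if flag],
        ids=ids,
        delta_p=[float(x) for x in dp],
        ssim_values=[float(x) for x in ssims],
    )
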