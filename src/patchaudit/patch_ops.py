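"""Patch extraction and counterfactual compositing.

Builds a library of coloured-patch templates cut out of images that contain
them, and composites templates into patch-free images to create the
"patch inserted" counterfactuals.  Placement mirrors where real patches
occur (near the image boundary) and is required to be disjoint from the
lesion; images where no disjoint placement exists within a bounded number
of attempts are excluded explicitly, replacing the manual visual screening
such audits otherwise need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inpaint import InpaintBackend, inpaint

MAX_PLACEMENT_ATTEMPTS = 50


class PlacementError(RuntimeError):
    """No patch placement disjoint from the lesion could be found."""

    def __init__(self, image_id: str, attempts: int):
        self.image_id = image_id
        super().__init__(
            f"no lesion-disjoint patch placement found for image "
            f"{image_id!r} in {attempts} attempts"
        )


@dataclass(frozen=True)
class PatchTemplate:
    """A coloured patch cut out of a source image.

    ``pixels`` is the tight bounding-box RGB crop around the patch;
    ``mask`` marks the patch pixels within the crop; ``source_id`` records
    provenance.
    """

    pixels: np.ndarray
    mask: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("template mask is empty")
        rows = self.mask.any(axis=1)
        cols = self.mask.any(axis=0)
        if not (rows[0] and rows[-1] and cols[0] and cols[-1]):
            raise ValueError("crop is not the tight bounding box of the mask")


def extract_patch(image: np.ndarray, patch_mask: np.ndarray, source_id: str = "") -> PatchTemplate:
    """Cut the tight bounding-box crop of ``patch_mask`` out of ``image``.

    Masked pixels are copied bit-exactly; re-inserting the template at its
    original location reproduces the source image.
    """
    patch_mask = np.asarray(patch_mask, dtype=bool)
    if not patch_mask.any():
        raise ValueError("patch_mask is empty")
    rows = np.flatnonzero(patch_mask.any(axis=1))
    cols = np.flatnonzero(patch_mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return PatchTemplate(
        pixels=np.asarray(image)[r0:r1, c0:c1].copy(),
        mask=patch_mask[r0:r1, c0:c1].copy(),
        source_id=source_id,
    )


def insert_patch(
    image: np.ndarray,
    template: PatchTemplate,
    lesion_mask: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    boundary_ring: float = 0.25,
    max_attempts: int = MAX_PLACEMENT_ATTEMPTS,
    image_id: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Composite ``template`` into ``image`` at a random boundary location.

    The placement centre lies within ``boundary_ring`` (fraction of the
    image side) of an edge, the whole template fits inside the image, and
    the placed mask is disjoint from ``lesion_mask``.  Compositing is
    hard-edged (no feathering): exactly the placed-mask pixels change.

    Returns ``(altered_image, inserted_mask)``.  Raises
    :class:`PlacementError` when no legal placement is found within
    ``max_attempts``; callers exclude such images and log them.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    th, tw = template.mask.shape
    if th > h or tw > w:
        raise PlacementError(image_id, 0)
    rng = np.random.default_rng(rng)
    band = boundary_ring * min(h, w)
    for attempt in range(max_attempts):
        r0 = int(rng.integers(0, h - th + 1))
        c0 = int(rng.integers(0, w - tw + 1))
        cy, cx = r0 + th / 2, c0 + tw / 2
        if not (min(cy, h - cy) <= band or min(cx, w - cx) <= band):
            continue
        placed = np.zeros((h, w), dtype=bool)
        placed[r0 : r0 + th, c0 : c0 + tw] = template.mask
        if lesion_mask is not None and (placed & lesion_mask).any():
            continue
        out = image.copy()
        region = out[r0 : r0 + th, c0 : c0 + tw]
        region[template.mask] = template.pixels[template.mask]
        return out, placed
    raise PlacementError(image_id, max_attempts)


def inpaint_footprint_control(
    image: np.ndarray,
    inserted_mask: np.ndarray,
    backend: InpaintBackend | str = "biharmonic",
) -> np.ndarray:
    """Inpaint the footprint a patch *would* cover, without compositing it.

    Control condition separating the effect of the patch's colour content
    from the effect of occluding that image region: the original image has
    the insertion footprint filled by the backend, and the classifier's
    response is compared with the response to actual insertion.
    """
    return inpaint(image, inserted_mask, backend)


def build_template_library(images) -> list[PatchTemplate]:
    """Extract one template from every image with a non-empty patch mask."""
    out = []
    for im in images:
        if im.patch_mask is not None and im.patch_mask.any():
            out.append(extract_patch(im.pixels, im.patch_mask, source_id=im.id))
    return out


def save_template_library(templates, out_dir) -> None:
    """Write templates as paired PNGs (crop + mask) with a CSV index."""
    import csv
    from pathlib import Path

    from skimage.io import imsave

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "index.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_id", "crop", "mask"])
        for t in templates:
            crop_name = f"{t.source_id}_crop.png"
            mask_name = f"{t.source_id}_mask.png"
            imsave(out_dir / crop_name,
                   (np.clip(t.pixels, 0, 1) * 255).round().astype(np.uint8),
                   check_contrast=False)
            imsave(out_dir / mask_name,
                   t.mask.astype(np.uint8) * 255, check_contrast=False)
            w.writerow([t.source_id, crop_name, mask_name])


def load_template_library(in_dir) -> list[PatchTemplate]:
    """Load a template library written by :func:`save_template_library`."""
    import csv
    from pathlib import Path

    from skimage.io import imread

    in_dir = Path(in_dir)
    out = []
    with open(in_dir / "index.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PatchTemplate(
                    pixels=(imread(in_dir / row["crop"]) / 255.0).astype(np.float32),
                    mask=imread(in_dir / row["mask"]) > 127,
                    source_id=row["source_id"],
                )
            )
    return out
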