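"""Synthetic confounded dermoscopy-like datasets with ground-truth masks.

Generates two classes of lesion images on a textured skin background where a
saturated elliptical colour-calibration patch appears near the image boundary
in a configurable fraction of the benign images (default 46%) and never in
malignant images.  Patch presence is therefore a perfect predictor of the
benign class — the confound structure this package exists to audit — while
lesion darkness and border irregularity carry the legitimate class signal.

Every image carries ground-truth ``lesion_mask`` and ``patch_mask`` so each
downstream stage (segmentation, inpainting, compositing, metrics) can be
validated without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

BENIGN = "benign"
MALIGNANT = "malignant"

# Saturated patch hues kept far from skin tones (skin hue is ~0.05-0.08):
# azure, blue, green, magenta.  (h, s, v) ranges sampled uniformly.
_PATCH_HUES = (0.55, 0.62, 0.33, 0.83)
_PATCH_SAT = (0.70, 0.95)
_PATCH_VAL = (0.70, 0.95)

# Border irregularity (relative radial modulation amplitude) per class.
_IRREGULARITY = {BENIGN: 0.05, MALIGNANT: 0.18}

# Per-image spread of lesion darkness around the class contrast parameter.
_CONTRAST_SD = 0.10

_MAX_PATCH_ATTEMPTS = 20


@dataclass(frozen=True)
class GeneratorParams:
    """Configuration of the synthetic dataset generator.

    Parameters
    ----------
    image_size : int
        Pixels per side of the square images (>= 32).
    n_benign, n_malignant : int
        Number of images per class.
    patch_fraction_benign : float
        Fraction of benign images receiving a coloured patch.  The default
        0.46 matches the prevalence of calibration patches among benign
        images in the ISIC archive snapshot this generator emulates.
    patch_fraction_malignant : float
        Fraction of malignant images receiving a patch (default 0, i.e. the
        patch is a perfect predictor of the benign class).
    lesion_contrast_benign, lesion_contrast_malignant : float
        Mean darkness of the lesion relative to the surrounding skin, in
        [0, 1].  The class difference in darkness (plus border irregularity)
        is the legitimate, non-shortcut signal a classifier can use.
    noise_sd : float
        Standard deviation of additive Gaussian pixel noise (intensity
        units on the [0, 1] scale).
    seed : int
        Master RNG seed; identical params reproduce the dataset bit-exactly.
    """

    image_size: int = 128
    n_benign: int = 100
    n_malignant: int = 100
    patch_fraction_benign: float = 0.46
    patch_fraction_malignant: float = 0.0
    lesion_contrast_benign: float = 0.28
    lesion_contrast_malignant: float = 0.58
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("image counts must be >= 0")
        for name in ("patch_fraction_benign", "patch_fraction_malignant"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LabeledImage:
    """An RGB image with class label and optional ground-truth masks.

    ``pixels`` is H x W x 3 float32 in [0, 1].  ``lesion_mask`` and
    ``patch_mask`` are boolean H x W arrays; the patch mask is all-False
    when the image carries no patch.  ``patch_failed`` flags images where
    patch placement was abandoned because no position disjoint from the
    lesion could be found.
    """

    id: str
    pixels: np.ndarray
    label: str
    lesion_mask: np.ndarray | None = None
    patch_mask: np.ndarray | None = None
    patch_failed: bool = False

    @property
    def has_patch(self) -> bool:
        return self.patch_mask is not None and bool(self.patch_mask.any())

    def __post_init__(self) -> None:
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"label must be '{BENIGN}' or '{MALIGNANT}'")
        h, w = self.pixels.shape[:2]
        for m in (self.lesion_mask, self.patch_mask):
            if m is not None and m.shape != (h, w):
                raise ValueError("mask shape must match image shape")


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    """Boolean mask of a filled rotated ellipse (clipped at the borders)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _lesion_mask(size: int, rng: np.random.Generator, irregularity: float) -> np.ndarray:
    """Roughly elliptical blob with radial border modulation, near the centre."""
    cy, cx = (size / 2 + rng.uniform(-0.06, 0.06, 2) * size)
    r0 = rng.uniform(0.15, 0.26) * size
    aspect = rng.uniform(0.7, 1.0)
    theta0 = rng.uniform(0, np.pi)
    # Low-order Fourier modulation of the radius encodes border irregularity.
    ks = np.arange(2, 7)
    amps = rng.normal(0.0, irregularity, ks.size)
    phases = rng.uniform(0, 2 * np.pi, ks.size)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta0), np.sin(theta0)
    u = dx * c + dy * s
    v = (-dx * s + dy * c) / aspect
    rad = np.hypot(u, v)
    ang = np.arctan2(v, u)
    rim = r0 * (1.0 + sum(a * np.cos(k * ang + p) for a, k, p in zip(amps, ks, phases)))
    return rad <= np.maximum(rim, 2.0)


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.asarray(rgb)


def _generate_one(
    image_id: str,
    label: str,
    want_patch: bool,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> LabeledImage:
    size = params.image_size
    contrast = (
        params.lesion_contrast_benign if label == BENIGN else params.lesion_contrast_malignant
    )

    # Skin background: per-image base tone + low-frequency multiplicative texture.
    base = np.array([0.80, 0.62, 0.55]) + rng.uniform(-0.04, 0.04, 3)
    tex = rng.standard_normal((size, size))
    tex = gaussian_filter(tex, sigma=size / 16.0, mode="reflect")
    tex /= max(tex.std(), 1e-12)
    img = base[None, None, :] * (1.0 + 0.06 * tex)[:, :, None]

    # Lesion: darker, slightly browner region with class-dependent darkness
    # and border irregularity; soft photometric edge, hard ground-truth mask.
    lesion = _lesion_mask(size, rng, _IRREGULARITY[label])
    darkness = float(np.clip(rng.normal(contrast, _CONTRAST_SD), 0.05, 0.90))
    lesion_rgb = base * (1.0 - darkness) * np.array([1.0, 0.82, 0.72])
    soft = gaussian_filter(lesion.astype(float), sigma=1.5, mode="constant")
    img = img * (1 - soft[:, :, None]) + lesion_rgb[None, None, :] * soft[:, :, None]

    # Coloured calibration patch: saturated ellipse, centre in the outer 25%
    # border ring, disjoint from the lesion; bounded retry on overlap.
    patch = np.zeros((size, size), dtype=bool)
    patch_failed = False
    if want_patch:
        placed = False
        for _ in range(_MAX_PATCH_ATTEMPTS):
            center = _draw_boundary_center(size, 0.25, rng)
            axes = rng.uniform(0.10, 0.25, 2) * size
            angle = rng.uniform(0, np.pi)
            cand = _ellipse_mask((size, size), center, (axes[0], axes[1]), angle)
            if cand.any() and not (cand & lesion).any():
                patch = cand
                placed = True
                break
        if placed:
            hue = _PATCH_HUES[rng.integers(len(_PATCH_HUES))]
            colour = _hsv_to_rgb(
                hue, rng.uniform(*_PATCH_SAT), rng.uniform(*_PATCH_VAL)
            )
            img[patch] = colour
        else:
            patch_failed = True

    img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return LabeledImage(
        id=image_id,
        pixels=img,
        label=label,
        lesion_mask=lesion,
        patch_mask=patch,
        patch_failed=patch_failed,
    )


def _draw_boundary_center(
    size: int, ring: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Uniform draw of a centre whose row or column lies in the outer ring."""
    band = ring * size
    while True:
        cy, cx = rng.uniform(0, size, 2)
        if min(cy, size - cy) <= band or min(cx, size - cx) <= band:
            return float(cy), float(cx)


def generate_dataset(params: GeneratorParams) -> list[LabeledImage]:
    """Generate ``n_benign + n_malignant`` labelled images with masks.

    Patch assignment is an independent Bernoulli draw per image at the
    class-specific fraction.  Identical ``params`` (including ``seed``)
    reproduce the dataset bit-exactly.
    """
    ss = np.random.SeedSequence(params.seed)
    specs = [(BENIGN, i) for i in range(params.n_benign)] + [
        (MALIGNANT, i) for i in range(params.n_malignant)
    ]
    children = ss.spawn(len(specs))
    out: list[LabeledImage] = []
    for (label, i), child in zip(specs, children):
        rng = np.random.default_rng(child)
        frac = (
            params.patch_fraction_benign
            if label == BENIGN
            else params.patch_fraction_malignant
        )
        want_patch = rng.random() < frac
        out.append(_generate_one(f"{label}_{i:04d}", label, want_patch, params, rng))
    return out


def split_train_test(
    dataset: Sequence[LabeledImage], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Stratified random split into disjoint, exhaustive train/test sets."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[LabeledImage] = []
    test: list[LabeledImage] = []
    for label in (BENIGN, MALIGNANT):
        members = [im for im in dataset if im.label == label]
        if not members:
            continue
        if len(members) < 2:
            raise ValueError(f"class '{label}' has fewer than 2 members")
        order = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[j] for j in order[:n_train])
        test.extend(members[j] for j in order[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# On-disk layout: 8-bit RGB PNGs, single-channel 0/255 mask PNGs, a labels
# CSV (id,label,has_patch) and a YAML manifest tying them together.
# ---------------------------------------------------------------------------

def save_dataset(
    dataset: Iterable[LabeledImage],
    out_dir: str | Path,
    params: GeneratorParams | None = None,
) -> Path:
    """Write images, masks, labels CSV and manifest; returns manifest path."""
    from skimage.io import imsave

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    rows = []
    for im in dataset:
        imsave(
            out_dir / "images" / f"{im.id}.png",
            (im.pixels * 255).round().astype(np.uint8),
            check_contrast=False,
        )
        for kind, mask in (("lesion", im.lesion_mask), ("patch", im.patch_mask)):
            if mask is not None:
                imsave(
                    out_dir / "masks" / f"{im.id}_{kind}.png",
                    (mask.astype(np.uint8) * 255),
                    check_contrast=False,
                )
        rows.append({"id": im.id, "label": im.label, "has_patch": im.has_patch})
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    manifest = {
        "images": "images",
        "masks": "masks",
        "labels": "labels.csv",
        "n_images": len(rows),
        "params": dataclasses.asdict(params) if params is not None else None,
    }
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest))
    return path


def load_dataset(manifest_path: str | Path) -> list[LabeledImage]:
    """Load a dataset written by :func:`save_dataset`."""
    from skimage.io import imread

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    labels = pd.read_csv(root / manifest["labels"])
    out = []
    for row in labels.itertuples():
        pixels = imread(root / manifest["images"] / f"{row.id}.png") / 255.0
        masks = {}
        for kind in ("lesion", "patch"):
            p = root / manifest["masks"] / f"{row.id}_{kind}.png"
            masks[kind] = imread(p) > 127 if p.exists() else None
        out.append(
            LabeledImage(
                id=str(row.id),
                pixels=pixels.astype(np.float32),
                label=str(row.label),
                lesion_mask=masks["lesion"],
                patch_mask=masks["patch"],
            )
        )
    return out
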