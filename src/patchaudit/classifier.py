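"""Model-agnostic classifier contract and the desk-scale reference model.

The audit needs only a ``predict_proba`` surface producing two-class
probabilities that sum to one; any model satisfying it can be audited
(an adapter shim for external models reads images from disk and writes a
prediction CSV).  The bundled reference classifier is a logistic
regression over engineered colour/intensity features of the kind used in
classical dermoscopy CAD: a global hue-saturation histogram (which pools
colour evidence over the whole image the way a CNN pools feature maps),
global and central-region intensity statistics, and brightness
percentiles.  It is deliberately small — the audit methodology, not the
classifier, is the point — but it learns both the legitimate lesion
signal and, when present in training, the colour-patch shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import sobel
from sklearn.linear_model import LogisticRegression

from .metrics import BENIGN, MALIGNANT, DEFAULT_THRESHOLD, PredictionRecord


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration for the reference classifier.

    ``hue_bins``/``sat_bins`` shape the global hue-saturation histogram;
    ``hist_weight`` scales those features relative to the intensity
    statistics (larger values make pooled colour evidence more salient to
    the L2-regularised model); ``central_radius`` is the radius (fraction
    of the side) of the central disc over which lesion-focused statistics
    are computed; ``c`` is the inverse L2 regularisation strength;
    ``threshold`` is the decision threshold on P(malignant | x), stored
    here but applied only at metric time, never during training.
    """

    hue_bins: int = 8
    sat_bins: int = 4
    hist_weight: float = 6.0
    central_radius: float = 0.35
    c: float = 1.0
    max_iter: int = 5000
    seed: int = 0
    threshold: float = DEFAULT_THRESHOLD
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if self.hue_bins < 2 or self.sat_bins < 1:
            raise ValueError("histogram must have >= 2 hue and >= 1 sat bins")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if not 0 < self.central_radius <= 0.5:
            raise ValueError("central_radius must be in (0, 0.5]")


def _image_features(px: np.ndarray, config: TrainConfig) -> np.ndarray:
    """Engineered feature vector for one RGB [0, 1] image.

    Concatenates the weighted global hue-saturation histogram, per-channel
    global mean/sd, brightness (HSV value) percentiles, central-disc
    channel means plus dark-end brightness percentiles, and central-disc
    edge statistics (border-irregularity cues in the spirit of the ABCD
    rule's B criterion).  The central disc targets the lesion (lesions sit
    near the image centre; calibration patches near the boundary), so the
    legitimate class signal and the artefact signal live in largely
    separate coordinates.
    """
    px = np.asarray(px, dtype=float)
    hsv = rgb2hsv(px)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    hist, _, _ = np.histogram2d(
        h.ravel(), s.ravel(),
        bins=(config.hue_bins, config.sat_bins), range=((0, 1), (0, 1)),
    )
    hist = config.hist_weight * hist / h.size
    n0, n1 = px.shape[:2]
    yy, xx = np.mgrid[0:n0, 0:n1]
    central = (yy - n0 / 2) ** 2 + (xx - n1 / 2) ** 2 <= (
        config.central_radius * min(n0, n1)
    ) ** 2
    cen = px[central]
    global_stats = [px[..., c].mean() for c in range(3)] + [
        px[..., c].std() for c in range(3)
    ]
    v_percentiles = list(np.percentile(v, [5, 10, 25, 50, 75]))
    central_stats = [cen[:, c].mean() for c in range(3)] + list(
        np.percentile(v[central], [10, 25])
    )
    grad = sobel(v)
    edge_stats = [
        grad[central].mean(),
        float(np.percentile(grad[central], 95)),
        v[central].std(),
    ]
    return np.concatenate(
        [hist.ravel(), global_stats, v_percentiles, central_stats, edge_stats]
    )


def _features(pixels_list: Sequence[np.ndarray], config: TrainConfig) -> np.ndarray:
    return np.array([_image_features(px, config) for px in pixels_list])


class ReferenceClassifier:
    """Logistic regression over engineered image features.

    ``predict_proba`` accepts ``LabeledImage`` objects or bare pixel
    arrays and returns order-preserving :class:`PredictionRecord` lists;
    predictions are deterministic for a fixed trained model.
    """

    def __init__(self, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self._model: LogisticRegression | None = None

    # -- contract ----------------------------------------------------------
    def fit(self, train, config: TrainConfig | None = None) -> "ReferenceClassifier":
        if config is not None:
            self.config = config
        labels = [im.label for im in train]
        present = set(labels)
        if present != {BENIGN, MALIGNANT}:
            raise ValueError(
                f"training set must contain both classes, got {sorted(present)}"
            )
        x = _features([im.pixels for im in train], self.config)
        y = np.array([1 if l == MALIGNANT else 0 for l in labels])
        self._model = LogisticRegression(
            C=self.config.c,
            max_iter=self.config.max_iter,
            random_state=self.config.seed,
            class_weight=self.config.class_weight,
        )
        self._model.fit(x, y)
        return self

    def predict_proba(self, images) -> list[PredictionRecord]:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        if len(images) == 0:
            return []
        pixels, ids = [], []
        for i, im in enumerate(images):
            if hasattr(im, "pixels"):
                pixels.append(im.pixels)
                ids.append(im.id)
            else:
                pixels.append(np.asarray(im))
                ids.append(str(i))
        x = _features(pixels, self.config)
        # Row-wise scoring so batch and one-by-one evaluation are
        # bit-identical (batched GEMM may round differently than GEMV).
        coef = self._model.coef_[0]
        b = float(self._model.intercept_[0])
        scores = np.array([float(np.dot(row, coef)) + b for row in x])
        p = 1.0 / (1.0 + np.exp(-scores))
        return [
            PredictionRecord(id=i, p_malignant=float(pm), p_benign=float(1 - pm))
            for i, pm in zip(ids, p)
        ]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Self-describing single-file checkpoint (.npz)."""
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        np.savez(
            path,
            coef=self._model.coef_,
            intercept=self._model.intercept_,
            classes=self._model.classes_,
            hue_bins=self.config.hue_bins,
            sat_bins=self.config.sat_bins,
            hist_weight=self.config.hist_weight,
            central_radius=self.config.central_radius,
            c=self.config.c,
            max_iter=self.config.max_iter,
            seed=self.config.seed,
            threshold=self.config.threshold,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceClassifier":
        data = np.load(path, allow_pickle=False)
        config = TrainConfig(
            hue_bins=int(data["hue_bins"]),
            sat_bins=int(data["sat_bins"]),
            hist_weight=float(data["hist_weight"]),
            central_radius=float(data["central_radius"]),
            c=float(data["c"]),
            max_iter=int(data["max_iter"]),
            seed=int(data["seed"]),
            threshold=float(data["threshold"]),
        )
        clf = cls(config)
        model = LogisticRegression(C=config.c, max_iter=config.max_iter,
                                   random_state=config.seed)
        model.coef_ = data["coef"]
        model.intercept_ = data["intercept"]
        model.classes_ = data["classes"]
        clf._model = model
        return clf


class CsvPredictionAdapter:
    """Adapter exposing externally computed predictions via the contract.

    Wraps a mapping id -> P(malignant) (e.g. read from a CSV with columns
    ``id,p_malignant`` produced by any external model) as a predict-only
    classifier, so foreign models can be audited without being loaded here.
    """

    def __init__(self, p_malignant_by_id: dict[str, float]):
        self._p = dict(p_malignant_by_id)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CsvPredictionAdapter":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(dict(zip(df["id"].astype(str), df["p_malignant"].astype(float))))

    def predict_proba(self, images) -> list[PredictionRecord]:
        out = []
        for im in images:
            pid = im.id if hasattr(im, "id") else str(im)
            p = float(self._p[pid])
            out.append(PredictionRecord(id=pid, p_malignant=p, p_benign=1 - p))
        return out
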