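"""Deviation statistics for paired original/altered predictions.

Quantifies a classifier's reliance on an artefact by comparing its
predicted probabilities before and after the artefact is removed from, or
inserted into, each image.  All statistics work on the *true-class*
probability: P(benign | .) for benign images, P(malignant | .) for
malignant images, so that a negative deviation always means the alteration
pushed the prediction away from the truth.

Reported quantities:

- MAD: mean absolute deviation of the true-class probability,
- %P-down (``frac_decreased``): fraction of pairs whose true-class
  probability decreased,
- MND: mean magnitude of deviation over that decreased subset (undefined,
  not zero, when no pair decreased),
- %flip (``flip_fraction``): fraction of initially correctly classified
  pairs whose predicted class crossed the decision boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

BENIGN = "benign"
MALIGNANT = "malignant"

#: Decision threshold on P(malignant | x); chosen low (rather than 0.5) to
#: favour sensitivity, i.e. to capture more cancerous lesions.
DEFAULT_THRESHOLD = 0.4


@dataclass(frozen=True)
class PredictionRecord:
    """Two-class probability output of a classifier for one image."""

    id: str
    p_malignant: float
    p_benign: float

    def __post_init__(self) -> None:
        if abs(self.p_malignant + self.p_benign - 1.0) > 1e-9:
            raise ValueError(
                f"probabilities must sum to 1: {self.p_malignant} + {self.p_benign}"
            )


def record(id: str, p_malignant: float) -> PredictionRecord:
    """Convenience constructor from P(malignant) alone."""
    return PredictionRecord(id=id, p_malignant=float(p_malignant),
                            p_benign=1.0 - float(p_malignant))


@dataclass(frozen=True)
class PairedPredictions:
    """Matched original/altered predictions for a single-alteration audit.

    ``alteration`` names what was done to produce the altered images:
    ``patch_removed``, ``patch_inserted``, ``random_inpaint`` or
    ``footprint_inpaint``.  Original and altered records are matched by id,
    one-to-one; ``labels`` gives each pair's true class.
    """

    original: tuple[PredictionRecord, ...]
    altered: tuple[PredictionRecord, ...]
    labels: tuple[str, ...]
    alteration: str = ""

    def __post_init__(self) -> None:
        if not (len(self.original) == len(self.altered) == len(self.labels)):
            raise ValueError("original, altered and labels must have equal length")
        for o, a in zip(self.original, self.altered):
            if o.id != a.id:
                raise ValueError(f"id mismatch: {o.id!r} vs {a.id!r}")
        for lab in self.labels:
            if lab not in (BENIGN, MALIGNANT):
                raise ValueError(f"unknown label {lab!r}")

    def __len__(self) -> int:
        return len(self.original)

    def true_class_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """(original, altered) probabilities of each pair's true class."""
        po, pa = [], []
        for o, a, lab in zip(self.original, self.altered, self.labels):
            if lab == MALIGNANT:
                po.append(o.p_malignant)
                pa.append(a.p_malignant)
            else:
                po.append(o.p_benign)
                pa.append(a.p_benign)
        return np.asarray(po), np.asarray(pa)


def mad(pairs: PairedPredictions) -> float:
    """Mean absolute deviation of the true-class probability."""
    if len(pairs) == 0:
        raise ValueError("empty prediction set")
    po, pa = pairs.true_class_probs()
    return float(np.mean(np.abs(pa - po)))


def deviation_summary(pairs: PairedPredictions) -> tuple[float, float | None]:
    """(fraction decreased, mean negative deviation magnitude).

    The deviation is true-class(altered) - true-class(original); the MND is
    the mean |deviation| over the strictly-decreased subset and is ``None``
    (undefined, not zero) when no pair decreased.
    """
    if len(pairs) == 0:
        raise ValueError("empty prediction set")
    po, pa = pairs.true_class_probs()
    d = pa - po
    neg = d < 0
    frac = float(neg.mean())
    mnd = float(np.abs(d[neg]).mean()) if neg.any() else None
    return frac, mnd


def _classify(p_malignant: np.ndarray, threshold: float) -> np.ndarray:
    """Predicted label array; boundary tie p == threshold goes to malignant."""
    return np.where(p_malignant >= threshold, MALIGNANT, BENIGN)


def flip_fraction(
    pairs: PairedPredictions,
    threshold: float = DEFAULT_THRESHOLD,
    restrict_to_correct: bool = True,
) -> float:
    """Fraction of pairs whose predicted class flips to incorrect.

    With ``restrict_to_correct`` (default), the denominator is the pairs
    whose *original* prediction was correct, and the numerator those of
    them whose altered prediction is incorrect.  With it off, the
    denominator is all pairs and the numerator every originally-correct
    pair that became incorrect.
    """
    if len(pairs) == 0:
        raise ValueError("empty prediction set")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p_orig = np.array([r.p_malignant for r in pairs.original])
    p_alt = np.array([r.p_malignant for r in pairs.altered])
    labels = np.asarray(pairs.labels)
    orig_correct = _classify(p_orig, threshold) == labels
    alt_correct = _classify(p_alt, threshold) == labels
    flipped = orig_correct & ~alt_correct
    if restrict_to_correct:
        if not orig_correct.any():
            raise ValueError("no originally-correct pairs; flip fraction undefined")
        return float(flipped.sum() / orig_correct.sum())
    return float(flipped.mean())


def sens_spec(
    predictions: Sequence[PredictionRecord],
    labels: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) at the given probability threshold.

    Positive class is malignant.  A metric whose class is absent from
    ``labels`` is returned as ``None`` (not applicable) rather than raising.
    """
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    p = np.array([r.p_malignant for r in predictions])
    y = np.asarray(labels)
    pred = _classify(p, threshold)
    pos = y == MALIGNANT
    neg = y == BENIGN
    sens = float((pred[pos] == MALIGNANT).mean()) if pos.any() else None
    spec = float((pred[neg] == BENIGN).mean()) if neg.any() else None
    return sens, spec


def pearson_fidelity(
    preds_a: Sequence[PredictionRecord],
    preds_b: Sequence[PredictionRecord],
    subgroups: dict[str, Sequence[str]] | None = None,
) -> dict[str, float | None]:
    """Pearson r of P(malignant) between two classifiers, per subgroup.

    ``subgroups`` maps a subgroup name to the ids it contains; the overall
    correlation is always reported under ``"overall"``.  Zero variance in
    either vector makes r undefined for that subgroup (``None``).
    """
    pa = {r.id: r.p_malignant for r in preds_a}
    pb = {r.id: r.p_malignant for r in preds_b}
    if set(pa) != set(pb):
        raise ValueError("prediction sets must cover identical ids")
    groups = {"overall": list(pa)}
    if subgroups:
        groups.update({k: list(v) for k, v in subgroups.items()})
    out: dict[str, float | None] = {}
    for name, ids in groups.items():
        if len(ids) < 3:
            raise ValueError(f"subgroup {name!r} has fewer than 3 members")
        xa = np.array([pa[i] for i in ids])
        xb = np.array([pb[i] for i in ids])
        if xa.std() == 0 or xb.std() == 0:
            out[name] = None
            continue
        out[name] = float(stats.pearsonr(xa, xb).statistic)
    return out


@dataclass
class ShortcutReport:
    """Full deviation-statistics report for one audit.

    Fractions are stored on the [0, 1] scale; use :meth:`as_percent_row`
    for table-style formatting (x100).  ``flip_fraction_all_pairs`` is the
    unrestricted variant whose denominator is every pair, logged alongside
    the default restricted one.
    """

    alteration: str
    n: int
    mad: float
    frac_decreased: float
    mnd: float | None
    n_decreased: int
    flip_fraction: float
    flip_fraction_all_pairs: float
    threshold: float

    @classmethod
    def from_pairs(
        cls, pairs: PairedPredictions, threshold: float = DEFAULT_THRESHOLD
    ) -> "ShortcutReport":
        frac, mnd_ = deviation_summary(pairs)
        po, pa = pairs.true_class_probs()
        return cls(
            alteration=pairs.alteration,
            n=len(pairs),
            mad=mad(pairs),
            frac_decreased=frac,
            mnd=mnd_,
            n_decreased=int((pa - po < 0).sum()),
            flip_fraction=flip_fraction(pairs, threshold),
            flip_fraction_all_pairs=flip_fraction(pairs, threshold, False),
            threshold=threshold,
        )

    def to_dict(self) -> dict:
        return {
            "alteration": self.alteration,
            "n": self.n,
            "mad": self.mad,
            "frac_decreased": self.frac_decreased,
            "mnd": self.mnd,
            "n_decreased": self.n_decreased,
            "flip_fraction": self.flip_fraction,
            "flip_fraction_all_pairs": self.flip_fraction_all_pairs,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShortcutReport":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ShortcutReport":
        return cls.from_dict(json.loads(s))

    def as_percent_row(self) -> dict:
        """Row with percentage-scaled fractions (MAD/MND stay probabilities)."""
        return {
            "alteration": self.alteration,
            "n": self.n,
            "MAD": round(self.mad, 3),
            "%P_down": round(100 * self.frac_decreased, 1),
            "MND": None if self.mnd is None else round(self.mnd, 3),
            "%flip": round(100 * self.flip_fraction, 1),
        }
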