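"""End-to-end audit orchestration.

Runs the four experiments — inpainting validity check, removal audit,
insertion audit, and de-bias-and-retrain — against any classifier
satisfying the contract, and collects the deviation statistics,
threshold performance, SSIM distributions and fidelity correlations into
a single reproducible :class:`AuditRun`.

Seeding: a single master seed is split into independent per-experiment
streams with ``numpy.random.SeedSequence.spawn``, so each audit is
reproducible on its own and the full run is byte-identical for identical
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import ReferenceClassifier, TrainConfig
from .inpaint import (
    InpaintBackend,
    RandomMaskParams,
    ValidityReport,
    get_backend,
    inpaint,
    ssim,
    validity_check,
)
from .metrics import (
    BENIGN,
    DEFAULT_THRESHOLD,
    MALIGNANT,
    PairedPredictions,
    PredictionRecord,
    ShortcutReport,
    pearson_fidelity,
    sens_spec,
)
from .patch_ops import (
    PlacementError,
    build_template_library,
    inpaint_footprint_control,
    insert_patch,
)
from .segmentation import SegmentationConfig, dilate_mask, elliptical_kernel, segment_patches
from .synthetic import LabeledImage

logger = logging.getLogger("patchaudit")

# Seed-stream indices of the independent per-experiment RNGs.
_STREAMS = ("train", "validity", "insertion", "debias", "retrain")


@dataclass(frozen=True)
class AuditConfig:
    """All knobs of a full audit run."""

    seed: int = 0
    threshold: float = DEFAULT_THRESHOLD
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    mask_params: RandomMaskParams = field(default_factory=RandomMaskParams)
    backend: str = "biharmonic"
    train_config: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str | None = None

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AuditConfig":
        """Build a config from a YAML mapping of (nested) field names."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        nested = {
            "segmentation": SegmentationConfig,
            "mask_params": RandomMaskParams,
            "train_config": TrainConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**(value or {}))
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class AuditRun:
    """Manifest of a full vanilla-vs-retrained audit experiment."""

    config: AuditConfig
    validity: dict[str, ValidityReport] = field(default_factory=dict)
    removal: dict[str, ShortcutReport] = field(default_factory=dict)
    insertion: dict[str, ShortcutReport] = field(default_factory=dict)
    footprint_mean_abs_dp: dict[str, float] = field(default_factory=dict)
    insertion_mean_abs_dp: dict[str, float] = field(default_factory=dict)
    performance: pd.DataFrame | None = None
    fidelity: dict[str, float | None] = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)
    removal_ssim: dict[str, float] = field(default_factory=dict)
    insertion_ssim: dict[str, float] = field(default_factory=dict)

    def report_dict(self) -> dict:
        return {
            "seed": self.config.seed,
            "threshold": self.config.threshold,
            "backend": self.config.backend,
            "validity": {k: v.to_dict() for k, v in self.validity.items()},
            "removal": {k: v.to_dict() for k, v in self.removal.items()},
            "insertion": {k: v.to_dict() for k, v in self.insertion.items()},
            "footprint_mean_abs_dp": self.footprint_mean_abs_dp,
            "insertion_mean_abs_dp": self.insertion_mean_abs_dp,
            "removal_ssim": self.removal_ssim,
            "insertion_ssim": self.insertion_ssim,
            "performance": (
                None if self.performance is None
                else self.performance.to_dict(orient="records")
            ),
            "fidelity": self.fidelity,
            "n_excluded": len(self.exclusions),
        }

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(self.report_dict(), indent=2, sort_keys=True)
        )
        if self.performance is not None:
            self.performance.to_csv(out_dir / "performance.csv", index=False)
        pd.DataFrame(self.exclusions).to_csv(out_dir / "exclusions.csv", index=False)
        rows = []
        for kind, reports in (("removal", self.removal), ("insertion", self.insertion)):
            for clf_name, rep in reports.items():
                rows.append({"experiment": kind, "classifier": clf_name,
                             **rep.as_percent_row()})
        pd.DataFrame(rows).to_csv(out_dir / "shortcut_stats.csv", index=False)


def _pair(
    classifier,
    originals: Sequence[LabeledImage],
    altered_pixels: Sequence[np.ndarray],
    labels: Sequence[str],
    alteration: str,
) -> PairedPredictions:
    po = classifier.predict_proba(originals)
    pa_raw = classifier.predict_proba(altered_pixels)
    pa = tuple(
        PredictionRecord(id=o.id, p_malignant=r.p_malignant, p_benign=r.p_benign)
        for o, r in zip(po, pa_raw)
    )
    return PairedPredictions(tuple(po), pa, tuple(labels), alteration)


def removal_counterfactuals(
    images: Sequence[LabeledImage],
    config: AuditConfig,
    masks: Sequence[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[float]]:
    """Segment (or take), dilate and inpaint patch masks; returns
    (inpainted pixels, per-image SSIM to the original)."""
    backend = get_backend(config.backend)
    kernel = elliptical_kernel(config.segmentation.dilation_kernel_size)
    out, ssims = [], []
    for i, im in enumerate(images):
        mask = masks[i] if masks is not None else segment_patches(im.pixels, config.segmentation)
        alt = inpaint(im.pixels, dilate_mask(mask, kernel), backend)
        out.append(alt)
        ssims.append(ssim(im.pixels, alt))
    return out, ssims


def run_removal_audit(
    classifier,
    test_set: Sequence[LabeledImage],
    config: AuditConfig,
    masks: Sequence[np.ndarray] | None = None,
) -> tuple[ShortcutReport, dict]:
    """Patch-removal audit on the benign-with-patch subset (set A).

    Segments each patch (unless precomputed ``masks`` are given), dilates,
    inpaints, and compares predictions for the original and inpainted
    versions.  Also reports specificity on the subset before and after
    removal, and the SSIM distribution of the alterations.
    """
    t0 = time.perf_counter()
    a_set = [im for im in test_set if im.label == BENIGN and im.has_patch]
    if not a_set:
        raise ValueError("removal audit requires benign images with patches")
    altered, ssims = removal_counterfactuals(a_set, config, masks)
    pairs = _pair(classifier, a_set, altered, [BENIGN] * len(a_set), "patch_removed")
    report = ShortcutReport.from_pairs(pairs, config.threshold)
    labels = [BENIGN] * len(a_set)
    _, spec_before = sens_spec(pairs.original, labels, config.threshold)
    _, spec_after = sens_spec(pairs.altered, labels, config.threshold)
    extras = {
        "n": len(a_set),
        "specificity_before": spec_before,
        "specificity_after": spec_after,
        "ssim_mean": float(np.mean(ssims)),
        "ssim_median": float(np.median(ssims)),
    }
    logger.info("removal audit: n=%d in %.1fs", len(a_set), time.perf_counter() - t0)
    return report, extras


def insertion_counterfactuals(
    test_set: Sequence[LabeledImage],
    templates,
    rng: np.random.Generator,
) -> tuple[list[LabeledImage], list[np.ndarray], list[np.ndarray], list[float], list[dict]]:
    """Composite one random template into each malignant patch-free image.

    Returns (kept images, altered pixels, placed footprint masks, SSIMs,
    exclusion log).  Images with no lesion-disjoint placement within the
    attempt budget are excluded and logged, not silently dropped.
    """
    b_set = [im for im in test_set if im.label == MALIGNANT and not im.has_patch]
    if not b_set or not templates:
        raise ValueError("insertion audit requires malignant images and templates")
    kept, altered, footprints, ssims, exclusions = [], [], [], [], []
    for im in b_set:
        tmpl = templates[int(rng.integers(len(templates)))]
        try:
            alt, placed = insert_patch(
                im.pixels, tmpl, im.lesion_mask, rng, image_id=im.id
            )
        except PlacementError as e:
            exclusions.append({"id": im.id, "reason": str(e)})
            continue
        kept.append(im)
        altered.append(alt)
        footprints.append(placed)
        ssims.append(ssim(im.pixels, alt))
    if not kept:
        raise ValueError("all patch placements failed")
    return kept, altered, footprints, ssims, exclusions


def run_insertion_audit(
    classifier,
    test_set: Sequence[LabeledImage],
    templates,
    config: AuditConfig,
    rng: np.random.Generator,
    with_footprint_control: bool = True,
    precomputed: tuple | None = None,
) -> tuple[ShortcutReport, dict, list[dict]]:
    """Patch-insertion audit on the malignant-without-patch subset (set B).

    One template (drawn at random from the library) is composited per
    image at a lesion-disjoint boundary location; images with no legal
    placement are excluded and logged.  Also runs the footprint-inpainting
    control: the same footprint is inpainted instead of composited, and
    the mean |delta P| of both alterations is reported.  Pass
    ``precomputed`` (the output of :func:`insertion_counterfactuals`) to
    audit several classifiers against identical counterfactuals.
    """
    t0 = time.perf_counter()
    if precomputed is None:
        precomputed = insertion_counterfactuals(test_set, templates, rng)
    kept, altered, footprints, ssims, exclusions = precomputed
    pairs = _pair(classifier, kept, altered, [MALIGNANT] * len(kept), "patch_inserted")
    report = ShortcutReport.from_pairs(pairs, config.threshold)
    labels = [MALIGNANT] * len(kept)
    sens_before, _ = sens_spec(pairs.original, labels, config.threshold)
    sens_after, _ = sens_spec(pairs.altered, labels, config.threshold)
    extras = {
        "n": len(kept),
        "n_excluded": len(exclusions),
        "sensitivity_before": sens_before,
        "sensitivity_after": sens_after,
        "ssim_mean": float(np.mean(ssims)),
        "ssim_median": float(np.median(ssims)),
    }
    p_orig = np.array([r.p_malignant for r in pairs.original])
    p_ins = np.array([r.p_malignant for r in pairs.altered])
    extras["insertion_mean_abs_dp"] = float(np.abs(p_ins - p_orig).mean())
    if with_footprint_control:
        backend = get_backend(config.backend)
        controls = [
            inpaint_footprint_control(im.pixels, fp, backend)
            for im, fp in zip(kept, footprints)
        ]
        p_ctrl = np.array(
            [r.p_malignant for r in classifier.predict_proba(controls)]
        )
        extras["footprint_mean_abs_dp"] = float(np.abs(p_ctrl - p_orig).mean())
        extras["footprint_mean_dp"] = float((p_ctrl - p_orig).mean())
        extras["insertion_mean_dp"] = float((p_ins - p_orig).mean())
    logger.info(
        "insertion audit: n=%d excluded=%d in %.1fs",
        len(kept), len(exclusions), time.perf_counter() - t0,
    )
    return report, extras, exclusions


def debias_dataset(
    train_set: Sequence[LabeledImage],
    segmentation: SegmentationConfig | None = None,
    backend: InpaintBackend | str = "biharmonic",
) -> tuple[list[LabeledImage], list[str]]:
    """Replace every detected patch in the training set by its inpainting.

    Returns the de-biased dataset (patch-free images passed through
    unchanged) and the ids of the altered images.
    """
    segmentation = segmentation or SegmentationConfig()
    kernel = elliptical_kernel(segmentation.dilation_kernel_size)
    out, altered_ids = [], []
    for im in train_set:
        mask = segment_patches(im.pixels, segmentation)
        if mask.any():
            pixels = inpaint(im.pixels, dilate_mask(mask, kernel), backend)
            altered_ids.append(im.id)
            out.append(
                LabeledImage(
                    id=im.id, pixels=pixels, label=im.label,
                    lesion_mask=im.lesion_mask,
                    patch_mask=np.zeros(pixels.shape[:2], dtype=bool),
                )
            )
        else:
            out.append(im)
    return out, altered_ids


def _subgroups(test_set: Sequence[LabeledImage]) -> dict[str, list[str]]:
    return {
        "malignant": [im.id for im in test_set if im.label == MALIGNANT],
        "benign_no_patch": [
            im.id for im in test_set if im.label == BENIGN and not im.has_patch
        ],
        "benign_with_patch": [
            im.id for im in test_set if im.label == BENIGN and im.has_patch
        ],
    }


def run_debias_experiment(
    train_set: Sequence[LabeledImage],
    test_set: Sequence[LabeledImage],
    config: AuditConfig | None = None,
) -> AuditRun:
    """Train vanilla and de-biased classifiers and audit both.

    The full experiment: fit the vanilla classifier on the raw training
    set, de-bias the training set by inpainting detected patches, retrain,
    then run the validity check, removal audit, insertion audit and
    footprint control for each classifier, plus per-subgroup Pearson
    fidelity between the two and a threshold-performance table.
    """
    config = config or AuditConfig()
    rngs = config.rngs()
    run = AuditRun(config=config)

    t0 = time.perf_counter()
    vanilla = ReferenceClassifier(config.train_config).fit(train_set)
    logger.info("vanilla fit in %.1fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    debiased, altered_ids = debias_dataset(
        train_set, config.segmentation, config.backend
    )
    logger.info(
        "debias: %d/%d images inpainted in %.1fs",
        len(altered_ids), len(train_set), time.perf_counter() - t0,
    )
    retrained = ReferenceClassifier(config.train_config).fit(debiased)

    templates = build_template_library(train_set)
    patch_free_test = [im for im in test_set if not im.has_patch]

    # Counterfactuals are computed once and shared by both classifiers so
    # the vanilla/retrained comparison sees identical altered images.
    a_set = [im for im in test_set if im.label == BENIGN and im.has_patch]
    a_masks = [segment_patches(im.pixels, config.segmentation) for im in a_set]
    ins_pre = insertion_counterfactuals(test_set, templates, rngs["insertion"])
    validity_seed = int(rngs["validity"].integers(2**31))

    perf_rows = []
    for name, clf in (("vanilla", vanilla), ("retrained", retrained)):
        run.validity[name] = validity_check(
            clf, patch_free_test, config.mask_params, config.backend,
            rng=np.random.default_rng(validity_seed),
        )
        rem_report, rem_extras = run_removal_audit(clf, test_set, config, a_masks)
        run.removal[name] = rem_report
        run.removal_ssim[name] = rem_extras["ssim_median"]
        ins_report, ins_extras, exclusions = run_insertion_audit(
            clf, test_set, templates, config, rngs["insertion"],
            precomputed=ins_pre,
        )
        run.insertion[name] = ins_report
        run.insertion_ssim[name] = ins_extras["ssim_median"]
        run.footprint_mean_abs_dp[name] = ins_extras["footprint_mean_abs_dp"]
        run.insertion_mean_abs_dp[name] = ins_extras["insertion_mean_abs_dp"]
        if name == "vanilla":
            run.exclusions = exclusions

        sens, spec = sens_spec(
            clf.predict_proba(test_set), [im.label for im in test_set],
            config.threshold,
        )
        sens_pf, spec_pf = sens_spec(
            clf.predict_proba(patch_free_test),
            [im.label for im in patch_free_test], config.threshold,
        )
        perf_rows.append(
            {
                "classifier": name,
                "sensitivity": sens,
                "specificity": spec,
                "sensitivity_patch_free": sens_pf,
                "specificity_patch_free": spec_pf,
                "specificity_A_before": rem_extras["specificity_before"],
                "specificity_A_after": rem_extras["specificity_after"],
                "sensitivity_B_before": ins_extras["sensitivity_before"],
                "sensitivity_B_after": ins_extras["sensitivity_after"],
            }
        )
    run.performance = pd.DataFrame(perf_rows)
    # Subgroups too small for a meaningful correlation are dropped rather
    # than aborting the run; pearson_fidelity itself stays strict.
    subgroups = {k: v for k, v in _subgroups(test_set).items() if len(v) >= 3}
    run.fidelity = pearson_fidelity(
        vanilla.predict_proba(test_set),
        retrained.predict_proba(test_set),
        subgroups,
    )
    if config.out_dir:
        run.save(config.out_dir)
    return run
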