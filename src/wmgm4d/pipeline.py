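"""End-to-end orchestration: series → WTA → intracranial → masks → features →
SVM → evaluation, with leave-one-out cross-validation over cases.

A *case* bundles a 4D series with (for phantoms) its ground truth and a
coarse intracranial mask used to initialise the levelset.  ``process_case``
runs the image-processing stages and caches every intermediate volume
under the output directory together with a provenance stamp (config hash
and seed), so re-running with the same configuration reloads cached
artifacts bit-identically.  ``run_loocv`` trains the voxel classifier on
all-but-one case (sampling, normalization statistics and the model fit use
the training folds only), tests on the held-out case, and aggregates the
slice-wise metrics and the merged ROC over folds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import csf_vessel, evaluation, features, levelset, registration, wta
from .classifier import (
    GM_LABEL,
    WM_LABEL,
    ProbabilityMap,
    SvmConfig,
    TrainedSvm,
    harden,
    predict_probabilities,
    sample_training_voxels,
    train_svm,
)
from .core import LabelMask, Series4D, Volume3D
from .features import FeatureConfig, FeatureMatrix
from .levelset import LevelSetConfig
from .phantom import PhantomSpec, PhantomTruth, build_phantom

__all__ = [
    "PipelineConfig",
    "Case",
    "CaseArtifacts",
    "FoldResult",
    "LoocvResult",
    "phantom_case",
    "process_case",
    "run_case",
    "run_loocv",
    "compare_variants",
]

log = logging.getLogger(__name__)

VARIANTS = ("full", "no_temporal")
UNLABELED = -1


@dataclass
class PipelineConfig:
    levelset: LevelSetConfig = field(default_factory=LevelSetConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    variant: str = "full"
    threshold: float = 0.5
    skull_threshold_hu: float = 200.0
    motion_correct: bool = False
    seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)

    def config_hash(self) -> str:
        """Hash of the settings the cached image stages depend on.

        The feature variant and classifier settings are excluded: cached
        artifacts (WTA, masks) are identical across variants.
        """
        payload = {
            "levelset": asdict(self.levelset),
            "skull_threshold_hu": self.skull_threshold_hu,
            "motion_correct": self.motion_correct,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def fold_seed(self, case_index: int) -> int:
        return (self.seed * 1_000_003 + 7919 * case_index + 1) % (2**31)


@dataclass
class Case:
    """One subject: a 4D series plus (phantom) truth and a coarse brain mask."""

    name: str
    series: Series4D
    truth: PhantomTruth | None = None
    coarse_intracranial: LabelMask | None = None


def phantom_case(spec: PhantomSpec, name: str | None = None) -> Case:
    """Build a phantom case; the coarse levelset init is the true intracranial mask."""
    series, truth = build_phantom(spec)
    return Case(
        name=name or f"phantom_seed{spec.rng_seed}",
        series=series,
        truth=truth,
        coarse_intracranial=truth.intracranial,
    )


@dataclass
class CaseArtifacts:
    name: str
    wta: Volume3D
    intracranial: LabelMask
    csf: LabelMask
    vessels: LabelMask
    soft_tissue: LabelMask
    groups: list[tuple[str, np.ndarray]]
    raw_features: FeatureMatrix
    labels: np.ndarray  # per soft-tissue voxel: 0 WM, 1 GM, -1 unlabeled

    @property
    def labeled(self) -> np.ndarray:
        return self.labels >= 0


class _Cache:
    """Stage-level artifact cache keyed by a provenance stamp."""

    def __init__(self, directory: Path | None, stamp: dict):
        self.dir = directory
        self.stamp = stamp
        if directory is not None:
            directory.mkdir(parents=True, exist_ok=True)
            stamp_file = directory / "provenance.json"
            if stamp_file.exists():
                try:
                    old = json.loads(stamp_file.read_text())
                except json.JSONDecodeError:
                    old = None
                if old != stamp:
                    log.info("provenance changed under %s; cache invalidated", directory)
                    for f in directory.glob("*.nii.gz"):
                        f.unlink()
            stamp_file.write_text(json.dumps(stamp, indent=2, sort_keys=True))

    def volume(self, key: str, compute) -> Volume3D:
        if self.dir is None:
            return compute()
        path = self.dir / f"{key}.nii.gz"
        if path.exists():
            return Volume3D.load(path)
        vol = compute()
        vol.save(path)
        return vol

    def mask(self, key: str, compute) -> LabelMask:
        if self.dir is None:
            return compute()
        path = self.dir / f"{key}.nii.gz"
        if path.exists():
            return LabelMask.load(path)
        m = compute()
        m.save(path)
        return m


def _stage(name: str, fn):
    t0 = time.perf_counter()
    out = fn()
    log.info("stage %-16s %6.2f s", name, time.perf_counter() - t0)
    return out


def feature_groups(
    wta_img: Volume3D,
    series: Series4D,
    intracranial: LabelMask,
    skull: LabelMask,
    csf: LabelMask,
    vessels: LabelMask,
    config: FeatureConfig,
    variant: str = "full",
) -> list[tuple[str, np.ndarray]]:
    """Ordered feature images: intensity → contextual → (temporal)."""
    groups = features.intensity_features(wta_img, config)
    groups += features.contextual_features(intracranial, skull, csf, vessels)
    if variant == "full":
        groups += features.temporal_features(series, config)
    return groups


def process_case(config: PipelineConfig, case: Case) -> CaseArtifacts:
    """Run the image-processing stages of one case (no classification)."""
    case_dir = None
    if config.output_dir is not None:
        case_dir = config.output_dir / case.name
    cache = _Cache(case_dir, {"config_hash": config.config_hash(), "seed": config.seed})

    series = case.series
    if config.motion_correct:
        transforms = _stage("registration", lambda: registration.register_series(series))
        series = _stage("resample", lambda: registration.resample_series(series, transforms))

    wta_img = cache.volume(
        "wta", lambda: _stage("wta", lambda: wta.weighted_temporal_average(series))
    )

    if case.coarse_intracranial is None:
        raise ValueError(
            f"case {case.name} has no coarse intracranial mask; "
            "provide one (phantom truth or atlas propagation)"
        )
    intracranial = cache.mask(
        "intracranial",
        lambda: _stage(
            "levelset",
            lambda: levelset.refine_intracranial(
                wta_img, case.coarse_intracranial, config.levelset
            ).mask,
        ),
    )

    stats = csf_vessel.histogram_stats(wta_img, intracranial)
    csf_mask = cache.mask(
        "csf", lambda: _stage("csf", lambda: csf_vessel.segment_csf(wta_img, intracranial, stats))
    )
    vessel_mask = cache.mask(
        "vessels",
        lambda: _stage("vessels", lambda: csf_vessel.segment_vessels(wta_img, intracranial, stats)),
    )
    soft = csf_vessel.soft_tissue_mask(intracranial, csf_mask, vessel_mask)

    skull = registration.extract_bone_mask(wta_img, config.skull_threshold_hu).mask
    groups = _stage(
        "features",
        lambda: feature_groups(
            wta_img, series, intracranial, skull, csf_mask, vessel_mask,
            config.features, config.variant,
        ),
    )
    raw = features.assemble(groups, soft)

    labels = np.full(raw.values.shape[0], UNLABELED, dtype=int)
    if case.truth is not None:
        truth_at = case.truth.labels[soft.data]
        from .phantom import LABEL_CODES

        labels[truth_at == LABEL_CODES["wm"]] = WM_LABEL
        labels[truth_at == LABEL_CODES["gm"]] = GM_LABEL

    return CaseArtifacts(
        case.name, wta_img, intracranial, csf_mask, vessel_mask, soft, groups, raw, labels
    )


@dataclass
class FoldResult:
    test_case: str
    prob: ProbabilityMap
    wm_mask: LabelMask
    gm_mask: LabelMask
    roc_scores: np.ndarray
    roc_labels: np.ndarray
    model: TrainedSvm


@dataclass
class LoocvResult:
    report: evaluation.EvalReport
    roc: evaluation.RocSummary
    folds: list[FoldResult]
    variant: str


def run_case(config: PipelineConfig, case: Case) -> tuple[CaseArtifacts, FoldResult]:
    """Single-case pipeline: the classifier is trained on the case's own
    sampled voxels (a self-training demonstration; for unbiased accuracy
    use :func:`run_loocv`)."""
    art = process_case(config, case)
    fold = _classify_fold(config, [art], art, fold_index=0)
    return art, fold


def _pooled_training(
    config: PipelineConfig, train_arts: list[CaseArtifacts], fold_index: int
) -> tuple[np.ndarray, np.ndarray, features.FeatureNormalization]:
    xs, ys = [], []
    for j, art in enumerate(train_arts):
        valid = art.labeled
        matrix = FeatureMatrix(
            art.raw_features.values[valid], art.raw_features.names,
            art.raw_features.coords[valid], None,
        )
        sub, sub_labels = sample_training_voxels(
            matrix, art.labels[valid], rate=config.svm.sampling_rate,
            seed=config.fold_seed(fold_index * 97 + j),
        )
        xs.append(sub.values)
        ys.append(sub_labels)
    x = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0)
    stats = features.fit_normalization(x)
    return (x - stats.mean) / stats.std, y, stats


def _classify_fold(
    config: PipelineConfig,
    train_arts: list[CaseArtifacts],
    test_art: CaseArtifacts,
    fold_index: int,
) -> FoldResult:
    x_train, y_train, stats = _pooled_training(config, train_arts, fold_index)
    svm_cfg = replace(config.svm, rng_seed=config.fold_seed(fold_index))
    model = train_svm(
        FeatureMatrix(
            x_train.astype(np.float32), test_art.raw_features.names,
            np.zeros((x_train.shape[0], 3), dtype=int), stats,
        ),
        y_train,
        svm_cfg,
    )
    test_matrix = features.apply_normalization(test_art.raw_features, stats)
    prob = predict_probabilities(model, test_matrix, test_art.soft_tissue)
    wm_mask, gm_mask = harden(prob, config.threshold)
    valid = test_art.labeled
    return FoldResult(
        test_case=test_art.name,
        prob=prob,
        wm_mask=wm_mask,
        gm_mask=gm_mask,
        roc_scores=prob.prob_gm[valid],
        roc_labels=test_art.labels[valid],
        model=model,
    )


def drop_temporal(art: CaseArtifacts) -> CaseArtifacts:
    """Derive the no-temporal artifact view from fully processed artifacts.

    The image stages are identical across feature variants, so the 16-column
    variant is just a column selection of the 120-column matrix.
    """
    keep = [i for i, n in enumerate(art.raw_features.names)
            if not n.startswith("temporal/")]
    raw = FeatureMatrix(
        art.raw_features.values[:, keep],
        [art.raw_features.names[i] for i in keep],
        art.raw_features.coords,
        None,
    )
    groups = [g for g in art.groups if not g[0].startswith("temporal/")]
    return CaseArtifacts(
        art.name, art.wta, art.intracranial, art.csf, art.vessels,
        art.soft_tissue, groups, raw, art.labels,
    )


def run_loocv(
    config: PipelineConfig,
    cases: list[Case],
    artifacts: list[CaseArtifacts] | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation over cases.

    Voxel sampling, normalization statistics and the SVM fit see the
    training folds only; the held-out case is evaluated slice-wise against
    its truth, and the fold soft classifications are pooled into one ROC.
    ``artifacts`` allows reusing already processed cases (they must match
    ``config.variant``).
    """
    if len(cases) < 2:
        raise ValueError("LOOCV requires at least 2 cases")
    arts = artifacts if artifacts is not None else [process_case(config, c) for c in cases]
    if len(arts) != len(cases):
        raise ValueError("one artifact set per case required")
    report = evaluation.EvalReport()
    folds: list[FoldResult] = []
    for i, test_art in enumerate(arts):
        if len(np.unique(test_art.labels[test_art.labeled])) < 2:
            log.warning("fold %s skipped: single-class truth", test_art.name)
            continue
        train_arts = [a for j, a in enumerate(arts) if j != i]
        fold = _classify_fold(config, train_arts, test_art, fold_index=i)
        folds.append(fold)
        case = cases[i]
        assert case.truth is not None
        for structure, seg in (("WM", fold.wm_mask), ("GM", fold.gm_mask)):
            ref = case.truth.masks[structure.lower()]
            report.add(test_art.name, structure, evaluation.slicewise_evaluate(seg, ref))
    roc = evaluation.merged_roc(
        [f.roc_scores for f in folds], [f.roc_labels for f in folds]
    )
    return LoocvResult(report, roc, folds, config.variant)


def compare_variants(
    config: PipelineConfig,
    cases: list[Case],
    n_boot: int = 2000,
) -> tuple[LoocvResult, LoocvResult, evaluation.BootstrapComparison]:
    """Run LOOCV with and without temporal features and bootstrap-compare A_z."""
    full_config = replace(config, variant="full")
    arts = [process_case(full_config, c) for c in cases]
    full = run_loocv(full_config, cases, artifacts=arts)
    no_temp = run_loocv(
        replace(config, variant="no_temporal"), cases,
        artifacts=[drop_temporal(a) for a in arts],
    )
    comparison = evaluation.bootstrap_compare(
        np.concatenate([f.roc_scores for f in full.folds]),
        np.concatenate([f.roc_labels for f in full.folds]),
        np.concatenate([f.roc_scores for f in no_temp.folds]),
        np.concatenate([f.roc_labels for f in no_temp.folds]),
        n_boot=max(n_boot, 1000),
        seed=config.seed,
    )
    return full, no_temp, comparison
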