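"""Quantitative evaluation of segmentations against ground truth.

Overlap and boundary metrics per structure (WM, GM):

* Dice coefficient DC = 2|A∩B| / (|A|+|B|);
* Hausdorff distance HD (max of directed maxima), modified HD (max of
  directed means, after Dubuisson & Jain), 95th-percentile HD, and the
  contour mean distance CMD (symmetric mean of the directed mean boundary
  distances), all between boundary-voxel point sets in mm;
* absolute volume difference AVD = 100·||A|−|B|| / |B| (%).

For slice-based reference standards the metrics are computed per axial
slice in 2D and aggregated over slices by their mean (DC, CMD, AVD) or
maximum (HD, MHD, 95% HD); cross-validation folds are then reported as
mean ± std over folds.  ROC analysis pools the soft classifications of all
folds into one curve, with bootstrap confidence intervals and a paired
bootstrap test for the difference between two feature sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.metrics import roc_curve

from .core import LabelMask

__all__ = [
    "SurfaceDistances",
    "StructureMetrics",
    "EvalReport",
    "RocSummary",
    "BootstrapComparison",
    "dice",
    "surface_distances",
    "avd",
    "slicewise_evaluate",
    "merged_roc",
    "bootstrap_compare",
]

log = logging.getLogger(__name__)

METRIC_NAMES = ("DC", "AVD", "HD", "MHD", "HD95", "CMD")


def dice(a: LabelMask | np.ndarray, b: LabelMask | np.ndarray) -> float:
    """Dice overlap; 1.0 when both masks are empty."""
    a = a.data if isinstance(a, LabelMask) else np.asarray(a, dtype=bool)
    b = b.data if isinstance(b, LabelMask) else np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must be aligned")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a face-adjacent background neighbour (4/6-adjacency)."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


@dataclass(frozen=True)
class SurfaceDistances:
    hd: float
    mhd: float
    hd95: float
    cmd: float


def surface_distances(
    a: LabelMask | np.ndarray,
    b: LabelMask | np.ndarray,
    spacing=None,
) -> SurfaceDistances:
    """Boundary distance metrics between two masks (any dimensionality ≥ 2)."""
    if isinstance(a, LabelMask):
        spacing = a.spacing if spacing is None else spacing
        a = a.data
    if isinstance(b, LabelMask):
        b = b.data
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must be aligned")
    if not a.any():
        raise ValueError("first mask is empty")
    if not b.any():
        raise ValueError("second mask is empty")
    spacing = np.ones(a.ndim) if spacing is None else np.asarray(spacing, dtype=float)

    pa = np.argwhere(_boundary(a)) * spacing
    pb = np.argwhere(_boundary(b)) * spacing
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return SurfaceDistances(
        hd=float(max(d_ab.max(), d_ba.max())),
        mhd=float(max(d_ab.mean(), d_ba.mean())),
        hd95=float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))),
        cmd=float(0.5 * (d_ab.mean() + d_ba.mean())),
    )


def avd(a: LabelMask | np.ndarray, b: LabelMask | np.ndarray) -> float:
    """Absolute volume difference in percent of the reference volume ``b``."""
    a = a.data if isinstance(a, LabelMask) else np.asarray(a, dtype=bool)
    b = b.data if isinstance(b, LabelMask) else np.asarray(b, dtype=bool)
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("reference mask is empty")
    return 100.0 * abs(int(a.sum()) - nb) / nb


@dataclass(frozen=True)
class StructureMetrics:
    """Slice-aggregated metrics for one structure in one case."""

    DC: float
    AVD: float
    HD: float
    MHD: float
    HD95: float
    CMD: float
    n_slices: int

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def slicewise_evaluate(
    seg: LabelMask,
    ref: LabelMask,
    slice_indices=None,
) -> StructureMetrics:
    """Per-axial-slice 2D metrics, aggregated by mean (DC/CMD/AVD), max (HD family).

    Slices where either mask is empty are skipped (and logged), mirroring a
    reference standard that annotates selected slices only.
    """
    if not seg.same_grid(ref):
        raise ValueError("segmentation and reference must share one grid")
    if slice_indices is None:
        slice_indices = range(seg.shape[2])
    spacing2d = seg.spacing[:2]
    dcs, avds, cmds, hds, mhds, hd95s = [], [], [], [], [], []
    used = 0
    for z in slice_indices:
        s2 = seg.data[:, :, z]
        r2 = ref.data[:, :, z]
        if not s2.any() or not r2.any():
            log.debug("slice %d skipped: empty segmentation or reference", z)
            continue
        used += 1
        dcs.append(dice(s2, r2))
        avds.append(avd(s2, r2))
        sd = surface_distances(s2, r2, spacing=spacing2d)
        hds.append(sd.hd)
        mhds.append(sd.mhd)
        hd95s.append(sd.hd95)
        cmds.append(sd.cmd)
    if used == 0:
        raise ValueError("no slice had both masks nonempty")
    return StructureMetrics(
        DC=float(np.mean(dcs)),
        AVD=float(np.mean(avds)),
        HD=float(np.max(hds)),
        MHD=float(np.max(mhds)),
        HD95=float(np.max(hd95s)),
        CMD=float(np.mean(cmds)),
        n_slices=used,
    )


@dataclass
class EvalReport:
    """Per-fold, per-structure metrics with cross-fold aggregation."""

    rows: list[dict] = field(default_factory=list)

    @property
    def per_fold(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["fold", "structure", *METRIC_NAMES, "n_slices"]
        )

    def add(self, fold, structure: str, metrics: StructureMetrics) -> None:
        self.rows.append({"fold": fold, "structure": structure,
                          **metrics.as_dict(), "n_slices": metrics.n_slices})

    def summary(self) -> pd.DataFrame:
        """Mean ± std over folds, per structure and metric."""
        g = self.per_fold.groupby("structure")[list(METRIC_NAMES)]
        mean = g.mean()
        std = g.std(ddof=1).fillna(0.0)
        out = pd.DataFrame(index=mean.index)
        for m in METRIC_NAMES:
            out[f"{m}_mean"] = mean[m]
            out[f"{m}_std"] = std[m]
        return out

    def to_table(self) -> pd.DataFrame:
        """Human-readable structure × metric table of 'mean ± std' strings."""
        s = self.summary()
        return pd.DataFrame(
            {
                m: [f"{s.loc[i, f'{m}_mean']:.2f} ± {s.loc[i, f'{m}_std']:.2f}"
                    for i in s.index]
                for m in METRIC_NAMES
            },
            index=s.index,
        )


@dataclass
class RocSummary:
    fpr: np.ndarray
    tpr: np.ndarray
    az: float
    ci95: tuple[float, float] | None = None
    n_boot: int = 0


def _auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """A_z by the rank (Mann–Whitney) statistic, tie-aware."""
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for a ROC curve")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(labels.size)
    sorted_scores = scores[order]
    # average ranks over ties
    ranks_sorted = np.arange(1, labels.size + 1, dtype=float)
    _, inv, counts = np.unique(sorted_scores, return_inverse=True, return_counts=True)
    sums = np.bincount(inv, weights=ranks_sorted)
    ranks_sorted = (sums / counts)[inv]
    ranks[order] = ranks_sorted
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def merged_roc(
    prob_maps: list[np.ndarray],
    truths: list[np.ndarray],
) -> RocSummary:
    """Single ROC over the pooled voxels of all folds; A_z by trapezoidal rule."""
    if len(prob_maps) != len(truths):
        raise ValueError("one truth vector per fold required")
    scores = np.concatenate([np.asarray(p).ravel() for p in prob_maps])
    labels = np.concatenate([np.asarray(t).ravel() for t in truths]).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("pooled voxels contain a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    az = float(np.trapezoid(tpr, fpr))
    return RocSummary(fpr, tpr, az)


@dataclass
class BootstrapComparison:
    az_a: float
    az_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    p_value: float
    n_boot: int


def bootstrap_compare(
    scores_a: np.ndarray,
    labels_a: np.ndarray,
    scores_b: np.ndarray,
    labels_b: np.ndarray,
    n_boot: int = 50_000,
    seed: int = 0,
) -> BootstrapComparison:
    """Bootstrap A_z confidence intervals and a two-sided test for ΔA_z.

    Voxel-level resampling with replacement.  When the two approaches score
    the same voxels (equal lengths) the resampling is paired, which is the
    relevant design for comparing feature sets on one cohort.  The p-value
    is the (two-sided, +1-corrected) tail mass of the bootstrap ΔA_z
    distribution around zero.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels_a = np.asarray(labels_a, dtype=int)
    labels_b = np.asarray(labels_b, dtype=int)
    rng = np.random.default_rng(seed)
    paired = scores_a.size == scores_b.size and np.array_equal(labels_a, labels_b)

    az_a = _auc(labels_a, scores_a)
    az_b = _auc(labels_b, scores_b)
    boot_a = np.empty(n_boot)
    boot_b = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, scores_a.size, scores_a.size)
        ib = ia if paired else rng.integers(0, scores_b.size, scores_b.size)
        la, lb = labels_a[ia], labels_b[ib]
        if len(np.unique(la)) < 2 or len(np.unique(lb)) < 2:
            boot_a[i] = np.nan
            boot_b[i] = np.nan
            continue
        boot_a[i] = _auc(la, scores_a[ia])
        boot_b[i] = _auc(lb, scores_b[ib])
    ok = ~np.isnan(boot_a) & ~np.isnan(boot_b)
    boot_a, boot_b = boot_a[ok], boot_b[ok]
    delta = boot_a - boot_b
    p_low = float(np.mean(delta <= 0))
    p_high = float(np.mean(delta >= 0))
    p = min(1.0, 2.0 * min(p_low, p_high) + 1.0 / (delta.size + 1))
    return BootstrapComparison(
        az_a=az_a,
        az_b=az_b,
        ci_a=(float(np.percentile(boot_a, 2.5)), float(np.percentile(boot_a, 97.5))),
        ci_b=(float(np.percentile(boot_b, 2.5)), float(np.percentile(boot_b, 97.5))),
        p_value=p,
        n_boot=int(delta.size),
    )
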