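"""Per-voxel feature extraction for WM/GM classification.

Every soft-tissue voxel is described by 120 features in three groups:

* 10 intensity features from the temporal-average (WTA) image: the image
  itself and Gaussian scale space at 1/2/4 mm (4), Gaussian gradient
  magnitude at 1/2/3 mm (3), and locally (contrast-limited) histogram
  equalized images at window radii 5/10/15 voxels (3);
* 6 contextual features: slice-wise distances to skull, CSF and vessels,
  each normalized by the maximum distance on the slice (3), and the
  cumulative fraction of intracranial volume along x, y and z (3);
* 104 temporal features from the first 14 time points: each time point raw
  and spatially smoothed at 1/2/4 mm (56), each time point after temporal
  Gaussian smoothing at 1/2/4 s (42), the area under the temporal gradient
  magnitude curve at derivative scales 1/2/4/6/8 s (5), and the time to the
  first peak of the enhancement curve (1).

Only the first 14 time points enter so the feature count is protocol
independent.  Time is in absolute seconds from the first acquisition;
irregularly spaced curves are linearly resampled onto a uniform 1 s grid
before any temporal filtering.  All features are z-scored with training-set
statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.exposure import equalize_adapthist

from .core import LabelMask, Series4D, Volume3D

__all__ = [
    "FeatureConfig",
    "FeatureNormalization",
    "FeatureMatrix",
    "intensity_features",
    "contextual_features",
    "temporal_features",
    "assemble",
    "fit_normalization",
    "apply_normalization",
    "assemble_and_normalize",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    intensity_scales: tuple[float, ...] = (1.0, 2.0, 4.0)       # mm
    gradient_scales: tuple[float, ...] = (1.0, 2.0, 3.0)        # mm
    histeq_alpha: float = 0.3
    histeq_beta: float = 0.5
    histeq_radii: tuple[int, ...] = (5, 10, 15)                 # voxels
    n_timepoints: int = 14
    spatial_temporal_scales: tuple[float, ...] = (1.0, 2.0, 4.0)  # mm
    temporal_scales_s: tuple[float, ...] = (1.0, 2.0, 4.0)
    gradient_temporal_scales_s: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0)
    histeq_window_hu: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        for scales in (
            self.intensity_scales, self.gradient_scales, self.spatial_temporal_scales,
            self.temporal_scales_s, self.gradient_temporal_scales_s,
        ):
            if any(s <= 0 for s in scales):
                raise ValueError("all scales must be positive")


@dataclass
class FeatureNormalization:
    """Per-feature mean/std (training-set statistics used for z-scoring)."""

    mean: np.ndarray
    std: np.ndarray


@dataclass
class FeatureMatrix:
    """Voxel × feature matrix with names, voxel coordinates and normalization."""

    values: np.ndarray          # (n_voxels, n_features)
    names: list[str]
    coords: np.ndarray          # (n_voxels, 3) voxel indices
    normalization: FeatureNormalization | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.names):
            raise ValueError("one name per feature column required")
        if self.values.shape[0] != self.coords.shape[0]:
            raise ValueError("one coordinate row per voxel required")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for name in self.names:
            group = name.split("/", 1)[0]
            sizes[group] = sizes.get(group, 0) + 1
        return sizes


def _sigma_voxels(scale_mm: float, spacing) -> tuple[float, ...]:
    return tuple(scale_mm / s for s in spacing)


def intensity_features(
    wta: Volume3D, config: FeatureConfig | None = None
) -> list[tuple[str, np.ndarray]]:
    """The 10 intensity features of the WTA image."""
    config = config or FeatureConfig()
    data = np.asarray(wta.data, dtype=np.float32)
    out: list[tuple[str, np.ndarray]] = [("intensity/wta", data)]

    for scale in config.intensity_scales:
        if scale < min(wta.spacing):
            warnings.warn(f"smoothing scale {scale} mm below the voxel size")
        sm = ndimage.gaussian_filter(data, sigma=_sigma_voxels(scale, wta.spacing))
        out.append((f"intensity/gauss_{scale:g}mm", sm))

    for scale in config.gradient_scales:
        grad_sq = np.zeros_like(data)
        for axis, sp in enumerate(wta.spacing):
            order = [0, 0, 0]
            order[axis] = 1
            sigma = list(_sigma_voxels(scale, wta.spacing))
            d = ndimage.gaussian_filter(data, sigma=sigma, order=tuple(order)) / sp
            grad_sq += d * d
        out.append((f"intensity/gradmag_{scale:g}mm", np.sqrt(grad_sq)))

    lo, hi = config.histeq_window_hu
    norm = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    for radius in config.histeq_radii:
        eq = equalize_adapthist(
            norm, kernel_size=2 * radius + 1, clip_limit=config.histeq_alpha
        ).astype(np.float32)
        blended = config.histeq_beta * eq + (1.0 - config.histeq_beta) * norm
        out.append((f"intensity/histeq_r{radius}", blended))
    return out


def _slice_distance_feature(
    target: np.ndarray, intracranial: np.ndarray, spacing, name: str
) -> np.ndarray:
    """Per-axial-slice normalized distance-to-structure map, in [0, 1]."""
    out = np.ones(target.shape, dtype=np.float32)
    sampling = spacing[:2]
    for z in range(target.shape[2]):
        ic = intracranial[:, :, z]
        if not ic.any():
            continue
        tgt = target[:, :, z]
        if not tgt.any():
            log.debug("slice %d has no %s voxels; distance set to 1", z, name)
            continue
        dist = ndimage.distance_transform_edt(~tgt, sampling=sampling)
        max_dist = dist[ic].max()
        if max_dist <= 0:
            out[:, :, z] = 0.0
        else:
            out[:, :, z] = np.minimum(dist / max_dist, 1.0)
    return out


def contextual_features(
    intracranial: LabelMask,
    skull: LabelMask,
    csf: LabelMask,
    vessels: LabelMask,
) -> list[tuple[str, np.ndarray]]:
    """The 6 contextual features (slice distances and cumulative position)."""
    spacing = intracranial.spacing
    out: list[tuple[str, np.ndarray]] = []
    for name, mask in (("skull", skull), ("csf", csf), ("vessels", vessels)):
        out.append(
            (f"context/dist_{name}",
             _slice_distance_feature(mask.data, intracranial.data, spacing, name))
        )

    ic = intracranial.data
    total = float(ic.sum())
    for axis, axis_name in enumerate("xyz"):
        counts = ic.sum(axis=tuple(i for i in range(3) if i != axis))
        cumfrac = (np.cumsum(counts) / max(total, 1.0)).astype(np.float32)
        shape = [1, 1, 1]
        shape[axis] = -1
        out.append(
            (f"context/cumpos_{axis_name}",
             np.broadcast_to(cumfrac.reshape(shape), ic.shape).copy())
        )
    return out


def _resample_uniform(stack: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear resampling of per-voxel curves onto a uniform 1 s grid."""
    t_uniform = np.arange(times[0], times[-1] + 1e-9, 1.0)
    idx = np.searchsorted(times, t_uniform, side="right") - 1
    idx = np.clip(idx, 0, len(times) - 2)
    t0 = times[idx]
    t1 = times[idx + 1]
    w1 = ((t_uniform - t0) / (t1 - t0)).astype(np.float32)
    w0 = 1.0 - w1
    shape = (len(t_uniform),) + stack.shape[1:]
    out = np.empty(shape, dtype=np.float32)
    for k in range(len(t_uniform)):
        out[k] = w0[k] * stack[idx[k]] + w1[k] * stack[idx[k] + 1]
    return out, t_uniform


def _sample_at_times(uniform: np.ndarray, t_uniform: np.ndarray, times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(t_uniform, times, side="right") - 1
    idx = np.clip(idx, 0, len(t_uniform) - 2)
    w1 = ((times - t_uniform[idx]) / (t_uniform[idx + 1] - t_uniform[idx])).astype(np.float32)
    out = np.empty((len(times),) + uniform.shape[1:], dtype=np.float32)
    for k in range(len(times)):
        out[k] = (1.0 - w1[k]) * uniform[idx[k]] + w1[k] * uniform[idx[k] + 1]
    return out


def time_to_first_peak(uniform: np.ndarray, t_uniform: np.ndarray) -> np.ndarray:
    """First local maximum (after 1 s temporal smoothing) of each voxel curve, in s.

    Curves without an interior local maximum fall back to the global
    maximum.  The 1 s pre-smoothing suppresses spurious noise peaks.
    """
    smooth = ndimage.gaussian_filter1d(uniform, sigma=1.0, axis=0)
    n = smooth.shape[0]
    if n < 3:
        return np.full(uniform.shape[1:], t_uniform[0], dtype=np.float32)
    is_peak = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] > smooth[2:])
    any_peak = is_peak.any(axis=0)
    first = is_peak.argmax(axis=0) + 1
    fallback = smooth.argmax(axis=0)
    idx = np.where(any_peak, first, fallback)
    return t_uniform[idx].astype(np.float32)


def temporal_features(
    series: Series4D, config: FeatureConfig | None = None
) -> list[tuple[str, np.ndarray]]:
    """The 104 temporal features from the first ``n_timepoints`` time points."""
    config = config or FeatureConfig()
    n_t = config.n_timepoints
    if len(series) < n_t:
        raise ValueError(
            f"series has {len(series)} time points; at least {n_t} are required "
            "so the feature count is identical for every subject"
        )
    times = series.times_s[:n_t]
    vols = series.volumes[:n_t]
    spacing = series.spacing
    stack = np.stack([np.asarray(v.data, dtype=np.float32) for v in vols], axis=0)

    out: list[tuple[str, np.ndarray]] = []
    # 14 x (raw + 3 spatial scales) = 56
    for i in range(n_t):
        out.append((f"temporal/t{i:02d}_raw", stack[i]))
    for scale in config.spatial_temporal_scales:
        sigma = _sigma_voxels(scale, spacing)
        for i in range(n_t):
            out.append(
                (f"temporal/t{i:02d}_spatial_{scale:g}mm",
                 ndimage.gaussian_filter(stack[i], sigma=sigma))
            )

    uniform, t_uniform = _resample_uniform(stack, times)

    # 14 x 3 temporal scales = 42
    for scale_s in config.temporal_scales_s:
        smooth = ndimage.gaussian_filter1d(uniform, sigma=scale_s, axis=0)
        sampled = _sample_at_times(smooth, t_uniform, times)
        for i in range(n_t):
            out.append((f"temporal/t{i:02d}_temporal_{scale_s:g}s", sampled[i]))

    # 5 gradient-AUC features
    for scale_s in config.gradient_temporal_scales_s:
        deriv = ndimage.gaussian_filter1d(uniform, sigma=scale_s, order=1, axis=0)
        auc = np.trapezoid(np.abs(deriv), dx=1.0, axis=0).astype(np.float32)
        out.append((f"temporal/gradauc_{scale_s:g}s", auc))

    # time of the first peak
    out.append(("temporal/time_to_first_peak", time_to_first_peak(uniform, t_uniform)))
    return out


def assemble(groups: list[tuple[str, np.ndarray]], mask: LabelMask) -> FeatureMatrix:
    """Sample feature images at mask voxels into a raw (unnormalized) matrix."""
    coords = np.argwhere(mask.data)
    names = [name for name, _ in groups]
    values = np.empty((coords.shape[0], len(groups)), dtype=np.float32)
    flat = mask.data
    for j, (_, image) in enumerate(groups):
        if image.shape != mask.shape:
            raise ValueError(f"feature image {names[j]} not aligned with the mask")
        values[:, j] = np.asarray(image, dtype=np.float32)[flat]
    return FeatureMatrix(values, names, coords, None)


def fit_normalization(values: np.ndarray) -> FeatureNormalization:
    """Per-column mean/std; zero-variance columns get std clamped to 1."""
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    zero_var = std < 1e-12
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature column(s); std clamped to 1"
        )
        std = np.where(zero_var, 1.0, std)
    return FeatureNormalization(mean.astype(np.float64), std.astype(np.float64))


def apply_normalization(matrix: FeatureMatrix, stats: FeatureNormalization) -> FeatureMatrix:
    values = (matrix.values - stats.mean.astype(np.float32)) / stats.std.astype(np.float32)
    return FeatureMatrix(values, matrix.names, matrix.coords, stats)


def assemble_and_normalize(
    groups: list[tuple[str, np.ndarray]],
    mask: LabelMask,
    stats: FeatureNormalization | None = None,
) -> FeatureMatrix:
    """Sample feature images at mask voxels and z-score the columns.

    In training mode (``stats=None``) the per-column mean/std are computed
    from this matrix and stored; in test mode the provided training
    statistics are applied unchanged, so no test-set information leaks into
    the normalization.
    """
    raw = assemble(groups, mask)
    if stats is None:
        stats = fit_normalization(raw.values)
    return apply_normalization(raw, stats)
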