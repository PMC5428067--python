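"""Coarse CSF and vessel segmentation inside the intracranial mask.

Within the intracranial space, CSF is the dark tail and contrast-filled
vessels the bright tail of the soft-tissue intensity histogram.  Both are
segmented from the temporal-average image with thresholds placed at
μ ± 1.96σ of the histogram restricted to [0, 400] HU, followed by a
radius-1 erosion (suppressing isolated noise voxels) and connected region
growing back to the full thresholded extent; the CSF mask additionally
gets a radius-1 morphological closing.  A slight over-segmentation is
acceptable — the goal is that only WM and GM remain for classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .core import LabelMask, Volume3D

__all__ = [
    "HistogramStats",
    "histogram_stats",
    "segment_csf",
    "segment_vessels",
    "soft_tissue_mask",
]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)
HU_WINDOW = (0.0, 400.0)


@dataclass(frozen=True)
class HistogramStats:
    """Mean and std of intracranial intensities within the [0, 400] HU window."""

    mu: float
    sigma: float

    @property
    def csf_threshold(self) -> float:
        return self.mu - 1.96 * self.sigma

    @property
    def vessel_threshold(self) -> float:
        return self.mu + 1.96 * self.sigma


def histogram_stats(wta: Volume3D, intracranial: LabelMask) -> HistogramStats:
    """Sample mean/std over intracranial voxels with 0 ≤ HU ≤ 400."""
    if not intracranial.data.any():
        raise ValueError("intracranial mask is empty")
    values = wta.data[intracranial.data]
    values = values[(values >= HU_WINDOW[0]) & (values <= HU_WINDOW[1])]
    if values.size == 0:
        raise ValueError("no intracranial voxels inside the [0, 400] HU window")
    return HistogramStats(float(values.mean()), float(values.std()))


def _erode_and_regrow(candidate: np.ndarray) -> np.ndarray:
    """Radius-1 erosion, then re-admit candidate voxels 26-connected to a seed."""
    seeds = ndimage.binary_erosion(candidate, structure=ball(1))
    if not seeds.any():
        return np.zeros_like(candidate)
    labels, _ = ndimage.label(candidate, structure=_CONN26)
    keep = np.unique(labels[seeds])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def segment_csf(
    wta: Volume3D, intracranial: LabelMask, stats: HistogramStats
) -> LabelMask:
    """CSF: voxels below μ − 1.96σ, eroded, re-grown, then closed (radius 1)."""
    candidate = (wta.data < stats.csf_threshold) & intracranial.data
    grown = _erode_and_regrow(candidate)
    closed = ndimage.binary_closing(grown, structure=ball(1)) & intracranial.data
    result = closed | grown  # closing must not remove voxels, only fill gaps
    if not result.any():
        log.info("CSF segmentation empty (threshold %.1f HU)", stats.csf_threshold)
    return LabelMask(result, intracranial.spacing, intracranial.origin)


def segment_vessels(
    wta: Volume3D, intracranial: LabelMask, stats: HistogramStats
) -> LabelMask:
    """Vessels: voxels above μ + 1.96σ, eroded, re-grown (no closing)."""
    candidate = (wta.data > stats.vessel_threshold) & intracranial.data
    grown = _erode_and_regrow(candidate)
    if not grown.any():
        log.info("vessel segmentation empty (threshold %.1f HU)", stats.vessel_threshold)
    return LabelMask(grown, intracranial.spacing, intracranial.origin)


def soft_tissue_mask(
    intracranial: LabelMask, csf: LabelMask, vessels: LabelMask
) -> LabelMask:
    """Voxels submitted to WM/GM classification: intracranial ∖ (CSF ∪ vessels)."""
    data = intracranial.data & ~csf.data & ~vessels.data
    if not data.any():
        raise ValueError("soft-tissue mask is empty; nothing left to classify")
    return LabelMask(data, intracranial.spacing, intracranial.origin)
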