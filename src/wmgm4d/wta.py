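"""Exposure-weighted temporal averaging (WTA) of a 4D CT series.

A 4D CT protocol acquires N volumes at different tube exposures E_i.  With
weights ω_i (Σω_i = 1) the temporal average has noise variance

    σ²_WTA = Σ ω_i² σ_i² ,

minimised by weighting each volume with its reciprocal variance,

    ω_i = (1/σ_i²) / Σ_j (1/σ_j²),       giving   σ²_WTA = 1 / Σ_i (1/σ_i²).

Quantum noise dominates clinical CT and scales as σ ∝ 1/√E, so the optimal
weights reduce to exposure weighting ω_i = E_i / ΣE_i, and σ_WTA depends on
the total exposure only — not on how it is distributed over acquisitions.
The pipeline weights by exposure; the σ-based path exists to make the
optimality argument directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Series4D, Volume3D

__all__ = [
    "ExposureWeights",
    "NoiseModel",
    "optimal_weights_from_sigmas",
    "weights_from_exposures",
    "wta_sigma",
    "optimal_wta_sigma",
    "weighted_temporal_average",
]


@dataclass(frozen=True)
class ExposureWeights:
    """Normalised per-acquisition averaging weights (ω_i ≥ 0, Σω_i = 1)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D vector")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class NoiseModel:
    """Per-acquisition noise levels and the resulting averaged noise (HU)."""

    sigmas: np.ndarray
    wta_sigma: float

    def __post_init__(self) -> None:
        s = np.asarray(self.sigmas, dtype=float)
        object.__setattr__(self, "sigmas", s)
        if np.any(s <= 0):
            raise ValueError("sigmas must be positive")
        if self.wta_sigma > s.min() + 1e-12:
            raise ValueError("averaged noise cannot exceed the best single acquisition")


def optimal_weights_from_sigmas(sigmas) -> ExposureWeights:
    """Reciprocal-variance weights, the minimiser of Σ ω_i² σ_i² on the simplex."""
    s = np.asarray(sigmas, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("sigmas must be a non-empty 1-D vector")
    if np.any(s <= 0):
        raise ValueError("sigmas must be positive")
    inv_var = 1.0 / s**2
    return ExposureWeights(inv_var / inv_var.sum())


def weights_from_exposures(exposures) -> ExposureWeights:
    """Exposure-proportional weights ω_i = E_i / ΣE_i (optimal under σ ∝ 1/√E)."""
    e = np.asarray(exposures, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise ValueError("exposures must be a non-empty 1-D vector")
    if np.any(e <= 0):
        raise ValueError("exposures must be positive")
    return ExposureWeights(e / e.sum())


def wta_sigma(weights: ExposureWeights, sigmas) -> float:
    """Noise std of the weighted average: sqrt(Σ ω_i² σ_i²)."""
    s = np.asarray(sigmas, dtype=float)
    w = weights.weights
    if len(w) != len(s):
        raise ValueError("weights and sigmas must have equal length")
    return float(np.sqrt(np.sum(w**2 * s**2)))


def optimal_wta_sigma(sigmas) -> float:
    """Closed-form minimum noise std, sqrt(1 / Σ 1/σ_i²)."""
    s = np.asarray(sigmas, dtype=float)
    if np.any(s <= 0):
        raise ValueError("sigmas must be positive")
    return float(np.sqrt(1.0 / np.sum(1.0 / s**2)))


def noise_model(sigmas) -> NoiseModel:
    return NoiseModel(np.asarray(sigmas, dtype=float), optimal_wta_sigma(sigmas))


def weighted_temporal_average(series: Series4D) -> Volume3D:
    """Voxelwise Σ ω_i I_i with exposure-proportional weights.

    Assumes the series is already registered (all volumes on one grid,
    which :class:`~wmgm4d.core.Series4D` enforces).
    """
    w = weights_from_exposures(series.exposures_mAs).weights
    out = np.zeros(series.shape, dtype=np.float64)
    for wi, vol in zip(w, series.volumes):
        out += wi * vol.data
    ref = series.volumes[0]
    return Volume3D(out.astype(np.float32), ref.spacing, ref.origin)
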