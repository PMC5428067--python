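"""Synthetic 4D CT head phantom with known tissue labels.

The phantom provides what patient data cannot in a self-contained setting:
a contrast-enhanced 4D CT series together with exact per-voxel tissue
truth.  The geometry is deliberately simple — nested ellipsoids — but it
reproduces the properties the pipeline depends on:

* a bright skull shell (>600 HU) enclosing the intracranial space,
* a subarachnoid CSF layer and ventricles (dark),
* a cortical gray-matter ribbon and deep gray nuclei around a white-matter
  core, with a small (~10 HU) WM/GM density difference,
* tubular vessels with strong contrast enhancement,
* tissue-specific gamma-variate enhancement curves sampled at the
  acquisition times of the protocol (GM is more perfused than WM),
* per-volume zero-mean Gaussian quantum noise with standard deviation
  ``k / sqrt(E_i)`` for exposure ``E_i`` in mAs.

Baseline HU values are not dictated by any single source; the defaults sit
in standard radiological ranges (air −1000, skull ~1000, CSF ~4, WM ~35,
GM ~45, blood ~50 HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import LabelMask, Series4D, Volume3D
from .registration import RigidTransform, transform_volume

__all__ = [
    "TISSUES",
    "LABEL_CODES",
    "AcquisitionProtocol",
    "EnhancementCurve",
    "PhantomSpec",
    "PhantomTruth",
    "stroke_protocol",
    "build_phantom",
    "apply_rigid_motion",
    "temporal_contrast_only_spec",
]

TISSUES = ("air", "skull", "csf", "wm", "gm", "vessel")
LABEL_CODES = {name: i for i, name in enumerate(TISSUES)}


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered acquisition times (s, first at 0) and per-volume exposures (mAs)."""

    times_s: tuple[float, ...]
    exposures_mAs: tuple[float, ...]
    kV: float = 80.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        exposures = np.asarray(self.exposures_mAs, dtype=float)
        if times.size == 0 or times[0] != 0.0:
            raise ValueError("first acquisition time must be 0 s")
        if np.any(np.diff(times) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        if len(exposures) != len(times):
            raise ValueError("one exposure per acquisition required")
        if np.any(exposures <= 0):
            raise ValueError("exposures must be positive")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def total_exposure_mAs(self) -> float:
        return float(np.sum(self.exposures_mAs))


def stroke_protocol(late_phase: bool = True) -> AcquisitionProtocol:
    """The 4D CT stroke protocol.

    One high-dose volume at 200 mAs at t = 0; after 4 s, 13 volumes every
    2 s at 100 mAs; then 5 (or, with the late contrast phase, 10) volumes
    every 5 s at 75 mAs — 19 or 24 acquisitions in total.
    """
    times = [0.0]
    exposures = [200.0]
    t = 4.0
    for _ in range(13):
        times.append(t)
        exposures.append(100.0)
        t += 2.0
    t = times[-1] + 5.0
    for _ in range(10 if late_phase else 5):
        times.append(t)
        exposures.append(75.0)
        t += 5.0
    return AcquisitionProtocol(tuple(times), tuple(exposures))


@dataclass(frozen=True)
class EnhancementCurve:
    """Gamma-variate contrast enhancement: peak ``amplitude_hu`` at ``ttp_s``.

    ``width_s`` controls the curve's spread; the shape exponent is
    ``(ttp/width)**2`` so that narrower widths give sharper washin/washout.
    """

    amplitude_hu: float = 0.0
    ttp_s: float = 10.0
    width_s: float = 5.0

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.amplitude_hu == 0.0:
            return np.zeros_like(t)
        k = (self.ttp_s / self.width_s) ** 2
        u = np.clip(t / self.ttp_s, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(u > 0, np.exp(k * (np.log(np.where(u > 0, u, 1.0)) + 1.0 - u)), 0.0)
        return self.amplitude_hu * y


def _default_enhancement() -> dict[str, EnhancementCurve]:
    return {
        "air": EnhancementCurve(0.0),
        "skull": EnhancementCurve(0.0),
        "csf": EnhancementCurve(0.0),
        "wm": EnhancementCurve(6.0, ttp_s=16.0, width_s=10.0),
        "gm": EnhancementCurve(12.0, ttp_s=14.0, width_s=8.0),
        "vessel": EnhancementCurve(150.0, ttp_s=12.0, width_s=6.0),
    }


def _default_hu() -> dict[str, float]:
    return {"air": -1000.0, "skull": 1000.0, "csf": 4.0, "wm": 35.0, "gm": 45.0, "vessel": 50.0}


@dataclass
class PhantomSpec:
    """Full description of a phantom instance; validated on construction."""

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_hu: dict[str, float] = field(default_factory=_default_hu)
    enhancement: dict[str, EnhancementCurve] = field(default_factory=_default_enhancement)
    protocol: AcquisitionProtocol = field(default_factory=lambda: stroke_protocol(False))
    noise_constant: float = 50.0  # k in sigma = k / sqrt(E), HU * sqrt(mAs)
    rng_seed: int = 0
    skull_thickness_mm: float = 4.0
    csf_thickness_mm: float = 1.5
    gm_thickness_mm: float = 4.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive on all axes")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        missing = set(TISSUES) - set(self.tissue_hu)
        if missing:
            raise ValueError(f"tissue_hu missing classes: {sorted(missing)}")
        if self.tissue_hu["skull"] <= 600:
            raise ValueError("skull baseline must exceed 600 HU")
        vessel_peak = self.tissue_hu["vessel"] + self.enhancement["vessel"].amplitude_hu
        if not (
            self.tissue_hu["csf"] < self.tissue_hu["wm"] < self.tissue_hu["gm"] < vessel_peak
        ):
            raise ValueError("require CSF < WM < GM baseline < vessel peak HU")
        if not self.enhancement["gm"].amplitude_hu > self.enhancement["wm"].amplitude_hu:
            raise ValueError("GM enhancement amplitude must exceed WM (GM is more perfused)")
        if self.noise_constant < 0:
            raise ValueError("noise_constant must be non-negative")
        if self.skull_thickness_mm < min(self.spacing_mm):
            raise ValueError("skull shell thinner than one voxel")


@dataclass
class PhantomTruth:
    """Ground truth: integer label map, per-tissue masks, noise-free series."""

    labels: np.ndarray
    masks: dict[str, LabelMask]
    clean_series: Series4D

    @property
    def intracranial(self) -> LabelMask:
        m = self.masks["csf"]
        data = m.data | self.masks["wm"].data | self.masks["gm"].data | self.masks["vessel"].data
        return LabelMask(data, m.spacing, m.origin)

    def save_labels(self, path) -> None:
        Volume3D(self.labels.astype(np.int16), self.masks["wm"].spacing).save(path)


def _ellipsoid(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, sp, c, a in zip(grids, spacing, center_mm, semi_mm):
        acc = acc + ((g * sp - c) / a) ** 2
    return acc <= 1.0


def _ygrid(shape, spacing) -> np.ndarray:
    return np.ogrid[tuple(slice(0, n) for n in shape)][1] * spacing[1]


def _cylinder(shape, spacing, axis, center_mm, radius_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    other = [i for i in range(3) if i != axis]
    acc = np.zeros(shape, dtype=float)
    for i in other:
        acc = acc + (grids[i] * spacing[i] - center_mm[i]) ** 2
    return acc <= radius_mm**2


def _build_labels(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    sp = spec.spacing_mm
    extent = np.array(shape) * np.array(sp)
    center = extent / 2.0

    outer = np.array([0.42 * extent[0], 0.46 * extent[1], 0.44 * extent[2]])
    inner_skull = outer - spec.skull_thickness_mm
    brain = inner_skull - spec.csf_thickness_mm
    wm_core = brain - spec.gm_thickness_mm
    if np.any(wm_core <= 2.0):
        raise ValueError("degenerate geometry: grid too small for the requested shells")

    labels = np.full(shape, LABEL_CODES["air"], dtype=np.uint8)
    skull_outer = _ellipsoid(shape, sp, center, outer)
    skull_inner = _ellipsoid(shape, sp, center, inner_skull)
    labels[skull_outer & ~skull_inner] = LABEL_CODES["skull"]

    brain_m = _ellipsoid(shape, sp, center, brain)
    labels[skull_inner & ~brain_m] = LABEL_CODES["csf"]  # subarachnoid layer
    wm_m = _ellipsoid(shape, sp, center, wm_core)
    labels[brain_m & ~wm_m] = LABEL_CODES["gm"]  # cortical ribbon
    labels[wm_m] = LABEL_CODES["wm"]

    # lateral ventricles (CSF) inside the WM core, each connected to the
    # subarachnoid layer by a thin channel so the CSF space is one
    # 26-connected component (as in real anatomy)
    vent_semi = np.maximum(0.032 * extent, 2.0)
    vent_semi[1] = max(0.085 * extent[1], 3.0)
    for dx in (-0.08, 0.08):
        c = center + np.array([dx * extent[0], 0.02 * extent[1], 0.0])
        vent = _ellipsoid(shape, sp, c, vent_semi) & wm_m
        labels[vent] = LABEL_CODES["csf"]
        channel = _cylinder(shape, sp, 1, c, 1.2) & brain_m & (c[1] <= _ygrid(shape, sp))
        labels[channel & (labels != LABEL_CODES["skull"])] = LABEL_CODES["csf"]

    # deep gray nuclei (basal-ganglia stand-ins)
    deep_semi = np.maximum(0.055 * extent, 2.5)
    for dx in (-0.16, 0.16):
        c = center + np.array([dx * extent[0], -0.04 * extent[1], 0.0])
        deep = _ellipsoid(shape, sp, c, deep_semi) & wm_m & (labels != LABEL_CODES["csf"])
        labels[deep] = LABEL_CODES["gm"]

    # tubular vessels within the brain
    soft = brain_m & (labels != LABEL_CODES["csf"])
    r = 1.8
    vessels = _cylinder(shape, sp, 1, center + np.array([0.0, 0.0, 0.12 * extent[2]]), r)
    vessels |= _cylinder(shape, sp, 2, center + np.array([0.24 * extent[0], -0.12 * extent[1], 0.0]), r)
    vessels |= _cylinder(shape, sp, 2, center + np.array([-0.24 * extent[0], -0.12 * extent[1], 0.0]), r)
    labels[vessels & soft] = LABEL_CODES["vessel"]
    return labels


def build_phantom(spec: PhantomSpec) -> tuple[Series4D, PhantomTruth]:
    """Build the noisy 4D series and its ground truth from a spec.

    The clean series is baseline HU plus the per-tissue enhancement curve
    sampled at the protocol times; the noisy series adds zero-mean Gaussian
    noise with per-volume std ``k / sqrt(E_i)``.  Bit-identical for equal
    seeds.
    """
    labels = _build_labels(spec)
    sp = spec.spacing_mm
    masks = {
        name: LabelMask(labels == code, sp) for name, code in LABEL_CODES.items()
    }

    base = np.zeros(spec.grid_shape, dtype=np.float32)
    for name, code in LABEL_CODES.items():
        base[labels == code] = spec.tissue_hu[name]

    times = np.asarray(spec.protocol.times_s)
    exposures = np.asarray(spec.protocol.exposures_mAs)
    rng = np.random.default_rng(spec.rng_seed)

    clean_vols: list[Volume3D] = []
    noisy_vols: list[Volume3D] = []
    for i, t in enumerate(times):
        vol = base.copy()
        for name, code in LABEL_CODES.items():
            enh = float(spec.enhancement[name](t))
            if enh != 0.0:
                vol[labels == code] += enh
        clean_vols.append(Volume3D(vol, sp))
        if spec.noise_constant > 0:
            sigma = spec.noise_constant / np.sqrt(exposures[i])
            noisy = vol + rng.normal(0.0, sigma, size=vol.shape).astype(np.float32)
        else:
            noisy = vol.copy()
        noisy_vols.append(Volume3D(noisy, sp))

    clean = Series4D(clean_vols, times, exposures)
    noisy_series = Series4D(noisy_vols, times.copy(), exposures.copy())
    return noisy_series, PhantomTruth(labels, masks, clean)


def apply_rigid_motion(
    series: Series4D,
    transforms: list[RigidTransform],
    interpolation: str = "linear",
) -> Series4D:
    """Move each volume under its rigid transform (first must be identity).

    The volume content is displaced *by* the transform (a +2 mm translation
    moves the head +2 mm), so registering the result back to the first time
    point should recover the applied transforms.  A transform that pushes
    skull out of the grid is rejected.  ``interpolation='nearest'`` keeps
    thresholded masks crisp (useful for recovery fixtures); the default is
    linear, as for real resampled HU data.
    """
    if len(transforms) != len(series):
        raise ValueError("one transform per volume required")
    if not transforms[0].is_identity():
        raise ValueError("first transform must be the identity")
    ref = series.volumes[0]
    out = []
    for vol, t in zip(series.volumes, transforms):
        if t.is_identity():
            out.append(vol.with_data(vol.data.copy()))
            continue
        bone = np.argwhere(vol.data > 600)
        if bone.size:
            pts = bone * np.asarray(vol.spacing) + np.asarray(vol.origin)
            moved_pts = t.apply_to_points(pts)
            extent = (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)
            lo = np.asarray(vol.origin)
            if np.any(moved_pts < lo) or np.any(moved_pts > lo + extent):
                raise ValueError("transform moves skull outside the grid")
        out.append(transform_volume(vol, t.inverse(), reference=ref,
                                    interpolation=interpolation))
    return Series4D(out, series.times_s.copy(), series.exposures_mAs.copy())


def temporal_contrast_only_spec(base: PhantomSpec | None = None) -> PhantomSpec:
    """A spec whose WM and GM differ *only* in contrast dynamics.

    WM and GM get identical baseline HU, and the WM enhancement amplitude is
    rescaled so that the exposure-weighted temporal mean of the two
    enhancement curves is equal.  The temporal-average image then carries no
    WM/GM intensity contrast; only the curve shapes (and context) separate
    the tissues.  GM keeps a sharper, earlier curve with the larger peak.
    """
    spec = base if base is not None else PhantomSpec()
    hu = dict(spec.tissue_hu)
    mid = 0.5 * (spec.tissue_hu["wm"] + spec.tissue_hu["gm"])
    hu["wm"] = mid
    hu["gm"] = mid + 1e-9  # keeps the strict CSF < WM < GM ordering; visually identical

    times = np.asarray(spec.protocol.times_s)
    w = np.asarray(spec.protocol.exposures_mAs, dtype=float)
    w = w / w.sum()

    gm = EnhancementCurve(14.0, ttp_s=12.0, width_s=5.0)
    wm_shape = EnhancementCurve(1.0, ttp_s=18.0, width_s=14.0)
    gm_mean = float(np.sum(w * gm(times)))
    wm_unit_mean = float(np.sum(w * wm_shape(times)))
    wm_amp = gm_mean / wm_unit_mean
    if wm_amp >= gm.amplitude_hu:
        raise RuntimeError("temporal-only construction failed to keep GM amplitude dominant")
    enhancement = dict(spec.enhancement)
    enhancement["gm"] = gm
    enhancement["wm"] = EnhancementCurve(wm_amp, ttp_s=wm_shape.ttp_s, width_s=wm_shape.width_s)
    return replace(spec, tissue_hu=hu, enhancement=enhancement)
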