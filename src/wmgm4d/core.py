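"""Core grid-aware containers for the 4D CT segmentation pipeline.

All volumetric data is carried by three light containers:

``Volume3D``
    one scalar volume in Hounsfield units (HU) on a regular grid,
``LabelMask``
    a boolean mask aligned to a ``Volume3D`` grid,
``Series4D``
    an ordered stack of :class:`Volume3D` sharing one grid, with the
    acquisition time (s) and tube exposure (mAs) of every time point.

Arrays are indexed ``(x, y, z)`` with ``z`` the axial (slice) axis;
``spacing`` is the voxel size in mm along the same axes.  NIfTI I/O goes
through nibabel, and conversion helpers to/from SimpleITK are provided for
the registration backend (SimpleITK stores arrays ``(z, y, x)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

AIR_HU = -1000.0

__all__ = [
    "AIR_HU",
    "Volume3D",
    "LabelMask",
    "Series4D",
    "read_protocol_config",
    "write_protocol_config",
]


@dataclass
class Volume3D:
    """A scalar HU volume on a regular axis-aligned grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume3D | LabelMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data, self.spacing, self.origin)

    # -- SimpleITK interop -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T, dtype=np.float64))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume3D":
        arr = sitk.GetArrayFromImage(img).T
        return cls(np.ascontiguousarray(arr), tuple(img.GetSpacing()), tuple(img.GetOrigin()))

    # -- NIfTI I/O ---------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine()), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume3D":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(data, spacing, origin)


@dataclass
class LabelMask:
    """A boolean voxel mask aligned to a :class:`Volume3D` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMask requires a 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def volume_voxels(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "Volume3D | LabelMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "LabelMask":
        return LabelMask(data, self.spacing, self.origin)

    def save(self, path: str | Path) -> None:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), aff), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "LabelMask":
        vol = Volume3D.load(path)
        return cls(vol.data > 0.5, vol.spacing, vol.origin)


@dataclass
class Series4D:
    """An ordered 4D CT series: 3D volumes plus per-volume time and exposure.

    ``times_s`` are acquisition times in seconds relative to the first
    acquisition (which is at 0 s); ``exposures_mAs`` are the per-volume tube
    exposures in mAs that drive the quantum-noise model and the temporal
    averaging weights.
    """

    volumes: list[Volume3D]
    times_s: np.ndarray
    exposures_mAs: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.exposures_mAs = np.asarray(self.exposures_mAs, dtype=float)
        n = len(self.volumes)
        if n == 0:
            raise ValueError("Series4D requires at least one volume")
        if len(self.times_s) != n or len(self.exposures_mAs) != n:
            raise ValueError("times and exposures must match the number of volumes")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        if np.any(self.exposures_mAs <= 0):
            raise ValueError("exposures must be positive")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not ref.same_grid(v):
                raise ValueError("all volumes in a Series4D must share one grid")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volumes[0].spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def stack(self) -> np.ndarray:
        """Return the series as a single ``(n_t, nx, ny, nz)`` array."""
        return np.stack([v.data for v in self.volumes], axis=0)

    def save(self, directory: str | Path, prefix: str = "vol") -> None:
        """Write per-timepoint NIfTI files plus a flat protocol config."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, v in enumerate(self.volumes):
            v.save(directory / f"{prefix}_{i:03d}.nii.gz")
        write_protocol_config(
            directory / "protocol.cfg", self.times_s, self.exposures_mAs
        )

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "vol") -> "Series4D":
        directory = Path(directory)
        paths = sorted(directory.glob(f"{prefix}_*.nii.gz"))
        if not paths:
            raise FileNotFoundError(f"no {prefix}_*.nii.gz volumes under {directory}")
        times, exposures, _ = read_protocol_config(directory / "protocol.cfg")
        return cls([Volume3D.load(p) for p in paths], times, exposures)


def write_protocol_config(
    path: str | Path,
    times_s: Sequence[float],
    exposures_mAs: Sequence[float],
    kV: float | None = None,
) -> None:
    """Write an acquisition protocol as a flat ``key = value`` text file."""
    lines = [
        "# 4D CT acquisition protocol",
        "times_s = " + " ".join(f"{t:g}" for t in times_s),
        "exposures_mAs = " + " ".join(f"{e:g}" for e in exposures_mAs),
    ]
    if kV is not None:
        lines.append(f"kV = {kV:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_protocol_config(path: str | Path) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Read a flat protocol config; returns (times_s, exposures_mAs, kV)."""
    entries: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    if "times_s" not in entries or "exposures_mAs" not in entries:
        raise ValueError(f"protocol config {path} missing times_s/exposures_mAs")
    times = np.array([float(x) for x in entries["times_s"].split()])
    exposures = np.array([float(x) for x in entries["exposures_mAs"].split()])
    kV = float(entries["kV"]) if "kV" in entries else None
    return times, exposures, kV
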