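"""Spatial data containers for ventilation imaging.

Conventions used throughout the package:

* Arrays are 3D, indexed ``(x, y, z)`` with 0-based voxel indices.
* ``spacing`` is the voxel edge length in mm per axis; ``origin`` is the
  physical position (mm) of the *corner* of voxel ``(0, 0, 0)``, so the
  center of voxel ``i`` lies at ``origin + (i + 0.5) * spacing``.
* Specific ventilation (SV) is unitless (ΔV/V over the breath); values may
  be negative (local compression) but must be finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VentilationVolume",
    "LungMask",
    "PhaseSeries",
    "CTVolume",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_phase_series",
    "save_phase_series",
]


def _check_grid(values: np.ndarray, spacing: Sequence[float]) -> None:
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D grid, got {values.ndim}D")
    if any(d < 1 for d in values.shape):
        raise ValueError("grid dimensions must be >= 1 on every axis")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be three positive edge lengths (mm)")


@dataclass
class VentilationVolume:
    """One 3D specific-ventilation map at a single breath phase."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_grid(self.values, self.spacing)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("specific ventilation values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LungMask:
    """Boolean lung segmentation on the same grid as its paired volumes."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class CTVolume:
    """CT gray values (arbitrary scanner units) on the imaging grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_grid(self.values, self.spacing)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class PhaseSeries:
    """Ordered specific-ventilation volumes across one breath.

    Each volume holds the cumulative expansion relative to phase 0 (peak
    exhalation), so the final phase is the full-breath specific ventilation
    used for the scalar metrics.
    """

    volumes: list[VentilationVolume]
    mask: LungMask = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("a phase series needs at least one volume")
        shape = self.volumes[0].shape
        spacing = self.volumes[0].spacing
        for v in self.volumes:
            if v.shape != shape or v.spacing != spacing:
                raise ValueError("all phase volumes must share shape and spacing")
        idx = [v.phase_index for v in self.volumes]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("phase_index must be strictly increasing")
        if self.mask is not None and self.mask.shape != shape:
            raise ValueError("mask shape must match volume shape")

    @property
    def n_phases(self) -> int:
        return len(self.volumes)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volumes[0].spacing

    @property
    def final(self) -> VentilationVolume:
        """Full-breath volume (peak exhalation → peak inspiration)."""
        return self.volumes[-1]


# ---------------------------------------------------------------------------
# NIfTI-1 I/O (nibabel). The affine is diagonal in the voxel spacing with the
# origin in the translation column; orientation handling beyond that is out
# of scope for phantom data.
# ---------------------------------------------------------------------------


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: VentilationVolume | CTVolume, path: str | Path) -> None:
    origin = getattr(vol, "origin", (0.0, 0.0, 0.0))
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing, origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path, phase_index: int = 0) -> VentilationVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VentilationVolume(
        np.asarray(img.dataobj, dtype=float),
        spacing=spacing,
        origin=origin,
        phase_index=phase_index,
    )


def load_ct(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(np.asarray(img.dataobj, dtype=float), spacing=spacing)


def save_mask(mask: LungMask, spacing: Sequence[float], path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(spacing, (0, 0, 0)))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> LungMask:
    img = nib.load(str(path))
    return LungMask(np.asarray(img.dataobj) > 0)


def save_phase_series(series: PhaseSeries, directory: str | Path) -> Path:
    """Write one NIfTI per phase plus a JSON manifest listing file order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for vol in series.volumes:
        name = f"phase_{vol.phase_index:02d}.nii.gz"
        save_volume(vol, directory / name)
        names.append(name)
    mask_name = None
    if series.mask is not None:
        mask_name = "mask.nii.gz"
        save_mask(series.mask, series.spacing, directory / mask_name)
    manifest = {
        "phases": names,
        "phase_indices": [v.phase_index for v in series.volumes],
        "mask": mask_name,
        "spacing_mm": list(series.spacing),
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_phase_series(manifest_path: str | Path, mask_path: str | Path | None = None) -> PhaseSeries:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    volumes = [
        load_volume(directory / name, phase_index=idx)
        for name, idx in zip(manifest["phases"], manifest["phase_indices"])
    ]
    mask = None
    if mask_path is not None:
        mask = load_mask(mask_path)
    elif manifest.get("mask"):
        mask = load_mask(directory / manifest["mask"])
    return PhaseSeries(volumes, mask=mask)
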