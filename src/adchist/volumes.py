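"""Volume containers and NIfTI-1 I/O.

The canonical ADC unit throughout the package is µm²/ms
(1 µm²/ms = 1.0e-3 mm²/s, the unit clinical ADC maps are usually
distributed in). Readers convert mm²/s maps on load and record the unit
the file declared. NIfTI headers carry no diffusivity unit, so the unit
must be given explicitly or through a JSON sidecar with an ``adc_unit``
key next to the image file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import ValidationError

CANONICAL_ADC_UNIT = "um2/ms"
#: accepted unit spellings -> multiplicative factor into µm²/ms
_UNIT_FACTORS = {
    "um2/ms": 1.0,
    "µm2/ms": 1.0,
    "um^2/ms": 1.0,
    "mm2/s": 1000.0,
    "mm^2/s": 1000.0,
}


def _check_3d(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValidationError(f"expected 3-D volume, got {values.ndim}-D")
    return values


def _check_spacing(voxel_size_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in voxel_size_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"voxel sizes must be three positive lengths, got {voxel_size_mm}")
    return spacing


@dataclass
class AnatomicalVolume:
    """A 3-D anatomical raster (arbitrary signal units) on a regular grid."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _check_3d(self.values)
        self.voxel_size_mm = _check_spacing(self.voxel_size_mm)
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class AdcVolume:
    """A 3-D apparent-diffusion-coefficient map in µm²/ms.

    ``source_unit`` records the unit the data were loaded in before
    conversion to the canonical µm²/ms.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    unit: str = CANONICAL_ADC_UNIT
    source_unit: str = CANONICAL_ADC_UNIT
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _check_3d(self.values)
        self.voxel_size_mm = _check_spacing(self.voxel_size_mm)
        if self.unit not in ("um2/ms", "µm2/ms"):
            raise ValidationError(f"AdcVolume must hold canonical µm²/ms values, got unit {self.unit!r}")
        self.unit = CANONICAL_ADC_UNIT
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


def _load_nifti(path: str | Path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate trailing singleton dimensions, reject genuine 4-D data
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValidationError(f"expected 3-D volume in {path}, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=float), spacing, np.asarray(img.affine)


def read_anatomical(path: str | Path) -> AnatomicalVolume:
    """Read an anatomical (e.g. T1-weighted) NIfTI-1 volume."""
    data, spacing, affine = _load_nifti(path)
    return AnatomicalVolume(values=data, voxel_size_mm=spacing, affine=affine)


def read_adc(path: str | Path, unit: str | None = None) -> AdcVolume:
    """Read an ADC NIfTI-1 volume, converting to µm²/ms.

    ``unit`` names the on-disk unit; if None a JSON sidecar
    ``<path minus .nii[.gz]>.json`` with an ``adc_unit`` entry is consulted.
    A missing or unrecognised unit raises a :class:`ValidationError`
    demanding an explicit flag.
    """
    data, spacing, affine = _load_nifti(path)
    if unit is None:
        unit = _sidecar_unit(Path(path))
    if unit is None:
        raise ValidationError(
            f"no ADC unit declared for {path}; pass unit='um2/ms' or 'mm2/s' "
            "or provide a JSON sidecar with an 'adc_unit' key"
        )
    factor = _UNIT_FACTORS.get(unit)
    if factor is None:
        raise ValidationError(f"unrecognised ADC unit {unit!r}; expected one of {sorted(_UNIT_FACTORS)}")
    return AdcVolume(
        values=data * factor, voxel_size_mm=spacing, source_unit=unit, affine=affine
    )


def _sidecar_unit(path: Path) -> str | None:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    sidecar = path.with_name(name + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        return meta.get("adc_unit")
    return None


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask volume; any nonzero voxel is True."""
    data, _, _ = _load_nifti(path)
    return data != 0


def write_volume(values: np.ndarray, path: str | Path, affine: np.ndarray | None = None,
                 voxel_size_mm=None) -> None:
    """Write a 3-D array as NIfTI-1; affine defaults to diag(voxel sizes)."""
    values = np.asarray(values)
    if affine is None:
        spacing = _check_spacing(voxel_size_mm if voxel_size_mm is not None else (1, 1, 1))
        affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(values.astype(np.float64), affine)
    nib.save(img, str(path))
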