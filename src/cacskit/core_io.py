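"""Volume and mask data model, geometry conventions, and NIfTI/CSV I/O.

Conventions used throughout the package
---------------------------------------
* In-memory arrays are indexed ``(axial slice, row, column)`` — axis 0 is the
  craniocaudal slice index, axes 1-2 are the in-plane rows/columns.
* Spacing is ``(dz, dy, dx)`` in millimetres, matching the array axis order.
* Coordinates are 0-based and voxel-centred: world position =
  ``origin + index * spacing``.
* On disk, volumes are standard NIfTI with the fastest-varying axis in-plane
  (the array is transposed to ``(x, y, z)`` before writing) and HU stored as
  signed 16-bit integers so integer-valued fixtures round-trip bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

#: Legal vessel/confuser labels: 0 background, 1 LM, 2 LAD, 3 LCX, 4 RCA,
#: 5 non-coronary (e.g. aortic sinus) calcification.
BACKGROUND = 0
LM, LAD, LCX, RCA = 1, 2, 3, 4
NON_CORONARY = 5
CORONARY_LABELS = (LM, LAD, LCX, RCA)
LEGAL_LABELS = frozenset({BACKGROUND, LM, LAD, LCX, RCA, NON_CORONARY})
VESSEL_NAMES = {LM: "LM", LAD: "LAD", LCX: "LCX", RCA: "RCA", NON_CORONARY: "NCC"}

HU_MIN, HU_MAX = -1024.0, 4095.0


class FormatError(ValueError):
    """An on-disk image violates the package's format contract."""


class GeometryError(ValueError):
    """Two gridded objects that must share geometry do not."""


@dataclass
class CtVolume:
    """A 3-D CT attenuation volume in Hounsfield units.

    Parameters
    ----------
    voxels
        3-D float array of HU, indexed (slice, row, column).
    spacing
        Voxel spacing ``(dz, dy, dx)`` in mm; all components positive.
    origin
        World position of voxel (0, 0, 0) in mm, ``(z, y, x)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"volume must be 3-D, got {self.voxels.ndim} dimension(s)"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite voxels")
        if self.voxels.min() < HU_MIN or self.voxels.max() > HU_MAX:
            raise FormatError(
                f"HU values outside [{HU_MIN:g}, {HU_MAX:g}]: "
                f"range [{self.voxels.min():g}, {self.voxels.max():g}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[1] * self.spacing[2]

    def index_to_world(self, index: Sequence[float]) -> tuple[float, float, float]:
        return tuple(
            o + i * s for o, i, s in zip(self.origin, index, self.spacing)
        )


@dataclass
class VesselLabelMask:
    """Per-voxel vessel calcification labels sharing a CtVolume's geometry."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"mask must be 3-D, got {self.labels.ndim} dimension(s)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise FormatError("mask voxels must be integer-valued")
            self.labels = as_int
        else:
            self.labels = self.labels.astype(np.int64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        illegal = set(np.unique(self.labels)) - LEGAL_LABELS
        if illegal:
            raise FormatError(
                f"illegal label value(s) {sorted(illegal)}; legal set is "
                f"{sorted(LEGAL_LABELS)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class CaseRecord:
    """One cohort row: file references plus provenance of the mask."""

    case_id: str
    volume_path: str
    mask_path: str
    provenance: str = "phantom"  # manual | automatic | phantom

    def __post_init__(self) -> None:
        if self.provenance not in {"manual", "automatic", "phantom"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")


def check_congruent(vol: CtVolume, mask: VesselLabelMask) -> None:
    """Raise GeometryError unless volume and mask share shape and spacing."""
    if vol.shape != mask.shape:
        raise GeometryError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    if not np.allclose(vol.spacing, mask.spacing):
        raise GeometryError(
            f"spacing mismatch: volume {vol.spacing} vs mask {mask.spacing}"
        )


def _affine(spacing: tuple[float, float, float],
            origin: tuple[float, float, float]) -> np.ndarray:
    # On-disk axis order is (x, y, z); in-memory is (z, y, x).
    dz, dy, dx = spacing
    oz, oy, ox = origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def write_volume(vol: CtVolume, path: str | Path) -> Path:
    """Write a CtVolume as NIfTI with HU stored as int16.

    Fractional HU are rounded to the nearest integer on disk; integer-valued
    volumes round-trip bit-exactly.
    """
    path = Path(path)
    data = np.rint(vol.voxels).astype(np.int16)
    img = nib.Nifti1Image(data.transpose(2, 1, 0), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> CtVolume:
    """Read a NIfTI CT volume; spacing is taken from the header as (dz, dy, dx)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3-D image, got {img.ndim}-D")
    data = np.asanyarray(img.dataobj)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path.name}: non-finite voxels")
    dx, dy, dz = img.header.get_zooms()[:3]
    ox, oy, oz = img.affine[:3, 3]
    return CtVolume(
        voxels=np.asarray(data, dtype=np.float64).transpose(2, 1, 0),
        spacing=(float(dz), float(dy), float(dx)),
        origin=(float(oz), float(oy), float(ox)),
    )


def write_mask(mask: VesselLabelMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        mask.labels.astype(np.uint8).transpose(2, 1, 0),
        _affine(mask.spacing, mask.origin),
    )
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, ref: CtVolume) -> VesselLabelMask:
    """Read a label mask and validate it against a reference volume's geometry."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3-D image, got {img.ndim}-D")
    data = np.asanyarray(img.dataobj)
    labels = np.asarray(data).transpose(2, 1, 0)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise FormatError(f"{path.name}: mask voxels are not integer-valued")
        labels = rounded.astype(np.int64)
    mask = VesselLabelMask(labels=labels, spacing=ref.spacing, origin=ref.origin)
    if mask.shape != ref.shape:
        raise GeometryError(
            f"{path.name}: mask shape {mask.shape} does not match "
            f"reference volume shape {ref.shape}"
        )
    return mask


COHORT_COLUMNS = ("case_id", "volume_path", "mask_path", "provenance")


def write_cohort_csv(records: Iterable[CaseRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            writer.writerow([rec.case_id, rec.volume_path, rec.mask_path,
                             rec.provenance])
    return path


def read_cohort_csv(path: str | Path) -> list[CaseRecord]:
    path = Path(path)
    records: list[CaseRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"cohort table missing column(s) {sorted(missing)}")
        for row in reader:
            if row["case_id"] in seen:
                raise FormatError(f"duplicate case_id {row['case_id']!r}")
            seen.add(row["case_id"])
            records.append(CaseRecord(
                case_id=row["case_id"],
                volume_path=row["volume_path"],
                mask_path=row["mask_path"],
                provenance=row["provenance"],
            ))
    return records
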