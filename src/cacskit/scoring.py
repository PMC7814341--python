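"""Coronary calcium quantification: lesion extraction at the 130 HU threshold,
Agatston / volume / mass scores at total and per-vessel level, calcified-vessel
counting, and CAC-DRS classification.

Scoring conventions
-------------------
The Agatston score is computed per axial slice over 2-D connected components
(8-connectivity by default) of supra-threshold voxels within one vessel label,
discarding components smaller than 1 mm^2. Each component contributes
``area(mm^2) * w(peak HU)`` where the density weight ``w`` is the standard
step function: 130-199 HU -> 1, 200-299 -> 2, 300-399 -> 3, >= 400 -> 4.
Scores are defined on 3 mm axial reconstructions; non-3 mm inputs trigger a
warning (or an error under ``thickness_policy="require-3mm"``) rather than a
silent slice-thickness correction.

The volume score counts every supra-threshold coronary-labelled voxel times
the voxel volume (no minimum-area filter). The mass score is
``calibration * sum(mean HU * lesion volume in cm^3)`` over extracted lesions,
reported in mg with a default calibration of 0.79 mg/cm^3 per HU (a typical
120 kV value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import (
    CORONARY_LABELS,
    NON_CORONARY,
    VESSEL_NAMES,
    CtVolume,
    GeometryError,
    VesselLabelMask,
    check_congruent,
)

A_CATEGORIES = ("A0", "A1", "A2", "A3")
N_CATEGORIES = ("N0", "N1", "N2", "N3", "N4")


class ThicknessWarning(UserWarning):
    """Slice thickness differs from the 3 mm the scores are defined on."""


@dataclass
class ScoringConfig:
    """Tunable scoring conventions; defaults are the clinical standard."""

    hu_threshold: float = 130.0
    min_area_mm2: float = 1.0
    connectivity_2d: int = 8  # 4 or 8
    mass_calibration: float = 0.79  # mg/cm^3 per HU
    thickness_policy: str = "warn"  # warn | require-3mm

    def __post_init__(self) -> None:
        if self.hu_threshold <= 0:
            raise ValueError("hu_threshold must be positive")
        if self.min_area_mm2 < 0:
            raise ValueError("min_area_mm2 must be >= 0")
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")
        if self.mass_calibration <= 0:
            raise ValueError("mass_calibration must be positive")
        if self.thickness_policy not in ("warn", "require-3mm"):
            raise ValueError("thickness_policy must be 'warn' or 'require-3mm'")


@dataclass
class Lesion:
    """One 2-D in-slice connected calcified component of a single vessel."""

    vessel: int
    slice_index: int
    voxels: list[tuple[int, int]]  # in-slice (row, col) coordinates
    area_mm2: float
    peak_hu: float
    mean_hu: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class CacsResult:
    """Per-vessel and total AS/VS/MS plus CAC-DRS categories for one case."""

    agatston: dict[str, float]  # keys LM/LAD/LCX/RCA/Total
    volume: dict[str, float]  # mm^3
    mass: dict[str, float]  # mg
    calcified_vessels: tuple[str, ...]
    n_vessels: int
    a_category: str
    n_category: str

    def to_dict(self) -> dict:
        return {
            "agatston": dict(self.agatston),
            "volume_mm3": dict(self.volume),
            "mass_mg": dict(self.mass),
            "calcified_vessels": list(self.calcified_vessels),
            "n_vessels": self.n_vessels,
            "a_category": self.a_category,
            "n_category": self.n_category,
        }


def agatston_weight(peak_hu: float) -> int:
    """Density weight for one lesion from its peak attenuation.

    130-199 HU -> 1, 200-299 -> 2, 300-399 -> 3, >= 400 -> 4.
    """
    if peak_hu < 130:
        raise ValueError(f"peak HU {peak_hu} below the 130 HU scoring threshold")
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def extract_lesions(
    vol: CtVolume, mask: VesselLabelMask, cfg: ScoringConfig | None = None
) -> list[Lesion]:
    """Per-slice, per-vessel 2-D connected components above the HU threshold.

    Components with area below ``cfg.min_area_mm2`` are discarded; label-5
    (non-coronary) voxels never yield lesions. Lesions are sorted by
    (slice, vessel, minimum (row, col)) for reproducible reports.
    """
    cfg = cfg or ScoringConfig()
    check_congruent(vol, mask)
    structure = _STRUCT_8 if cfg.connectivity_2d == 8 else _STRUCT_4
    pixel_area = vol.pixel_area_mm2
    supra = vol.voxels >= cfg.hu_threshold

    lesions: list[Lesion] = []
    for z in range(vol.shape[0]):
        hu_slice = vol.voxels[z]
        for vessel in CORONARY_LABELS:
            binary = (mask.labels[z] == vessel) & supra[z]
            if not binary.any():
                continue
            labeled, n_comp = ndimage.label(binary, structure=structure)
            for comp in range(1, n_comp + 1):
                rows, cols = np.nonzero(labeled == comp)
                area = rows.size * pixel_area
                if area < cfg.min_area_mm2:
                    continue
                hu_vals = hu_slice[rows, cols]
                lesions.append(Lesion(
                    vessel=vessel,
                    slice_index=z,
                    voxels=sorted(zip(rows.tolist(), cols.tolist())),
                    area_mm2=area,
                    peak_hu=float(hu_vals.max()),
                    mean_hu=float(hu_vals.mean()),
                ))
    lesions.sort(key=lambda l: (l.slice_index, l.vessel, l.voxels[0]))
    return lesions


def _per_vessel_dict() -> dict[str, float]:
    return {VESSEL_NAMES[v]: 0.0 for v in CORONARY_LABELS} | {"Total": 0.0}


def agatston_score(lesions: list[Lesion]) -> dict[str, float]:
    """Per-vessel and total Agatston score from extracted lesions."""
    scores = _per_vessel_dict()
    for lesion in lesions:
        if lesion.vessel == NON_CORONARY:
            continue
        contrib = lesion.area_mm2 * agatston_weight(lesion.peak_hu)
        scores[VESSEL_NAMES[lesion.vessel]] += contrib
    scores["Total"] = sum(scores[VESSEL_NAMES[v]] for v in CORONARY_LABELS)
    return scores


def volume_score(
    vol: CtVolume, mask: VesselLabelMask, cfg: ScoringConfig | None = None
) -> dict[str, float]:
    """Calcium volume in mm^3: supra-threshold labelled voxels x voxel volume."""
    cfg = cfg or ScoringConfig()
    check_congruent(vol, mask)
    supra = vol.voxels >= cfg.hu_threshold
    voxvol = vol.voxel_volume_mm3
    scores = _per_vessel_dict()
    for vessel in CORONARY_LABELS:
        count = int(np.count_nonzero((mask.labels == vessel) & supra))
        scores[VESSEL_NAMES[vessel]] = count * voxvol
    scores["Total"] = sum(scores[VESSEL_NAMES[v]] for v in CORONARY_LABELS)
    return scores


def mass_score(
    vol: CtVolume,
    mask: VesselLabelMask,
    cfg: ScoringConfig | None = None,
    lesions: list[Lesion] | None = None,
) -> dict[str, float]:
    """Calcium mass in mg: calibration x sum(mean HU x lesion volume in cm^3)."""
    cfg = cfg or ScoringConfig()
    if lesions is None:
        lesions = extract_lesions(vol, mask, cfg)
    dz = vol.spacing[0]
    scores = _per_vessel_dict()
    for lesion in lesions:
        if lesion.vessel == NON_CORONARY:
            continue
        volume_cm3 = lesion.area_mm2 * dz / 1000.0
        scores[VESSEL_NAMES[lesion.vessel]] += (
            cfg.mass_calibration * lesion.mean_hu * volume_cm3
        )
    scores["Total"] = sum(scores[VESSEL_NAMES[v]] for v in CORONARY_LABELS)
    return scores


def count_calcified_vessels(per_vessel_as: dict[str, float]) -> tuple[tuple[str, ...], int]:
    """Vessels with Agatston score > 0, in LM/LAD/LCX/RCA order, and their count."""
    calcified = tuple(
        VESSEL_NAMES[v] for v in CORONARY_LABELS if per_vessel_as[VESSEL_NAMES[v]] > 0
    )
    return calcified, len(calcified)


def cac_drs(total_as: float, n_vessels: int) -> tuple[str, str]:
    """CAC-DRS categories: A0 (AS=0), A1 (0<AS<100), A2 (100<=AS<300),
    A3 (AS>=300); N{k} from the number of calcified vessels."""
    if total_as < 0:
        raise ValueError(f"Agatston score must be >= 0, got {total_as}")
    if not 0 <= n_vessels <= 4:
        raise ValueError(f"n_vessels must be in 0..4, got {n_vessels}")
    if total_as == 0:
        a_cat = "A0"
    elif total_as < 100:
        a_cat = "A1"
    elif total_as < 300:
        a_cat = "A2"
    else:
        a_cat = "A3"
    return a_cat, N_CATEGORIES[n_vessels]


def score_case(
    vol: CtVolume, mask: VesselLabelMask, cfg: ScoringConfig | None = None
) -> CacsResult:
    """Full quantification of one case: lesions -> AS/VS/MS -> CAC-DRS."""
    cfg = cfg or ScoringConfig()
    check_congruent(vol, mask)
    if abs(vol.spacing[0] - 3.0) > 1e-9:
        msg = (
            f"slice thickness {vol.spacing[0]:g} mm differs from the 3 mm "
            f"the Agatston score is defined on; no rescaling is applied"
        )
        if cfg.thickness_policy == "require-3mm":
            raise GeometryError(msg)
        warnings.warn(msg, ThicknessWarning, stacklevel=2)
    lesions = extract_lesions(vol, mask, cfg)
    as_scores = agatston_score(lesions)
    vs_scores = volume_score(vol, mask, cfg)
    ms_scores = mass_score(vol, mask, cfg, lesions=lesions)
    calcified, n_vessels = count_calcified_vessels(as_scores)
    a_cat, n_cat = cac_drs(as_scores["Total"], n_vessels)
    return CacsResult(
        agatston=as_scores,
        volume=vs_scores,
        mass=ms_scores,
        calcified_vessels=calcified,
        n_vessels=n_vessels,
        a_category=a_cat,
        n_category=n_cat,
    )
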