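"""Seeded synthetic cardiac CT phantom with analytically known calcium scores.

The phantom emulates a non-contrast cardiac-gated CT acquisition at desk
scale: a soft-tissue background with lateral lung bands and a cardiac blood
pool, four fixed parametric coronary vessel territories (a short left main
segment bifurcating into LAD and LCX, plus a separate RCA arc), an aortic
root disk adjacent to the LM and RCA origins, and cylindrical calcified
lesions of controlled peak HU and size. Non-coronary "confuser"
calcifications (label 5) can be inserted inside the aortic root next to the
coronary ostia — the adjacency that makes automatic per-vessel attribution
hard on real scans.

Every generated case carries a :class:`GroundTruthCertificate` whose
Agatston / volume / mass scores are computed by direct brute-force summation
(its own flood fill and its own inline weight table), independent of the
scoring module, so it can serve as an exact oracle.

In oracle mode (no blur, noise only on non-lesion voxels) the certificate is
exact: lesion HU profiles are piecewise-constant cylinders and the label mask
marks exactly the supra-threshold lesion voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import warnings

import numpy as np
from scipy import ndimage

from .core_io import (
    BACKGROUND,
    CORONARY_LABELS,
    LAD,
    LCX,
    LM,
    NON_CORONARY,
    RCA,
    VESSEL_NAMES,
    CaseRecord,
    CtVolume,
    VesselLabelMask,
    write_cohort_csv,
    write_mask,
    write_volume,
)

# Certificate scoring conventions, duplicated on purpose so the oracle path
# shares no code with the scoring module.
_CERT_HU_THRESHOLD = 130.0
_CERT_MIN_AREA_MM2 = 1.0


class GenerationError(ValueError):
    """A phantom spec cannot be realised (lesion outside volume, overlap...)."""


@dataclass
class LesionSpec:
    """One cylindrical calcified lesion.

    The lesion occupies ``axial_extent`` consecutive slices starting at the
    slice containing ``center[0]``; in each slice its footprint is the set of
    pixels whose centres lie within ``radius_mm`` of ``(center[1], center[2])``.
    """

    vessel: int
    center: tuple[float, float, float]  # world mm (z, y, x)
    radius_mm: float
    axial_extent: int = 1
    peak_hu: float = 400.0
    profile: str = "uniform"  # uniform | core-rim
    rim_hu: float = 200.0

    def __post_init__(self) -> None:
        if self.vessel not in (*CORONARY_LABELS, NON_CORONARY):
            raise GenerationError(f"illegal vessel label {self.vessel}")
        if self.peak_hu < 130:
            raise GenerationError(
                f"peak_hu {self.peak_hu} below the 130 HU detectability floor"
            )
        if self.radius_mm <= 0:
            raise GenerationError("radius_mm must be positive")
        if self.axial_extent < 1:
            raise GenerationError("axial_extent must be >= 1")
        if self.profile not in ("uniform", "core-rim"):
            raise GenerationError(f"unknown profile {self.profile!r}")


@dataclass
class PhantomSpec:
    """Full description of one synthetic case."""

    shape: tuple[int, int, int] = (24, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 0.5, 0.5)
    background_hu: float = 40.0
    blood_hu: float = 45.0
    lung_hu: float = -800.0
    noise_sigma: float = 0.0
    blur_mm: float = 0.0  # optional partial-volume emulation; breaks exactness
    lesions: list[LesionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise GenerationError("shape components must be positive")
        if self.noise_sigma < 0:
            raise GenerationError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Fixed vessel geometry (world mm), parameterised by the volume extent so the
# same relative layout works for any phantom shape.

def _extent_mm(spec: PhantomSpec) -> tuple[float, float, float]:
    return tuple((n - 1) * s for n, s in zip(spec.shape, spec.spacing))


def vessel_centerline(spec: PhantomSpec, vessel: int, n_points: int = 40
                      ) -> np.ndarray:
    """World-mm points (z, y, x) along a vessel's fixed parametric curve.

    LM is a short segment leaving the aortic root; LAD and LCX continue from
    its distal end toward the apex and the lateral wall; RCA is a separate
    arc on the other side of the root.
    """
    ez, ey, ex = _extent_mm(spec)
    t = np.linspace(0.0, 1.0, n_points)
    if vessel == LM:
        z = 0.26 * ez + 0.04 * ez * t
        y = np.full_like(t, 0.46 * ey)
        x = 0.65 * ex + 0.08 * ex * t
    elif vessel == LAD:
        z = 0.30 * ez + 0.55 * ez * t
        y = 0.44 * ey - 0.18 * ey * t
        x = 0.73 * ex + 0.10 * ex * t
    elif vessel == LCX:
        z = 0.30 * ez + 0.45 * ez * t
        y = 0.48 * ey + 0.24 * ey * t
        x = 0.73 * ex - 0.10 * ex * t
    elif vessel == RCA:
        z = 0.22 * ez + 0.60 * ez * t
        y = 0.48 * ey + 0.18 * ey * t
        x = 0.29 * ex - 0.13 * ex * t
    else:
        raise GenerationError(f"no centerline for label {vessel}")
    return np.column_stack([z, y, x])


def aortic_root_geometry(spec: PhantomSpec) -> dict:
    """Centre, radius and slice range of the aortic-root blood disk."""
    ez, ey, ex = _extent_mm(spec)
    dz = spec.spacing[0]
    return {
        "center_yx": (0.46 * ey, 0.46 * ex),
        "radius_mm": 0.145 * ex,
        "slices": (int(round(0.14 * ez / dz)), int(round(0.40 * ez / dz))),
    }


def confuser_sites(spec: PhantomSpec) -> list[tuple[float, float, float]]:
    """World-mm centres inside the aortic root adjacent to the LM/RCA ostia."""
    root = aortic_root_geometry(spec)
    cy, cx = root["center_yx"]
    r = root["radius_mm"]
    z_lo, z_hi = root["slices"]
    dz = spec.spacing[0]
    z_mid = 0.5 * (z_lo + z_hi) * dz
    return [
        (z_mid, cy, cx + 0.5 * r),   # toward the LM ostium
        (z_mid, cy, cx - 0.5 * r),   # toward the RCA ostium
    ]


# ---------------------------------------------------------------------------
# Rasterisation

def _lesion_footprint(spec: PhantomSpec, lesion: LesionSpec
                      ) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Slices and in-plane (rows, cols) of one lesion's cylindrical footprint."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    cz, cy, cx = lesion.center
    z0 = int(round(cz / dz))
    slices = list(range(z0, z0 + lesion.axial_extent))
    if z0 < 0 or slices[-1] >= nz:
        raise GenerationError(
            f"lesion at z={cz:g} mm with extent {lesion.axial_extent} "
            f"falls outside the {nz}-slice volume"
        )
    yy = np.arange(ny) * dy
    xx = np.arange(nx) * dx
    dist2 = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2
    rows, cols = np.nonzero(dist2 <= lesion.radius_mm ** 2 + 1e-12)
    if rows.size == 0:
        raise GenerationError(
            f"lesion radius {lesion.radius_mm:g} mm covers no pixel centres"
        )
    if rows.min() == 0 or cols.min() == 0 or rows.max() == ny - 1 or cols.max() == nx - 1:
        raise GenerationError("lesion touches the in-plane volume boundary")
    return slices, rows, cols


def _lesion_hu(spec: PhantomSpec, lesion: LesionSpec,
               rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    dy, dx = spec.spacing[1], spec.spacing[2]
    cy, cx = lesion.center[1], lesion.center[2]
    if lesion.profile == "uniform":
        return np.full(rows.shape, float(lesion.peak_hu))
    dist = np.hypot(rows * dy - cy, cols * dx - cx)
    hu = np.where(dist <= lesion.radius_mm / 2.0, lesion.peak_hu, lesion.rim_hu)
    return hu.astype(np.float64)


def _paint_anatomy(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    ez, ey, ex = _extent_mm(spec)
    dy, dx = spec.spacing[1], spec.spacing[2]
    hu = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    # lateral lung bands
    n_lung = max(1, int(round(0.10 * nx)))
    hu[:, :, :n_lung] = spec.lung_hu
    hu[:, :, nx - n_lung:] = spec.lung_hu
    # cardiac blood pool: in-plane ellipse over the mid slices
    yy = (np.arange(ny) * dy - 0.5 * ey) / (0.36 * ey)
    xx = (np.arange(nx) * dx - 0.5 * ex) / (0.36 * ex)
    inside = yy[:, None] ** 2 + xx[None, :] ** 2 <= 1.0
    z_lo = int(round(0.12 * nz))
    z_hi = int(round(0.88 * nz))
    hu[z_lo:z_hi, inside] = spec.blood_hu
    # aortic root disk
    root = aortic_root_geometry(spec)
    cy, cx = root["center_yx"]
    dist2 = (np.arange(ny)[:, None] * dy - cy) ** 2 + (np.arange(nx)[None, :] * dx - cx) ** 2
    disk = dist2 <= root["radius_mm"] ** 2
    hu[root["slices"][0]: root["slices"][1] + 1, disk] = spec.blood_hu
    return hu


@dataclass
class GroundTruthCertificate:
    """Exact per-lesion bookkeeping and brute-force scores for one phantom.

    ``components`` holds one record per 2-D in-slice connected component that
    survives the minimum-area rule; ``supra_voxels`` holds every
    supra-threshold labelled voxel (used by the volume score, which applies
    no area filter). All scores are recomputable from these lists alone via
    :meth:`recompute_scores`.
    """

    components: list[dict]
    supra_voxels: dict[int, list[tuple[int, int, int]]]
    agatston: dict[str, float]
    volume: dict[str, float]
    mass: dict[str, float]
    n_vessels: int
    a_category: str
    n_category: str
    pixel_area_mm2: float
    voxel_volume_mm3: float
    slice_thickness_mm: float
    mass_calibration: float = 0.79

    def recompute_scores(self) -> tuple[dict, dict, dict]:
        """Re-derive AS/VS/MS from the stored voxel lists (self-check)."""
        agatston = {name: 0.0 for name in _score_keys()}
        mass = {name: 0.0 for name in _score_keys()}
        volume = {name: 0.0 for name in _score_keys()}
        for comp in self.components:
            name = VESSEL_NAMES[comp["vessel"]]
            if comp["vessel"] == NON_CORONARY:
                continue
            agatston[name] += comp["area_mm2"] * _cert_weight(comp["peak_hu"])
            mass[name] += (self.mass_calibration * comp["mean_hu"]
                           * comp["area_mm2"] * self.slice_thickness_mm / 1000.0)
        for vessel, voxels in self.supra_voxels.items():
            if vessel == NON_CORONARY:
                continue
            volume[VESSEL_NAMES[vessel]] += len(voxels) * self.voxel_volume_mm3
        for d in (agatston, volume, mass):
            d["Total"] = sum(d[VESSEL_NAMES[v]] for v in CORONARY_LABELS)
        return agatston, volume, mass

    def to_dict(self) -> dict:
        return {
            "agatston": dict(self.agatston),
            "volume_mm3": dict(self.volume),
            "mass_mg": dict(self.mass),
            "n_vessels": self.n_vessels,
            "a_category": self.a_category,
            "n_category": self.n_category,
            "n_components": len(self.components),
        }


def _score_keys() -> list[str]:
    return [VESSEL_NAMES[v] for v in CORONARY_LABELS] + ["Total"]


def _cert_weight(peak_hu: float) -> int:
    # inline normative table; deliberately not imported from the scoring module
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


def _flood_fill_components(binary: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected 2-D components by explicit stack-based flood fill."""
    visited = np.zeros(binary.shape, dtype=bool)
    comps: list[list[tuple[int, int]]] = []
    rows, cols = np.nonzero(binary)
    for r0, c0 in zip(rows.tolist(), cols.tolist()):
        if visited[r0, c0]:
            continue
        stack = [(r0, c0)]
        visited[r0, c0] = True
        comp: list[tuple[int, int]] = []
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < binary.shape[0] and 0 <= cc < binary.shape[1]
                            and binary[rr, cc] and not visited[rr, cc]):
                        visited[rr, cc] = True
                        stack.append((rr, cc))
        comps.append(sorted(comp))
    comps.sort(key=lambda c: c[0])
    return comps


def _build_certificate(spec: PhantomSpec, hu: np.ndarray, labels: np.ndarray
                       ) -> GroundTruthCertificate:
    dz, dy, dx = spec.spacing
    pixel_area = dy * dx
    voxvol = dz * dy * dx
    components: list[dict] = []
    supra: dict[int, list[tuple[int, int, int]]] = {
        v: [] for v in (*CORONARY_LABELS, NON_CORONARY)
    }
    for vessel in (*CORONARY_LABELS, NON_CORONARY):
        vol_mask = labels == vessel
        if not vol_mask.any():
            continue
        for z in range(spec.shape[0]):
            binary = vol_mask[z] & (hu[z] >= _CERT_HU_THRESHOLD)
            if not binary.any():
                continue
            for (r, c) in zip(*np.nonzero(binary)):
                supra[vessel].append((z, int(r), int(c)))
            for comp in _flood_fill_components(binary):
                area = len(comp) * pixel_area
                if area < _CERT_MIN_AREA_MM2:
                    continue
                hu_vals = [hu[z, r, c] for r, c in comp]
                components.append({
                    "vessel": vessel,
                    "slice": z,
                    "voxels": comp,
                    "n_voxels": len(comp),
                    "area_mm2": area,
                    "peak_hu": float(max(hu_vals)),
                    "mean_hu": float(np.mean(hu_vals)),
                })
    cert = GroundTruthCertificate(
        components=components,
        supra_voxels={v: lst for v, lst in supra.items() if lst},
        agatston={}, volume={}, mass={},
        n_vessels=0, a_category="A0", n_category="N0",
        pixel_area_mm2=pixel_area,
        voxel_volume_mm3=voxvol,
        slice_thickness_mm=dz,
    )
    agatston, volume, mass = cert.recompute_scores()
    cert.agatston, cert.volume, cert.mass = agatston, volume, mass
    calcified = [v for v in CORONARY_LABELS if agatston[VESSEL_NAMES[v]] > 0]
    cert.n_vessels = len(calcified)
    total = agatston["Total"]
    cert.a_category = ("A0" if total == 0 else
                       "A1" if total < 100 else
                       "A2" if total < 300 else "A3")
    cert.n_category = f"N{cert.n_vessels}"
    return cert


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[CtVolume, VesselLabelMask, GroundTruthCertificate]:
    """Rasterise a phantom spec into (volume, label mask, exact certificate).

    Identical spec + seed produce bit-identical outputs. Lesions of different
    vessels may not overlap; same-vessel overlaps merge (maximum HU wins).
    """
    hu = _paint_anatomy(spec)
    labels = np.zeros(spec.shape, dtype=np.int64)
    lesion_voxels = np.zeros(spec.shape, dtype=bool)
    for lesion in spec.lesions:
        slices, rows, cols = _lesion_footprint(spec, lesion)
        hu_vals = _lesion_hu(spec, lesion, rows, cols)
        for z in slices:
            existing = labels[z, rows, cols]
            clash = (existing != BACKGROUND) & (existing != lesion.vessel)
            if clash.any():
                other = int(existing[clash][0])
                raise GenerationError(
                    f"lesion of vessel {VESSEL_NAMES[lesion.vessel]} overlaps "
                    f"vessel {VESSEL_NAMES[other]} at slice {z}"
                )
            hu[z, rows, cols] = np.maximum(hu[z, rows, cols], hu_vals)
            lesion_voxels[z, rows, cols] = True
            supra = hu[z, rows, cols] >= _CERT_HU_THRESHOLD
            labels[z, rows[supra], cols[supra]] = lesion.vessel
    if spec.blur_mm > 0:
        sigma_vox = [spec.blur_mm / s for s in spec.spacing]
        hu = ndimage.gaussian_filter(hu, sigma=sigma_vox)
        # the label mask keeps marking the nominal lesion voxels; blur mode is
        # for model-training realism and voids certificate exactness
        labels[(labels != 0) & (hu < _CERT_HU_THRESHOLD)] = 0
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        hu = np.where(lesion_voxels, hu, hu + noise)
        hu = np.clip(hu, -1024.0, 4095.0)
    cert = _build_certificate(spec, hu, labels)
    vol = CtVolume(voxels=hu, spacing=spec.spacing)
    mask = VesselLabelMask(labels=labels, spacing=spec.spacing)
    return vol, mask, cert


# ---------------------------------------------------------------------------
# Standard cohort

@dataclass
class PhantomCase:
    """A generated case: cohort record, spec, arrays, and its certificate."""

    record: CaseRecord
    spec: PhantomSpec
    volume: CtVolume
    mask: VesselLabelMask
    certificate: GroundTruthCertificate


#: Per-category Agatston total target band used by the cohort builder.
_CATEGORY_BANDS = {"A0": (0.0, 0.0), "A1": (5.0, 95.0),
                   "A2": (110.0, 290.0), "A3": (320.0, 700.0)}
#: Lesion radius templates (mm) - sizes chosen to give multi-voxel footprints
#: at the default 0.5 mm pixel.
_RADII_SMALL = (0.6, 0.9)
_RADII_LARGE = (1.1, 1.4, 1.7)


def _cohort_case_spec(index: int, seed: int, shape, spacing,
                      noise_sigma: float, blur_mm: float = 0.0) -> PhantomSpec:
    """Deterministically build one cohort case's spec.

    Categories cycle A0-A3 so every stratum is represented; the number of
    calcified vessels alternates within a category so N0-N4 all occur; every
    third case carries an aortic-sinus confuser.
    """
    rng = np.random.default_rng([seed, index])
    a_target = ("A0", "A1", "A2", "A3")[index % 4]
    nv_by_cat = {"A0": 0,
                 "A1": 1 + (index // 4) % 2,
                 "A2": 2 + (index // 4) % 2,
                 "A3": 3 + (index // 4) % 2}
    n_vessels = nv_by_cat[a_target]
    base = PhantomSpec(shape=tuple(shape), spacing=tuple(spacing),
                       noise_sigma=noise_sigma, blur_mm=blur_mm,
                       seed=int(seed * 100003 + index))
    lo, hi = _CATEGORY_BANDS[a_target]
    # rotate deterministically so every vessel recurs every few cases and
    # any plausible train split sees all four labels
    vessels = [CORONARY_LABELS[(index + k) % 4] for k in range(n_vessels)]
    lesions: list[LesionSpec] = []

    pixel_area = spacing[1] * spacing[2]
    used_slices: dict[int, set[int]] = {v: set() for v in CORONARY_LABELS}

    def clashes(center, radius: float, needed: set[int]) -> bool:
        # reject candidates whose in-plane footprint could touch a lesion of
        # another vessel on a shared slice (the bifurcation region is tight)
        for other in lesions:
            oz = int(round(other.center[0] / spacing[0]))
            other_slices = set(range(oz, oz + other.axial_extent))
            if not needed & other_slices:
                continue
            d = np.hypot(center[1] - other.center[1], center[2] - other.center[2])
            if d < radius + other.radius_mm + 1.0:
                return True
        return False

    def candidate(vessel: int, radius: float, peak: float, extent: int
                  ) -> LesionSpec | None:
        """Place a lesion on the vessel's centerline in free slices."""
        pts = vessel_centerline(base, vessel)
        # keep LAD/LCX lesions distal to the shared bifurcation segment so
        # vessel identity is unambiguous by construction
        if vessel in (LAD, LCX):
            pts = pts[int(0.12 * len(pts)):]
        dz = spacing[0]
        nz = shape[0]
        z_span = (pts[0][0] - dz / 2, pts[-1][0] + dz / 2)
        order = rng.permutation(len(pts))
        for k in order:
            z0 = int(round(pts[k][0] / dz))
            needed = set(range(z0, z0 + extent))
            if z0 < 1 or z0 + extent > nz - 1:
                continue
            # the whole axial extent must stay within the vessel's z-span so
            # no labelled voxel ends up far from its own centerline
            if z0 * dz < z_span[0] or (z0 + extent - 1) * dz > z_span[1]:
                continue
            # keep one empty slice between same-vessel lesions so the exact
            # per-lesion score accounting never merges
            guard = needed | {min(needed) - 1, max(needed) + 1}
            if guard & used_slices[vessel]:
                continue
            center = (z0 * dz, float(pts[k][1]), float(pts[k][2]))
            if clashes(center, radius, needed):
                continue
            lesion = LesionSpec(vessel=vessel, center=center, radius_mm=radius,
                                axial_extent=extent, peak_hu=peak)
            try:
                _, rows, _ = _lesion_footprint(base, lesion)
            except GenerationError:
                continue
            used_slices[vessel].update(needed)
            return lesion
        return None

    def exact_as(lesion: LesionSpec) -> float:
        _, rows, _cols = _lesion_footprint(base, lesion)
        area = rows.size * pixel_area
        if area < _CERT_MIN_AREA_MM2:
            return 0.0
        return area * _cert_weight(lesion.peak_hu) * lesion.axial_extent

    total = 0.0
    if a_target != "A0":
        # one seed lesion per chosen vessel, sized toward its share of the
        # band midpoint, then top up within the band
        share = 0.5 * (lo + hi) / n_vessels
        for vessel in vessels:
            options = [(r, p, e)
                       for r in (*_RADII_SMALL, *_RADII_LARGE)
                       for p in (160.0, 250.0, 350.0, 450.0)
                       for e in (1, 2, 3)]
            rng.shuffle(options)
            best, best_gap = None, np.inf
            for r, p, e in options:
                lesion = candidate(vessel, r, p, e)
                if lesion is None:
                    continue
                contrib = exact_as(lesion)
                gap = abs(contrib - min(share, hi - total))
                if total + contrib <= hi and gap < best_gap:
                    best, best_gap = (lesion, contrib), gap
                # candidate() reserved slices; release them for the next try
                oz = int(round(lesion.center[0] / spacing[0]))
                used_slices[vessel] -= set(range(oz, oz + e))
            if best is not None:
                lesion, contrib = best
                oz = int(round(lesion.center[0] / spacing[0]))
                used_slices[vessel] |= set(range(oz, oz + lesion.axial_extent))
                lesions.append(lesion)
                total += contrib
        attempts = 0
        while total < lo and attempts < 200:
            attempts += 1
            vessel = int(vessels[attempts % len(vessels)])
            big = hi - total > 60
            radius = float(rng.choice(_RADII_LARGE if big else _RADII_SMALL))
            peak = float(rng.choice([350, 450] if big else [160, 250]))
            extent = int(rng.integers(1, 4)) if big else 1
            lesion = candidate(vessel, radius, peak, extent)
            if lesion is None:
                continue
            contrib = exact_as(lesion)
            if total + contrib > hi:
                continue
            lesions.append(lesion)
            total += contrib
    if index % 3 == 0:
        sites = confuser_sites(base)
        # alternate sites so any contiguous 8-case split sees both ostia
        first = (index // 3) % 2
        radius = float(rng.choice([1.1, 1.4]))
        extent = int(rng.integers(1, 3))
        peak = float(rng.choice([300, 450, 600]))
        dz = spacing[0]
        for site in (sites[first], sites[1 - first]):
            z0 = int(round(site[0] / dz))
            if not clashes(site, radius, set(range(z0, z0 + extent))):
                lesions.append(LesionSpec(
                    vessel=NON_CORONARY, center=site, radius_mm=radius,
                    axial_extent=extent, peak_hu=peak,
                ))
                break
    return replace(base, lesions=lesions)


def standard_cohort(n_cases: int, seed: int,
                    shape: tuple[int, int, int] = (24, 96, 96),
                    spacing: tuple[float, float, float] = (3.0, 0.5, 0.5),
                    noise_sigma: float = 0.0,
                    blur_mm: float = 0.0) -> list[PhantomCase]:
    """Generate a reproducible mixed-severity cohort.

    Cases span all CAC-DRS strata A0-A3 and vessel counts N0-N4 (for
    ``n_cases >= 8``) and at least every third case carries an aortic-sinus
    confuser. Fully deterministic in ``(n_cases, seed)``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cases: list[PhantomCase] = []
    for i in range(n_cases):
        spec = _cohort_case_spec(i, seed, shape, spacing, noise_sigma, blur_mm)
        vol, mask, cert = generate_phantom(spec)
        case_id = f"case_{i:03d}"
        record = CaseRecord(case_id=case_id,
                            volume_path=f"{case_id}_vol.nii.gz",
                            mask_path=f"{case_id}_mask.nii.gz",
                            provenance="phantom")
        cases.append(PhantomCase(record=record, spec=spec, volume=vol,
                                 mask=mask, certificate=cert))
    return cases


def write_cohort(cases: list[PhantomCase], out_dir: str | Path) -> Path:
    """Persist a cohort as NIfTI volumes/masks plus a cohort CSV; returns the CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for case in cases:
        vol_path = out_dir / case.record.volume_path
        mask_path = out_dir / case.record.mask_path
        write_volume(case.volume, vol_path)
        write_mask(case.mask, mask_path)
        records.append(replace(case.record,
                               volume_path=str(vol_path),
                               mask_path=str(mask_path)))
        case.record = records[-1]
    return write_cohort_csv(records, out_dir / "cohort.csv")


# ---------------------------------------------------------------------------
# Controlled mask perturbations (for agreement-analysis tests)

def perturb_mask(mask: VesselLabelMask, mode: str, seed: int = 0
                 ) -> VesselLabelMask:
    """Return a copy of ``mask`` altered in one documented way.

    Modes: ``dilate-1`` grows every nonzero label by one in-plane voxel
    (never overwriting another label); ``drop-smallest-lesion`` removes the
    3-D coronary component with the fewest voxels (ties broken by lowest
    (slice, row, col) of the component's minimum coordinate);
    ``relabel-one-vessel`` moves all voxels of one seeded-chosen coronary
    vessel to another coronary label.
    """
    labels = mask.labels.copy()
    rng = np.random.default_rng(seed)
    if mode == "dilate-1":
        struct = np.zeros((1, 3, 3), dtype=bool)
        struct[0] = True
        out = labels.copy()
        for value in sorted(set(np.unique(labels)) - {0}):
            grown = ndimage.binary_dilation(labels == value, structure=struct)
            out[grown & (labels == 0)] = value
        labels = out
    elif mode == "drop-smallest-lesion":
        comps = []
        struct3d = np.ones((3, 3, 3), dtype=bool)
        for value in CORONARY_LABELS:
            lab, n = ndimage.label(labels == value, structure=struct3d)
            for comp in range(1, n + 1):
                idx = np.argwhere(lab == comp)
                anchor = tuple(idx.min(axis=0))
                comps.append((idx.shape[0], anchor, value, idx))
        if not comps:
            warnings.warn("drop-smallest-lesion on an empty coronary mask is a "
                          "no-op", UserWarning, stacklevel=2)
        else:
            comps.sort(key=lambda c: (c[0], c[1]))
            _, _, _, idx = comps[0]
            labels[idx[:, 0], idx[:, 1], idx[:, 2]] = 0
    elif mode == "relabel-one-vessel":
        present = [v for v in CORONARY_LABELS if (labels == v).any()]
        if not present:
            warnings.warn("relabel-one-vessel on an empty coronary mask is a "
                          "no-op", UserWarning, stacklevel=2)
        else:
            src = int(present[int(rng.integers(len(present)))])
            others = [v for v in CORONARY_LABELS if v != src]
            dst = int(others[int(rng.integers(len(others)))])
            labels[labels == src] = dst
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    return VesselLabelMask(labels=labels, spacing=mask.spacing,
                           origin=mask.origin)
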