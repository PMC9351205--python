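"""Synthetic chest-CT lung phantom with known airway tree, lobes, tumor and survival.

The phantom is a soft-tissue block (0 HU) holding two parenchyma ellipsoids
(-800 HU) carved by an air-filled Y-shaped airway tree (-1000 HU): a
vertical trachea splitting at a carina into two main bronchi that end
inside their hemithorax.  A spherical tumor (+40 HU plus a configurable
offset) is planted inside one lobe compartment, and survival times follow
an exponential model whose hazard depends on tumor diameter — a planted,
recoverable signal for every downstream learning stage.

Intensity palette (before noise): air/lumen -1000, parenchyma -800,
soft tissue 0, tumor +40 + offset.  Only the ordering matters downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from lunggraph.roles import LOBE_ROLES, NodeRole
from lunggraph.sampling import TumorAnnotation
from lunggraph.volume import CTVolume

HU_AIR = -1000.0
HU_PARENCHYMA = -800.0
HU_SOFT_TISSUE = 0.0
HU_TUMOR = 40.0

#: Clearance (mm) kept between a planted tumor surface and its lobe boundary.
TUMOR_MARGIN_MM = 1.0


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TracheaSpec:
    radius_mm: float = 4.0
    length_mm: float = 45.0
    #: voxel (z, y, x) where the trachea enters; None = near-top, centred.
    entry: Optional[tuple[int, int, int]] = None


@dataclass(frozen=True)
class TumorSpec:
    lobe: int = 1  # 1=LUL, 2=LLL, 3=RUL, 4=RML, 5=RLL
    diameter_mm: float = 20.0
    intensity_offset_hu: float = 0.0


@dataclass(frozen=True)
class LobeLayout:
    """Partition rule: fractions of each lung's z-extent given to the upper lobes."""

    left_upper_frac: float = 0.5
    right_upper_frac: float = 0.40
    right_middle_frac: float = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (96, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.25, 1.25, 1.25)
    trachea: TracheaSpec = field(default_factory=TracheaSpec)
    branch_angles_deg: tuple[float, float] = (35.0, 45.0)  # (left, right) from vertical
    lobe_layout: LobeLayout = field(default_factory=LobeLayout)
    tumor: TumorSpec = field(default_factory=TumorSpec)
    noise_sd_hu: float = 10.0
    seed: int = 0
    n_generations: int = 2  # 2 = trachea + main bronchi (Y-tree)

    def validate(self) -> None:
        if any(s < 64 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be >= 64 per axis, got {self.volume_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        min_inplane = min(self.spacing_mm[1], self.spacing_mm[2])
        if self.trachea.radius_mm / min_inplane < 2.0:
            raise ValueError(
                f"trachea radius {self.trachea.radius_mm} mm is below 2 voxels "
                f"at spacing {min_inplane} mm"
            )
        if self.tumor.lobe not in range(1, 6):
            raise ValueError(f"tumor lobe must be 1..5, got {self.tumor.lobe}")
        if self.tumor.diameter_mm <= 0:
            raise ValueError("tumor diameter must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if self.n_generations < 2:
            raise ValueError("airway needs at least 2 generations (trachea + bronchi)")

    def geometry_key(self) -> tuple:
        """Hashable key of the tumor-independent geometry (for base caching)."""
        return (
            self.volume_shape,
            self.spacing_mm,
            self.trachea,
            self.branch_angles_deg,
            self.lobe_layout,
            self.n_generations,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: exponential survival with hazard tied to tumor diameter."""

    n_patients: int = 100
    baseline_hazard: float = 0.0015  # events / month at diameter 0
    beta_size: float = math.log(2.0)  # log-hazard per cm of tumor diameter
    censor_horizon_months: float = 84.0
    seed: int = 0
    diameter_range_mm: tuple[float, float] = (6.0, 55.0)
    recurrence_hazard_ratio: float = 1.5  # RFS hazard multiplier vs OS
    # cohort volumes are a little larger than the single-phantom default so
    # every diameter in the range fits at least one lobe
    base: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(
            volume_shape=(112, 144, 144), spacing_mm=(1.5, 1.5, 1.5)
        )
    )

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError(f"cohort needs >= 2 patients, got {self.n_patients}")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_horizon_months < 60:
            raise ValueError("censor_horizon_months must be >= 60")
        lo, hi = self.diameter_range_mm
        if not 0 < lo <= hi:
            raise ValueError(f"bad diameter range {self.diameter_range_mm}")


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------


@dataclass
class PatientSurvival:
    """Per-patient outcome record.

    ``label_5yr`` is 1 for death within 60 months, 0 for documented 5-year
    survival, and None when the patient was censored alive before 60 months
    (excluded from binary classification, retained for KM/Cox).
    """

    os_months: float
    os_event: int
    rfs_months: float
    rfs_event: int
    label_5yr: Optional[int]


def five_year_label(time_months: float, event: int) -> Optional[int]:
    if event and time_months <= 60.0:
        return 1
    if time_months >= 60.0:
        return 0
    return None  # censored alive before 60 months


@dataclass
class PhantomSample:
    """One synthetic patient: CT, ground truth masks, annotation, outcome."""

    ct: CTVolume
    airway_truth: np.ndarray  # bool
    lobe_labels: np.ndarray  # uint8, 0 background / 1..5 lobes
    tumor_annotation: TumorAnnotation
    survival: Optional[PatientSurvival] = None
    landmarks_truth: Optional[dict[NodeRole, tuple[int, int, int]]] = None
    tumor_diameter_mm: float = 0.0
    tumor_center: Optional[tuple[int, int, int]] = None
    patient_id: str = ""


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _carve_capsule(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    p0: np.ndarray,
    p1: np.ndarray,
    radius_mm: float,
) -> None:
    """Set to True all voxels within radius_mm of segment p0-p1 (voxel coords)."""
    sp = np.asarray(spacing)
    r_vox = radius_mm / sp.min()
    lo = np.maximum(np.floor(np.minimum(p0, p1) - r_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + r_vox + 2).astype(int), mask.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij", sparse=False
    )
    pts = np.stack(grids, axis=-1).astype(np.float64) * sp  # mm coords
    a = p0 * sp
    b = p1 * sp
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    mask[sub] |= dist2 <= radius_mm**2


def _airway_segments(spec: PhantomSpec) -> tuple[list[tuple[np.ndarray, np.ndarray, float]], dict]:
    """Build the airway segment list and the designed landmark positions."""
    Z, Y, X = spec.volume_shape
    sz, sy, sx = spec.spacing_mm
    entry = spec.trachea.entry or (3, Y // 2, X // 2)
    entry = np.asarray(entry, dtype=np.float64)
    carina = entry + np.array([spec.trachea.length_mm / sz, 0.0, 0.0])
    segments = [(entry, carina, spec.trachea.radius_mm)]
    r_bronchus = 0.7 * spec.trachea.radius_mm
    length_mm = {"left": 45.0, "right": 40.0}
    tips: dict[str, np.ndarray] = {}
    # patient-left = increasing x
    for side, sign, ang in (
        ("left", +1.0, spec.branch_angles_deg[0]),
        ("right", -1.0, spec.branch_angles_deg[1]),
    ):
        theta = math.radians(ang)
        d_mm = np.array([math.cos(theta), 0.0, sign * math.sin(theta)]) * length_mm[side]
        tip = carina + d_mm / np.array([sz, sy, sx])
        segments.append((carina, tip, r_bronchus))
        tips[side] = tip
        # optional deeper generations: two children per tip, shrinking
        parent_dir, parent_tip, r, L = d_mm, tip, r_bronchus, length_mm[side]
        for _gen in range(spec.n_generations - 2):
            r *= 0.6
            L *= 0.6
            base_ang = math.atan2(sign * parent_dir[2], parent_dir[0])
            new_tips = []
            for dtheta in (-0.45, 0.45):
                th = base_ang + dtheta
                d = np.array([math.cos(th), 0.0, sign * math.sin(th)]) * L
                child_tip = parent_tip + d / np.array([sz, sy, sx])
                segments.append((parent_tip, child_tip, r))
                new_tips.append((child_tip, d))
            parent_tip, parent_dir = new_tips[0]
    landmarks = {
        NodeRole.ROOT: tuple(int(round(v)) for v in entry),
        NodeRole.CENTER: tuple(int(round(v)) for v in carina),
        NodeRole.LEFT: tuple(int(round(v)) for v in tips["left"]),
        NodeRole.RIGHT: tuple(int(round(v)) for v in tips["right"]),
    }
    return segments, landmarks


@dataclass
class _BaseGeometry:
    ct: np.ndarray  # float32 HU, no tumor, no noise
    airway: np.ndarray  # bool
    lobe_labels: np.ndarray  # uint8
    landmarks: dict[NodeRole, tuple[int, int, int]]
    lobe_edt_mm: dict[int, np.ndarray]  # distance-to-lobe-boundary per lobe
    designed_airway_volume_mm3: float


_BASE_CACHE: dict[tuple, _BaseGeometry] = {}


def _build_base(spec: PhantomSpec) -> _BaseGeometry:
    key = spec.geometry_key()
    if key in _BASE_CACHE:
        return _BASE_CACHE[key]
    Z, Y, X = spec.volume_shape
    sp = spec.spacing_mm
    zz, yy, xx = np.meshgrid(
        np.arange(Z), np.arange(Y), np.arange(X), indexing="ij", sparse=True
    )
    # lung ellipsoids
    zc, a_z = 0.58 * Z, 0.36 * Z
    yc, a_y = 0.50 * Y, 0.32 * Y
    a_x = 0.20 * X
    lungs = {}
    for side, xc in (("right", 0.25 * X), ("left", 0.75 * X)):
        lungs[side] = (
            ((zz - zc) / a_z) ** 2 + ((yy - yc) / a_y) ** 2 + ((xx - xc) / a_x) ** 2
        ) <= 1.0
    ct = np.full(spec.volume_shape, HU_SOFT_TISSUE, dtype=np.float32)
    ct[lungs["left"] | lungs["right"]] = HU_PARENCHYMA

    airway = np.zeros(spec.volume_shape, dtype=bool)
    segments, landmarks = _airway_segments(spec)
    vol = 0.0
    for p0, p1, r in segments:
        _carve_capsule(airway, sp, p0, p1, r)
        length = float(np.linalg.norm((p1 - p0) * np.asarray(sp)))
        vol += math.pi * r * r * length
    ct[airway] = HU_AIR

    # lobe partition by z-planes within each lung, airway lumen excluded
    labels = np.zeros(spec.volume_shape, dtype=np.uint8)
    layout = spec.lobe_layout
    for side, lobe_ids, fracs in (
        ("left", (1, 2), (layout.left_upper_frac,)),
        ("right", (3, 4, 5), (layout.right_upper_frac, layout.right_middle_frac)),
    ):
        mask = lungs[side] & ~airway
        z_any = np.any(mask, axis=(1, 2))
        z_idx = np.nonzero(z_any)[0]
        z0, z1 = int(z_idx[0]), int(z_idx[-1]) + 1
        extent = z1 - z0
        cuts = [z0]
        acc = 0.0
        for f in fracs:
            acc += f
            cuts.append(z0 + int(round(acc * extent)))
        cuts.append(z1)
        zcol = np.arange(Z)[:, None, None]
        for lobe_id, (lo, hi) in zip(lobe_ids, zip(cuts[:-1], cuts[1:])):
            labels[mask & (zcol >= lo) & (zcol < hi)] = lobe_id

    lobe_edt = {}
    for lobe_id in range(1, 6):
        lobe_edt[lobe_id] = ndimage.distance_transform_edt(
            labels == lobe_id, sampling=sp
        ).astype(np.float32)

    base = _BaseGeometry(
        ct=ct,
        airway=airway,
        lobe_labels=labels,
        landmarks=landmarks,
        lobe_edt_mm=lobe_edt,
        designed_airway_volume_mm3=vol,
    )
    _BASE_CACHE[key] = base
    return base


def designed_airway_volume_mm3(spec: PhantomSpec) -> float:
    """Closed-form cylinder volume of the designed airway tree (no caps/overlap)."""
    return _build_base(spec).designed_airway_volume_mm3


def lobe_max_tumor_diameter_mm(spec: PhantomSpec) -> dict[int, float]:
    """Largest tumor diameter that fits in each lobe of this geometry."""
    base = _build_base(spec)
    return {
        lobe: 2.0 * (float(edt.max()) - TUMOR_MARGIN_MM)
        for lobe, edt in base.lobe_edt_mm.items()
    }


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one synthetic patient volume; deterministic for a fixed seed."""
    spec.validate()
    base = _build_base(spec)
    rng = np.random.default_rng(spec.seed)

    radius = spec.tumor.diameter_mm / 2.0
    edt = base.lobe_edt_mm[spec.tumor.lobe]
    feasible = np.flatnonzero(edt >= radius + TUMOR_MARGIN_MM)
    lobe_name = LOBE_ROLES[spec.tumor.lobe - 1].value
    if feasible.size == 0:
        raise ValueError(
            f"tumor of diameter {spec.tumor.diameter_mm:g} mm does not fit in "
            f"lobe {lobe_name} (label {spec.tumor.lobe})"
        )
    center_flat = int(feasible[rng.integers(feasible.size)])
    center = np.unravel_index(center_flat, spec.volume_shape)

    ct = base.ct.copy()
    sp = np.asarray(spec.spacing_mm)
    r_vox = np.ceil(radius / sp).astype(int)
    lo = np.maximum(np.asarray(center) - r_vox - 1, 0)
    hi = np.minimum(np.asarray(center) + r_vox + 2, spec.volume_shape)
    sub = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(int(l), int(h)) for l, h in zip(lo, hi)], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, sp))
    sphere = d2 <= radius**2
    ct[sub][sphere] = HU_TUMOR + spec.tumor.intensity_offset_hu

    overlapped = np.unique(base.lobe_labels[sub][sphere])
    lobes = [int(v) for v in overlapped if v > 0] or [spec.tumor.lobe]

    ann = _annotation_bbox(center, spec)

    if spec.noise_sd_hu > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd_hu, size=ct.shape).astype(np.float32)

    return PhantomSample(
        ct=CTVolume(ct, spec.spacing_mm, meta={"phantom_seed": spec.seed}),
        airway_truth=base.airway.copy(),
        lobe_labels=base.lobe_labels.copy(),
        tumor_annotation=TumorAnnotation(bbox=ann, lobes=lobes),
        landmarks_truth=dict(base.landmarks),
        tumor_diameter_mm=spec.tumor.diameter_mm,
        tumor_center=tuple(int(c) for c in center),
    )


def _annotation_bbox(
    center: tuple[int, ...], spec: PhantomSpec
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Fixed-margin annotation cube around the tumor (>= 64 voxels per side).

    Mimics a loose radiologist bounding box of constant physical size so the
    tumor's extent relative to the box carries size information.
    """
    extent = int(np.ceil(spec.tumor.diameter_mm / min(spec.spacing_mm))) + 8
    side = max(64, extent)
    lo, hi = [], []
    for c, dim in zip(center, spec.volume_shape):
        s = min(side, dim)
        a = int(c) - s // 2
        a = max(0, min(a, dim - s))
        lo.append(a)
        hi.append(a + s)
    return (tuple(lo), tuple(hi))


def _survival_draw(
    rng: np.random.Generator, cs: CohortSpec, diameter_mm: float
) -> PatientSurvival:
    rate = cs.baseline_hazard * math.exp(cs.beta_size * diameter_mm / 10.0)
    t_death = rng.exponential(1.0 / rate)
    t_rec = rng.exponential(1.0 / (cs.recurrence_hazard_ratio * rate))
    horizon = cs.censor_horizon_months
    os_event = int(t_death <= horizon)
    os_months = float(min(t_death, horizon))
    t_rfs = min(t_death, t_rec)
    rfs_event = int(t_rfs <= horizon)
    rfs_months = float(min(t_rfs, horizon))
    return PatientSurvival(
        os_months=os_months,
        os_event=os_event,
        rfs_months=rfs_months,
        rfs_event=rfs_event,
        label_5yr=five_year_label(os_months, os_event),
    )


def iter_cohort(cs: CohortSpec, imaging: bool = True) -> Iterator[PhantomSample]:
    """Lazily generate cohort patients (memory-friendly for large n).

    With ``imaging=False`` the CT/masks are skipped and only the tumor draw
    and survival record are produced; because the phantom's voxel synthesis
    uses its own per-patient seed, the resulting cohort table is identical
    to the imaging run (asserted in tests).
    """
    cs.validate()
    cs.base.validate()
    fits = lobe_max_tumor_diameter_mm(cs.base)
    children = np.random.SeedSequence(cs.seed).spawn(cs.n_patients)
    lo, hi = cs.diameter_range_mm
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        d = float(rng.uniform(lo, hi))
        feasible = [lobe for lobe, dmax in fits.items() if d <= dmax]
        if not feasible:
            raise ValueError(f"diameter {d:.1f} mm fits no lobe of the base geometry")
        lobe = feasible[int(rng.integers(len(feasible)))]
        phantom_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        spec_i = replace(
            cs.base,
            tumor=TumorSpec(lobe=lobe, diameter_mm=d,
                            intensity_offset_hu=cs.base.tumor.intensity_offset_hu),
            seed=phantom_seed,
        )
        if imaging:
            sample = generate_phantom(spec_i)
        else:
            sample = PhantomSample(
                ct=None,  # type: ignore[arg-type]
                airway_truth=None,  # type: ignore[arg-type]
                lobe_labels=None,  # type: ignore[arg-type]
                tumor_annotation=TumorAnnotation(bbox=((0, 0, 0), (1, 1, 1)), lobes=[lobe]),
                tumor_diameter_mm=d,
            )
        sample.survival = _survival_draw(rng, cs, d)
        sample.patient_id = f"P{i:05d}"
        yield sample


def cohort_table(samples: list[PhantomSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        sv = s.survival
        rows.append(
            {
                "id": s.patient_id,
                "os_months": sv.os_months,
                "os_event": sv.os_event,
                "rfs_months": sv.rfs_months,
                "rfs_event": sv.rfs_event,
                "label_5yr": sv.label_5yr if sv.label_5yr is not None else np.nan,
                "tumor_diameter_mm": s.tumor_diameter_mm,
                "tumor_lobe": s.tumor_annotation.lobes[0],
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    cs: CohortSpec, imaging: bool = True
) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Generate the full cohort eagerly and return samples + cohort table.

    For survival-only analyses pass ``imaging=False``: the cohort table is
    identical but no volumes are synthesized or held in memory.
    """
    samples = list(iter_cohort(cs, imaging=imaging))
    return samples, cohort_table(samples)
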