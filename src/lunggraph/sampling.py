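"""Per-patient patch extraction: 4 landmark cubes, 5 lobe patches, 1 tumor patch.

Every node of the lung graph is backed by one 64x64x64 patch of normalized
intensity.  Landmark patches are fixed-size crops centred on an airway
landmark; lobe and tumor patches are bounding-box crops resampled to the
common cube so all nodes share one encoder input shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from lunggraph.roles import LOBE_LABELS, LOBE_ROLES, NodeRole
from lunggraph.volume import CTVolume

#: Default cube side of every patch, voxels per axis.
PATCH_SIZE = 64

#: Out-of-volume / out-of-lobe fill value: air.
PAD_HU = -1000.0

#: HU window clipped before min-max scaling (lung window through soft tissue).
HU_WINDOW = (-1000.0, 400.0)

BBox = tuple[tuple[int, int, int], tuple[int, int, int]]  # half-open [min, max)


@dataclass
class TumorAnnotation:
    """Radiologist-style tumor annotation: bounding box + lobe membership.

    ``bbox`` is a half-open voxel box ((z0,y0,x0), (z1,y1,x1)); ``lobes`` is
    the nonempty list of lobe label ids (1..5) the tumor overlaps.
    """

    bbox: BBox
    lobes: list[int]

    def __post_init__(self) -> None:
        lo, hi = self.bbox
        if len(lo) != 3 or len(hi) != 3:
            raise ValueError("bbox must be ((z0,y0,x0),(z1,y1,x1))")
        if any(h <= l for l, h in zip(lo, hi)):
            raise ValueError(f"empty tumor bbox {self.bbox!r}")
        if not self.lobes:
            raise ValueError("tumor annotation must name at least one lobe")
        if not set(self.lobes) <= {1, 2, 3, 4, 5}:
            raise ValueError(f"invalid lobe ids {self.lobes!r}")

    @property
    def lobe_roles(self) -> list[NodeRole]:
        return [LOBE_ROLES[i - 1] for i in self.lobes]

    def to_json(self) -> dict:
        return {
            "bbox_zyx_min": [int(v) for v in self.bbox[0]],
            "bbox_zyx_max": [int(v) for v in self.bbox[1]],
            "lobes": [int(v) for v in self.lobes],
        }

    @classmethod
    def from_json(cls, d: dict) -> "TumorAnnotation":
        return cls(
            bbox=(tuple(d["bbox_zyx_min"]), tuple(d["bbox_zyx_max"])),
            lobes=list(d["lobes"]),
        )


@dataclass
class Patch:
    """A 64^3 normalized-intensity cube tagged with its graph role."""

    values: np.ndarray
    role: NodeRole
    source_bbox: BBox

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("patch must be 3D")


def normalize_hu(values: np.ndarray) -> np.ndarray:
    """Clip to the lung HU window and min-max scale to [0, 1].

    Monotone on the clipped range.  Input already scaled to [0, 1] is
    returned unchanged, making the operation idempotent.
    """
    values = np.asarray(values, dtype=np.float32)
    if values.size and float(values.min()) >= 0.0 and float(values.max()) <= 1.0:
        return values
    lo, hi = HU_WINDOW
    return (np.clip(values, lo, hi) - lo) / (hi - lo)


def crop_landmark_patch(
    ct: CTVolume, point: tuple[int, int, int], size: int = PATCH_SIZE
) -> Patch:
    """Crop a ``size``^3 cube centred on a landmark voxel, padding with air.

    The centre voxel sits at patch index ``size // 2`` on every axis.
    Regions outside the volume are filled with -1000 HU before
    normalization, so border landmarks never fail.
    """
    point = tuple(int(p) for p in point)
    if any(p < 0 or p >= s for p, s in zip(point, ct.shape)):
        raise ValueError(f"landmark {point} outside volume of shape {ct.shape}")
    half = size // 2
    lo = tuple(p - half for p in point)
    hi = tuple(p - half + size for p in point)
    out = np.full((size, size, size), PAD_HU, dtype=np.float32)
    src = tuple(slice(max(l, 0), min(h, s)) for l, h, s in zip(lo, hi, ct.shape))
    dst = tuple(slice(s.start - l, s.stop - l) for s, l in zip(src, lo))
    out[dst] = ct.values[src]
    return Patch(values=normalize_hu(out), role=NodeRole.CENTER, source_bbox=(lo, hi))


def _resample_to_cube(values: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    """Trilinear resample an arbitrary box to ``size``^3 (identity if already cubic)."""
    if values.shape == (size, size, size):
        return values.astype(np.float32)
    axes = [
        (np.arange(size) + 0.5) * (s / size) - 0.5 for s in values.shape
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndimage.map_coordinates(
        values.astype(np.float32), coords, order=1, mode="nearest"
    )
    return out.reshape(size, size, size)


def crop_tumor_patch(ct: CTVolume, ann: TumorAnnotation, size: int = PATCH_SIZE) -> Patch:
    """Crop the annotated tumor box and resample it to the common cube."""
    lo, hi = ann.bbox
    if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, ct.shape)):
        raise ValueError(f"tumor bbox {ann.bbox!r} extends outside volume {ct.shape}")
    sub = ct.values[tuple(slice(l, h) for l, h in zip(lo, hi))]
    cube = _resample_to_cube(np.asarray(sub, dtype=np.float32), size)
    return Patch(values=normalize_hu(cube), role=NodeRole.TUMOR, source_bbox=ann.bbox)


def crop_lobe_patch(
    ct: CTVolume, lobe_labels: np.ndarray, lobe_id: int, size: int = PATCH_SIZE
) -> Patch:
    """Crop one lobe's bounding box with out-of-lobe voxels zeroed to air.

    The lobe mask is taken from ``lobe_labels == lobe_id``; voxels outside
    the lobe are set to -1000 HU before the crop is resampled to the cube.
    """
    if lobe_id not in range(1, 6):
        raise ValueError(f"lobe id must be in 1..5, got {lobe_id}")
    role = LOBE_ROLES[lobe_id - 1]
    mask = np.asarray(lobe_labels) == lobe_id
    if not mask.any():
        raise ValueError(f"lobe {role.value} (label {lobe_id}) absent from label map")
    zs, ys, xs = np.nonzero(mask)
    lo = (int(zs.min()), int(ys.min()), int(xs.min()))
    hi = (int(zs.max()) + 1, int(ys.max()) + 1, int(xs.max()) + 1)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = np.where(mask[sl], ct.values[sl], PAD_HU).astype(np.float32)
    cube = _resample_to_cube(sub, size)
    return Patch(values=normalize_hu(cube), role=role, source_bbox=(lo, hi))


def extract_patient_patches(
    ct: CTVolume,
    landmarks: dict[NodeRole, tuple[int, int, int]],
    lobe_labels: np.ndarray,
    tumor: TumorAnnotation,
    size: int = PATCH_SIZE,
) -> dict[NodeRole, Patch]:
    """Extract all 10 patches (4 landmarks, 5 lobes, 1 tumor) for one patient."""
    patches: dict[NodeRole, Patch] = {}
    for role in (NodeRole.ROOT, NodeRole.CENTER, NodeRole.LEFT, NodeRole.RIGHT):
        p = crop_landmark_patch(ct, landmarks[role], size)
        p.role = role
        patches[role] = p
    for role, label in LOBE_LABELS.items():
        patches[role] = crop_lobe_patch(ct, lobe_labels, label, size)
    patches[NodeRole.TUMOR] = crop_tumor_patch(ct, tumor, size)
    return patches


def save_patch(patch: Patch, path: str | Path) -> None:
    """Cache a patch as ``.npy`` plus a JSON sidecar (role, source_bbox)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), patch.values)
    sidecar = {
        "role": patch.role.value,
        "source_bbox": [list(map(int, b)) for b in patch.source_bbox],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_patch(path: str | Path) -> Patch:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    bbox = tuple(tuple(b) for b in sidecar["source_bbox"])
    return Patch(values=values, role=NodeRole(sidecar["role"]), source_bbox=bbox)
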