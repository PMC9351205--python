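"""NIfTI input/output and on-disk cohort layout.

Volumes are stored on disk as NIfTI and held in memory as (z, y, x) arrays
with superior = decreasing z and patient-left = increasing x (see
:mod:`lunggraph.volume`).  ``load_volume`` reorients any input to this
canonical convention via nibabel's RAS canonicalization, so downstream
left/right logic is well defined regardless of the source orientation.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from lunggraph.phantom import PhantomSample
from lunggraph.sampling import TumorAnnotation
from lunggraph.volume import CTVolume


def save_volume(ct: CTVolume, path: str | Path, dtype=np.float32) -> None:
    """Write a CTVolume as NIfTI, encoding the package orientation convention."""
    sz, sy, sx = ct.spacing_mm
    data = np.asarray(ct.values, dtype=dtype).transpose(2, 1, 0)  # (x, y, z)
    affine = np.diag([-sx, -sy, -sz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_volume(
    path: str | Path,
    slice_thickness_mm: float | None = None,
    in_plane_shape: tuple[int, int] | None = None,
) -> CTVolume:
    """Read a NIfTI volume and canonicalize to the (z, y, x) convention.

    Optionally resamples to a target slice thickness (z spacing, mm) and
    in-plane matrix (y, x), e.g. ``slice_thickness_mm=1.0,
    in_plane_shape=(512, 512)`` for the standard preprocessing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj)  # (R, A, S) axes
    zooms = img.header.get_zooms()[:3]
    # RAS -> (z, y, x) = (-S, -A, -R)
    arr = data.transpose(2, 1, 0)[::-1, ::-1, ::-1].copy()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    ct = CTVolume(arr, spacing, meta={"source": str(path)})
    if slice_thickness_mm is not None or in_plane_shape is not None:
        ct = resample_volume(ct, slice_thickness_mm, in_plane_shape)
    return ct


def resample_volume(
    ct: CTVolume,
    slice_thickness_mm: float | None = None,
    in_plane_shape: tuple[int, int] | None = None,
) -> CTVolume:
    """Trilinear resample to a z spacing and/or in-plane matrix size."""
    z, y, x = ct.shape
    sz, sy, sx = ct.spacing_mm
    new_z = int(round(z * sz / slice_thickness_mm)) if slice_thickness_mm else z
    new_y, new_x = in_plane_shape if in_plane_shape else (y, x)
    factors = (new_z / z, new_y / y, new_x / x)
    if factors == (1.0, 1.0, 1.0):
        return ct
    values = ndimage.zoom(ct.values.astype(np.float32), factors, order=1)
    # pad/trim rounding slack so the requested matrix is exact
    values = values[: new_z, : new_y, : new_x]
    new_spacing = (
        sz * z / values.shape[0],
        sy * y / values.shape[1],
        sx * x / values.shape[2],
    )
    return CTVolume(values, new_spacing, dict(ct.meta))


# ---------------------------------------------------------------------------
# Phantom cohort directory layout: one subdirectory per patient + cohort.csv
# ---------------------------------------------------------------------------


def save_sample(sample: PhantomSample, patient_dir: str | Path) -> None:
    patient_dir = Path(patient_dir)
    patient_dir.mkdir(parents=True, exist_ok=True)
    save_volume(sample.ct, patient_dir / "ct.nii.gz")
    save_volume(
        CTVolume(sample.airway_truth.astype(np.uint8), sample.ct.spacing_mm),
        patient_dir / "airway_truth.nii.gz",
        dtype=np.uint8,
    )
    save_volume(
        CTVolume(sample.lobe_labels, sample.ct.spacing_mm),
        patient_dir / "lobe_labels.nii.gz",
        dtype=np.uint8,
    )
    (patient_dir / "tumor.json").write_text(
        json.dumps(sample.tumor_annotation.to_json(), indent=2)
    )
    if sample.landmarks_truth is not None:
        marks = {k.value.lower(): list(map(int, v)) for k, v in sample.landmarks_truth.items()}
        (patient_dir / "landmarks_truth.json").write_text(json.dumps(marks, indent=2))


def load_sample(patient_dir: str | Path) -> PhantomSample:
    patient_dir = Path(patient_dir)
    ct = load_volume(patient_dir / "ct.nii.gz")
    airway = load_volume(patient_dir / "airway_truth.nii.gz").values.astype(bool)
    lobes = load_volume(patient_dir / "lobe_labels.nii.gz").values.astype(np.uint8)
    ann = TumorAnnotation.from_json(json.loads((patient_dir / "tumor.json").read_text()))
    sample = PhantomSample(
        ct=ct,
        airway_truth=airway,
        lobe_labels=lobes,
        tumor_annotation=ann,
        patient_id=patient_dir.name,
    )
    lm_path = patient_dir / "landmarks_truth.json"
    if lm_path.exists():
        from lunggraph.roles import NodeRole

        marks = json.loads(lm_path.read_text())
        sample.landmarks_truth = {
            NodeRole(k.upper()): tuple(v) for k, v in marks.items()
        }
    return sample


def save_cohort_dir(samples, table: pd.DataFrame, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        save_sample(sample, out_dir / sample.patient_id)
    table.to_csv(out_dir / "cohort.csv", index=False)
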