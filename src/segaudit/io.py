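"""Reading and writing cohorts: NIfTI volumes plus a JSON manifest.

A cohort manifest is a JSON list of patient records, each naming the image
volume (4-D NIfTI, last axis = channels T1, T1-Gd, T2, FLAIR, or four 3-D
files), the whole-tumor label volume, the optional brain-mask volume, and the
patient's site code and grade group.  Volumes are (H, W, S) on disk per the
NIfTI convention and converted to per-slice stacks in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import CHANNELS, Cohort, PatientCase, SegAuditError


def _to_slices(vol: np.ndarray) -> np.ndarray:
    """(H, W, S) volume -> (S, H, W) slice stack."""
    return np.moveaxis(vol, -1, 0)


def load_nifti_case(record: dict, base_dir: str | Path = ".") -> PatientCase:
    """Load one patient from a manifest record.

    Required keys: ``patient_id``, ``site_code``, ``grade_group``, ``image``
    (4-D NIfTI path, channels last) and ``label``.  Optional: ``brain_mask``
    (derived from the image's nonzero union when absent) and ``raw_image``
    (pre-normalization volume for the data-quality axis).
    """
    base = Path(base_dir)
    img = np.asarray(nib.load(base / record["image"]).dataobj, dtype=float)
    if img.ndim != 4 or img.shape[-1] != len(CHANNELS):
        raise SegAuditError(
            f"image volume must be (H, W, S, 4); got {img.shape}"
        )
    lab = np.asarray(nib.load(base / record["label"]).dataobj)
    gt = _to_slices(lab > 0)
    slices = np.stack([_to_slices(img[..., c]) for c in range(len(CHANNELS))], axis=1)
    if "brain_mask" in record:
        brain = _to_slices(np.asarray(nib.load(base / record["brain_mask"]).dataobj) > 0)
    else:
        brain = np.any(slices != 0, axis=1)
    raw = None
    if "raw_image" in record:
        rawv = np.asarray(nib.load(base / record["raw_image"]).dataobj, dtype=float)
        raw = np.stack([_to_slices(rawv[..., c]) for c in range(len(CHANNELS))], axis=1)
    return PatientCase(
        patient_id=record["patient_id"],
        site_code=record["site_code"],
        grade_group=record["grade_group"],
        slices=slices,
        gt_masks=gt & brain,
        brain_masks=brain,
        raw_slices=raw,
    )


def load_cohort_manifest(path: str | Path, name: str, split: str) -> Cohort:
    """Load a cohort from a JSON manifest (list of patient records)."""
    path = Path(path)
    records = json.loads(path.read_text())
    cases = [load_nifti_case(r, base_dir=path.parent) for r in records]
    return Cohort(name=name, cases=cases, split=split)


def save_case_nifti(case: PatientCase, out_dir: str | Path) -> dict:
    """Write one patient as NIfTI volumes; returns its manifest record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)

    def vol(stack4: np.ndarray) -> np.ndarray:  # (S,4,H,W) -> (H,W,S,4)
        return np.moveaxis(stack4, (0, 1), (2, 3))

    rec = {
        "patient_id": case.patient_id,
        "site_code": case.site_code,
        "grade_group": case.grade_group,
        "image": f"{case.patient_id}_image.nii",
        "label": f"{case.patient_id}_label.nii",
        "brain_mask": f"{case.patient_id}_brain.nii",
    }
    nib.save(nib.Nifti1Image(vol(case.slices), affine), out / rec["image"])
    nib.save(
        nib.Nifti1Image(np.moveaxis(case.gt_masks, 0, 2).astype(np.uint8), affine),
        out / rec["label"],
    )
    nib.save(
        nib.Nifti1Image(np.moveaxis(case.brain_masks, 0, 2).astype(np.uint8), affine),
        out / rec["brain_mask"],
    )
    if case.raw_slices is not None:
        rec["raw_image"] = f"{case.patient_id}_raw.nii"
        nib.save(nib.Nifti1Image(vol(case.raw_slices), affine), out / rec["raw_image"])
    return rec


def save_cohort_nifti(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as NIfTI volumes + JSON manifest; returns the manifest
    path."""
    out = Path(out_dir)
    records = [save_case_nifti(c, out) for c in cohort.cases]
    manifest = out / f"{cohort.name}_{cohort.split}_manifest.json"
    manifest.write_text(json.dumps(records, indent=2))
    return manifest
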