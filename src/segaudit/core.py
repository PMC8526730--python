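"""Domain types and shared conventions for segmentation-model auditing.

The unit of analysis is a *patient*: an ordered stack of 2-D multi-modal MRI
slices (channels T1, T1-Gd, T2, FLAIR), a binary whole-tumor ground-truth mask
per slice, and a brain mask per slice.  All evaluation downstream is restricted
to pixels inside the brain mask (skull-stripped convention: background pixels
are exactly zero in every channel of the model-input image), and every reported
quantity is aggregated per patient before any cohort-level averaging.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Channel order of every modality stack.
CHANNELS: tuple[str, ...] = ("T1", "T1Gd", "T2", "FLAIR")

#: Grade groups recognised by the audit.
GRADE_GROUPS: tuple[str, ...] = ("GBM", "LGG")

#: Default in-plane crop size (pixels).
DEFAULT_SHAPE: tuple[int, int] = (144, 144)

#: Default number of slices per patient in the full-resolution convention.
SLICES_PER_PATIENT: int = 144


class SegAuditError(ValueError):
    """Raised on violated domain invariants or degenerate inputs."""


@dataclass(frozen=True)
class ModalityStack:
    """One slice's 4-channel image, shape (4, H, W), channels per CHANNELS.

    In the model-input (normalized) representation, non-brain pixels are
    exactly zero in all channels.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[0] != len(CHANNELS):
            raise SegAuditError(
                f"modality stack must have shape (4, H, W), got {px.shape}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


def brain_mask_from_stack(stack: ModalityStack | np.ndarray) -> np.ndarray:
    """Brain mask = union of nonzero support across the four channels.

    The skull-stripped convention guarantees background pixels are zero in
    every channel, so any nonzero pixel belongs to the brain.  An all-zero
    stack has no brain and is an error.
    """
    px = stack.pixels if isinstance(stack, ModalityStack) else np.asarray(stack)
    if px.ndim != 3 or px.shape[0] != len(CHANNELS):
        raise SegAuditError(f"expected a (4, H, W) stack, got shape {px.shape}")
    mask = np.any(px != 0, axis=0)
    if not mask.any():
        raise SegAuditError("all-zero stack: no brain present")
    return mask


@dataclass
class PatientCase:
    """One patient's slice stack, ground truth, brain masks and tags.

    Parameters
    ----------
    slices
        Model-input (normalized) images, shape (S, 4, H, W); background zero.
    gt_masks
        Binary whole-tumor masks, shape (S, H, W); subset of brain mask.
    brain_masks
        Binary brain masks, shape (S, H, W).
    raw_slices
        Optional pre-normalization images (same shape as ``slices``), used by
        the data-quality axis.  Unlike the skull-stripped model input, these
        may contain background (air) signal.
    """

    patient_id: str
    site_code: str
    grade_group: str
    slices: np.ndarray
    gt_masks: np.ndarray
    brain_masks: np.ndarray
    raw_slices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.grade_group not in GRADE_GROUPS:
            raise SegAuditError(f"unknown grade group {self.grade_group!r}")
        self.slices = np.asarray(self.slices, dtype=float)
        self.gt_masks = np.asarray(self.gt_masks, dtype=bool)
        self.brain_masks = np.asarray(self.brain_masks, dtype=bool)
        if self.slices.ndim != 4 or self.slices.shape[1] != len(CHANNELS):
            raise SegAuditError(
                f"slices must have shape (S, 4, H, W), got {self.slices.shape}"
            )
        spatial = (self.slices.shape[0],) + self.slices.shape[2:]
        if self.gt_masks.shape != spatial or self.brain_masks.shape != spatial:
            raise SegAuditError("slice/gt/brain shape mismatch")
        if np.any(self.gt_masks & ~self.brain_masks):
            raise SegAuditError("ground-truth mask extends outside brain mask")
        if not self.gt_masks.any():
            raise SegAuditError("patient has no tumor pixels on any slice")
        if self.raw_slices is not None:
            self.raw_slices = np.asarray(self.raw_slices, dtype=float)
            if self.raw_slices.shape != self.slices.shape:
                raise SegAuditError("raw_slices shape mismatch")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.slices.shape[2:]

    def stack(self, i: int) -> ModalityStack:
        return ModalityStack(self.slices[i])

    def tumor_area_per_slice(self) -> np.ndarray:
        return self.gt_masks.reshape(self.n_slices, -1).sum(axis=1)


def summary_slice_index(case: PatientCase) -> int:
    """Index of the patient's summary slice: the slice with the largest tumor
    cross-section; ties broken by the lowest index."""
    areas = case.tumor_area_per_slice()
    if areas.max() == 0:
        raise SegAuditError("no tumor pixels anywhere; no summary slice")
    return int(np.argmax(areas))


@dataclass
class Cohort:
    """A named, split-tagged list of patients (e.g. GBM / LGG / ALL test)."""

    name: str
    cases: list[PatientCase]
    split: str  # train | validation | test

    def __post_init__(self) -> None:
        ids = [c.patient_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise SegAuditError("duplicate patient_id within cohort")

    def __len__(self) -> int:
        return len(self.cases)

    def patient_ids(self) -> list[str]:
        return [c.patient_id for c in self.cases]


def make_all_cohort(gbm: Cohort, lgg: Cohort, name: str = "ALL") -> Cohort:
    """Concatenate a GBM and an LGG cohort of the same split into an ALL
    cohort (no deduplication, no reweighting)."""
    if gbm.split != lgg.split:
        raise SegAuditError(
            f"cannot merge cohorts from different splits: {gbm.split} vs {lgg.split}"
        )
    return Cohort(name=name, cases=list(gbm.cases) + list(lgg.cases), split=gbm.split)


class Predictor(abc.ABC):
    """Contract for a binary segmentation model under audit.

    The audit needs two things from a model: per-pixel logits, and the
    gradient of its training loss with respect to the input image (for the
    white-box adversarial axis).  Both must be deterministic for fixed
    weights.
    """

    @abc.abstractmethod
    def predict_logits(self, pixels: np.ndarray) -> np.ndarray:
        """Per-pixel real-valued logit map for a (4, H, W) input; shape (H, W)."""

    @abc.abstractmethod
    def loss_input_gradient(self, pixels: np.ndarray, gt_mask: np.ndarray) -> np.ndarray:
        """Gradient of the training loss w.r.t. the input; shape (4, H, W)."""

    def predict_probs(self, pixels: np.ndarray) -> np.ndarray:
        """Uncalibrated foreground probabilities sigma(z)."""
        z = self.predict_logits(pixels)
        return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Manifest arithmetic
# ---------------------------------------------------------------------------

def split_slice_totals(
    patient_counts: Mapping[str, Mapping[str, int]],
    slices_per_patient: int = SLICES_PER_PATIENT,
) -> pd.DataFrame:
    """Patients and slice totals per (split, dataset), with the ALL dataset as
    the GBM + LGG concatenation.

    ``patient_counts`` maps split name -> {"GBM": n, "LGG": n}.  Each patient
    contributes ``slices_per_patient`` independent 2-D slices.
    """
    rows = []
    for split, counts in patient_counts.items():
        gbm = int(counts["GBM"])
        lgg = int(counts["LGG"])
        for name, n in (("GBM", gbm), ("LGG", lgg), ("ALL", gbm + lgg)):
            rows.append(
                {
                    "split": split,
                    "dataset": name,
                    "patients": n,
                    "slices": n * slices_per_patient,
                }
            )
    return pd.DataFrame(rows)


def pooled_brain_pixels(
    case: PatientCase, predictor: Predictor
) -> tuple[np.ndarray, np.ndarray]:
    """Pool (logits, labels) over all brain pixels of all slices of a patient.

    This is the per-patient pooling convention: pixels are pooled across a
    patient's slices before any metric is computed, so each patient yields one
    value per metric regardless of how tumor is distributed across slices.
    """
    zs, ys = [], []
    for i in range(case.n_slices):
        m = case.brain_masks[i]
        z = predictor.predict_logits(case.slices[i])
        zs.append(z[m])
        ys.append(case.gt_masks[i][m])
    return np.concatenate(zs), np.concatenate(ys)
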