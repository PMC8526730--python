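"""Synthetic multi-modal MRI cohorts and a desk-scale differentiable segmenter.

The generator emulates the conventions of skull-stripped, co-registered glioma
imaging: 4-channel (T1, T1-Gd, T2, FLAIR) 2-D slices, an elliptical brain with
zero background in the model-input images, a whole-tumor label formed by
merging tumor sub-components, and tumor occupying roughly 6-9% of the brain
volume.  Two phenotypes reproduce the qualitative contrast patterns that
distinguish the grade groups:

* GBM-like: a heterogeneous core, a bright rim on T1-Gd (rim-enhancing), and
  surrounding FLAIR-bright edema; whole tumor = core + rim + edema.
* LGG-like: a single diffuse FLAIR-hyperintense mass with essentially no
  T1-Gd enhancement.

Per-site batch effects (intensity offset/gain, noise level, smoothing) are
applied to the *raw* images before normalization, so the data-quality axis can
detect them while the model sees percentile-normalized inputs.  Raw images
additionally carry a faint background air-noise floor, mimicking original
(pre-skull-strip) scans on which quality features are measured; the
model-input images are skull-stripped (background exactly zero).

The toy segmenter is a pixelwise logistic scorer over channel intensities and
local-mean features, trained by gradient descent on soft Dice loss.  Its input
gradient is available in closed form, which the adversarial axis requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    CHANNELS,
    DEFAULT_SHAPE,
    Cohort,
    PatientCase,
    Predictor,
    SegAuditError,
    make_all_cohort,
)

# ---------------------------------------------------------------------------
# Phenotypes and site effects
# ---------------------------------------------------------------------------

#: Baseline tissue intensity per channel (arbitrary raw units).
TISSUE_MEAN: dict[str, float] = {"T1": 100.0, "T1Gd": 95.0, "T2": 120.0, "FLAIR": 110.0}

#: Within-brain tissue texture standard deviation (raw units).
TISSUE_SD: float = 6.0

#: Background (air) noise scale in raw images (raw units).
AIR_NOISE_SD: float = 3.0


@dataclass(frozen=True)
class PhenotypeParams:
    """Appearance model of one grade group.

    ``contrast`` maps channel -> component -> (additive mean shift, sd) in raw
    intensity units, relative to the channel's tissue baseline.  Components
    are "core", "rim", "edema" for GBM-like tumors and "mass" for LGG-like
    ones; the whole-tumor label is the union of all components.
    """

    grade_group: str
    contrast: Mapping[str, Mapping[str, tuple[float, float]]]
    core_frac: float = 0.45  # core radius as fraction of whole-tumor radius
    rim_frac: float = 0.65  # rim outer radius as fraction of whole-tumor radius
    edge_blur_sigma: float = 1.5  # boundary softness of contrast maps (px)
    tumor_fraction_range: tuple[float, float] = (0.065, 0.085)
    axis_ratio_range: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self) -> None:
        if not (0 < self.core_frac < self.rim_frac < 1):
            raise SegAuditError("need 0 < core_frac < rim_frac < 1")
        lo, hi = self.tumor_fraction_range
        if not (0 < lo <= hi < 0.5):
            raise SegAuditError("tumor fraction range must lie in (0, 0.5)")


def gbm_phenotype() -> PhenotypeParams:
    """Heterogeneous rim-enhancing phenotype with perifocal edema."""
    return PhenotypeParams(
        grade_group="GBM",
        contrast={
            "T1": {"core": (-25.0, 14.0), "rim": (-10.0, 10.0), "edema": (-8.0, 6.0)},
            "T1Gd": {"core": (10.0, 20.0), "rim": (85.0, 18.0), "edema": (2.0, 6.0)},
            "T2": {"core": (45.0, 18.0), "rim": (25.0, 12.0), "edema": (35.0, 8.0)},
            "FLAIR": {"core": (40.0, 16.0), "rim": (30.0, 10.0), "edema": (60.0, 10.0)},
        },
        edge_blur_sigma=1.2,
    )


def lgg_phenotype() -> PhenotypeParams:
    """Diffuse FLAIR-hyperintense phenotype with no enhancement on T1-Gd."""
    return PhenotypeParams(
        grade_group="LGG",
        contrast={
            "T1": {"mass": (-20.0, 8.0)},
            "T1Gd": {"mass": (0.0, 5.0)},  # near-isointense: no enhancement
            "T2": {"mass": (40.0, 10.0)},
            "FLAIR": {"mass": (55.0, 9.0)},
        },
        edge_blur_sigma=2.5,
    )


@dataclass(frozen=True)
class SiteEffect:
    """Site-level technical variation applied identically to all patients of
    a site: per-channel affine intensity distortion, noise level, smoothing."""

    site_code: str
    offset: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    gain: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    noise_sd: float = 8.0
    smooth_sigma: float = 0.0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain):
            raise SegAuditError("site gains must be positive")
        if self.noise_sd < 0 or self.smooth_sigma < 0:
            raise SegAuditError("noise/smoothing parameters must be nonnegative")


#: Default site rosters.  GBM sites carry numeric codes and LGG sites carry
#: alphabetic codes, with disjoint technical profiles, mirroring the TCGA
#: convention of numeric GBM vs alphabetic LGG tissue source sites.
DEFAULT_GBM_SITES: tuple[SiteEffect, ...] = (
    SiteEffect("06", offset=(4.0, 3.0, 6.0, 5.0), gain=(1.06, 1.04, 1.08, 1.05), noise_sd=8.0),
    SiteEffect("08", offset=(-6.0, -4.0, -8.0, -5.0), gain=(0.92, 0.95, 0.90, 0.94), noise_sd=11.0),
    SiteEffect("12", offset=(10.0, 8.0, 12.0, 9.0), gain=(1.15, 1.12, 1.18, 1.14), noise_sd=6.0, smooth_sigma=0.6),
)
DEFAULT_LGG_SITES: tuple[SiteEffect, ...] = (
    SiteEffect("HT", offset=(-10.0, -8.0, -12.0, -9.0), gain=(0.85, 0.88, 0.84, 0.86), noise_sd=9.0),
    SiteEffect("DU", offset=(6.0, 5.0, 8.0, 6.0), gain=(1.10, 1.08, 1.12, 1.10), noise_sd=7.0, smooth_sigma=0.5),
    SiteEffect("CS", offset=(0.0, 0.0, 0.0, 0.0), gain=(1.0, 1.0, 1.0, 1.0), noise_sd=13.0),
)


# ---------------------------------------------------------------------------
# Patient generation
# ---------------------------------------------------------------------------

def _brain_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Elliptical brain roughly filling the frame, jittered per patient."""
    h, w = shape
    cy, cx = h / 2 + rng.uniform(-2, 2), w / 2 + rng.uniform(-2, 2)
    ry = h * rng.uniform(0.36, 0.40)
    rx = w * rng.uniform(0.32, 0.36)
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _component_masks(
    shape: tuple[int, int],
    n_slices: int,
    phenotype: PhenotypeParams,
    brain: np.ndarray,
    rng: np.random.Generator,
    target_fraction: float,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Voxelized tumor component masks and the merged whole-tumor label.

    The tumor is a randomly placed, randomly oriented 3-D ellipsoid; in-plane
    radii shrink away from the central slice.  Radii are calibrated
    iteratively so the whole-tumor voxel count hits ``target_fraction`` of the
    brain voxel count.
    """
    h, w = shape
    brain_volume = float(brain.sum()) * n_slices
    # Tumor center well inside the brain.
    ys, xs = np.nonzero(ndimage.binary_erosion(brain, iterations=max(4, h // 12)))
    if len(ys) == 0:
        raise SegAuditError("shape too small to fit a tumor inside the brain")
    k = rng.integers(len(ys))
    cy, cx = float(ys[k]), float(xs[k])
    cz = n_slices / 2 + rng.uniform(-0.15, 0.15) * n_slices
    theta = rng.uniform(0, np.pi)
    ratio = rng.uniform(*phenotype.axis_ratio_range)
    rz = max(1.5, 0.38 * n_slices)

    # Solve rx*ry*rz for the target ellipsoid volume, then correct for
    # voxelization / brain clipping with a few multiplicative updates.
    target_vox = target_fraction * brain_volume
    rxry = target_vox * 3.0 / (4.0 * np.pi * rz)
    rx = np.sqrt(rxry / ratio)

    yy, xx = np.mgrid[0:h, 0:w]
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    u = (xx - cx) * cos_t + (yy - cy) * sin_t
    v = -(xx - cx) * sin_t + (yy - cy) * cos_t

    def whole_mask(rx_: float) -> np.ndarray:
        ry_ = rx_ * ratio
        out = np.zeros((n_slices, h, w), dtype=bool)
        for s in range(n_slices):
            t2 = 1.0 - ((s - cz) / rz) ** 2
            if t2 <= 0:
                continue
            t = np.sqrt(t2)
            out[s] = ((u / (rx_ * t)) ** 2 + (v / (ry_ * t)) ** 2 <= 1.0) & brain
        return out

    for _ in range(6):
        whole = whole_mask(rx)
        got = whole.sum()
        if got == 0:
            rx *= 1.5
            continue
        err = got / target_vox
        if 0.96 <= err <= 1.04:
            break
        rx *= err ** (-1.0 / 2.0)  # in-plane radii only -> volume ~ rx^2
    whole = whole_mask(rx)
    if whole.sum() == 0:
        raise SegAuditError("shape too small to fit a tumor")

    components: dict[str, np.ndarray] = {}
    names = set()
    for ch_map in phenotype.contrast.values():
        names.update(ch_map.keys())
    if "mass" in names:  # diffuse single-component phenotype
        components["mass"] = whole
    else:  # core + rim + edema
        core = whole_mask(rx * phenotype.core_frac)
        rim_outer = whole_mask(rx * phenotype.rim_frac)
        components["core"] = core
        components["rim"] = rim_outer & ~core
        components["edema"] = whole & ~rim_outer
    return components, whole


def generate_patient(
    seed: int | np.random.SeedSequence,
    phenotype: PhenotypeParams,
    site: SiteEffect,
    n_slices: int = 16,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    patient_id: str | None = None,
    normalize_percentile: float = 99.0,
    with_components: bool = False,
) -> PatientCase | tuple[PatientCase, dict[str, np.ndarray]]:
    """Generate one synthetic patient; bit-deterministic given the seed.

    Raw images are built as tissue baseline + phenotype contrast (blurred at
    component boundaries) + site distortion + noise, with a faint air-noise
    floor outside the brain.  Model-input images are the raw images
    skull-stripped and per-channel normalized by the ``normalize_percentile``
    brain intensity over the patient volume.
    """
    if min(shape) < 32:
        raise SegAuditError("shape too small to fit a brain and tumor")
    rng = np.random.default_rng(seed)
    h, w = shape
    brain2d = _brain_mask(shape, rng)
    target_fraction = rng.uniform(*phenotype.tumor_fraction_range)
    components, whole = _component_masks(
        shape, n_slices, phenotype, brain2d, rng, target_fraction
    )

    brain_masks = np.broadcast_to(brain2d, (n_slices, h, w)).copy()
    gt_masks = whole & brain_masks

    raw = np.zeros((n_slices, len(CHANNELS), h, w))
    for ci, ch in enumerate(CHANNELS):
        base = TISSUE_MEAN[ch] + rng.normal(0.0, TISSUE_SD, size=(n_slices, h, w))
        # Slowly varying per-patient anatomy texture, shared across slices.
        texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 8.0)
        base += 25.0 * texture[None]
        contrast = np.zeros((n_slices, h, w))
        for comp, mask3 in components.items():
            mu, sd = phenotype.contrast.get(ch, {}).get(comp, (0.0, 0.0))
            bump = np.where(mask3, mu + rng.normal(0.0, sd, size=mask3.shape), 0.0)
            contrast += bump
        # Soften component boundaries slice-wise.
        for s in range(n_slices):
            contrast[s] = ndimage.gaussian_filter(
                contrast[s], phenotype.edge_blur_sigma
            )
        img = base + contrast
        # Site batch effect on raw intensities (brain only).
        img = site.gain[ci] * img + site.offset[ci]
        img += rng.normal(0.0, site.noise_sd, size=img.shape)
        if site.smooth_sigma > 0:
            for s in range(n_slices):
                img[s] = ndimage.gaussian_filter(img[s], site.smooth_sigma)
        img = np.where(brain_masks, np.clip(img, 0.0, None), 0.0)
        # Air-noise floor outside the brain (raw scans are not skull-stripped).
        air = np.abs(rng.normal(0.0, AIR_NOISE_SD, size=img.shape))
        raw[:, ci] = img + np.where(brain_masks, 0.0, air)

    # Skull-strip + per-channel percentile normalization for the model input.
    norm = np.zeros_like(raw)
    for ci in range(len(CHANNELS)):
        vals = raw[:, ci][brain_masks]
        scale = np.percentile(vals, normalize_percentile)
        if scale <= 0:
            raise SegAuditError("degenerate intensities: normalization scale <= 0")
        norm[:, ci] = np.where(brain_masks, raw[:, ci] / scale, 0.0)

    pid = patient_id or f"{phenotype.grade_group}-{site.site_code}-{rng.integers(10**6):06d}"
    case = PatientCase(
        patient_id=pid,
        site_code=site.site_code,
        grade_group=phenotype.grade_group,
        slices=norm,
        gt_masks=gt_masks,
        brain_masks=brain_masks,
        raw_slices=raw,
    )
    if with_components:
        return case, components
    return case


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation configuration: patients per (split, grade), image
    geometry, phenotypes and site rosters."""

    patients: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "train": {"GBM": 6, "LGG": 6},
            "validation": {"GBM": 4, "LGG": 4},
            "test": {"GBM": 5, "LGG": 6},
        }
    )
    n_slices: int = 16
    shape: tuple[int, int] = DEFAULT_SHAPE
    gbm_sites: tuple[SiteEffect, ...] = DEFAULT_GBM_SITES
    lgg_sites: tuple[SiteEffect, ...] = DEFAULT_LGG_SITES

    def __post_init__(self) -> None:
        for split, counts in self.patients.items():
            for g in ("GBM", "LGG"):
                if counts.get(g, 0) < 1:
                    raise SegAuditError(
                        f"need >= 1 patient per (split, grade); got {counts} for {split}"
                    )


def generate_cohorts(
    config: SynthConfig, seed: int
) -> dict[str, dict[str, Cohort]]:
    """Generate the 3x3 cohort grid {train,validation,test} x {GBM,LGG,ALL}.

    Patients are disjoint across splits (globally unique ids); sites rotate
    round-robin within each grade group so every site appears in every split.
    """
    root = np.random.SeedSequence(seed)
    out: dict[str, dict[str, Cohort]] = {}
    phenos = {"GBM": gbm_phenotype(), "LGG": lgg_phenotype()}
    sites = {"GBM": config.gbm_sites, "LGG": config.lgg_sites}
    counter = 0
    for split in ("train", "validation", "test"):
        by_grade: dict[str, Cohort] = {}
        for grade in ("GBM", "LGG"):
            n = config.patients[split][grade]
            cases = []
            for j in range(n):
                counter += 1
                site = sites[grade][j % len(sites[grade])]
                child = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(counter,)
                )
                cases.append(
                    generate_patient(
                        child,
                        phenos[grade],
                        site,
                        n_slices=config.n_slices,
                        shape=config.shape,
                        patient_id=f"SYN-{grade}-{site.site_code}-{counter:04d}",
                    )
                )
            by_grade[grade] = Cohort(name=grade, cases=cases, split=split)
        by_grade["ALL"] = make_all_cohort(by_grade["GBM"], by_grade["LGG"])
        out[split] = by_grade
    return out


# ---------------------------------------------------------------------------
# Toy differentiable segmenter
# ---------------------------------------------------------------------------

@dataclass
class ToyPredictorParams:
    """Training configuration of the pixelwise logistic scorer."""

    local_size: int = 5  # box size of the local-mean features (px)
    learning_rate: float = 2.0
    iterations: int = 300
    max_slices: int = 48  # slices sampled from the training cohort
    dice_smooth: float = 1.0
    seed: int = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class ToyPredictor(Predictor):
    """Pixelwise logistic segmenter over channel intensities and local means.

    The logit at pixel i is ``z_i = sum_c wd_c x_ci + sum_c wl_c m_ci + b``
    where ``m_c`` is a zero-padded box mean of channel c.  The training loss
    is soft Dice over brain pixels.  Because the box filter with zero padding
    is a self-adjoint linear operator, the input gradient of the loss has the
    closed form ``wd_c g + wl_c box(g)`` with ``g = dL/dz``.
    """

    def __init__(
        self,
        w_direct: np.ndarray,
        w_local: np.ndarray,
        bias: float,
        local_size: int = 5,
        dice_smooth: float = 1.0,
    ) -> None:
        self.w_direct = np.asarray(w_direct, dtype=float)
        self.w_local = np.asarray(w_local, dtype=float)
        if self.w_direct.shape != (len(CHANNELS),) or self.w_local.shape != (
            len(CHANNELS),
        ):
            raise SegAuditError("weights must have one entry per channel")
        self.bias = float(bias)
        self.local_size = int(local_size)
        self.dice_smooth = float(dice_smooth)

    # -- features ----------------------------------------------------------
    def _local_mean(self, img2d: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(img2d, size=self.local_size, mode="constant")

    def predict_logits(self, pixels: np.ndarray) -> np.ndarray:
        px = np.asarray(pixels, dtype=float)
        if px.ndim != 3 or px.shape[0] != len(CHANNELS):
            raise SegAuditError(f"expected (4, H, W) input, got {px.shape}")
        z = np.full(px.shape[1:], self.bias)
        for c in range(len(CHANNELS)):
            z += self.w_direct[c] * px[c]
            z += self.w_local[c] * self._local_mean(px[c])
        return z

    # -- soft Dice loss and gradients ---------------------------------------
    def _dice_loss_and_gz(
        self, pixels: np.ndarray, gt_mask: np.ndarray, brain_mask: np.ndarray
    ) -> tuple[float, np.ndarray]:
        z = self.predict_logits(pixels)
        p = _sigmoid(z)
        m = brain_mask
        y = gt_mask.astype(float)
        eps = self.dice_smooth
        num = 2.0 * float((p * y)[m].sum()) + eps
        den = float(p[m].sum() + y[m].sum()) + eps
        loss = 1.0 - num / den
        # dL/dp_i = -(2 y_i den - num) / den^2 on brain pixels
        dldp = np.where(m, -(2.0 * y * den - num) / den**2, 0.0)
        gz = dldp * p * (1.0 - p)
        return loss, gz

    def loss_input_gradient(self, pixels: np.ndarray, gt_mask: np.ndarray) -> np.ndarray:
        """Closed-form gradient of soft Dice loss w.r.t. the input image.

        The brain mask is derived from the input's nonzero support, matching
        how the loss itself is restricted at evaluation time.
        """
        px = np.asarray(pixels, dtype=float)
        brain = np.any(px != 0, axis=0)
        if not brain.any():
            raise SegAuditError("all-zero input: no brain to attack")
        _, gz = self._dice_loss_and_gz(px, np.asarray(gt_mask, dtype=bool), brain)
        grad = np.zeros_like(px)
        for c in range(len(CHANNELS)):
            grad[c] = self.w_direct[c] * gz + self.w_local[c] * self._local_mean(gz)
        return grad

    def dice_loss(self, pixels: np.ndarray, gt_mask: np.ndarray) -> float:
        px = np.asarray(pixels, dtype=float)
        brain = np.any(px != 0, axis=0)
        loss, _ = self._dice_loss_and_gz(px, np.asarray(gt_mask, dtype=bool), brain)
        return loss


def train_toy_predictor(
    cohort: Cohort, config: ToyPredictorParams | None = None
) -> ToyPredictor:
    """Fit the pixelwise logistic scorer by full-batch gradient descent on
    soft Dice loss over slices sampled from the training cohort.

    Deterministic given the config seed.  Slices are sampled uniformly across
    patients, preferring slices that contain tumor (the loss is vacuous on
    tumor-free slices).
    """
    config = config or ToyPredictorParams()
    if len(cohort) == 0:
        raise SegAuditError("empty training cohort")
    rng = np.random.default_rng(config.seed)

    # Collect candidate (case, slice) pairs with tumor present.
    pool = [
        (ci, si)
        for ci, case in enumerate(cohort.cases)
        for si in range(case.n_slices)
        if case.gt_masks[si].any()
    ]
    if not pool:
        raise SegAuditError("training cohort has no tumor pixels")
    if len(pool) > config.max_slices:
        idx = rng.choice(len(pool), size=config.max_slices, replace=False)
        pool = [pool[i] for i in sorted(idx)]

    # Precompute pooled features over brain pixels of the sampled slices.
    feats, labels = [], []
    for ci, si in pool:
        case = cohort.cases[ci]
        px = case.slices[si]
        m = case.brain_masks[si]
        f = np.empty((int(m.sum()), 2 * len(CHANNELS)))
        for c in range(len(CHANNELS)):
            f[:, c] = px[c][m]
            f[:, len(CHANNELS) + c] = ndimage.uniform_filter(
                px[c], size=config.local_size, mode="constant"
            )[m]
        feats.append(f)
        labels.append(case.gt_masks[si][m].astype(float))
    X = np.concatenate(feats)  # (N, 8)
    y = np.concatenate(labels)

    w = np.zeros(X.shape[1])
    b = 0.0
    eps = config.dice_smooth
    sy = y.sum()
    for _ in range(config.iterations):
        z = X @ w + b
        p = _sigmoid(z)
        num = 2.0 * float(p @ y) + eps
        den = float(p.sum() + sy) + eps
        dldp = -(2.0 * y * den - num) / den**2
        g = dldp * p * (1.0 - p)
        gw = X.T @ g
        gb = g.sum()
        # The soft-Dice gradient is scale-free in the pixel count (each term
        # is O(1/N)), so a fixed step size works across cohort sizes.
        w -= config.learning_rate * gw
        b -= config.learning_rate * gb

    return ToyPredictor(
        w_direct=w[: len(CHANNELS)],
        w_local=w[len(CHANNELS) :],
        bias=b,
        local_size=config.local_size,
        dice_smooth=config.dice_smooth,
    )
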