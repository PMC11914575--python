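"""Building (H&E, vascular-mask) training pairs from paired H&E/IHC.

Pipeline: cut corresponding patch pairs inside the tumor region, register
them (affine, then B-spline deformable, both multi-resolution, driven by the
shared hematoxylin concentration channel), center-crop to discard warp edge
effects, and binarize the aligned IHC into a CD31+ mask. Pixels classified
as non-specific staining artifacts count as negative, exactly like true
negatives. Pairs whose registration fails to improve the similarity metric
are excluded, and train/eval splitting is always by slide, never by patch.

The IHC 3-class labeling here is a deterministic stain-deconvolution +
morphology classifier: DAB-positive components that are large, solid and
round (blob-like, lacking vessel elongation) are called artifacts, the rest
CD31-positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from skimage import measure
from skimage.registration import phase_cross_correlation

from .stains import HDAB_BASIS, HE_BASIS, hematoxylin_channel, deconvolve_stains, sample_patches
from .synth import AffineMisalignment

__all__ = [
    "TrainingPair",
    "SlideImagePair",
    "RegistrationConfig",
    "RegistrationResult",
    "register_pair",
    "center_crop",
    "center_crop_pair",
    "classify_ihc",
    "binarize_ihc",
    "build_training_pairs",
    "mean_residual_displacement",
]


@dataclass
class TrainingPair:
    """An aligned H&E patch with its binary vascular mask (1 = CD31+)."""

    he_patch: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.he_patch.shape[:2] != self.mask.shape:
            raise ValueError("patch and mask dimensions differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


@dataclass
class SlideImagePair:
    """Pre-cut corresponding H&E / IHC images for one slide, with an optional
    tumor-region mask (all-tissue if omitted)."""

    slide_id: str
    he: np.ndarray
    ihc: np.ndarray
    region_mask: np.ndarray | None = None


@dataclass
class RegistrationConfig:
    pair_size: int = 512          # registration patch size
    crop_size: int = 416          # central crop after registration
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    affine_iterations: int = 120
    deformable: bool = True
    bspline_mesh: tuple[int, int] = (3, 3)
    bspline_iterations: int = 25
    improvement_margin: float = 0.0   # required NCC gain to accept
    n_patches_per_slide: int = 4
    eval_fraction: float = 0.25
    seed: int = 0


@dataclass
class RegistrationResult:
    transform: sitk.Transform
    aligned_ihc: np.ndarray
    similarity_before: float
    similarity_after: float
    success: bool


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def _resample(moving: np.ndarray, reference: sitk.Image,
              transform: sitk.Transform, order=sitk.sitkLinear,
              cval: float = 0.0) -> np.ndarray:
    img = sitk.GetImageFromArray(np.asarray(moving, dtype=np.float32))
    out = sitk.Resample(img, reference, transform, order, cval)
    return sitk.GetArrayFromImage(out)


def register_pair(he_patch: np.ndarray, ihc_patch: np.ndarray,
                  config: RegistrationConfig | None = None) -> RegistrationResult:
    """Align an IHC patch onto its H&E counterpart.

    Both images are reduced to their hematoxylin concentration channel (the
    nuclear stain both modalities share); an affine stage then an optional
    B-spline stage maximize intensity correlation over a multi-resolution
    pyramid. If the final normalized cross-correlation does not exceed the
    pre-registration value by ``improvement_margin``, the identity transform
    is returned with ``success=False`` so the pair can be excluded.
    """
    config = config or RegistrationConfig()
    sitk.ProcessObject_SetGlobalWarningDisplay(False)
    if he_patch.shape[:2] != ihc_patch.shape[:2]:
        raise ValueError("patch sizes differ")
    hem_f = hematoxylin_channel(he_patch, HE_BASIS).astype(np.float32)
    hem_m = hematoxylin_channel(ihc_patch, HDAB_BASIS).astype(np.float32)
    fixed = sitk.GetImageFromArray(hem_f)
    moving = sitk.GetImageFromArray(hem_m)
    sim_before = _ncc(hem_f, hem_m)
    identity = sitk.Transform(2, sitk.sitkIdentity)

    def _common(reg):
        reg.SetMetricAsCorrelation()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetShrinkFactorsPerLevel(list(config.shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(config.smoothing_sigmas))

    reg = sitk.ImageRegistrationMethod()
    _common(reg)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4,
        numberOfIterations=config.affine_iterations,
        gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    # phase correlation seeds the translation: pure gradient descent has a
    # small capture range on sparse vascular content
    shift = phase_cross_correlation(hem_f, hem_m)[0]
    init = sitk.AffineTransform(init)
    init.SetTranslation((-float(shift[1]), -float(shift[0])))
    reg.SetInitialTransform(init, inPlace=False)
    try:
        affine = reg.Execute(fixed, moving)
    except RuntimeError:
        affine = None

    candidates: list[sitk.Transform] = []
    if affine is not None:
        candidates.append(affine)
    if affine is not None and config.deformable:
        reg2 = sitk.ImageRegistrationMethod()
        _common(reg2)
        reg2.SetOptimizerAsGradientDescent(
            learningRate=0.5, numberOfIterations=config.bspline_iterations,
            convergenceMinimumValue=1e-7)
        reg2.SetOptimizerScalesFromPhysicalShift()
        reg2.SetMovingInitialTransform(affine)
        bspline = sitk.BSplineTransformInitializer(
            fixed, list(config.bspline_mesh))
        reg2.SetInitialTransform(bspline, inPlace=False)
        try:
            bspline_opt = reg2.Execute(fixed, moving)
            comp = sitk.CompositeTransform(2)
            comp.AddTransform(affine)
            comp.AddTransform(bspline_opt)   # applied first, then the affine
            candidates.append(comp)
        except RuntimeError:
            pass

    # never worsen the metric: the identity is always a candidate, so the
    # reported similarity is monotone in the registration
    final, sim_after = identity, sim_before
    for cand in candidates:
        sim = _ncc(hem_f, _resample(hem_m, fixed, cand))
        if sim > sim_after:
            final, sim_after = cand, sim

    if sim_after < sim_before + config.improvement_margin:
        return RegistrationResult(
            transform=identity,
            aligned_ihc=np.asarray(ihc_patch).copy(),
            similarity_before=sim_before,
            similarity_after=sim_before,
            success=False,
        )
    if final is identity:
        return RegistrationResult(identity, np.asarray(ihc_patch).copy(),
                                  sim_before, sim_before, True)

    aligned = np.stack(
        [_resample(ihc_patch[..., ch], fixed, final, cval=float(ihc_patch[..., ch].mean()))
         for ch in range(3)], axis=-1)
    aligned = np.clip(np.round(aligned), 0, 255).astype(np.uint8)
    return RegistrationResult(final, aligned, sim_before, sim_after, True)


def mean_residual_displacement(transform: sitk.Transform,
                               misalignment: AffineMisalignment,
                               shape: tuple[int, int],
                               central_margin: float = 0.25,
                               grid_n: int = 9) -> float:
    """Mean distance, over a central grid, between where the recovered
    transform sends each point and where the inverse of the planted warp
    sends it. The recovered fixed-to-moving map should undo the planted
    pull-back warp, i.e. equal its inverse; zero means perfect recovery."""
    h, w = shape
    rows = np.linspace(central_margin * h, (1 - central_margin) * h, grid_n)
    cols = np.linspace(central_margin * w, (1 - central_margin) * w, grid_n)
    ctr = (np.array([h, w], dtype=float) - 1) / 2
    minv = np.linalg.inv(misalignment.matrix)
    t = np.asarray(misalignment.translation, dtype=float)
    errs = []
    for r in rows:
        for c in cols:
            true_rc = minv @ (np.array([r, c]) - ctr - t) + ctr
            x, y = transform.TransformPoint((float(c), float(r)))
            errs.append(np.hypot(y - true_rc[0], x - true_rc[1]))
    return float(np.mean(errs))


def center_crop(image: np.ndarray, crop_size: int = 416) -> np.ndarray:
    """Centered crop; refuses inputs smaller than the crop."""
    h, w = image.shape[:2]
    if h < crop_size or w < crop_size:
        raise ValueError(f"input {h}x{w} smaller than crop {crop_size}")
    r0 = (h - crop_size) // 2
    c0 = (w - crop_size) // 2
    return image[r0:r0 + crop_size, c0:c0 + crop_size]


def center_crop_pair(a: np.ndarray, b: np.ndarray,
                     crop_size: int = 416) -> tuple[np.ndarray, np.ndarray]:
    """Crop both modalities identically."""
    return center_crop(a, crop_size), center_crop(b, crop_size)


def classify_ihc(ihc_patch: np.ndarray, dab_threshold: float = 0.25,
                 eccentricity_max: float = 0.92,
                 solidity_min: float = 0.85) -> np.ndarray:
    """3-class labeling of an IHC patch: 0 negative, 1 CD31+, 2 artifact.

    DAB concentration above ``dab_threshold`` marks candidate staining;
    connected components that are nearly convex AND round are called
    artifacts (non-specific blobs); elongated or branched ones — vessels
    fail either the solidity or the eccentricity test — stay CD31-positive.
    A relaxed-solidity clause catches blobs with threshold holes, which stay
    very round but lose convexity.
    """
    dab = deconvolve_stains(ihc_patch, HDAB_BASIS)[..., 1]
    cand = dab > dab_threshold
    labels = np.zeros(cand.shape, dtype=np.uint8)
    comp = measure.label(cand, connectivity=2)
    for region in measure.regionprops(comp):
        blobby = (region.solidity >= solidity_min
                  and region.eccentricity <= eccentricity_max) or (
            region.solidity >= 0.75 and region.eccentricity <= 0.6)
        labels[comp == region.label] = 2 if blobby else 1
    return labels


def binarize_ihc(ihc_patch: np.ndarray, **kwargs) -> np.ndarray:
    """Binary vascular mask from IHC: artifact pixels are treated as
    negative staining, so only class 1 survives."""
    return (classify_ihc(ihc_patch, **kwargs) == 1).astype(np.uint8)


def build_training_pairs(
    slide_pairs: Sequence[SlideImagePair],
    config: RegistrationConfig | None = None,
) -> dict:
    """Sample, register, crop and binarize patch pairs for every slide, then
    split by slide.

    Returns ``{"train": [TrainingPair...], "eval": [...], "report": {...}}``.
    Pairs failing registration QC are dropped; a slide with zero surviving
    pairs is skipped with a warning. The split partitions slides (seeded
    shuffle, ``eval_fraction`` of slides to eval), so no slide contributes
    patches to both partitions.
    """
    config = config or RegistrationConfig()
    rng = np.random.default_rng(config.seed)
    per_slide: dict[str, list[TrainingPair]] = {}
    n_failed = 0
    for sp in slide_pairs:
        region = sp.region_mask if sp.region_mask is not None \
            else np.ones(sp.he.shape[:2], dtype=bool)
        coords = sample_patches(region, config.pair_size,
                                config.n_patches_per_slide, rng=rng)
        pairs = []
        for coord in coords:
            sl = np.s_[coord.y:coord.y + coord.height, coord.x:coord.x + coord.width]
            he_p, ihc_p = sp.he[sl], sp.ihc[sl]
            reg = register_pair(he_p, ihc_p, config)
            if not reg.success:
                n_failed += 1
                continue
            he_c, ihc_c = center_crop_pair(he_p, reg.aligned_ihc, config.crop_size)
            pairs.append(TrainingPair(
                he_patch=he_c,
                mask=binarize_ihc(ihc_c),
                provenance={"slide_id": sp.slide_id, "coords": (coord.x, coord.y),
                            "transform_used": "affine+bspline" if config.deformable else "affine"},
            ))
        if not pairs:
            warnings.warn(f"slide {sp.slide_id}: no pair survived registration QC",
                          stacklevel=2)
            continue
        per_slide[sp.slide_id] = pairs

    slide_ids = sorted(per_slide)
    rng.shuffle(slide_ids)
    n_eval = int(round(config.eval_fraction * len(slide_ids)))
    eval_ids = set(slide_ids[:n_eval])
    out = {"train": [], "eval": [],
           "report": {"n_failed_registration": n_failed,
                      "eval_slides": sorted(eval_ids),
                      "train_slides": sorted(set(slide_ids) - eval_ids)}}
    for sid, pairs in per_slide.items():
        out["eval" if sid in eval_ids else "train"].extend(pairs)
    return out
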