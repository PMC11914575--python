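"""Color-space operations on H&E / IHC patches.

Optical-density stain deconvolution (Ruifrok-Johnston style), Reinhard-type
color normalization in Lab space, the training-time augmentation (mirroring,
HED channel multipliers, saturation fade), magnification standardization to
~0.5 um/px, and uniform patch sampling inside a tumor-region mask.

Conventions used throughout: images are 8-bit RGB numpy arrays (H, W, 3);
patch coordinates are 0-based, top-left anchored, half-open, reported as
(x, y, width, height) with x = column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage import color as skcolor
from skimage.transform import downscale_local_mean

__all__ = [
    "StainBasis",
    "HE_BASIS",
    "HDAB_BASIS",
    "ReferenceStats",
    "AugmentParams",
    "PatchCoord",
    "deconvolve_stains",
    "recompose_stains",
    "hematoxylin_channel",
    "compute_reference_stats",
    "normalize_color",
    "augment_patch",
    "standardize_magnification",
    "sample_patches",
]


@dataclass(frozen=True)
class StainBasis:
    """3x3 matrix of unit optical-density vectors, rows = stains.

    Row order is (hematoxylin, eosin-or-DAB, residual). Rows are renormalized
    to unit length at construction and the matrix must be well conditioned.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "stain2", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain basis must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if (norms == 0).any():
            raise ValueError("zero stain vector")
        m = m / norms[:, None]
        if np.linalg.cond(m) > 1e6:
            raise ValueError("stain basis is singular or near-singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_inv", np.linalg.inv(m))

    @property
    def inverse(self) -> np.ndarray:
        return self._inv


def _third_vector(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    v = np.cross(a, b)
    return v / np.linalg.norm(v)


# Ruifrok-Johnston published OD vectors (as distributed with scikit-image's
# HED matrices). The residual row is the unit vector orthogonal to the two
# physical stains.
_H = np.array([0.65, 0.70, 0.29])
_E = np.array([0.07, 0.99, 0.11])
_D = np.array([0.27, 0.57, 0.78])

HE_BASIS = StainBasis(np.array([_H, _E, _third_vector(_H, _E)]),
                      names=("hematoxylin", "eosin", "residual"))
HDAB_BASIS = StainBasis(np.array([_H, _D, _third_vector(_H, _D)]),
                        names=("hematoxylin", "dab", "residual"))


def deconvolve_stains(rgb: np.ndarray, basis: StainBasis = HE_BASIS) -> np.ndarray:
    """Unmix an 8-bit RGB image into per-stain concentration channels.

    Optical density is OD = -log((I + 1) / 256) per channel (the +1 keeps
    black pixels finite); concentrations are OD projected through the basis
    inverse and clipped at zero. Returns float (H, W, 3), channels in the
    basis row order.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    od = -np.log((rgb.astype(np.float64) + 1.0) / 256.0)
    conc = od @ basis.inverse
    return np.clip(conc, 0.0, None)


def recompose_stains(conc: np.ndarray, basis: StainBasis = HE_BASIS) -> np.ndarray:
    """Inverse of :func:`deconvolve_stains`: concentrations back to 8-bit RGB."""
    od = np.asarray(conc, dtype=np.float64) @ basis.matrix
    rgb = 256.0 * np.exp(-od) - 1.0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def hematoxylin_channel(rgb: np.ndarray, basis: StainBasis) -> np.ndarray:
    """The shared nuclear-stain concentration map used for cross-modality
    registration (H&E vs IHC both carry hematoxylin)."""
    return deconvolve_stains(rgb, basis)[..., 0]


# ---------------------------------------------------------------------------
# color normalization (Reinhard mean/sd matching in Lab)


class ReferenceStats(NamedTuple):
    mean: np.ndarray  # per-channel Lab mean
    sd: np.ndarray    # per-channel Lab sd


def compute_reference_stats(images) -> ReferenceStats:
    """Pool per-channel Lab statistics over a set of reference images."""
    labs = [skcolor.rgb2lab(np.asarray(im) / 255.0).reshape(-1, 3) for im in images]
    allpix = np.concatenate(labs, axis=0)
    return ReferenceStats(mean=allpix.mean(axis=0), sd=allpix.std(axis=0))


def normalize_color(image: np.ndarray, reference_stats: ReferenceStats) -> np.ndarray:
    """Reinhard normalization: shift/scale each Lab channel to the reference
    mean/sd, then convert back to 8-bit RGB.

    A constant-color image has zero variance and nothing to rescale; it is
    returned unchanged with a warning.
    """
    image = np.asarray(image)
    lab = skcolor.rgb2lab(image / 255.0)
    sd = lab.reshape(-1, 3).std(axis=0)
    if (sd < 1e-6).any():
        warnings.warn("constant-color input: normalization skipped", stacklevel=2)
        return image.copy()
    mean = lab.reshape(-1, 3).mean(axis=0)
    lab = (lab - mean) / sd * reference_stats.sd + reference_stats.mean
    rgb = skcolor.lab2rgb(lab)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentParams:
    """Training augmentation: random mirroring, per-channel multiplicative
    jitter of the HED stain concentrations (default range (0.975, 1.025)),
    and a random saturation multiplier (default range (0, 0.5), emulating
    faded slides)."""

    hed_range: tuple[float, float] = (0.975, 1.025)
    saturation_range: tuple[float, float] = (0.0, 0.5)
    mirror: bool = True
    basis: StainBasis = field(default=HE_BASIS)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("hed_range", self.hed_range),
                               ("saturation_range", self.saturation_range)):
            if lo > hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")


def augment_patch(patch: np.ndarray, rng: np.random.Generator,
                  params: AugmentParams = AugmentParams()) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to a patch.

    The mirror is drawn uniformly over {identity, horizontal, vertical,
    both}; HED multipliers act in deconvolved space and are recomposed.
    Degenerate parameter draws (all multipliers exactly 1) skip their stage,
    so identity parameters give the identity map exactly.
    """
    out = np.asarray(patch)
    if params.mirror:
        flip = rng.integers(0, 4)
        if flip & 1:
            out = out[:, ::-1]
        if flip & 2:
            out = out[::-1, :]
    mult = rng.uniform(*params.hed_range, size=3)
    if not np.all(mult == 1.0):
        conc = deconvolve_stains(out, params.basis) * mult
        out = recompose_stains(conc, params.basis)
    sat = rng.uniform(*params.saturation_range)
    if sat != 1.0:
        hsv = skcolor.rgb2hsv(np.ascontiguousarray(out) / 255.0)
        hsv[..., 1] *= sat
        out = np.clip(np.round(skcolor.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# magnification


def standardize_magnification(image: np.ndarray, source_mpp: float,
                              rel_tol: float = 0.15) -> np.ndarray:
    """Bring an image to the model's working resolution of ~0.5 um/px.

    40X scans (~0.25 um/px) are area-downsampled by a factor of 2; 20X scans
    (~0.5 um/px) pass through. Any other resolution is refused.
    """
    image = np.asarray(image)
    if abs(source_mpp - 0.5) <= rel_tol * 0.5:
        return image
    if abs(source_mpp - 0.25) <= rel_tol * 0.25:
        factors = (2, 2) + (1,) * (image.ndim - 2)
        down = downscale_local_mean(image.astype(np.float64), factors)
        return np.clip(np.round(down), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported resolution {source_mpp} um/px (need ~0.25 or ~0.5)")


# ---------------------------------------------------------------------------
# patch sampling


class PatchCoord(NamedTuple):
    x: int  # column of top-left corner
    y: int  # row of top-left corner
    width: int
    height: int


def sample_patches(
    region_mask: np.ndarray,
    patch_size: int,
    n_target: int,
    density_cap: float = 3.0,
    rng: np.random.Generator | None = None,
) -> list[PatchCoord]:
    """Place patches uniformly at random with every patch fully inside the
    region.

    The count is min(n_target, floor(density_cap * region_area /
    patch_area)): the cap bounds total sampled area relative to the region so
    small regions are not oversampled. A region that cannot hold a single
    patch yields an empty list with a warning.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = rng or np.random.default_rng()
    region = np.asarray(region_mask).astype(bool)
    if not region.any():
        warnings.warn("empty region mask: no patches sampled", stacklevel=2)
        return []
    # window sums via 2-D cumulative sums: valid anchors are positions whose
    # patch window lies entirely in the region
    p = patch_size
    padded = np.pad(region.astype(np.int64), ((1, 0), (1, 0)))
    s = padded.cumsum(axis=0).cumsum(axis=1)
    h, w = region.shape
    if h < p or w < p:
        warnings.warn("region smaller than one patch", stacklevel=2)
        return []
    win = s[p:, p:] - s[:-p, p:] - s[p:, :-p] + s[:-p, :-p]
    anchors = np.argwhere(win == p * p)
    if len(anchors) == 0:
        warnings.warn("no window of the region fits a full patch", stacklevel=2)
        return []
    cap = int(density_cap * region.sum() / (p * p))
    n = min(n_target, max(cap, 0))
    if n == 0:
        warnings.warn("density cap excludes all patches for this region",
                      stacklevel=2)
        return []
    picks = anchors[rng.integers(0, len(anchors), size=n)]
    return [PatchCoord(x=int(c), y=int(r), width=p, height=p) for r, c in picks]
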