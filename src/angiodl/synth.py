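"""Synthetic histology fixtures with known ground truth.

Everything downstream — stain math, registration, the three-arm network,
survival stratification — is exercised against data produced here, where the
vascular geometry, the slide-level Angioscore, the IHC artifact labels and the
survival hazards are all known exactly.

The generators are fully deterministic: the same seed and parameters give
byte-identical images and tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .expression import ExpressionTable, SIGNATURE_GENES
from .survival import SurvivalTable

__all__ = [
    "SyntheticPatch",
    "SyntheticSlideFixture",
    "AffineMisalignment",
    "VesselStyle",
    "UnsatisfiableFractionError",
    "make_vessel_patch",
    "make_synthetic_slide",
    "make_ihc_pair",
    "make_expression_matrix",
    "make_survival_cohort",
    "angio_link",
    "save_slide_fixture",
]


class UnsatisfiableFractionError(ValueError):
    """Requested vessel area fraction cannot be generated."""


# ---------------------------------------------------------------------------
# palettes (8-bit RGB). Vessels are deliberately eosin-poor (pale, blue-shifted
# lumen with a mauve endothelial rim) so they are separable from the pink
# eosin background by color alone — a small network can learn them.
_HE_BACKGROUND = np.array([228, 178, 205], dtype=np.float32)
_HE_NUCLEUS = np.array([78, 62, 132], dtype=np.float32)
_HE_LUMEN = np.array([240, 236, 244], dtype=np.float32)
_HE_ENDOTHELIUM = np.array([148, 104, 158], dtype=np.float32)

_IHC_BACKGROUND = np.array([236, 233, 238], dtype=np.float32)
_IHC_NUCLEUS = np.array([88, 92, 168], dtype=np.float32)
_IHC_DAB = np.array([118, 78, 40], dtype=np.float32)
_IHC_ARTIFACT = np.array([150, 104, 58], dtype=np.float32)


@dataclass(frozen=True)
class VesselStyle:
    """Rendering parameters for planted vessel networks.

    Vessels are branching random-walk strokes of varying width; nuclei are
    small dark disks scattered over the background. Units are pixels unless
    noted.
    """

    stroke_len_frac: float = 0.5      # mean stroke length as fraction of image side
    width_range: tuple[int, int] = (1, 3)
    branch_prob: float = 0.35         # chance a stroke spawns one branch
    turn_sd: float = 0.35             # radians, per-step direction jitter
    nucleus_density: float = 0.004    # nuclei per pixel^2
    nucleus_radius: tuple[int, int] = (2, 4)
    texture_sd: float = 6.0           # background RGB noise, 8-bit units
    fraction_tol: float = 0.03        # absolute tolerance on achieved fraction
    max_strokes: int = 4000


@dataclass
class SyntheticPatch:
    """An H&E-like patch with its planted binary vessel mask.

    ``vessel_fraction`` is exactly ``mask.mean()``. ``nuclei`` stores the
    (row, col, radius) layout so a paired IHC rendering shares the same
    hematoxylin structure (needed for registration fixtures).
    """

    rgb: np.ndarray
    mask: np.ndarray
    vessel_fraction: float
    seed: int
    nuclei: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.mask.shape:
            raise ValueError("rgb and mask dimensions differ")


@dataclass
class SyntheticSlideFixture:
    """A bundle of patches standing in for one slide.

    ``true_angioscore`` is the slide's target score: the monotone link
    g(f) = a*log(1 + b*f) of the mean planted vessel fraction, plus optional
    Gaussian noise. With ``noise_sd == 0`` the score is the exact closed form.
    """

    slide_id: str
    patches: list[SyntheticPatch]
    true_fraction: float
    true_angioscore: float
    noise_sd: float
    link_params: dict = field(default_factory=lambda: {"a": 1.0, "b": 10.0})


@dataclass(frozen=True)
class AffineMisalignment:
    """Planted 2-D affine warp, in output-to-input (pull-back) convention.

    The warped image is ``out(x) = in(M @ (x - c) + c + translation)`` with
    ``c`` the image center, matching ``scipy.ndimage.affine_transform``.
    ``translation`` is (row, col) in pixels.
    """

    translation: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    scale: float = 1.0

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return self.scale * r

    def is_identity(self) -> bool:
        return (
            self.translation == (0.0, 0.0)
            and self.rotation_deg == 0.0
            and self.scale == 1.0
        )


def angio_link(fraction, a: float = 1.0, b: float = 10.0):
    """The generator's slide-score link g(f) = a*log(1 + b*f), strictly
    increasing on [0, 1] for a, b > 0."""
    if a <= 0 or b <= 0:
        raise ValueError("link parameters must be positive")
    return a * np.log1p(b * np.asarray(fraction, dtype=float))


# ---------------------------------------------------------------------------
# vessel patch generation


def _draw_disk(canvas: np.ndarray, r: float, c: float, radius: float) -> None:
    h, w = canvas.shape
    r0, r1 = max(int(r - radius), 0), min(int(r + radius) + 1, h)
    c0, c1 = max(int(c - radius), 0), min(int(c + radius) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] |= (yy - r) ** 2 + (xx - c) ** 2 <= radius**2


def _walk_stroke(mask: np.ndarray, rng: np.random.Generator, style: VesselStyle,
                 start=None, direction=None) -> None:
    h, w = mask.shape
    n_steps = max(4, int(rng.normal(style.stroke_len_frac, 0.15 * style.stroke_len_frac) * h))
    if start is None:
        pos = rng.uniform(0, [h, w])
    else:
        pos = np.array(start, dtype=float)
    theta = rng.uniform(0, 2 * np.pi) if direction is None else direction
    width = rng.uniform(*style.width_range)
    branch_at = rng.integers(n_steps // 3, n_steps) if rng.random() < style.branch_prob else -1
    for step in range(n_steps):
        theta += rng.normal(0.0, style.turn_sd)
        pos += [np.sin(theta), np.cos(theta)]
        pos[0] = np.clip(pos[0], 0, h - 1)
        pos[1] = np.clip(pos[1], 0, w - 1)
        _draw_disk(mask, pos[0], pos[1], width)
        if step == branch_at:
            _walk_stroke(
                mask, rng,
                VesselStyle(**{**style.__dict__, "branch_prob": 0.0,
                               "stroke_len_frac": style.stroke_len_frac / 2}),
                start=pos.copy(),
                direction=theta + rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.2),
            )


def _scatter_nuclei(rng: np.random.Generator, size: int, style: VesselStyle) -> np.ndarray:
    n = rng.poisson(style.nucleus_density * size * size)
    if n == 0:
        return np.empty((0, 3))
    rows = rng.uniform(0, size, n)
    cols = rng.uniform(0, size, n)
    radii = rng.uniform(*style.nucleus_radius, n)
    return np.column_stack([rows, cols, radii])


def _paint(canvas: np.ndarray, where: np.ndarray, color: np.ndarray) -> None:
    canvas[where] = color


def make_vessel_patch(
    seed: int,
    size_px: int = 128,
    target_fraction: float = 0.05,
    style_params: VesselStyle | None = None,
) -> SyntheticPatch:
    """Generate one H&E-like patch with a planted vessel network.

    Strokes are added iteratively until the mask fraction is within
    ``style.fraction_tol`` of ``target_fraction`` (the achieved fraction is
    recorded exactly). Fractions at or above 0.5 are refused: the stroke
    process cannot fill that densely without merging into a blob.
    """
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    if not 0.0 <= target_fraction < 0.5:
        raise UnsatisfiableFractionError(
            f"target_fraction must lie in [0, 0.5); got {target_fraction}"
        )
    style = style_params or VesselStyle()
    rng = np.random.default_rng(seed)

    # expected area fraction of one stroke: a strip of ~2*mean_width px per
    # step, plus the occasional half-length branch
    mean_w = np.mean(style.width_range)
    est_stroke_frac = (style.stroke_len_frac * size_px * 2 * mean_w / size_px**2
                       * (1.0 + 0.5 * style.branch_prob))
    mask = np.zeros((size_px, size_px), dtype=bool)
    # stroke placement is stochastic; a handful of attempts absorbs the rare
    # draw whose final stroke overshoots the band (relevant at small sizes,
    # where one stroke is several percent of the area)
    for _attempt in range(4):
        mask[:] = False
        strokes = 0
        while (mask.mean() < target_fraction - 0.8 * style.fraction_tol
               and strokes < style.max_strokes):
            # taper stroke length/width near the target so the final stroke
            # lands inside the tolerance band
            remaining = target_fraction - mask.mean()
            scale = float(np.clip(remaining / est_stroke_frac, 0.05, 1.0))
            if scale == 1.0:
                stroke_style = style
            else:
                lo, hi = style.width_range
                stroke_style = VesselStyle(
                    **{**style.__dict__,
                       "stroke_len_frac": style.stroke_len_frac * scale,
                       "width_range": (lo, max(lo, hi * np.sqrt(scale))),
                       "branch_prob": 0.0})
            _walk_stroke(mask, rng, stroke_style)
            strokes += 1
        if abs(mask.mean() - target_fraction) <= style.fraction_tol:
            break
    else:
        raise UnsatisfiableFractionError(
            f"could not reach fraction {target_fraction:.3f} "
            f"(achieved {mask.mean():.3f})"
        )

    nuclei = _scatter_nuclei(rng, size_px, style)

    rgb = np.empty((size_px, size_px, 3), dtype=np.float32)
    rgb[:] = _HE_BACKGROUND
    rgb += rng.normal(0.0, style.texture_sd, rgb.shape).astype(np.float32)
    nuc_canvas = np.zeros((size_px, size_px), dtype=bool)
    for r, c, rad in nuclei:
        _draw_disk(nuc_canvas, r, c, rad)
    _paint(rgb, nuc_canvas & ~mask, _HE_NUCLEUS)
    interior = ndimage.binary_erosion(mask, iterations=1)
    _paint(rgb, mask & ~interior, _HE_ENDOTHELIUM)
    _paint(rgb, interior, _HE_LUMEN)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    mask8 = mask.astype(np.uint8)
    return SyntheticPatch(
        rgb=rgb, mask=mask8, vessel_fraction=float(mask8.mean()),
        seed=seed, nuclei=nuclei,
    )


def make_synthetic_slide(
    seed: int,
    n_patches: int = 8,
    slide_fraction: float = 0.05,
    noise_sd: float = 0.0,
    link_params: dict | None = None,
    size_px: int = 128,
    style_params: VesselStyle | None = None,
    slide_id: str | None = None,
) -> SyntheticSlideFixture:
    """Generate a slide fixture: patches whose vessel fractions jitter around
    ``slide_fraction`` and a slide score tied to the realized mean fraction
    through the monotone link ``g``."""
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    link = dict(link_params or {"a": 1.0, "b": 10.0})
    rng = np.random.default_rng(seed)
    jitter_sd = 0.2 * slide_fraction + 0.002
    patches = []
    for _ in range(n_patches):
        f = float(np.clip(rng.normal(slide_fraction, jitter_sd), 0.0, 0.45))
        patch_seed = int(rng.integers(0, 2**31 - 1))
        patches.append(make_vessel_patch(patch_seed, size_px, f, style_params))
    true_fraction = float(np.mean([p.vessel_fraction for p in patches]))
    score = float(angio_link(true_fraction, **link))
    if noise_sd > 0:
        score += float(rng.normal(0.0, noise_sd))
    return SyntheticSlideFixture(
        slide_id=slide_id or f"synth-{seed}",
        patches=patches,
        true_fraction=true_fraction,
        true_angioscore=score,
        noise_sd=noise_sd,
        link_params=link,
    )


# ---------------------------------------------------------------------------
# paired IHC


def _warp_rgb(img: np.ndarray, mis: AffineMisalignment) -> np.ndarray:
    c = (np.array(img.shape[:2], dtype=float) - 1) / 2
    offset = c - mis.matrix @ c + np.asarray(mis.translation, dtype=float)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = ndimage.affine_transform(
            img[..., ch], mis.matrix, offset=offset, order=1,
            mode="constant", cval=float(_IHC_BACKGROUND[ch]),
        )
    return out


def _warp_labels(lab: np.ndarray, mis: AffineMisalignment) -> np.ndarray:
    c = (np.array(lab.shape, dtype=float) - 1) / 2
    offset = c - mis.matrix @ c + np.asarray(mis.translation, dtype=float)
    return ndimage.affine_transform(lab, mis.matrix, offset=offset, order=0,
                                    mode="constant", cval=0)


def make_ihc_pair(
    patch: SyntheticPatch,
    artifact_rate: float = 0.0,
    misalignment: AffineMisalignment | None = None,
    seed: int | None = None,
):
    """Render the DAB-stained counterpart of an H&E patch.

    Vessel pixels become DAB-brown over a hematoxylin counterstain that reuses
    the patch's nucleus layout (the shared structure registration relies on).
    Round non-specific brown blobs (label 2) are planted off-vessel until
    their pixel fraction is close to ``artifact_rate``. If a misalignment is
    given, both the image and the 3-class truth labels are warped by it and
    the applied transform is returned for registration tests.

    Returns ``(ihc_rgb, truth_labels, applied_transform)`` where labels are
    0 = negative, 1 = CD31-positive, 2 = artifact.
    """
    if not 0.0 <= artifact_rate <= 1.0:
        raise ValueError("artifact_rate must lie in [0, 1]")
    rng = np.random.default_rng(patch.seed + 7919 if seed is None else seed)
    size = patch.mask.shape[0]

    labels = patch.mask.astype(np.uint8).copy()
    if artifact_rate > 0:
        art = np.zeros_like(patch.mask, dtype=bool)
        # keep blobs clear of vessels and of each other: non-specific droplets
        # are isolated, and isolation keeps the 3-class ground truth clean
        guard = ndimage.binary_dilation(patch.mask.astype(bool), iterations=3)
        tries = 0
        while art.mean() < artifact_rate - 0.002 and tries < 4000:
            r, c = rng.uniform(0, size, 2)
            # absolute radius floor: droplets below ~25 px^2 are not rendered
            # (too small to carry a reliable morphology label)
            rad_lo = max(3.2, 0.02 * size)
            rad = rng.uniform(rad_lo, max(rad_lo + 1.0, 0.06 * size))
            blob = np.zeros_like(art)
            _draw_disk(blob, r, c, rad)
            margin = ndimage.binary_dilation(blob, iterations=2)
            if not (margin & (guard | art)).any():
                art |= blob
            tries += 1
        labels[art] = 2

    ihc = np.empty((size, size, 3), dtype=np.float32)
    ihc[:] = _IHC_BACKGROUND
    ihc += rng.normal(0.0, 4.0, ihc.shape).astype(np.float32)
    nuc = np.zeros((size, size), dtype=bool)
    for r, c, rad in patch.nuclei:
        _draw_disk(nuc, r, c, rad)
    _paint(ihc, nuc & (labels == 0), _IHC_NUCLEUS)
    _paint(ihc, labels == 1, _IHC_DAB)
    _paint(ihc, labels == 2, _IHC_ARTIFACT)
    ihc = np.clip(ihc, 0, 255).astype(np.uint8)

    mis = misalignment or AffineMisalignment()
    if not mis.is_identity():
        ihc = _warp_rgb(ihc, mis)
        labels = _warp_labels(labels, mis)
    return ihc, labels, mis


# ---------------------------------------------------------------------------
# expression + survival


def make_expression_matrix(
    fixtures: list[SyntheticSlideFixture],
    n_background_genes: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionTable:
    """Build an FPKM table whose six angiogenesis signature genes scale with
    each slide's true vessel fraction, on top of fraction-independent
    housekeeping genes.

    Signature FPKM for gene g in sample s is
    ``base_g * (0.2 + 8 * fraction_s) * exp(noise)``: strictly increasing in
    the fraction, so at ``noise_sd = 0`` the downstream Angioscore ranks
    samples exactly by vascularity.
    """
    if not fixtures:
        raise ValueError("fixtures must be non-empty")
    rng = np.random.default_rng(seed)
    samples = [f.slide_id for f in fixtures]
    fractions = np.array([f.true_fraction for f in fixtures])

    sig_base = np.array([30.0, 20.0, 5.0, 40.0, 15.0, 25.0])
    sig = sig_base[:, None] * (0.2 + 8.0 * fractions[None, :])
    if noise_sd > 0:
        sig = sig * np.exp(rng.normal(0.0, noise_sd, sig.shape))

    bg_names = [f"HK{i:04d}" for i in range(n_background_genes)]
    bg_level = rng.lognormal(3.0, 1.0, n_background_genes)
    bg = np.tile(bg_level[:, None], (1, len(samples)))
    if noise_sd > 0:
        bg = bg * np.exp(rng.normal(0.0, noise_sd, bg.shape))

    values = np.vstack([sig, bg]) if n_background_genes else sig
    genes = list(SIGNATURE_GENES) + bg_names
    return ExpressionTable.from_array(values, genes, samples, unit="FPKM")


def make_survival_cohort(
    n: int,
    beta: float = 1.0,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.0,
    score_source=None,
    seed: int = 0,
    time_dist: str = "exponential",
    weibull_shape: float = 1.5,
) -> SurvivalTable:
    """Simulate a proportional-hazards cohort whose hazard decreases with the
    angiogenesis score: ``h(t | score) = baseline_hazard * exp(-beta * score)``
    (higher score, better survival — the direction seen for vascular tumors
    under anti-angiogenic-relevant scoring).

    ``score_source`` may be an array of scores, a list of slide fixtures
    (their true scores are used), an object with ``rvs(size, random_state)``,
    or None for standard-normal scores. Censoring is by an independent
    Uniform(0, c) time with c calibrated so the realized censor fraction is
    close to ``censor_rate``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    if score_source is None:
        scores = rng.normal(0.0, 1.0, n)
    elif hasattr(score_source, "rvs"):
        scores = np.asarray(score_source.rvs(size=n, random_state=rng), dtype=float)
    elif (isinstance(score_source, (list, tuple)) and score_source
          and isinstance(score_source[0], SyntheticSlideFixture)):
        pool = np.array([f.true_angioscore for f in score_source])
        scores = pool[rng.integers(0, len(pool), n)] if len(pool) != n else pool.copy()
    else:
        scores = np.asarray(score_source, dtype=float)
        if scores.shape != (n,):
            raise ValueError("score array length must equal n")

    hazard = baseline_hazard * np.exp(-beta * scores)
    if time_dist == "exponential":
        t_event = rng.exponential(1.0 / hazard)
    elif time_dist == "weibull":
        # PH-consistent Weibull: S(t) = exp(-h * t^k)
        u = rng.uniform(0, 1, n)
        t_event = (-np.log(u) / hazard) ** (1.0 / weibull_shape)
    else:
        raise ValueError(f"unknown time_dist {time_dist!r}")

    if censor_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        u = rng.uniform(0, 1, n)

        def censored_frac(cmax):
            return float(np.mean(cmax * u < t_event))

        lo, hi = 1e-9, float(t_event.max()) * 10
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_frac(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        c = 0.5 * (lo + hi) * u
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-9)

    ids = [f"P{i:05d}" for i in range(n)]
    return SurvivalTable.from_arrays(ids, time, event, scores)


# ---------------------------------------------------------------------------
# on-disk fixture layout (PNG patches + masks, JSON manifest)


def save_slide_fixture(fixture: SyntheticSlideFixture, out_dir: str | Path) -> Path:
    from PIL import Image

    out = Path(out_dir) / fixture.slide_id
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, p in enumerate(fixture.patches):
        rgb_name, mask_name = f"patch_{i:03d}.png", f"mask_{i:03d}.png"
        Image.fromarray(p.rgb).save(out / rgb_name)
        Image.fromarray(p.mask, mode="L").save(out / mask_name)
        entries.append({"rgb": rgb_name, "mask": mask_name,
                        "vessel_fraction": p.vessel_fraction, "seed": p.seed})
    manifest = {
        "slide_id": fixture.slide_id,
        "true_fraction": fixture.true_fraction,
        "true_angioscore": fixture.true_angioscore,
        "noise_sd": fixture.noise_sd,
        "link_params": fixture.link_params,
        "patches": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
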