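"""The three-arm network, its losses, and mixed-batch construction.

One shared convolutional encoder splits into:

* a **mask arm** — encoder-decoder with a skip connection that predicts a
  2-class (vessel / non-vessel) probability map per pixel;
* an **angio arm** — further convolutions on the encoder bottleneck, global
  average pooling, and a linear readout giving one Angioscore per patch;
* a **consistency arm** — consumes *only* the mask arm's output: the global
  average of the positive-class probability map ("fractional positive
  activation") passed through a small learnt scalar nonlinearity to predict
  the same Angioscore.

Training mixes two batch kinds: RNA batches (32 patches = 4 slides x 8, the
slide's RNA Angioscore as target) scored by the batch MSE of slide-averaged
angio and consistency outputs, and mask batches (4 patches with binary
vessel masks) scored by 0.9*Dice + 0.1*class-weighted cross-entropy plus an
MSE consistency tie between the two scalar arms.

The consistency pooling uses the *soft* positive-class probabilities during
training so the arm stays differentiable; hard thresholding only happens at
inference when the percent-positive slide score is read out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "ModelConfig",
    "NetworkOutputs",
    "MixedBatch",
    "RnaSlide",
    "TrainingPairLike",
    "ThreeArmNet",
    "build_network",
    "loss_rna",
    "loss_seg",
    "loss_consistency",
    "make_rna_batch",
    "make_cd31_batch",
    "wcce_weights_from_pairs",
]

_ENCODER_CHANNELS = {"small": 8, "base": 16}


@dataclass
class ModelConfig:
    encoder: str = "small"               # encoder width profile
    pretrained_encoder: bool = False     # accepted for API parity; init is random
    patch_size: int = 128
    n_mask_classes: int = 2
    dice_weight: float = 0.9
    wcce_weight: float = 0.1
    wcce_class_weights: tuple[float, float] = (1.0, 1.0)
    cons_hidden: int = 2
    cons_stop_gradient: bool = True      # block backprop from cons into the mask
    rna_n_slides: int = 4
    rna_patches_per_slide: int = 8
    cd31_batch_size: int = 4
    threshold: float = 0.5               # inference percent-positive cutoff
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder not in _ENCODER_CHANNELS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if abs(self.dice_weight + self.wcce_weight - 1.0) > 1e-9:
            raise ValueError("dice_weight + wcce_weight must sum to 1")
        if self.patch_size % 2 != 0:
            raise ValueError("patch_size must be even (one 2x pooling level)")
        if self.n_mask_classes != 2:
            raise ValueError("only 2-class masks are supported")

    @property
    def rna_batch_size(self) -> int:
        return self.rna_n_slides * self.rna_patches_per_slide

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class NetworkOutputs:
    """Per-patch outputs: ``mask_prob`` is (N, 2, H, W) and sums to 1 over
    classes per pixel; ``angio`` and ``cons`` are length-N scalars."""

    mask_prob: np.ndarray | Tensor
    angio: np.ndarray | Tensor
    cons: np.ndarray | Tensor

    def detach(self) -> "NetworkOutputs":
        def d(v):
            return v.data.copy() if isinstance(v, Tensor) else v

        return NetworkOutputs(d(self.mask_prob), d(self.angio), d(self.cons))


@dataclass
class RnaSlide:
    """One slide's worth of RNA-supervised training data."""

    slide_id: str
    patches: list[np.ndarray]
    target: float


@dataclass
class TrainingPairLike:
    """Minimal (H&E patch, binary mask) pair the mask batches consume."""

    he_patch: np.ndarray
    mask: np.ndarray


@dataclass
class MixedBatch:
    kind: str                               # "RNA" or "CD31"
    patches: np.ndarray                     # (N, H, W, 3) uint8
    slide_ids: list[str] | None = None      # RNA only, one per patch
    targets: dict[str, float] | None = None  # RNA: slide -> T^Angio
    masks: np.ndarray | None = None         # CD31: (N, H, W) binary
    with_replacement: bool = False          # CD31 fallback flag

    def __post_init__(self) -> None:
        if self.kind not in ("RNA", "CD31"):
            raise ValueError(f"unknown batch kind {self.kind!r}")


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class ThreeArmNet:
    """Compact encoder-decoder with angio and consistency heads.

    Width is set by the encoder profile (8 or 16 base channels); there is one
    2x pooling level with a skip connection, which keeps the parameter count
    small enough to train from random init on a single CPU while preserving
    the three-arm contract of the full-scale model.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        c = _ENCODER_CHANNELS[config.encoder]
        self.channels = c
        rng = np.random.default_rng(config.init_seed)
        P = Tensor.param
        self.params: dict[str, Tensor] = {
            # encoder
            "enc1a_w": P(_he_init(rng, (c, 3, 3, 3), 27)),
            "enc1a_b": P(np.zeros(c, np.float32)),
            "enc1b_w": P(_he_init(rng, (c, c, 3, 3), 9 * c)),
            "enc1b_b": P(np.zeros(c, np.float32)),
            "enc2_w": P(_he_init(rng, (2 * c, c, 3, 3), 9 * c)),
            "enc2_b": P(np.zeros(2 * c, np.float32)),
            # decoder + mask head
            "dec_w": P(_he_init(rng, (c, 3 * c, 3, 3), 27 * c)),
            "dec_b": P(np.zeros(c, np.float32)),
            "mask_w": P(_he_init(rng, (2, c, 1, 1), c)),
            "mask_b": P(np.zeros(2, np.float32)),
            # angio arm
            "ang1_w": P(_he_init(rng, (2 * c, 2 * c, 3, 3), 18 * c)),
            "ang1_b": P(np.zeros(2 * c, np.float32)),
            "ang2_w": P(_he_init(rng, (2 * c, 1), 2 * c)),
            "ang2_b": P(np.zeros(1, np.float32)),
            # consistency head: scalar -> hidden -> scalar, started near the
            # identity with positive slopes so it is monotone-capable from
            # the first step
            "cons1_w": P(np.full((1, config.cons_hidden), 1.0, np.float32)
                         + 0.01 * rng.standard_normal((1, config.cons_hidden)).astype(np.float32)),
            "cons1_b": P(np.zeros(config.cons_hidden, np.float32)),
            "cons2_w": P(np.full((config.cons_hidden, 1),
                                 1.0 / config.cons_hidden, np.float32)),
            "cons2_b": P(np.zeros(1, np.float32)),
        }

    # -- parameter groups ----------------------------------------------------
    def mask_arm_params(self) -> list[Tensor]:
        keys = ("enc1a", "enc1b", "enc2", "dec", "mask")
        return [self.params[f"{k}_{s}"] for k in keys for s in ("w", "b")]

    def head_params(self) -> list[Tensor]:
        """Angio and consistency head parameters (everything outside the
        pretrained mask arm)."""
        keys = ("ang1", "ang2", "cons1", "cons2")
        return [self.params[f"{k}_{s}"] for k in keys for s in ("w", "b")]

    def all_params(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward -------------------------------------------------------------
    @staticmethod
    def preprocess(patches: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) -> float32 (N, 3, H, W) in [0, 1]."""
        x = np.asarray(patches)
        if x.ndim == 3:
            x = x[None]
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32) / 255.0

    def forward_t(self, patches: np.ndarray) -> NetworkOutputs:
        """Differentiable forward pass; returns Tensors."""
        p = self.params
        x = Tensor(self.preprocess(patches))
        e1 = ag.conv2d(x, p["enc1a_w"], p["enc1a_b"]).relu()
        e1 = ag.conv2d(e1, p["enc1b_w"], p["enc1b_b"]).relu()
        e2 = ag.conv2d(ag.maxpool2x2(e1), p["enc2_w"], p["enc2_b"]).relu()
        d = ag.concat([ag.upsample2x(e2), e1], axis=1)
        d = ag.conv2d(d, p["dec_w"], p["dec_b"]).relu()
        logits = ag.conv2d(d, p["mask_w"], p["mask_b"])
        mask_prob = ag.softmax(logits, axis=1)

        a = ag.conv2d(e2, p["ang1_w"], p["ang1_b"]).relu()
        gap = a.mean(axis=(2, 3))                      # (N, 2c)
        angio = (gap @ p["ang2_w"] + p["ang2_b"]).reshape(-1)

        cons = self.cons_head_t(mask_prob)
        return NetworkOutputs(mask_prob=mask_prob, angio=angio, cons=cons)

    def cons_head_t(self, mask_prob: Tensor) -> Tensor:
        """Consistency arm: global average of the positive-class probability
        map through the learnt scalar nonlinearity. A function of the mask
        output only.

        With ``cons_stop_gradient`` (default) the pooled activation is
        treated as a constant input: the RNA loss then trains the head's
        nonlinearity but cannot push the mask probabilities themselves
        toward the score scale, which was observed to inflate the positive
        class and destroy segmentation precision. The mask stays shaped by
        its own supervision; the consistency tie is still enforced on the
        scalar outputs.
        """
        p = self.params
        n = mask_prob.data.shape[0]
        pooled = mask_prob[:, 1].mean(axis=(1, 2)).reshape(n, 1)
        if self.config.cons_stop_gradient:
            pooled = Tensor(pooled.data)
        h = (pooled @ p["cons1_w"] + p["cons1_b"]).tanh()
        return (h @ p["cons2_w"] + p["cons2_b"]).reshape(-1)

    def consistency_from_mask_prob(self, mask_prob: np.ndarray) -> np.ndarray:
        """Numpy-side consistency head for probing/inference."""
        return self.cons_head_t(Tensor(np.asarray(mask_prob))).data

    def forward(self, patches: np.ndarray) -> NetworkOutputs:
        """Inference forward pass; returns plain arrays."""
        return self.forward_t(patches).detach()

    # -- serialization -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{k: v.data for k, v in self.params.items()})
        path.with_suffix(".json").write_text(self.config.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ThreeArmNet":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        net = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            for k in net.params:
                net.params[k].data = data[k].astype(np.float32)
        return net


def build_network(config: ModelConfig | None = None) -> ThreeArmNet:
    return ThreeArmNet(config or ModelConfig())


# ---------------------------------------------------------------------------
# losses (each accepts Tensors or plain arrays; returns a Tensor so callers
# can .backward() during training or .item() in tests)


def _as_tensor(v) -> Tensor:
    return v if isinstance(v, Tensor) else Tensor(np.asarray(v))


def loss_rna(outputs: NetworkOutputs, targets: Mapping[str, float],
             slide_ids: Sequence[str]) -> Tensor:
    """Batch MSE on slide-averaged predictions:

    L = (1/N) * sum_slides [(T - mean P_angio)^2 + (T - mean P_cons)^2]

    where the means run over the patches of each slide present in the batch
    and N is the number of slides in the batch.
    """
    angio = _as_tensor(outputs.angio)
    cons = _as_tensor(outputs.cons)
    if len(slide_ids) != angio.data.shape[0]:
        raise ValueError("one slide_id per patch required")
    slides = list(dict.fromkeys(slide_ids))
    missing = [s for s in slides if s not in targets]
    if missing:
        raise KeyError(f"no target for slide(s) {missing}")
    total = Tensor(0.0)
    for s in slides:
        idx = [i for i, sid in enumerate(slide_ids) if sid == s]
        t = float(targets[s])
        total = total + (t - angio[idx].mean()) ** 2 + (t - cons[idx].mean()) ** 2
    return total * (1.0 / len(slides))


def _soft_dice_loss(prob: Tensor, truth: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - mean-over-classes soft Dice with additive smoothing in numerator
    and denominator, pooled over the whole batch."""
    total = Tensor(0.0)
    n_classes = prob.data.shape[1]
    for k in range(n_classes):
        t_k = Tensor((truth == k).astype(np.float32))
        p_k = prob[:, k]
        inter = (p_k * t_k).sum()
        dice_k = (2.0 * inter + smooth) / (p_k.sum() + t_k.sum() + smooth)
        total = total + dice_k
    return 1.0 - total * (1.0 / n_classes)


def _wcce_loss(prob: Tensor, truth: np.ndarray,
               class_weights: Sequence[float], eps: float = 1e-7) -> Tensor:
    """Class-weighted mean categorical cross-entropy from probabilities."""
    total = Tensor(0.0)
    for k, w in enumerate(class_weights):
        t_k = Tensor((truth == k).astype(np.float32))
        total = total + (-float(w)) * (t_k * (prob[:, k] + eps).log()).sum()
    return total * (1.0 / truth.size)


def loss_seg(mask_prob, truth, weights: tuple[float, float] = (0.9, 0.1),
             class_weights: Sequence[float] = (1.0, 1.0)) -> Tensor:
    """Segmentation loss: weights[0]*DiceLoss + weights[1]*WCCE."""
    prob = _as_tensor(mask_prob)
    truth = np.asarray(truth)
    if prob.data.shape[0] != truth.shape[0] or prob.data.shape[2:] != truth.shape[1:]:
        raise ValueError("mask_prob and truth shapes are inconsistent")
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth mask must be binary")
    return (weights[0] * _soft_dice_loss(prob, truth)
            + weights[1] * _wcce_loss(prob, truth, class_weights))


def loss_consistency(angio, cons) -> Tensor:
    """MSE between the per-patch angio-arm and consistency-arm scalars."""
    a = _as_tensor(angio)
    c = _as_tensor(cons)
    if a.data.shape != c.data.shape:
        raise ValueError("angio and cons must have equal length")
    return ((a - c) ** 2).mean()


def wcce_weights_from_pairs(pairs: Sequence[TrainingPairLike]) -> tuple[float, float]:
    """Inverse class-pixel-frequency weights, renormalized to mean 1."""
    pos = sum(float(np.asarray(p.mask).sum()) for p in pairs)
    tot = sum(np.asarray(p.mask).size for p in pairs)
    freq = np.array([tot - pos, pos]) / tot
    if (freq == 0).any():
        raise ValueError("both classes must be present to derive weights")
    w = 1.0 / freq
    w = w / w.mean()
    return float(w[0]), float(w[1])


# ---------------------------------------------------------------------------
# batch construction


def make_rna_batch(dataset: Sequence[RnaSlide], rng: np.random.Generator,
                   config: ModelConfig | None = None) -> MixedBatch:
    """Sample an RNA batch: exactly ``rna_n_slides`` distinct slides with
    ``rna_patches_per_slide`` patches each, drawn without replacement within
    a slide."""
    config = config or ModelConfig()
    n_s, per = config.rna_n_slides, config.rna_patches_per_slide
    eligible = [s for s in dataset if len(s.patches) >= per]
    if len(eligible) < n_s:
        raise ValueError(
            f"need >= {n_s} slides with >= {per} patches each "
            f"(have {len(eligible)}); lower rna_n_slides/rna_patches_per_slide "
            "in ModelConfig for smaller datasets")
    chosen = rng.choice(len(eligible), size=n_s, replace=False)
    patches, slide_ids, targets = [], [], {}
    for ci in chosen:
        slide = eligible[int(ci)]
        picks = rng.choice(len(slide.patches), size=per, replace=False)
        for pi in picks:
            patches.append(slide.patches[int(pi)])
            slide_ids.append(slide.slide_id)
        targets[slide.slide_id] = float(slide.target)
    return MixedBatch(kind="RNA", patches=np.stack(patches),
                      slide_ids=slide_ids, targets=targets)


def make_cd31_batch(pairs: Sequence[TrainingPairLike], rng: np.random.Generator,
                    config: ModelConfig | None = None) -> MixedBatch:
    """Sample a mask batch of ``cd31_batch_size`` pairs uniformly; if fewer
    pairs exist the draw is with replacement and flagged."""
    config = config or ModelConfig()
    if len(pairs) == 0:
        raise ValueError("empty training-pair dataset")
    k = config.cd31_batch_size
    replace = len(pairs) < k
    picks = rng.choice(len(pairs), size=k, replace=replace)
    return MixedBatch(
        kind="CD31",
        patches=np.stack([pairs[int(i)].he_patch for i in picks]),
        masks=np.stack([np.asarray(pairs[int(i)].mask) for i in picks]),
        with_replacement=replace,
    )
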