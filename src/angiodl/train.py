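"""Two-stage training schedule, checkpoint selection, and inference scoring.

Stage 1 pre-trains the mask arm alone (segmentation loss, Adam); stage 2
trains the full three-arm network on alternating RNA and mask batches
(gradient descent with momentum), checkpointing every epoch. The deployed
checkpoint is the one whose slide scores correlate best (Spearman) with the
validation targets.

At inference a patch's score is 100 x the fraction of pixels whose
positive-class probability exceeds the threshold; a slide's H&E DL
Angioscore is the mean over its patches. An epoch of mixed training is one
pass over the RNA patch inventory.

The full-scale defaults (10 + 10 epochs, learning rate 1e-4, momentum 0.9)
target a large pretrained-backbone setting; the desk-scale profile (see
``angiodl.experiments``) trains the small encoder from random init, which
wants larger step sizes (1e-2 Adam pretraining, 1e-3 SGD mixed) over its
few dozen updates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from . import autograd as ag
from .network import (MixedBatch, ModelConfig, RnaSlide, ThreeArmNet,
                      TrainingPairLike, build_network, loss_consistency,
                      loss_rna, loss_seg, make_cd31_batch, make_rna_batch)

__all__ = [
    "TrainState",
    "SlideScore",
    "pretrain_mask_arm",
    "train_mixed",
    "select_best_checkpoint",
    "score_patch",
    "score_slide",
    "render_heatmap",
    "kfold_slide_split",
]


@dataclass
class TrainState:
    epochs_completed: int
    optimizer_spec: str
    seed: int
    checkpoint_paths: list[Path] = field(default_factory=list)
    metric_history: list[float] = field(default_factory=list)
    loss_log: list[tuple[int, str, float]] = field(default_factory=list)  # (step, kind, loss)

    def write_loss_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "batch_kind", "loss"])
            w.writerows(self.loss_log)


@dataclass
class SlideScore:
    slide_id: str
    he_dl_angioscore: float    # percent positive pixels, in [0, 100]
    n_patches: int
    per_patch_scores: list[float] = field(default_factory=list)


def _check_finite(value: float, what: str) -> None:
    if not math.isfinite(value):
        raise RuntimeError(
            f"{what} diverged (loss = {value}); lower the learning rate")


def pretrain_mask_arm(
    pairs: Sequence[TrainingPairLike],
    config: ModelConfig | None = None,
    epochs: int = 10,
    lr: float = 1e-4,
    seed: int = 0,
    network: ThreeArmNet | None = None,
) -> ThreeArmNet:
    """Stage 1: train encoder + decoder + mask head with the segmentation
    loss only (Adam). Only mask-arm parameters are updated. The per-epoch
    mean segmentation loss is left on ``network.pretrain_log``."""
    if len(pairs) == 0:
        raise ValueError("empty pair dataset")
    config = config or ModelConfig()
    net = network or build_network(config)
    net.pretrain_log = []
    if epochs == 0:
        return net
    rng = np.random.default_rng(seed)
    opt = ag.Adam(net.mask_arm_params(), lr=lr)
    steps_per_epoch = max(1, math.ceil(len(pairs) / config.cd31_batch_size))
    for _ in range(epochs):
        losses = []
        for _ in range(steps_per_epoch):
            batch = make_cd31_batch(pairs, rng, config)
            out = net.forward_t(batch.patches)
            loss = loss_seg(out.mask_prob, batch.masks,
                            (config.dice_weight, config.wcce_weight),
                            config.wcce_class_weights)
            _check_finite(loss.item(), "pretraining")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        net.pretrain_log.append(float(np.mean(losses)))
    return net


def train_mixed(
    network: ThreeArmNet,
    rna_dataset: Sequence[RnaSlide],
    cd31_dataset: Sequence[TrainingPairLike],
    config: ModelConfig | None = None,
    epochs: int = 10,
    lr: float = 1e-4,
    momentum: float = 0.9,
    optimizer: str = "sgd",
    seed: int = 0,
    checkpoint_dir: str | Path | None = None,
    validation_slides: Sequence[RnaSlide] | None = None,
    warmup_epochs: int = 1,
    init_output_bias: bool = True,
) -> TrainState:
    """Stage 2: alternate RNA and mask batches (1:1) over the full network.

    RNA steps apply the slide-averaged batch MSE; mask steps apply the
    segmentation loss plus the consistency MSE between the two scalar arms.
    A checkpoint is written after every epoch; if validation slides are
    given, the per-epoch Spearman between their slide scores and targets is
    recorded in ``metric_history``.

    Two guards protect the pretrained mask arm from the initial shock of the
    untrained score heads (whose error gradient otherwise drives the shared
    encoder coherently away from its pretrained features):
    ``init_output_bias`` starts the angio head's output bias at the mean
    training target, removing the DC component of the RNA error, and
    ``warmup_epochs`` trains only the angio/consistency heads for the first
    epoch(s) before unfreezing the whole network.
    """
    if len(rna_dataset) == 0 or len(cd31_dataset) == 0:
        raise ValueError("mixed training needs both an RNA and a CD31 dataset")
    config = config or network.config
    rng = np.random.default_rng(seed)
    if init_output_bias:
        network.params["ang2_b"].data[:] = np.mean(
            [s.target for s in rna_dataset])

    def make_opt(params):
        if optimizer == "sgd":
            return ag.SGD(params, lr=lr, momentum=momentum), \
                f"sgd(lr={lr}, momentum={momentum})"
        if optimizer == "adam":
            return ag.Adam(params, lr=lr), f"adam(lr={lr})"
        raise ValueError(f"unknown optimizer {optimizer!r}")

    opt, spec = make_opt(network.head_params() if warmup_epochs > 0
                         else network.all_params())
    state = TrainState(epochs_completed=0, optimizer_spec=spec, seed=seed)
    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    n_rna_patches = sum(len(s.patches) for s in rna_dataset)
    steps_per_epoch = max(1, math.ceil(n_rna_patches / config.rna_batch_size))
    step = 0
    for epoch in range(epochs):
        if epoch == warmup_epochs and epoch > 0:
            opt, _ = make_opt(network.all_params())   # unfreeze after warmup
        for _ in range(steps_per_epoch):
            rna = make_rna_batch(rna_dataset, rng, config)
            out = network.forward_t(rna.patches)
            loss = loss_rna(out, rna.targets, rna.slide_ids)
            _check_finite(loss.item(), "mixed training (RNA step)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            state.loss_log.append((step, "RNA", loss.item()))
            step += 1

            cd31 = make_cd31_batch(cd31_dataset, rng, config)
            out = network.forward_t(cd31.patches)
            loss = (loss_seg(out.mask_prob, cd31.masks,
                             (config.dice_weight, config.wcce_weight),
                             config.wcce_class_weights)
                    + loss_consistency(out.angio, out.cons))
            _check_finite(loss.item(), "mixed training (CD31 step)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            state.loss_log.append((step, "CD31", loss.item()))
            step += 1
        state.epochs_completed = epoch + 1
        if ckpt_dir:
            path = ckpt_dir / f"epoch_{epoch + 1:03d}"
            network.save(path)
            state.checkpoint_paths.append(path)
        if validation_slides is not None:
            state.metric_history.append(
                _validation_spearman(network, validation_slides))
    return state


def _validation_spearman(net: ThreeArmNet, slides: Sequence[RnaSlide]) -> float:
    preds = [score_slide(net, s.patches, slide_id=s.slide_id).he_dl_angioscore
             for s in slides]
    targets = [s.target for s in slides]
    if np.ptp(preds) == 0 or np.ptp(targets) == 0:
        return -1.0
    rho = stats.spearmanr(preds, targets).statistic
    return -1.0 if np.isnan(rho) else float(rho)


def select_best_checkpoint(checkpoints: Sequence[str | Path],
                           validation_slides: Sequence[RnaSlide]) -> Path:
    """Pick the checkpoint whose validation slide scores have the highest
    Spearman correlation with the target scores. Constant predictions score
    -1 (undefined correlation); ties go to the earliest epoch."""
    if len(checkpoints) == 0:
        raise ValueError("no checkpoints")
    if len(validation_slides) < 3:
        raise ValueError("need >= 3 validation slides")
    best_path, best_rho = None, -np.inf
    for path in checkpoints:
        net = ThreeArmNet.load(path)
        rho = _validation_spearman(net, validation_slides)
        if rho > best_rho:   # strict: earlier checkpoint wins ties
            best_path, best_rho = Path(path), rho
    return best_path


# ---------------------------------------------------------------------------
# inference


def _positive_prob(net: ThreeArmNet, patches: np.ndarray,
                   batch: int = 16) -> np.ndarray:
    probs = []
    for i in range(0, len(patches), batch):
        out = net.forward(patches[i:i + batch])
        probs.append(out.mask_prob[:, 1])
    return np.concatenate(probs, axis=0)


def score_patch(network: ThreeArmNet, patch: np.ndarray,
                threshold: float | None = None) -> float:
    """Percent of pixels predicted CD31-positive: 100 x mean(P_pos > thr)."""
    thr = network.config.threshold if threshold is None else threshold
    pos = _positive_prob(network, np.asarray(patch)[None])[0]
    return float(100.0 * np.mean(pos > thr))


def score_slide(network: ThreeArmNet, patches: Sequence[np.ndarray],
                threshold: float | None = None,
                slide_id: str = "") -> SlideScore:
    """H&E DL Angioscore of a slide: the mean percent-positive over all its
    patches."""
    if len(patches) == 0:
        raise ValueError("score_slide needs at least one patch")
    thr = network.config.threshold if threshold is None else threshold
    pos = _positive_prob(network, np.stack(patches))
    per_patch = (100.0 * np.mean(pos > thr, axis=(1, 2))).tolist()
    return SlideScore(
        slide_id=slide_id,
        he_dl_angioscore=float(np.mean(per_patch)),
        n_patches=len(per_patch),
        per_patch_scores=per_patch,
    )


def consistency_slide_score(network: ThreeArmNet,
                            patches: Sequence[np.ndarray],
                            batch: int = 16) -> float:
    """Slide-mean consistency-arm output (the second readout that tracks the
    mask-arm percent-positive through the learnt nonlinearity)."""
    vals = []
    for i in range(0, len(patches), batch):
        out = network.forward(np.stack(patches[i:i + batch]))
        vals.append(out.cons)
    return float(np.concatenate(vals).mean())


def render_heatmap(network: ThreeArmNet,
                   slide_patches_with_coords,
                   grid_px: int = 416,
                   threshold: float | None = None) -> np.ndarray:
    """Grid-averaged heatmap of percent-positive predictions.

    ``slide_patches_with_coords`` is an iterable of ``(patch, (x, y))`` with
    (x, y) the patch's top-left slide coordinate. Each patch contributes its
    percent-positive score to the grid cell containing its center; cells
    with no patch are NaN (no-data) and should be excluded from color
    scaling.
    """
    items = list(slide_patches_with_coords)
    if not items:
        return np.full((0, 0), np.nan)
    thr = network.config.threshold if threshold is None else threshold
    cells: dict[tuple[int, int], list[float]] = {}
    for patch, (x, y) in items:
        patch = np.asarray(patch)
        cy = int((y + patch.shape[0] / 2) // grid_px)
        cx = int((x + patch.shape[1] / 2) // grid_px)
        score = score_patch(network, patch, thr)
        cells.setdefault((cy, cx), []).append(score)
    max_cy = max(c[0] for c in cells)
    max_cx = max(c[1] for c in cells)
    heat = np.full((max_cy + 1, max_cx + 1), np.nan)
    for (cy, cx), vals in cells.items():
        heat[cy, cx] = float(np.mean(vals))
    return heat


def kfold_slide_split(slide_ids: Sequence[str], n_folds: int = 3,
                      seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Seeded k-fold partition at the slide level: returns (train_ids,
    held_out_ids) per fold; every slide is held out exactly once."""
    ids = list(slide_ids)
    if n_folds < 2 or n_folds > len(ids):
        raise ValueError("need 2 <= n_folds <= number of slides")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    folds = [sorted(ids[i] for i in order[k::n_folds]) for k in range(n_folds)]
    return [(sorted(set(ids) - set(f)), f) for f in folds]
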