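"""Self-contained few-shot experiment harness on the phantom task.

Mirrors the study protocol: a 55-pair annotated set split 10/45
train/validation (k-shot uses the first k of the training side), parents
pretrained on a synthetic segmentation set and on unannotated phantom
frames, then joint CGAN transfer. Problem sizes default to desk scale
(64 px, narrow networks, hundreds of updates) so a full experiment runs in
minutes on one CPU.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import numpy as np

from . import phantom as ph
from . import training as T
from .networks import WeightState

__all__ = ["ExperimentSetup", "build_phantom_dataset", "pretrain_parents", "run_few_shot"]


@dataclass(frozen=True)
class ExperimentSetup:
    """Problem sizes for one few-shot experiment."""

    n_pairs: int = 55
    n_unannotated: int = 60  # frames for decoder pretraining
    n_segmentation: int = 150  # synthetic segmentation pairs for U-Net parent
    image_size: int = 64
    base_channels: int = 8
    pretrain_steps_u2s: int = 2000
    pretrain_steps_s2u: int = 300
    transfer_steps: int = 300
    max_val_pairs: int | None = None  # cap evaluation cost; None = all 45
    variability: float = 1.0  # inter-sample anatomy/acoustics variation
    seed: int = 0


def build_phantom_dataset(
    setup: ExperimentSetup,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The annotated paired set: sample i is the phantom with seed base+i."""
    base = ph.PhantomParams(image_size=setup.image_size, seed=setup.seed * 1000)
    out = []
    for i in range(setup.n_pairs):
        params = ph.vary_params(base, i, setup.variability)
        s = ph.generate_paired_sample(params)
        out.append((s.ultrasound, s.sketch))
    return out


def pretrain_parents(setup: ExperimentSetup) -> tuple[WeightState, WeightState]:
    """Pretrain both parents: the U-Net on a synthetic segmentation set and
    the decoder on unannotated phantom frames."""
    seg_dir = tempfile.mkdtemp(prefix="echosketch_seg_")
    seg_manifest = ph.generate_pretrain_segmentation_set(
        setup.n_segmentation,
        seed=setup.seed + 17,
        out_dir=seg_dir,
        image_size=setup.image_size,
        boundary_class=True,
    )
    u2s_parent, _ = T.pretrain_u2s_parent(
        seg_manifest,
        T.TrainConfig(
            phase="pretrain_u2s",
            steps=setup.pretrain_steps_u2s,
            batch_size=4,
            base_channels=setup.base_channels,
            image_size=setup.image_size,
            seed=setup.seed + 1,
        ),
    )
    base = ph.PhantomParams(image_size=setup.image_size, seed=setup.seed * 1000 + 5000)
    frames = [
        ph.generate_paired_sample(ph.vary_params(base, i, setup.variability)).ultrasound
        for i in range(setup.n_unannotated)
    ]
    s2u_parent, _ = T.pretrain_s2u_parent(
        frames,
        T.TrainConfig(
            phase="pretrain_s2u",
            steps=setup.pretrain_steps_s2u,
            base_channels=setup.base_channels,
            image_size=setup.image_size,
            seed=setup.seed + 2,
        ),
    )
    return u2s_parent, s2u_parent


def run_few_shot(
    shots: int,
    setup: ExperimentSetup,
    parents: tuple[WeightState, WeightState] | None = None,
    from_scratch: bool = False,
    dataset: list | None = None,
) -> T.TransferResult:
    """k-shot joint transfer on the phantom task; returns the TransferResult
    (its last MetricReport aggregates DICE/VOE/IOU/PSNR/SSIM over the
    validation pairs)."""
    if dataset is None:
        dataset = build_phantom_dataset(setup)
    if from_scratch:
        u2s_parent = s2u_parent = None
    else:
        u2s_parent, s2u_parent = parents or pretrain_parents(setup)
    split = T.few_shot_split(dataset, shots=shots, seed=setup.seed + 3)
    if setup.max_val_pairs is not None:
        split = T.FewShotSplit(
            train_ids=split.train_ids, val_ids=split.val_ids[: setup.max_val_pairs]
        )
    cfg = T.TrainConfig(
        phase="transfer",
        shots=shots,
        steps=setup.transfer_steps,
        base_channels=setup.base_channels,
        image_size=setup.image_size,
        seed=setup.seed + 4,
    )
    return T.transfer_learn_joint(u2s_parent, s2u_parent, split, dataset, cfg)
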