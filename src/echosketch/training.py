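"""Pretraining and few-shot joint transfer.

Three phases:

1. ``pretrain_u2s_parent`` — supervised segmentation pretraining of the
   U-Net on (image, class-mask) pairs with class-balanced cross-entropy.
   The resulting weights initialise the sketch generator G_S.
2. ``pretrain_s2u_parent`` — unconditional GAN pretraining of the decoder on
   unannotated ultrasound frames from seeded latent draws; the decoder learns
   ultrasound texture before ever seeing a sketch.
3. ``transfer_learn_joint`` — few-shot conditional-GAN transfer: a sketch
   encoder is attached to the pretrained decoder (G_U), G_S is initialised
   from the segmentation parent, and both directions train jointly on the
   same k annotated pairs, minimising L_total = L_S + L_U.

Each optimisation step processes one training pair (batch size 1, the
few-shot regime), taken round-robin, so equal step budgets mean equal update
counts regardless of k.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import losses as Lm
from . import metrics as M
from . import phantom as ph
from .losses import LossWeights
from .networks import (
    ComposedS2U,
    Decoder,
    DecoderSpec,
    Discriminator,
    DiscriminatorSpec,
    Encoder,
    EncoderSpec,
    UNet,
    UNetSpec,
    WeightState,
    attach_encoder,
    weight_state_of,
)
from .nn import Adam

__all__ = [
    "TrainConfig",
    "FewShotSplit",
    "LossLog",
    "TransferResult",
    "JointTrainer",
    "pretrain_u2s_parent",
    "pretrain_s2u_parent",
    "few_shot_split",
    "transfer_learn_joint",
    "evaluate_checkpoint",
    "load_pairs",
    "load_segmentation_pairs",
]


@dataclass(frozen=True)
class TrainConfig:
    phase: str = "transfer"  # pretrain_u2s | pretrain_s2u | transfer
    shots: int = 10
    steps: int = 200
    batch_size: int = 1
    learning_rate_g: float = 2e-3
    learning_rate_d: float = 5e-4
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    image_size: int = 64
    eval_every: int = 0  # 0 = only on demand
    base_channels: int = 16
    latent_channels: int = 64
    finetune_lr_scale: float = 1.0  # lr multiplier on parent-initialised params
    log_path: str | None = None

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.shots < 1:
            raise ValueError("shots must be >= 1")
        if self.image_size % 32 != 0:
            raise ValueError("image_size must be divisible by 32")


@dataclass(frozen=True)
class FewShotSplit:
    train_ids: tuple[int, ...]
    val_ids: tuple[int, ...]

    def __post_init__(self):
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train/val overlap")


class TrainingDiverged(RuntimeError):
    """Raised when a forward pass or loss turns non-finite."""


class LossLog:
    """(step, term, value) rows, optionally streamed to a TSV file."""

    def __init__(self, path: str | None = None):
        self.rows: list[tuple[int, str, float]] = []
        self._fh = open(path, "w") if path else None
        if self._fh:
            self._fh.write("step\tterm\tvalue\n")

    def add(self, step: int, term: str, value: float) -> None:
        self.rows.append((step, term, float(value)))
        if self._fh:
            self._fh.write(f"{step}\t{term}\t{value:.8g}\n")
            self._fh.flush()

    def values(self, term: str) -> list[float]:
        return [v for _, t, v in self.rows if t == term]

    def close(self) -> None:
        if self._fh:
            self._fh.close()
            self._fh = None


# ---------------------------------------------------------------------------
# data loading


def load_pairs(manifest: str | os.PathLike) -> list[tuple[np.ndarray, np.ndarray]]:
    """Manifest rows -> list of (ultrasound, sketch) arrays in [-1, 1]."""
    rows = ph.read_manifest(manifest)
    if not rows:
        raise ValueError(f"empty manifest {manifest}")
    return [
        (ph.load_image(r["path_ultrasound"]), ph.load_image(r["path_sketch"]))
        for r in rows
    ]


def load_segmentation_pairs(
    manifest: str | os.PathLike,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Manifest rows -> list of (image, class-mask) arrays."""
    rows = ph.read_manifest(manifest)
    if not rows:
        raise ValueError(f"empty manifest {manifest}")
    return [
        (ph.load_image(r["path_image"]), ph.load_mask(r["path_mask"])) for r in rows
    ]


def _batchify(img: np.ndarray) -> np.ndarray:
    return img[None, None].astype(np.float64)


# ---------------------------------------------------------------------------
# phase 1: segmentation pretraining of the U-Net parent


def pretrain_u2s_parent(
    seg_manifest: str | os.PathLike | list, config: TrainConfig
) -> tuple[WeightState, LossLog]:
    """Train the U-Net on multi-class segmentation with class-balanced
    cross-entropy; returns a 'parent' WeightState plus the loss log."""
    pairs = (
        load_segmentation_pairs(seg_manifest)
        if not isinstance(seg_manifest, list)
        else seg_manifest
    )
    if not pairs:
        raise ValueError("empty segmentation manifest")
    n_classes = int(max(m.max() for _, m in pairs)) + 1
    spec = UNetSpec(
        in_channels=1,
        out_channels=n_classes,
        base_channels=config.base_channels,
        final_activation="none",
    )
    net = UNet(spec, seed=config.seed)
    opt = Adam(net.parameters(), lr=config.learning_rate_g)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1157]))
    log = LossLog(config.log_path)
    for step in range(config.steps):
        idx = rng.integers(0, len(pairs), size=config.batch_size)
        imgs = np.stack([pairs[i][0] for i in idx])[:, None]
        masks = np.stack([pairs[i][1] for i in idx])
        logits = net(imgs)
        loss, grad = Lm.class_balanced_cross_entropy(logits, masks, return_grad=True)
        net.zero_grad()
        net.backward(grad)
        opt.step()
        log.add(step, "ce", loss)
    log.close()
    return weight_state_of(net, provenance="parent"), log


# ---------------------------------------------------------------------------
# phase 2: unconditional GAN pretraining of the decoder parent


def _d_real_grad(scores: np.ndarray) -> np.ndarray:
    s = np.clip(scores, Lm.EPS_SCORE, 1 - Lm.EPS_SCORE)
    return -1.0 / (s.size * s)


def _d_fake_grad(scores: np.ndarray) -> np.ndarray:
    s = np.clip(scores, Lm.EPS_SCORE, 1 - Lm.EPS_SCORE)
    return 1.0 / (s.size * (1.0 - s))


def pretrain_s2u_parent(
    ultrasound_manifest: str | os.PathLike | list, config: TrainConfig
) -> tuple[WeightState, LossLog]:
    """Adversarially train the decoder to generate ultrasound frames from
    seeded random latent grids; the discriminator is discarded afterwards."""
    if isinstance(ultrasound_manifest, list):
        frames = ultrasound_manifest
    else:
        rows = ph.read_manifest(ultrasound_manifest)
        if not rows:
            raise ValueError(f"empty manifest {ultrasound_manifest}")
        key = "path_ultrasound" if "path_ultrasound" in rows[0] else "path_image"
        frames = [ph.load_image(r[key]) for r in rows]
    if not frames:
        raise ValueError("empty ultrasound manifest")
    latent_size = config.image_size // 16
    dspec = DecoderSpec(
        latent_channels=config.latent_channels,
        latent_size=latent_size,
        base_channels=config.base_channels * 2,
    )
    if dspec.image_size != config.image_size:
        raise ValueError(
            f"decoder reaches {dspec.image_size}px, config wants {config.image_size}px"
        )
    dec = Decoder(dspec, seed=config.seed)
    disc = Discriminator(
        DiscriminatorSpec(in_channels=1, base_channels=config.base_channels),
        seed=config.seed + 1,
    )
    opt_g = Adam(dec.parameters(), lr=config.learning_rate_g)
    opt_d = Adam(disc.parameters(), lr=config.learning_rate_d)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x52E0]))
    log = LossLog(config.log_path)
    for step in range(config.steps):
        z = rng.normal(
            size=(config.batch_size, dspec.latent_channels, latent_size, latent_size)
        )
        idx = rng.integers(0, len(frames), size=config.batch_size)
        real = np.stack([frames[i] for i in idx])[:, None]

        fake = dec(z)
        # discriminator update: real then fake, grads accumulate
        disc.zero_grad()
        s_real = disc(real)
        disc.backward(_d_real_grad(s_real))
        s_fake = disc(fake)
        disc.backward(_d_fake_grad(s_fake))
        d_loss, _ = Lm.adversarial_terms(s_real, s_fake)
        opt_d.step()

        # generator update (fresh pass through the updated discriminator)
        fake = dec(z)
        s_fake = disc(fake)
        g_loss = float(-np.mean(np.log(np.clip(s_fake, Lm.EPS_SCORE, 1))))
        dimg = disc.backward(Lm.generator_adversarial_grad(s_fake))
        disc.zero_grad()
        dec.zero_grad()
        dec.backward(dimg)
        opt_g.step()

        log.add(step, "d_loss", d_loss)
        log.add(step, "g_loss", g_loss)
    log.close()
    return weight_state_of(dec, provenance="parent"), log


# ---------------------------------------------------------------------------
# phase 3: joint few-shot transfer


def few_shot_split(
    manifest: str | os.PathLike | list, shots: int, seed: int
) -> FewShotSplit:
    """Deterministic disjoint k-shot split of a paired manifest."""
    n = len(manifest) if isinstance(manifest, list) else len(ph.read_manifest(manifest))
    if shots > n:
        raise ValueError(f"requested {shots} shots but only {n} pairs available")
    perm = np.random.default_rng(np.random.SeedSequence([seed, 0x5117])).permutation(n)
    return FewShotSplit(
        train_ids=tuple(int(i) for i in perm[:shots]),
        val_ids=tuple(int(i) for i in perm[shots:]),
    )


class _GroupedAdam:
    """Adam over parameter groups with per-group learning rates (used for
    discriminative fine-tuning: transferred parameters move slower)."""

    def __init__(self, groups: list[tuple[list, float]]):
        self.opts = [Adam(params, lr=lr) for params, lr in groups if params]

    def step(self) -> None:
        for opt in self.opts:
            opt.step()

    def state_dict(self) -> list:
        return [o.state_dict() for o in self.opts]

    def load_state_dict(self, state: list) -> None:
        for opt, s in zip(self.opts, state):
            opt.load_state_dict(s)


@dataclass
class TransferResult:
    g_s: WeightState
    g_u_encoder: WeightState
    g_u_decoder: WeightState
    d_s: WeightState
    d_u: WeightState
    log: LossLog
    metric_reports: list[M.MetricReport]
    aborted: bool = False


class JointTrainer:
    """One-step-at-a-time joint CGAN transfer; resumable bit-exactly.

    Per step, on one training pair (U, S):
      1. forward both generators: S_hat = G_S(U), U_hat = G_U(S);
      2. update D_S on (S, U) vs (S_hat, U) and D_U on (U, S) vs (U_hat, S);
      3. one joint generator step: backprop L_S into G_S and L_U into
         G_U (encoder + parent-initialised decoder) and apply both updates.
    """

    def __init__(
        self,
        pairs: list[tuple[np.ndarray, np.ndarray]],
        config: TrainConfig,
        u2s_parent: WeightState | None = None,
        s2u_parent: WeightState | None = None,
    ):
        if not pairs:
            raise ValueError("no training pairs")
        self.pairs = pairs
        self.config = config
        w = config.weights

        gs_spec = UNetSpec(
            in_channels=1,
            out_channels=1,
            base_channels=config.base_channels,
            final_activation="tanh",
        )
        self.g_s = UNet(gs_spec, seed=config.seed)
        self.g_s_provenance = "random-init"
        gs_transferred: set[str] = set()
        if u2s_parent is not None:
            skipped = set(self.g_s.load_state_dict(u2s_parent.arrays, strict=False))
            # the parent's segmentation head has a different channel count;
            # everything else must transfer
            gs_transferred = {
                name for name, _ in self.g_s.named_parameters() if name not in skipped
            }
            self.g_s_provenance = "transferred"
            self._transfer_skipped = skipped

        latent_size = config.image_size // 16
        if s2u_parent is not None:
            enc = Encoder(
                EncoderSpec(
                    latent_channels=s2u_parent.spec.latent_channels,
                    latent_size=s2u_parent.spec.latent_size,
                    image_size=config.image_size,
                ),
                seed=config.seed + 1,
            )
            self.g_u = attach_encoder(enc, s2u_parent)
            self.g_u_decoder_provenance = "parent"
        else:
            dspec = DecoderSpec(
                latent_channels=config.latent_channels,
                latent_size=latent_size,
                base_channels=config.base_channels * 2,
            )
            enc = Encoder(
                EncoderSpec(
                    latent_channels=dspec.latent_channels,
                    latent_size=latent_size,
                    image_size=config.image_size,
                ),
                seed=config.seed + 1,
            )
            self.g_u = ComposedS2U(enc, Decoder(dspec, seed=config.seed + 2))
            self.g_u_decoder_provenance = "random-init"

        self.d_s = Discriminator(DiscriminatorSpec(), seed=config.seed + 3)
        self.d_u = Discriminator(DiscriminatorSpec(), seed=config.seed + 4)
        self.extractor = Lm.FeatureExtractor(seed=config.seed)
        self.weights = w
        lr_g, scale = config.learning_rate_g, config.finetune_lr_scale
        gs_fast = [p for n, p in self.g_s.named_parameters() if n not in gs_transferred]
        gs_slow = [p for n, p in self.g_s.named_parameters() if n in gs_transferred]
        self.opt_gs = _GroupedAdam([(gs_fast, lr_g), (gs_slow, lr_g * scale)])
        dec_lr = lr_g * scale if self.g_u_decoder_provenance == "parent" else lr_g
        self.opt_gu = _GroupedAdam(
            [
                (self.g_u.encoder.parameters(), lr_g),
                (self.g_u.decoder.parameters(), dec_lr),
            ]
        )
        self.opt_ds = Adam(self.d_s.parameters(), lr=config.learning_rate_d)
        self.opt_du = Adam(self.d_u.parameters(), lr=config.learning_rate_d)
        self.step_count = 0
        self.log = LossLog(config.log_path)

    # -- one optimisation step -------------------------------------------
    def step(self) -> tuple[Lm.LossReport, Lm.LossReport, float]:
        cfg, w = self.config, self.weights
        u_img, s_img = self.pairs[self.step_count % len(self.pairs)]
        U, S = _batchify(u_img), _batchify(s_img)

        s_hat = self.g_s(U)
        u_hat = self.g_u(S)
        if not (np.isfinite(s_hat).all() and np.isfinite(u_hat).all()):
            raise TrainingDiverged(f"non-finite generator output at step {self.step_count}")

        # --- D_S update
        self.d_s.zero_grad()
        sr = self.d_s(S, U)
        self.d_s.backward(_d_real_grad(sr))
        sf = self.d_s(s_hat, U)
        self.d_s.backward(_d_fake_grad(sf))
        d_loss_s, _ = Lm.adversarial_terms(sr, sf)
        self.opt_ds.step()

        # --- D_U update
        self.d_u.zero_grad()
        ur = self.d_u(U, S)
        self.d_u.backward(_d_real_grad(ur))
        uf = self.d_u(u_hat, S)
        self.d_u.backward(_d_fake_grad(uf))
        d_loss_u, _ = Lm.adversarial_terms(ur, uf)
        self.opt_du.step()

        # --- joint generator step (L_total = L_S + L_U)
        self.g_s.zero_grad()
        self.g_u.zero_grad()

        sf2 = self.d_s(s_hat, U)
        g_adv_s = float(-np.mean(np.log(np.clip(sf2, Lm.EPS_SCORE, 1))))
        dpair = self.d_s.backward(Lm.generator_adversarial_grad(sf2))
        self.d_s.zero_grad()
        d_s_hat = dpair[:, :1]
        l1_s, dl1 = Lm.l1_image_loss(s_hat, S, return_grad=True)
        if w.use_l1_in_LS:
            d_s_hat = d_s_hat + dl1
        self.g_s.backward(d_s_hat)

        uf2 = self.d_u(u_hat, S)
        g_adv_u = float(-np.mean(np.log(np.clip(uf2, Lm.EPS_SCORE, 1))))
        dpair = self.d_u.backward(Lm.generator_adversarial_grad(uf2))
        self.d_u.zero_grad()
        d_u_hat = dpair[:, :1]
        pcpt, dp = Lm.perceptual_loss(u_hat, U, self.extractor, return_grad=True)
        tv, dtv = Lm.tv_loss(u_hat, return_grad=True)
        l1_u, dl1u = Lm.l1_image_loss(u_hat, U, return_grad=True)
        d_u_hat = d_u_hat + w.lambda1 * dp + w.lambda2 * dtv + w.lambda3 * dl1u
        self.g_u.backward(d_u_hat)

        self.opt_gs.step()
        self.opt_gu.step()

        ls = Lm.compose_LS((d_loss_s, g_adv_s), l1_s, w)
        lu = Lm.compose_LU(
            (d_loss_u, g_adv_u), pcpt, tv, l1_u, w, self.extractor.name
        )
        tot = Lm.total_loss(ls, lu)
        step = self.step_count
        for term, value in [
            ("LS_d", ls.terms["d_loss"]),
            ("LS_g_adv", ls.terms["g_adv"]),
            ("LS_l1", l1_s),
            ("LS_total", ls.total),
            ("LU_d", lu.terms["d_loss"]),
            ("LU_g_adv", lu.terms["g_adv"]),
            ("LU_pcpt", pcpt),
            ("LU_tv", tv),
            ("LU_l1", l1_u),
            ("LU_total", lu.total),
            ("total", tot),
        ]:
            self.log.add(step, term, value)
        self.step_count += 1
        return ls, lu, tot

    # -- snapshots --------------------------------------------------------
    def weight_states(self) -> dict[str, WeightState]:
        return {
            "g_s": weight_state_of(self.g_s, self.g_s_provenance),
            "g_u_encoder": weight_state_of(self.g_u.encoder, "random-init"),
            "g_u_decoder": weight_state_of(
                self.g_u.decoder, self.g_u_decoder_provenance
            ),
            "d_s": weight_state_of(self.d_s),
            "d_u": weight_state_of(self.d_u),
        }

    def state(self) -> dict:
        """Full resumable snapshot (weights + optimiser moments + counter)."""
        return {
            "step_count": self.step_count,
            "nets": {
                name: net.state_dict()
                for name, net in [
                    ("g_s", self.g_s),
                    ("g_u", self.g_u),
                    ("d_s", self.d_s),
                    ("d_u", self.d_u),
                ]
            },
            "opts": {
                name: opt.state_dict()
                for name, opt in [
                    ("gs", self.opt_gs),
                    ("gu", self.opt_gu),
                    ("ds", self.opt_ds),
                    ("du", self.opt_du),
                ]
            },
        }

    def load_state(self, state: dict) -> None:
        self.step_count = int(state["step_count"])
        for name, net in [
            ("g_s", self.g_s),
            ("g_u", self.g_u),
            ("d_s", self.d_s),
            ("d_u", self.d_u),
        ]:
            net.load_state_dict(state["nets"][name], strict=True)
        for name, opt in [
            ("gs", self.opt_gs),
            ("gu", self.opt_gu),
            ("ds", self.opt_ds),
            ("du", self.opt_du),
        ]:
            opt.load_state_dict(state["opts"][name])


def transfer_learn_joint(
    u2s_parent: WeightState | None,
    s2u_parent: WeightState | None,
    split: FewShotSplit,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> TransferResult:
    """Run the full joint transfer loop over ``config.steps`` updates.

    Periodic validation (every ``config.eval_every`` steps, if set) plus a
    final evaluation produce MetricReports. A non-finite loss aborts the run
    and the last-good weights are returned with ``aborted=True``.
    """
    if not split.train_ids:
        raise ValueError("empty training split")
    train_pairs = [dataset[i] for i in split.train_ids]
    val_pairs = [dataset[i] for i in split.val_ids]
    trainer = JointTrainer(train_pairs, config, u2s_parent, s2u_parent)
    reports: list[M.MetricReport] = []
    last_good = trainer.weight_states()
    aborted = False
    for step in range(config.steps):
        try:
            ls, lu, tot = trainer.step()
        except TrainingDiverged:
            aborted = True
            break
        if not np.isfinite(tot):
            aborted = True
            break
        last_good = trainer.weight_states()
        if (
            config.eval_every
            and val_pairs
            and (step + 1) % config.eval_every == 0
            and (step + 1) < config.steps
        ):
            rep = evaluate_checkpoint(trainer.g_s, trainer.g_u, val_pairs)
            rep.metadata.update(step=step + 1, shots=len(train_pairs))
            reports.append(rep)
    if val_pairs and not aborted:
        rep = evaluate_checkpoint(trainer.g_s, trainer.g_u, val_pairs)
        rep.metadata.update(step=trainer.step_count, shots=len(train_pairs))
        reports.append(rep)
    trainer.log.close()
    return TransferResult(
        g_s=last_good["g_s"],
        g_u_encoder=last_good["g_u_encoder"],
        g_u_decoder=last_good["g_u_decoder"],
        d_s=last_good["d_s"],
        d_u=last_good["d_u"],
        log=trainer.log,
        metric_reports=reports,
        aborted=aborted,
    )


def evaluate_checkpoint(g_s, g_u, val_pairs) -> M.MetricReport:
    """Run both translations over the validation pairs.

    Sketch outputs are binarised at 0 and scored with DICE/VOE/IOU against
    the binarised ground-truth sketch; synthesized ultrasound is scored with
    PSNR/SSIM against the ground-truth frame. Aggregates are unweighted means.
    """
    was_training_s, was_training_u = g_s.training, g_u.training
    g_s.eval()
    g_u.eval()
    report = M.MetricReport()
    try:
        for u_img, s_img in val_pairs:
            s_hat = g_s(_batchify(u_img))[0, 0]
            u_hat = g_u(_batchify(s_img))[0, 0]
            pred, ref = M.binarize(s_hat), M.binarize(s_img)
            report.add(
                dice=M.dice(pred, ref),
                voe=M.voe(pred, ref),
                iou=M.iou(pred, ref),
                psnr=M.psnr(u_hat, u_img),
                ssim=M.ssim(u_hat, u_img),
            )
    finally:
        g_s.train(was_training_s)
        g_u.train(was_training_u)
    return report
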