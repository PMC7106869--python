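"""Loss terms and the composite CGAN objectives.

Both translation directions are trained as conditional GANs. The
sketch-direction generator objective is

    L_S = -E log D_S(G_S(U), U) + L_l1            (L1 optional),

the ultrasound-direction one adds perceptual, total-variation and L1
regularisers with weights lambda1, lambda2, lambda3 (defaults 6e-3, 2e-8, 1):

    L_U = -E log D_U(G_U(S), S) + l1*L_Pcpt + l2*L_TV + l3*L_l1,

and joint transfer minimises L_total = L_S + L_U. The discriminator term is
the standard  -E log D(real) - E log(1 - D(fake)); the generator uses the
non-saturating form -E log D(fake).

Every term is evaluable standalone on plain arrays and returns its gradient
w.r.t. the generated input alongside the scalar, so the training loop needs
no autodiff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "EPS_SCORE",
    "LossWeights",
    "LossReport",
    "class_balanced_cross_entropy",
    "adversarial_terms",
    "generator_adversarial_grad",
    "discriminator_grads",
    "l1_image_loss",
    "tv_loss",
    "FeatureExtractor",
    "IdentityExtractor",
    "perceptual_loss",
    "compose_LS",
    "compose_LU",
    "total_loss",
]

EPS_SCORE = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """lambda1 (perceptual), lambda2 (TV), lambda3 (L1) of the ultrasound
    objective, plus the optional-L1 toggle of the sketch objective."""

    lambda1: float = 6e-3
    lambda2: float = 2e-8
    lambda3: float = 1.0
    use_l1_in_LS: bool = True

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossReport:
    """Named scalar loss terms for one step; ``total`` must always equal the
    documented weighted sum of its parts."""

    terms: dict[str, float]
    total: float
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self, weights: LossWeights | None = None) -> None:
        t = self.terms
        if "pcpt" in t:
            w = weights or LossWeights()
            expected = (
                t["g_adv"]
                + w.lambda1 * t["pcpt"]
                + w.lambda2 * t["tv"]
                + w.lambda3 * t["l1"]
            )
        elif "l1" in t:
            expected = t["g_adv"] + t["l1"]
        else:
            expected = t["g_adv"]
        if not np.isclose(self.total, expected, rtol=0, atol=1e-12):
            raise AssertionError(
                f"LossReport total {self.total} != recomputed {expected}"
            )


# ---------------------------------------------------------------------------
# individual terms


def class_balanced_cross_entropy(
    pred_logits: np.ndarray, target: np.ndarray, return_grad: bool = False
):
    """Softmax cross-entropy with per-class weights w_c = 1 - n_c / N.

    ``pred_logits``: (N, C, H, W); ``target``: (N, H, W) integer classes.
    The weights are recomputed per batch, so a class occupying the whole
    batch gets weight 0. Returns the weighted per-pixel mean.
    """
    n, c = pred_logits.shape[:2]
    if target.shape != (n,) + pred_logits.shape[2:]:
        raise ValueError(
            f"target shape {target.shape} incompatible with logits {pred_logits.shape}"
        )
    if target.min() < 0 or target.max() >= c:
        raise ValueError(
            f"target classes span [{target.min()}, {target.max()}] but logits "
            f"have {c} channels"
        )
    total = target.size
    counts = np.bincount(target.ravel(), minlength=c)
    w = 1.0 - counts / total  # per-class weight
    shifted = pred_logits - pred_logits.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    onehot_logp = np.take_along_axis(logp, target[:, None], axis=1)[:, 0]
    wpix = w[target]
    loss = float(-(wpix * onehot_logp).sum() / total)
    if not return_grad:
        return loss
    p = np.exp(logp)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
    grad = wpix[:, None] * (p - onehot) / total
    return loss, grad


def _clamp_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)) or scores.min() < 0 or scores.max() > 1:
        raise ValueError("discriminator scores must lie in [0, 1]")
    return np.clip(scores, EPS_SCORE, 1.0 - EPS_SCORE)


def adversarial_terms(d_real: np.ndarray, d_fake: np.ndarray) -> tuple[float, float]:
    """(d_loss, g_loss): the CGAN discriminator loss and the non-saturating
    generator loss, both as means over all score-map elements."""
    r = _clamp_scores(d_real)
    f = _clamp_scores(d_fake)
    d_loss = float(-np.mean(np.log(r)) - np.mean(np.log(1.0 - f)))
    g_loss = float(-np.mean(np.log(f)))
    return d_loss, g_loss


def discriminator_grads(d_real: np.ndarray, d_fake: np.ndarray):
    """Gradients of d_loss w.r.t. the raw real / fake score maps."""
    r = _clamp_scores(d_real)
    f = _clamp_scores(d_fake)
    return -1.0 / (r.size * r), 1.0 / (f.size * (1.0 - f))


def generator_adversarial_grad(d_fake: np.ndarray) -> np.ndarray:
    """Gradient of the non-saturating g_loss w.r.t. the fake score map."""
    f = _clamp_scores(d_fake)
    return -1.0 / (f.size * f)


def l1_image_loss(a: np.ndarray, b: np.ndarray, return_grad: bool = False):
    """Mean absolute difference; zero iff the images are identical."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    diff = a - b
    loss = float(np.abs(diff).mean())
    if not return_grad:
        return loss
    return loss, np.sign(diff) / diff.size


def tv_loss(a: np.ndarray, return_grad: bool = False):
    """Anisotropic total variation: sum of absolute horizontal + vertical
    neighbour differences, normalised by the pixel count."""
    a = np.asarray(a, dtype=np.float64)
    npix = a.size
    dh = a[..., :, 1:] - a[..., :, :-1]
    dv = a[..., 1:, :] - a[..., :-1, :]
    loss = float((np.abs(dh).sum() + np.abs(dv).sum()) / npix)
    if not return_grad:
        return loss
    grad = np.zeros_like(a)
    sh, sv = np.sign(dh), np.sign(dv)
    grad[..., :, 1:] += sh
    grad[..., :, :-1] -= sh
    grad[..., 1:, :] += sv
    grad[..., :-1, :] -= sv
    return loss, grad / npix


class FeatureExtractor:
    """Fixed, seeded random-weight convolutional stack used for the
    perceptual loss: a small stack of stride-2 conv + relu stages whose
    weights never train. Random convolutional features preserve enough
    geometry for a feature-space distance while being fully deterministic
    and self-contained.

    ``taps`` selects which stage outputs (1-based) enter the loss.
    """

    name = "seeded-random-conv"

    def __init__(
        self,
        in_channels: int = 1,
        channels: tuple[int, ...] = (16, 32, 64),
        taps: tuple[int, ...] = (2, 3),
        seed: int = 0,
    ):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFEA7]))
        self.taps = tuple(taps)
        self.stages = []
        prev = in_channels
        for c in channels:
            self.stages.append(
                (
                    nn.Conv2d(prev, c, 3, stride=2, padding=1, rng=rng),
                    nn.ReLU(),
                )
            )
            prev = c

    def features(self, x: np.ndarray) -> list[np.ndarray]:
        out = []
        for conv, relu in self.stages:
            x = relu(conv(x))
            out.append(x)
        return [out[t - 1] for t in self.taps]

    def features_with_cache(self, x: np.ndarray):
        """Forward keeping per-stage caches so a subsequent backward through
        this extractor is valid for *this* input."""
        per_stage = []
        for conv, relu in self.stages:
            x = relu(conv(x))
            per_stage.append(x)
        return per_stage

    def backprop(self, stage_grads: list[np.ndarray | None]) -> np.ndarray:
        """Backpropagate injected per-stage gradients to the input image.
        Caches must come from the latest ``features_with_cache`` call."""
        dy = None
        for idx in range(len(self.stages) - 1, -1, -1):
            g = stage_grads[idx]
            if dy is None:
                dy = np.zeros_like(g) if g is None else g.copy()
            elif g is not None:
                dy = dy + g
            conv, relu = self.stages[idx]
            dy = conv.backward(relu.backward(dy))
            conv.zero_grad()  # frozen extractor: discard parameter grads
        return dy


class IdentityExtractor:
    """Pass-through extractor; perceptual loss then reduces to pixel MSE."""

    name = "identity"
    taps = (1,)

    def features(self, x: np.ndarray) -> list[np.ndarray]:
        return [x]

    def features_with_cache(self, x: np.ndarray):
        return [x]

    def backprop(self, stage_grads):
        return stage_grads[0].copy()


def perceptual_loss(
    a: np.ndarray, b: np.ndarray, extractor=None, return_grad: bool = False
):
    """Mean squared difference between the extractor's feature maps of
    ``a`` and ``b``, averaged over the tapped stages; gradient w.r.t. ``a``."""
    if extractor is None:
        extractor = FeatureExtractor()
    fb = [f.copy() for f in extractor.features(b)]
    if not return_grad:
        fa = extractor.features(a)
        return float(np.mean([np.mean((x - y) ** 2) for x, y in zip(fa, fb)]))
    per_stage = extractor.features_with_cache(a)
    taps = [t - 1 for t in extractor.taps] if hasattr(extractor, "taps") else [0]
    loss = 0.0
    stage_grads: list[np.ndarray | None] = [None] * len(per_stage)
    for k, (t, y) in enumerate(zip(taps, fb)):
        x = per_stage[t]
        loss += np.mean((x - y) ** 2)
        stage_grads[t] = 2.0 * (x - y) / (x.size * len(taps))
    loss = float(loss / len(taps))
    return loss, extractor.backprop(stage_grads)


# ---------------------------------------------------------------------------
# composite objectives


def compose_LS(
    d_terms: tuple[float, float], l1: float, weights: LossWeights
) -> LossReport:
    """Sketch-direction generator objective: g_adv (+ unweighted L1 when the
    optional toggle is on). The discriminator loss is reported alongside."""
    d_loss, g_adv = d_terms
    terms = {"d_loss": float(d_loss), "g_adv": float(g_adv)}
    total = float(g_adv)
    if weights.use_l1_in_LS:
        terms["l1"] = float(l1)
        total += float(l1)
    return LossReport(terms=terms, total=total)


def compose_LU(
    d_terms: tuple[float, float],
    pcpt: float,
    tv: float,
    l1: float,
    weights: LossWeights,
    extractor_name: str = FeatureExtractor.name,
) -> LossReport:
    """Ultrasound-direction generator objective:
    g_adv + lambda1*pcpt + lambda2*tv + lambda3*l1."""
    d_loss, g_adv = d_terms
    total = float(
        g_adv + weights.lambda1 * pcpt + weights.lambda2 * tv + weights.lambda3 * l1
    )
    return LossReport(
        terms={
            "d_loss": float(d_loss),
            "g_adv": float(g_adv),
            "pcpt": float(pcpt),
            "tv": float(tv),
            "l1": float(l1),
        },
        total=total,
        metadata={"perceptual_extractor": extractor_name},
    )


def total_loss(ls: LossReport, lu: LossReport) -> float:
    """Joint transfer objective: the sum of the two generator objectives."""
    for name, rep in (("LS", ls), ("LU", lu)):
        if rep is None or rep.total is None:
            raise ValueError(f"{name} report has no total")
    return float(ls.total + lu.total)
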