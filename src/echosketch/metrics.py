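"""Evaluation indices: DICE / VOE / IOU for the sketch direction (after
binarisation) and PSNR / SSIM for the ultrasound direction, plus the
per-validation-set MetricReport container.

Conventions where the definitions are degenerate:
- both masks empty -> dice = iou = 1, voe = 0 (perfect agreement on nothing);
- identical images -> psnr reported as ``inf``.

VOE is 1 - IOU, the standard volumetric overlap error. A *signed*
relative-volume-difference statistic is provided separately as
``signed_volume_difference`` and is never substituted for VOE.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "binarize",
    "dice",
    "iou",
    "voe",
    "signed_volume_difference",
    "psnr",
    "ssim",
    "MetricReport",
]


def binarize(img: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Foreground iff strictly above the threshold (default 0, the midpoint
    of the [-1, 1] image convention); ties go to background."""
    return np.asarray(img) > threshold


def _as_bool(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    return a if a.dtype == bool else a.astype(bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a, b = _as_bool(a), _as_bool(b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """|A∩B| / |A∪B|; 1.0 when both masks are empty."""
    a, b = _as_bool(a), _as_bool(b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def voe(a: np.ndarray, b: np.ndarray) -> float:
    """Volumetric overlap error, 1 - IOU; in [0, 1]."""
    return 1.0 - iou(a, b)


def signed_volume_difference(pred: np.ndarray, ref: np.ndarray) -> float:
    """(|pred| - |ref|) / |ref|: signed relative volume difference. Not VOE."""
    pred, ref = _as_bool(pred), _as_bool(ref)
    nref = ref.sum()
    if nref == 0:
        return 0.0 if pred.sum() == 0 else np.inf
    return float((int(pred.sum()) - int(nref)) / nref)


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 2.0) -> float:
    """10*log10(max_value^2 / MSE) in dB; ``inf`` when the images are
    identical. The default ``max_value`` of 2 is the [-1, 1] dynamic range."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 2.0) -> float:
    """Mean structural similarity with an 11x11 Gaussian window (sigma 1.5)
    and the canonical constants K1=0.01, K2=0.03."""
    return float(
        structural_similarity(
            np.asarray(a, float),
            np.asarray(b, float),
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


_COLUMNS = ("dice", "voe", "iou", "psnr", "ssim")


@dataclass
class MetricReport:
    """Per-pair rows of (dice, voe, iou, psnr, ssim) plus aggregate means.

    The aggregate is recomputed from the rows on demand, so it can never
    drift from them.
    """

    rows: list[dict[str, float]] = field(default_factory=list)
    metadata: dict[str, object] = field(default_factory=dict)

    def add(self, **values: float) -> None:
        self.rows.append({k: float(values[k]) for k in _COLUMNS})

    @property
    def aggregate(self) -> dict[str, float]:
        if not self.rows:
            raise ValueError("empty report")
        return {
            k: float(np.mean([r[k] for r in self.rows])) for k in _COLUMNS
        }

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("pair\t" + "\t".join(_COLUMNS) + "\n")
            for i, r in enumerate(self.rows):
                fh.write(f"{i}\t" + "\t".join(f"{r[k]:.6f}" for k in _COLUMNS) + "\n")
            agg = self.aggregate
            fh.write("mean\t" + "\t".join(f"{agg[k]:.6f}" for k in _COLUMNS) + "\n")
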