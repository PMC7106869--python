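"""Interactive translation applications.

Single-image translation in both directions, ROI amplification on a
pre-translated sketch (the translation happens once up front; zooming then
only resamples the sketch), and frame-by-frame video translation.

Inference is sampling-free: normalisation layers run in evaluation mode, so
the same input always yields the same output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .networks import WeightState, build_from_state

__all__ = [
    "ROI",
    "pad_to_multiple",
    "translate_u2s",
    "translate_s2u",
    "roi_zoom_sketch",
    "translate_video",
]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned region: 0-based top-left pixel, half-open extents."""

    x: int
    y: int
    width: int
    height: int

    def validate(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1")
        if (
            self.x < 0
            or self.y < 0
            or self.x + self.width > w
            or self.y + self.height > h
        ):
            cx = min(max(self.x, 0), max(w - self.width, 0))
            cy = min(max(self.y, 0), max(h - self.height, 0))
            raise ValueError(
                f"ROI {self} exceeds image bounds {h}x{w}; nearest valid "
                f"placement is x={cx}, y={cy}"
            )


def pad_to_multiple(img: np.ndarray, multiple: int = 32):
    """Pad bottom/right with background (-1) to the next multiple; returns
    (padded, original_shape) so the translation can be cropped back."""
    h, w = img.shape
    ph_ = (-h) % multiple
    pw = (-w) % multiple
    if ph_ == 0 and pw == 0:
        return img, (h, w)
    return np.pad(img, ((0, ph_), (0, pw)), constant_values=-1.0), (h, w)


def _run_generator(img: np.ndarray, state: WeightState) -> np.ndarray:
    net = build_from_state(state)
    net.eval()
    padded, orig = pad_to_multiple(np.asarray(img, dtype=np.float64))
    out = net(padded[None, None])[0, 0]
    return out[: orig[0], : orig[1]]


def translate_u2s(ultrasound: np.ndarray, g_s: WeightState) -> np.ndarray:
    """Ultrasound frame -> sketch, same size as the input (padding to the
    nearest divisible-by-32 size is applied and inverted internally)."""
    return _run_generator(ultrasound, g_s)


def translate_s2u(sketch: np.ndarray, g_u: WeightState | tuple) -> np.ndarray:
    """Sketch -> ultrasound. ``g_u`` is the (encoder, decoder) WeightState
    pair of the composed generator."""
    if isinstance(g_u, WeightState):
        return _run_generator(sketch, g_u)
    enc_state, dec_state = g_u
    from .networks import ComposedS2U

    net = ComposedS2U(build_from_state(enc_state), build_from_state(dec_state))
    net.eval()
    padded, orig = pad_to_multiple(np.asarray(sketch, dtype=np.float64))
    out = net(padded[None, None])[0, 0]
    return out[: orig[0], : orig[1]]


def roi_zoom_sketch(sketch: np.ndarray, roi: ROI) -> np.ndarray:
    """Crop the ROI from a (already translated) sketch and resample it to
    the full image size by cubic interpolation."""
    roi.validate(sketch.shape)
    crop = sketch[roi.y : roi.y + roi.height, roi.x : roi.x + roi.width]
    factors = (sketch.shape[0] / roi.height, sketch.shape[1] / roi.width)
    return ndimage.zoom(
        np.asarray(crop, dtype=np.float64),
        factors,
        order=3,
        grid_mode=True,
        mode="nearest",
    )


def _to_gray(frame: np.ndarray) -> np.ndarray:
    """uint8 frame (H, W[, 3/4]) -> [-1, 1] float via luma."""
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim == 3:
        f = 0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]
    return f / 127.5 - 1.0


def translate_video(
    video_in: str | os.PathLike,
    g_s: WeightState,
    video_out: str | os.PathLike,
) -> int:
    """Translate a video frame by frame with the sketch generator.

    Every frame is converted to grayscale, translated, and re-encoded at the
    source frame rate. Returns the number of frames processed. Supported
    containers are those the installed imageio plugins decode (GIF and
    multi-frame TIFF always work).
    """
    try:
        meta = iio.immeta(video_in)
    except Exception as exc:
        raise IOError(f"cannot read video {video_in}: {exc}") from exc
    duration = meta.get("duration")  # ms per frame for GIF
    net = build_from_state(g_s)
    net.eval()
    out_frames = []
    index = 0
    try:
        for frame in iio.imiter(video_in):
            gray = _to_gray(frame)
            padded, orig = pad_to_multiple(gray)
            sketch = net(padded[None, None])[0, 0][: orig[0], : orig[1]]
            out_frames.append(
                np.clip(np.round((sketch + 1.0) * 127.5), 0, 255).astype(np.uint8)
            )
            index += 1
    except Exception as exc:
        raise IOError(f"decode failed at frame {index}: {exc}") from exc
    if not out_frames:
        raise IOError(f"no frames decoded from {video_in}")
    kwargs = {}
    if duration is not None and str(video_out).lower().endswith(".gif"):
        kwargs["duration"] = duration
        kwargs["loop"] = 0
    try:
        iio.imwrite(video_out, np.stack(out_frames), **kwargs)
    except Exception as exc:
        raise IOError(f"encode failed after frame {index}: {exc}") from exc
    return index
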