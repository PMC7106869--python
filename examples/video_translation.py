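"""Frame-by-frame video translation.

Builds a short synthetic echo clip (phantoms with varying seed, saved as an
animated GIF), translates every frame with the sketch generator and
re-encodes at the source frame rate.
"""

import tempfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from echosketch import apps
from echosketch import phantom as ph
from echosketch.networks import UNetSpec, build_unet_generator, weight_state_of

tmp = Path(tempfile.mkdtemp(prefix="echosketch_video_"))
frames = []
for i in range(8):
    s = ph.generate_paired_sample(ph.PhantomParams(seed=100 + i))
    frames.append(np.clip(np.round((s.ultrasound + 1) * 127.5), 0, 255).astype(np.uint8))
clip = tmp / "echo.gif"
iio.imwrite(clip, np.stack(frames), duration=125, loop=0)  # 8 fps

net, _ = build_unet_generator(UNetSpec(base_channels=8), seed=1)
n = apps.translate_video(clip, weight_state_of(net), tmp / "sketch.gif")
print(f"translated {n} frames -> {tmp / 'sketch.gif'}")
print("duration per frame:", iio.immeta(tmp / "sketch.gif").get("duration"), "ms")
# Every frame passes through the same translate_u2s path as single images;
# the untrained generator here only demonstrates the I/O contract — train a
# transfer checkpoint (see few_shot_transfer.py) for meaningful sketches.
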