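"""Single-image translation and ROI amplification.

Trains a very short 1-shot transfer so the checkpoints exist, then runs the
three interactive applications: ultrasound -> sketch, sketch -> ultrasound,
and cubic-interpolation zoom into a region of the translated sketch.
"""


from echosketch import apps
from echosketch import experiments as E

setup = E.ExperimentSetup(
    seed=3, n_pairs=6, transfer_steps=60, pretrain_steps_u2s=200,
    pretrain_steps_s2u=100, n_segmentation=30, n_unannotated=20,
)
dataset = E.build_phantom_dataset(setup)
result = E.run_few_shot(1, setup, dataset=dataset)

test_us, test_sketch = dataset[-1]
sketch = apps.translate_u2s(test_us, result.g_s)
ultrasound = apps.translate_s2u(test_sketch, (result.g_u_encoder, result.g_u_decoder))
print(f"U2S: {test_us.shape} ultrasound -> sketch, foreground {(sketch > 0).mean():.3f}")
print(f"S2U: sketch -> ultrasound in [{ultrasound.min():.2f}, {ultrasound.max():.2f}]")

zoomed = apps.roi_zoom_sketch(sketch, apps.ROI(x=16, y=16, width=32, height=32))
print(f"ROI zoom: 32x32 region amplified to {zoomed.shape} by cubic interpolation")
# The zoom operates on the already-translated sketch, so panning around a
# frame needs no further network inference.
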