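"""Run a scaled-down few-shot transfer experiment end to end.

Pretrains both parent networks (U-Net on a synthetic segmentation set,
decoder on unannotated phantom frames), then fine-tunes the joint
ultrasound<->sketch CGAN on 5 annotated pairs and evaluates on held-out
pairs. Takes a few minutes on one CPU.
"""

from echosketch import experiments as E

setup = E.ExperimentSetup(
    seed=0,
    n_pairs=25,          # 5 train / 20 validation after the split
    transfer_steps=120,
    max_val_pairs=20,
)
dataset = E.build_phantom_dataset(setup)
print("pretraining parents (U-Net segmentation + decoder GAN) ...")
parents = E.pretrain_parents(setup)

print("5-shot joint transfer ...")
result = E.run_few_shot(5, setup, parents=parents, dataset=dataset)
agg = result.metric_reports[-1].aggregate

print("\nvalidation metrics after transfer:")
for key in ("dice", "voe", "iou", "psnr", "ssim"):
    print(f"  {key:>5}: {agg[key]:.3f}")
# DICE/VOE/IOU score the binarised sketch prediction against the ground-truth
# sketch (region overlap); PSNR (dB) and SSIM score the synthesized ultrasound
# against the true frame. Higher DICE/IOU/PSNR/SSIM and lower VOE are better.
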