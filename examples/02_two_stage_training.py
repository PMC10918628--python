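"""Train the reference CNN with the two-stage curriculum on synthetic data.

Stage 1 applies stochastic augmentations online to every mini-batch;
stage 2 finetunes on the unperturbed data at a tenth of the learning
rate. Prints held-out Pearson r per task after each stage — stage 2
typically recovers a little accuracy lost to the augmentation prior.
Runs in a couple of minutes on one CPU.
"""

import numpy as np

import seqaug as sa
from seqaug.benchmark import run_training

spec = sa.default_benchmark_spec(n_sequences=6000, seed=0)
splits, _ = sa.generate(spec)

aug = sa.AugmentationConfig(enabled=("translocation", "insertion", "deletion"),
                            max_augs=2, batch_mode=True)
cur = sa.CurriculumConfig(stage1_epochs=10, stage2_epochs=3, seed=0)

_, metrics = run_training(splits, aug, cur, spec.task_types)
for stage, scores in metrics.items():
    print(f"{stage}: held-out Pearson r per task =",
          " ".join(f"{s:.3f}" for s in scores))
print("(task labels are additive motif effects; r near 1 would mean the "
      "model fully recovered the planted regulatory grammar)")
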