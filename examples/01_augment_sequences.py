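"""Apply the six evolution-inspired augmentations to a handful of sequences.

Builds a tiny one-hot batch, applies each transform with fixed parameters,
and prints the decoded sequences so the effect of each augmentation is
visible directly.
"""

import numpy as np

import seqaug as sa

rng = np.random.default_rng(0)
batch = sa.encode(["ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAATTTT"])
print("input:            ", sa.decode(batch))

print("transversion (rc):", sa.decode(sa.transversion(batch, 1.0, rng)))
print("translocation ±5: ", sa.decode(sa.translocation(batch, 5, rng)))
print("deletion 3-5 nt:  ", sa.decode(sa.deletion(batch, 3, 5, rng)))
print("insertion ≤4 nt:  ", sa.decode(sa.insertion(batch, 2, 4, rng)))
print("inversion ≤8 nt:  ", sa.decode(sa.inversion(batch, 4, 8, rng)))
print("mutation 10%:     ", sa.decode(sa.mutation(batch, 0.10, rng)))

# the per-mini-batch policy: two types drawn per batch, applied to every
# sequence; with insertion enabled every output has length L + insert_max
cfg = sa.AugmentationConfig(insert_max=4, delete_max=5, shift_max=5,
                            invert_max=8, mutate_frac=0.1, max_augs=2)
out, drawn = sa.augment_batch(batch, cfg, rng, return_drawn=True)
print(f"augment_batch drew {drawn}; output length {out.length} "
      f"(= {batch.length} + insert_max since insertion is enabled)")
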