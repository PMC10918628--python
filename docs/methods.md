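# Methods

## Problem setting

Supervised models of regulatory DNA map a fixed-length one-hot sequence
(n × L × 4, channels A,C,G,T) to one or more scalar readouts — e.g.
enhancer activity of a 249-nt fragment for two promoter contexts, or
peak/non-peak class probability. Functional genomics assays yield limited
training data, so augmentation is attractive; but unlike images, DNA has
few label-preserving symmetries (reverse complement, small shifts).
`seqaug` implements the broader family of *evolution-inspired*
augmentations: transformations that mimic mutational processes
(translocation, insertion, deletion, inversion, point mutation,
reverse-complement "transversion", plus additive channel noise). These do
not strictly preserve the label; asserting that they do imposes a prior —
motif activity is shift-invariant, inter-motif spacing is unimportant.
The two-stage curriculum (augmented training, then finetuning on
unperturbed data) keeps the generalisation benefit of the prior while
restoring fidelity to the observed data.

## Augmentation semantics

All transforms act on the one-hot array; all randomness comes from a
caller-supplied `numpy.random.Generator`, so a seed fully determines a
run. Parameter draws are uniform over their stated ranges.

* **transversion** — with probability `rc_prob`, reverse the position axis
  and swap channels A↔T, C↔G.
* **translocation** — circular shift by s ~ U{−shift_max..shift_max};
  output position i holds input position (i − s) mod L.
* **deletion** — remove a segment of length l ~ U[delete_min, delete_max]
  at a uniform start; restore length with random DNA split evenly across
  the two ends (the odd base goes 3′).
* **insertion** — insert l ~ U[insert_min, insert_max] random bases at a
  uniform position, then end-pad with `insert_max − l` further random
  bases (split evenly, odd base 3′) so every output has length
  L + insert_max regardless of the drawn l.
* **inversion** — replace a segment of length l ~ U[invert_min,
  invert_max] by its reverse complement in place.
* **mutation** — exactly `round(mutate_frac · L)` distinct positions are
  substituted, each with one of the three *other* bases uniformly, so the
  realised Hamming distance equals the rounded count (self-substitution
  would make the realised rate stochastic).
* **noise** — i.i.d. Gaussian(0, noise_std²) added to every channel
  entry; the only transform that leaves the strict one-hot manifold.

`augment_batch` draws `max_augs` distinct types per mini-batch (without
replacement, uniform over the enabled set) and applies them to every
sequence in a fixed canonical order — inversion, deletion, translocation,
mutation, transversion, noise, insertion — chosen so the only
length-changing transform runs last and cannot invalidate coordinates
already used by the others. Per-sequence parameters are redrawn for each
sequence ("sequence mode"); in **batch mode** one parameter set is drawn
and shared by the whole mini-batch, trading sampling diversity for speed.
Whenever insertion is enabled, batches whose draw did not include it are
end-padded with random DNA so the model input shape is constant.

Default hyperparameters (`insert_max=20`, `delete_max=30`, `shift_max=20`,
`invert_max=20`, `rc_prob=0.5`, `mutate_frac=0.05`, `noise_std=0.3`,
`max_augs=2`) follow the ranges commonly used for enhancer-scale (~250 nt)
sequence models; they are starting points meant to be tuned per dataset
with `grid_search`, not universal constants.

## Two-stage curriculum

Stage 1 shuffles the training split each epoch and passes every
mini-batch through `augment_batch` before the gradient step; validation
uses unaugmented data padded to the model input length. The best epoch by
validation loss is checkpointed and restored at stage end. Stage 2 starts
from that checkpoint and trains on the original data at
`stage2_lr_factor` (default 0.1) times the stage-1 learning rate.
Checkpoint selection uses validation *loss* rather than the metric
because loss is task-type agnostic. Unaugmented data is brought to the
augmented input length by `evaluation_pad`: fixed-seed random DNA split
evenly between the ends (original sequence at offset ⌈pad/2⌉), so
evaluation is reproducible and its padding statistics match the random
padding seen in stage 1 — zero-padding would put evaluation data off the
training distribution. Data shuffling and augmentation draw from separate
seeded streams, so a run with null augmentations is bit-identical to
plain training with the same seed.

## Reference backend

The `ModelAdapter` contract (predict / train_on_batch / input_gradient /
get_weights / set_weights / learning-rate control) is all the curriculum
and interpretation code see, so any framework can be wrapped. The built-in
reference backend is a small convolutional network written directly on
numpy arrays with hand-derived backpropagation:

    conv1d(4→32 filters, width 15) → leaky ReLU → max-pool(4)
    → flatten → dense(64) → leaky ReLU → dense(n_tasks)

The flatten/dense head is deliberately position-sensitive — like the
widely used enhancer-activity architectures — which is exactly the
situation where translational augmentations have an invariance prior to
teach; a fully pooled (position-free) model would gain little. Training
is SGD with classical momentum (0.9), global-gradient-norm clipping at
5.0, and a leaky-ReLU slope of 0.1. Momentum and clipping were adopted
because memoryless SGD either crawled or diverged on the synthetic
benchmark across random initialisations, and the leaky slope prevents the
irreversible all-dead-filter collapse that plain ReLU nets can fall into
at aggressive learning rates; `momentum=0, grad_clip=inf, leak=0` recovers
the textbook configuration. Arithmetic is float32 by default for speed;
`dtype=np.float64` makes input gradients match central finite differences
to ~1e−4 relative error (verified in the test suite), which matters for
attribution work. A `LinearAdapter` (f(x)=⟨w,x⟩+b) provides analytic
gradients as an oracle for the attribution code.

## Attribution metrics

`saliency` is the input gradient of one task's scalar output;
`integrated_gradients` uses a midpoint Riemann sum of gradients along the
straight path from a baseline, scaled by (input − baseline), and
satisfies completeness to discretisation error (≤1% at 256 steps on the
reference backend). `correct_attribution` subtracts the per-position
channel mean — one-hot inputs live on the simplex, and only the tangent
component of the gradient is meaningful; the operation is an idempotent
projection leaving zero channel sums.

**Translational robustness.** Under the assumption of no salient signal
at the sequence ends, a small circular shift of the input should shift
the attribution map and nothing else. For `n_repeats` (default 20) draws
of s ~ U{−max_shift..max_shift} (default 30, with replacement, 0
included), the corrected attribution of the shifted sequence is computed
and inverse-shifted; the **variation score** is the RMS deviation of the
realigned maps from their positionwise mean map over repeats, positions
and channels. The mean-map reference makes the score symmetric across
repeats and zero exactly when all aligned maps agree; it is invariant to
adding any position-independent constant. `edge_exclusion` (off by
default) drops positions within `max_shift` of either end for use when
the no-edge-signal assumption is doubtful.

**k-attr consistency.** Across a population of maps (typically the
top-500 most active sequences for one task), every length-k window
(k default 6) is reduced to the k-vector of scores at the *observed*
nucleotides, and quantized to a discrete token: the window's sign pattern
(2^k possibilities) plus the position of its largest-magnitude entry
(k possibilities). Windows whose L2 norm falls in the top decile are the
"salient" set; the metric is KLD(P‖U) = log(2^k·k) − H(P) between their
empirical token distribution P and the uniform prior U over the full
token space. It is 0 iff P is uniform (no recurring structure), maximal
(log 2^k·k) for a point mass, and larger the more the same local
patterns recur across maps. This quantization is one concrete,
deterministic operationalization of "distribution of locally embedded
attribution scores"; alternatives (soft binning, learned embeddings)
would order populations similarly but are not implemented.

## Synthetic data generator

Sequences are i.i.d. uniform background (length 249 by default) with
0–3 motif instances (probabilities 0.15/0.35/0.30/0.20), identities
uniform over four information-rich PWMs (8–12 nt, consensus probability
0.95 per position, off-consensus uniform), embedded at uniform
non-overlapping positions on the forward strand. The label of each task
is the sum of the per-task effect weights of the embedded motifs plus
Gaussian noise (sd 0.3); binary tasks threshold that signal. Every
embedding is recorded with 0-based half-open coordinates, so labels are
an exact function of the annotation table when noise is zero, and a
log-odds PWM scan (threshold 0.25 of the maximal score) recovers ≥95% of
recorded embeddings — the consensus probability and scan threshold were
calibrated together to meet that recoverability requirement.

The generator emulates the *structure* of STARR-seq-style regression data
(249 nt, two tasks, additive motif grammar) but not its biology: real
enhancers have correlated background composition, motif syntax
(orientation, spacing, cooperativity), both strands, and heteroscedastic
assay noise. Because motif positions are uniform, shift-invariance of
labels holds *exactly* here, which is the augmentations' prior — so
passing efficacy results show the machinery works and the prior helps
when true, not that augmentations help on any particular real assay.

Non-overlapping placement keeps the additive label rule exact and the
attribution ground truth unambiguous. `downsample` subsamples the
training split only, leaving validation/test untouched, to probe the
low-data regime.

## Benchmark design and problem sizes

`run_benchmark` trains the reference CNN for each augmentation setting
(baseline, each augmentation alone, insertion+translocation+deletion,
all) × seed, reporting held-out Pearson r per regression task (AUROC for
binary tasks) after stage 1 and stage 2. The bundled efficacy experiment
uses the default 20,000 × 249-nt dataset down-sampled to 25% of the
training split, five random initialisations, batch-mode
insertion+translocation+deletion versus standard training — the regime
where the augmentation prior is most valuable — with 8 stage-1 and
2 stage-2 epochs, sized so the whole experiment completes in minutes on
one CPU core. The attribution comparison scores gradient-corrected
saliency maps of the top-500 test sequences per task with the variation
score and k-attr KLD for augmented versus standard models, compared with
a two-sided Mann–Whitney U test.

## Numerical and degenerate-input conventions

* Coordinates are 0-based, half-open everywhere.
* Ambiguous base N encodes as a uniform 0.25 row (keeps unit row mass,
  which mutation assumes); decoding ties break in alphabet order, so an
  all-0.25 row decodes to A.
* All "null" hyperparameters (zero ranges, zero probabilities/fractions)
  make every transform an exact identity — asserted as array equality in
  the tests.
* Mutation count uses banker's rounding (`np.rint`) of mutate_frac·L.
* Translocation requires shift_max < L, deletion delete_max < L,
  inversion invert_max ≤ L; violations raise `ValueError` before any
  randomness is consumed.
* `population_select` breaks label ties by index order (stable sort).

## Known limitations

* Only scalar single-/multi-task outputs are supported; profile and
  coverage outputs would need label-transforming augmentations.
* The reference backend is CPU numpy: adequate for the bundled benchmark
  and tests, not for genome-scale training; wrap a framework model via
  `ModelAdapter` for that.
* The k-attr token space grows as 2^k·k; for k ≫ 8 the uniform-prior KLD
  saturates near log-population-size and loses resolution.
* Batch mode shares drawn *parameters*, but deletion/insertion still draw
  their random replacement DNA per sequence; only the cut/insert
  coordinates are common.
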