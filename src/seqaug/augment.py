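"""Evolution-inspired stochastic augmentations on one-hot DNA batches.

Six transforms emulate the kinds of variation evolution samples in
regulatory sequence — reverse-complement transversion, circular
translocation, deletion, insertion, segment inversion, point mutation —
plus additive Gaussian noise on the one-hot channels. Each transform keeps
the training label of the wild-type sequence, which amounts to imposing a
prior (e.g. motif activity is invariant to small shifts; inter-motif
spacing is insignificant).

All transforms are exposed in two layers:

* deterministic cores (``apply_*``) taking explicit per-sequence
  parameters — used for testing and for batch-mode equivalence checks;
* stochastic wrappers drawing parameters from a ``numpy.random.Generator``,
  either per sequence ("sequence mode") or once for the whole mini-batch
  ("batch mode").

``augment_batch`` implements the per-mini-batch policy: a fixed number of
augmentation types is drawn once per batch (without replacement) and
applied to every sequence with stochastic per-sequence parameters, in a
fixed canonical order with insertion last so that length changes never
shift coordinates already used by other transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import OneHotBatch, complement_permutation

ALL_AUGMENTATIONS = (
    "transversion",
    "insertion",
    "translocation",
    "deletion",
    "inversion",
    "mutation",
    "noise",
)

# length changes must come last; earlier transforms keep coordinates valid
CANONICAL_ORDER = (
    "inversion",
    "deletion",
    "translocation",
    "mutation",
    "transversion",
    "noise",
    "insertion",
)

__all__ = [
    "ALL_AUGMENTATIONS",
    "CANONICAL_ORDER",
    "AugmentationConfig",
    "transversion",
    "translocation",
    "deletion",
    "insertion",
    "inversion",
    "mutation",
    "noise",
    "augment_batch",
    "random_onehot",
    "apply_transversion",
    "apply_translocation",
    "apply_deletion",
    "apply_insertion",
    "apply_inversion",
    "apply_mutation",
]


@dataclass
class AugmentationConfig:
    """Hyperparameters of the six transforms plus the sampling policy.

    Ranged transforms draw their size uniformly from ``[min, max]``;
    ``max_augs`` types are drawn per batch without replacement from
    ``enabled``. ``batch_mode`` shares one drawn parameter set across the
    mini-batch instead of drawing per sequence.
    """

    insert_min: int = 0
    insert_max: int = 20
    delete_min: int = 0
    delete_max: int = 30
    shift_max: int = 20
    invert_min: int = 0
    invert_max: int = 20
    rc_prob: float = 0.5
    mutate_frac: float = 0.05
    noise_std: float = 0.3
    enabled: tuple[str, ...] = ALL_AUGMENTATIONS
    max_augs: int = 2
    batch_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.enabled = tuple(self.enabled)
        for name in self.enabled:
            if name not in ALL_AUGMENTATIONS:
                raise ValueError(f"unknown augmentation {name!r}")
        for lo, hi, label in (
            (self.insert_min, self.insert_max, "insert"),
            (self.delete_min, self.delete_max, "delete"),
            (self.invert_min, self.invert_max, "invert"),
        ):
            if not 0 <= lo <= hi:
                raise ValueError(f"{label} range must satisfy 0 <= min <= max")
        if self.shift_max < 0:
            raise ValueError("shift_max must be >= 0")
        if not 0.0 <= self.rc_prob <= 1.0:
            raise ValueError("rc_prob must be in [0, 1]")
        if not 0.0 <= self.mutate_frac <= 1.0:
            raise ValueError("mutate_frac must be in [0, 1]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.enabled and not 1 <= self.max_augs <= len(self.enabled):
            raise ValueError(
                f"max_augs must be in [1, {len(self.enabled)}]; got {self.max_augs}"
            )

    @classmethod
    def null(cls, **overrides) -> "AugmentationConfig":
        """A config whose every transform is the identity."""
        base = dict(
            insert_min=0, insert_max=0, delete_min=0, delete_max=0,
            shift_max=0, invert_min=0, invert_max=0,
            rc_prob=0.0, mutate_frac=0.0, noise_std=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["enabled"] = list(self.enabled)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationConfig":
        return cls(**d)


def random_onehot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Strict one-hot array of ``shape + (4,)`` with i.i.d. uniform bases."""
    idx = rng.integers(0, 4, size=shape)
    return np.eye(4)[idx]


# ---------------------------------------------------------------------------
# Deterministic cores


def apply_transversion(x: np.ndarray, flags: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Reverse-complement sequences where ``flags`` is true."""
    out = x.copy()
    if np.any(flags):
        out[flags] = x[flags][:, ::-1][:, :, perm]
    return out


def apply_translocation(x: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Circular shift each sequence by its own offset; out[i] = in[(i-s) mod L]."""
    n, L, _ = x.shape
    pos = (np.arange(L)[None, :] - shifts[:, None]) % L
    return x[np.arange(n)[:, None], pos]

def apply_deletion(
    x: np.ndarray, lengths: np.ndarray, starts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Remove [start, start+l) per sequence; restore length with random DNA.

    Padding is split as evenly as possible between the 5' and 3' ends with
    the extra base going 3'.
    """
    n, L, _ = x.shape
    out = np.empty_like(x)
    for i in range(n):
        l, p = int(lengths[i]), int(starts[i])
        kept = np.concatenate([x[i, :p], x[i, p + l:]], axis=0)
        left = l // 2
        pad = random_onehot(rng, (l,))
        out[i] = np.concatenate([pad[:left], kept, pad[left:]], axis=0)
    return out


def apply_insertion(
    x: np.ndarray,
    lengths: np.ndarray,
    positions: np.ndarray,
    insert_max: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Insert l random bases at position p, then end-pad to length L + insert_max.

    The remaining ``insert_max - l`` bases are split evenly between the two
    ends (extra base 3') so every output sequence has the same length.
    """
    n, L, _ = x.shape
    out = np.empty((n, L + insert_max, 4), dtype=x.dtype)
    for i in range(n):
        l, p = int(lengths[i]), int(positions[i])
        ins = random_onehot(rng, (l,))
        rest = insert_max - l
        left = rest // 2
        pad = random_onehot(rng, (rest,))
        out[i] = np.concatenate(
            [pad[:left], x[i, :p], ins, x[i, p:], pad[left:]], axis=0
        )
    return out


def apply_inversion(
    x: np.ndarray, lengths: np.ndarray, starts: np.ndarray, perm: np.ndarray
) -> np.ndarray:
    """Replace [start, start+l) by its reverse complement in place."""
    out = x.copy()
    for i in range(x.shape[0]):
        l, p = int(lengths[i]), int(starts[i])
        if l > 0:
            out[i, p:p + l] = out[i, p:p + l][::-1][:, perm]
    return out


def apply_mutation(
    x: np.ndarray, positions: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """Substitute the base at each chosen position with a guaranteed-different one.

    ``positions[i]`` lists the m distinct positions of sequence i;
    ``offsets`` in {1,2,3} select among the three alternative bases, so the
    Hamming distance to the input is exactly m.
    """
    out = x.copy()
    n, m = positions.shape
    if m == 0:
        return out
    rows = np.repeat(np.arange(n), m)
    cols = positions.reshape(-1)
    cur = np.argmax(out[rows, cols], axis=1)
    new = (cur + offsets.reshape(-1)) % 4
    out[rows, cols] = 0.0
    out[rows, cols, new] = 1.0
    return out


# ---------------------------------------------------------------------------
# Stochastic transforms


def transversion(
    batch: OneHotBatch, rc_prob: float, rng: np.random.Generator, batch_mode: bool = False
) -> OneHotBatch:
    """Reverse-complement each sequence with probability ``rc_prob``.

    In batch mode one Bernoulli draw decides for the whole batch.
    """
    n = len(batch)
    perm = complement_permutation(batch.alphabet)
    if batch_mode:
        flags = np.full(n, rng.random() < rc_prob)
    else:
        flags = rng.random(n) < rc_prob
    return OneHotBatch(apply_transversion(batch.data, flags, perm), batch.alphabet)


def translocation(
    batch: OneHotBatch, shift_max: int, rng: np.random.Generator, batch_mode: bool = False
) -> OneHotBatch:
    """Circularly shift each sequence by s ~ U{-shift_max..shift_max}."""
    n, L = len(batch), batch.length
    if shift_max >= L:
        raise ValueError(f"shift_max ({shift_max}) must be < sequence length ({L})")
    size = 1 if batch_mode else n
    shifts = rng.integers(-shift_max, shift_max + 1, size=size)
    if batch_mode:
        shifts = np.repeat(shifts, n)
    return OneHotBatch(apply_translocation(batch.data, shifts), batch.alphabet)


def deletion(
    batch: OneHotBatch,
    delete_min: int,
    delete_max: int,
    rng: np.random.Generator,
    batch_mode: bool = False,
) -> OneHotBatch:
    """Delete a uniform-length segment and restore length with random DNA."""
    n, L = len(batch), batch.length
    if delete_max >= L:
        raise ValueError(f"delete_max ({delete_max}) must be < sequence length ({L})")
    size = 1 if batch_mode else n
    lengths = rng.integers(delete_min, delete_max + 1, size=size)
    starts = rng.integers(0, L - lengths + 1)
    if batch_mode:
        lengths, starts = np.repeat(lengths, n), np.repeat(starts, n)
    return OneHotBatch(apply_deletion(batch.data, lengths, starts, rng), batch.alphabet)


def insertion(
    batch: OneHotBatch,
    insert_min: int,
    insert_max: int,
    rng: np.random.Generator,
    batch_mode: bool = False,
) -> OneHotBatch:
    """Insert a uniform-length random segment; every output has length L + insert_max."""
    n, L = len(batch), batch.length
    if insert_max == 0:
        return batch.copy()
    size = 1 if batch_mode else n
    lengths = rng.integers(insert_min, insert_max + 1, size=size)
    positions = rng.integers(0, L + 1, size=size)
    if batch_mode:
        lengths, positions = np.repeat(lengths, n), np.repeat(positions, n)
    return OneHotBatch(
        apply_insertion(batch.data, lengths, positions, insert_max, rng), batch.alphabet
    )


def inversion(
    batch: OneHotBatch,
    invert_min: int,
    invert_max: int,
    rng: np.random.Generator,
    batch_mode: bool = False,
) -> OneHotBatch:
    """Reverse-complement a uniform-length segment in place."""
    n, L = len(batch), batch.length
    if invert_max > L:
        raise ValueError(f"invert_max ({invert_max}) must be <= sequence length ({L})")
    perm = complement_permutation(batch.alphabet)
    size = 1 if batch_mode else n
    lengths = rng.integers(invert_min, invert_max + 1, size=size)
    starts = rng.integers(0, L - lengths + 1)
    if batch_mode:
        lengths, starts = np.repeat(lengths, n), np.repeat(starts, n)
    return OneHotBatch(apply_inversion(batch.data, lengths, starts, perm), batch.alphabet)


def mutation(
    batch: OneHotBatch, mutate_frac: float, rng: np.random.Generator
) -> OneHotBatch:
    """Mutate round(mutate_frac * L) distinct positions per sequence.

    Each chosen base is replaced by one of the three alternatives uniformly
    (self-substitution excluded), so the realised Hamming distance is
    exactly the rounded count.
    """
    n, L = len(batch), batch.length
    m = int(np.rint(mutate_frac * L))
    if m == 0:
        return batch.copy()
    positions = np.stack([rng.choice(L, size=m, replace=False) for _ in range(n)])
    offsets = rng.integers(1, 4, size=(n, m))
    return OneHotBatch(apply_mutation(batch.data, positions, offsets), batch.alphabet)


def noise(batch: OneHotBatch, noise_std: float, rng: np.random.Generator) -> OneHotBatch:
    """Add i.i.d. Gaussian(0, noise_std^2) to every channel entry."""
    if noise_std == 0:
        return batch.copy()
    return OneHotBatch(
        batch.data + rng.normal(0.0, noise_std, size=batch.data.shape), batch.alphabet
    )


# ---------------------------------------------------------------------------
# Per-mini-batch policy


def draw_augmentations(
    config: AugmentationConfig, rng: np.random.Generator
) -> tuple[str, ...]:
    """Draw ``max_augs`` distinct types uniformly from the enabled set."""
    if config.max_augs > len(config.enabled):
        raise ValueError("max_augs exceeds the number of enabled augmentations")
    drawn = rng.choice(len(config.enabled), size=config.max_augs, replace=False)
    return tuple(config.enabled[i] for i in sorted(drawn))


def augment_batch(
    batch: OneHotBatch,
    config: AugmentationConfig,
    rng: np.random.Generator,
    return_drawn: bool = False,
):
    """Apply one per-mini-batch draw of augmentations to every sequence.

    ``max_augs`` types are drawn once per batch without replacement; each is
    applied to every sequence in the canonical order (inversion, deletion,
    translocation, mutation, transversion, noise, insertion) with
    per-sequence stochastic parameters, or shared parameters in batch mode.

    If insertion is enabled the output length is always ``L + insert_max``:
    batches whose draw did not include insertion are end-padded with random
    DNA (split evenly, extra base 3') so the model input shape is constant.
    """
    drawn = draw_augmentations(config, rng)
    out = batch
    for name in CANONICAL_ORDER:
        if name not in drawn:
            continue
        if name == "transversion":
            out = transversion(out, config.rc_prob, rng, config.batch_mode)
        elif name == "translocation":
            out = translocation(out, config.shift_max, rng, config.batch_mode)
        elif name == "deletion":
            out = deletion(out, config.delete_min, config.delete_max, rng, config.batch_mode)
        elif name == "insertion":
            out = insertion(out, config.insert_min, config.insert_max, rng, config.batch_mode)
        elif name == "inversion":
            out = inversion(out, config.invert_min, config.invert_max, rng, config.batch_mode)
        elif name == "mutation":
            out = mutation(out, config.mutate_frac, rng)
        elif name == "noise":
            out = noise(out, config.noise_std, rng)
    if "insertion" in config.enabled and "insertion" not in drawn and config.insert_max > 0:
        out = pad_to_length(out, batch.length + config.insert_max, rng)
    if return_drawn:
        return out, drawn
    return out


def pad_to_length(
    batch: OneHotBatch, target_length: int, rng: np.random.Generator
) -> OneHotBatch:
    """Pad with random DNA split evenly between ends (extra base 3')."""
    pad = target_length - batch.length
    if pad < 0:
        raise ValueError("target_length must be >= current length")
    if pad == 0:
        return batch
    n = len(batch)
    left = pad // 2
    ends = random_onehot(rng, (n, pad))
    return OneHotBatch(
        np.concatenate([ends[:, :left], batch.data, ends[:, left:]], axis=1),
        batch.alphabet,
    )
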