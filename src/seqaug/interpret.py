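"""Attribution maps and their robustness/consistency evaluation.

Attribution analysis asks which input positions drive a model's scalar
prediction. Besides computing saliency maps (input gradients) and
integrated gradients through the adapter contract, this module evaluates
attribution *quality* in two model-agnostic ways:

* **Translational robustness.** If no salient signal sits at the sequence
  ends, circularly shifting the input should simply shift the attribution
  map. The sequence is randomly translated, the (gradient-corrected)
  attribution is computed, the inverse translation realigns the map, and
  the root-mean-squared deviation of the realigned maps from their mean is
  the variation score — 0 for a perfectly shift-equivariant attribution
  function, larger the more the explanation churns under translation.

* **k-attr consistency.** Across a population of maps, recurring local
  patterns (motif-like signatures) are quantified by quantizing each
  length-k window of observed-nucleotide scores into a discrete token
  (sign pattern + position of the largest magnitude) and measuring the
  Kullback–Leibler divergence of the salient-window token distribution
  from a uniform prior. Higher KLD means the same local patterns recur
  across maps rather than varying arbitrarily.

Both metrics accept externally computed attribution arrays, so any
attribution method can be evaluated, not just the two built in here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .adapters import ModelAdapter
from .seqdata import LabeledDataset, OneHotBatch

__all__ = [
    "AttributionMap",
    "RobustnessConfig",
    "ConsistencyConfig",
    "saliency",
    "integrated_gradients",
    "correct_attribution",
    "translational_robustness",
    "kattr_consistency",
    "population_select",
    "compare_populations",
    "plot_attribution",
]


@dataclass
class AttributionMap:
    """Per-position, per-channel importance scores for one sequence."""

    scores: np.ndarray  # (length, 4)
    method_tag: str = "external"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != 4:
            raise ValueError(f"attribution map must be (length, 4); got {self.scores.shape}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attribution map contains non-finite entries")


@dataclass
class RobustnessConfig:
    """Parameters of the translational robustness test."""

    max_shift: int = 30
    n_repeats: int = 20
    edge_exclusion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")


@dataclass
class ConsistencyConfig:
    """Parameters of the k-attr consistency metric."""

    k: int = 6
    min_occurrences: int = 1
    salient_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.salient_fraction <= 1:
            raise ValueError("salient_fraction must be in (0, 1]")


def saliency(adapter: ModelAdapter, batch: OneHotBatch, task_index: int = 0) -> list[AttributionMap]:
    """Gradient of the selected scalar output w.r.t. the one-hot input."""
    grads = adapter.input_gradient(batch, task_index)
    return [AttributionMap(g, "saliency") for g in grads]


def integrated_gradients(
    adapter: ModelAdapter,
    sequence: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 256,
    task_index: int = 0,
) -> AttributionMap:
    """Path-integral attribution from baseline to input.

    The integral of gradients along the straight line is approximated by a
    midpoint Riemann sum over ``n_steps`` points and scaled elementwise by
    ``input - baseline``; the attributions then satisfy completeness
    (they sum to ``f(input) - f(baseline)``) up to discretisation error
    that shrinks with ``n_steps``.
    """
    x = np.asarray(sequence, dtype=np.float64)
    if x.ndim == 3:
        x = x[0]
    if baseline is None:
        baseline = np.zeros_like(x)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != x.shape:
        raise ValueError(f"baseline shape {baseline.shape} != input shape {x.shape}")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    points = baseline[None] + alphas[:, None, None] * (x - baseline)[None]
    grads = adapter.input_gradient(points, task_index)
    avg = grads.mean(axis=0)
    return AttributionMap(avg * (x - baseline), "integrated_gradients")


def correct_attribution(attr_map: AttributionMap) -> AttributionMap:
    """Remove the per-position channel mean (the off-simplex gradient component).

    One-hot inputs live on the probability simplex, so only the component
    of the gradient tangent to the simplex is meaningful; subtracting the
    channel mean at each position projects onto it. The projection is
    idempotent and leaves every position with zero channel sum.
    """
    s = attr_map.scores
    return AttributionMap(s - s.mean(axis=1, keepdims=True), attr_map.method_tag)


def translational_robustness(
    attr_fn: Callable[[np.ndarray], AttributionMap | np.ndarray],
    sequence: np.ndarray,
    config: RobustnessConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Variation score of attributions under random circular translations.

    For each of ``n_repeats`` draws: shift the sequence circularly by
    s ~ U{-max_shift..max_shift}, compute the gradient-corrected
    attribution of the shifted sequence, and apply the inverse shift to
    the map. The variation score is the RMS deviation of the realigned
    maps from their positionwise mean, over repeats, positions and
    channels; with ``edge_exclusion`` positions within ``max_shift`` of
    either end are omitted.

    Returns ``(score, aligned_maps)`` with ``aligned_maps`` of shape
    ``(n_repeats, length, 4)``.
    """
    if config is None:
        config = RobustnessConfig()
    x = np.asarray(sequence, dtype=np.float64)
    if x.ndim == 3:
        x = x[0]
    L = x.shape[0]
    if config.max_shift >= L:
        raise ValueError("max_shift must be < sequence length")
    rng = np.random.default_rng(config.seed)
    aligned = np.empty((config.n_repeats, L, 4))
    for r in range(config.n_repeats):
        s = int(rng.integers(-config.max_shift, config.max_shift + 1))
        shifted = np.roll(x, s, axis=0)
        m = attr_fn(shifted)
        scores = m.scores if isinstance(m, AttributionMap) else np.asarray(m, dtype=np.float64)
        if scores.shape != x.shape:
            raise ValueError(
                f"attr_fn output shape {scores.shape} != sequence shape {x.shape}"
            )
        corrected = scores - scores.mean(axis=1, keepdims=True)
        aligned[r] = np.roll(corrected, -s, axis=0)
    if config.edge_exclusion and config.max_shift > 0:
        core = aligned[:, config.max_shift : L - config.max_shift]
    else:
        core = aligned
    mean_map = core.mean(axis=0, keepdims=True)
    score = float(np.sqrt(np.mean((core - mean_map) ** 2)))
    return score, aligned


# ---------------------------------------------------------------------------
# k-attr consistency


def _window_vectors(map_scores: np.ndarray, onehot: np.ndarray, k: int) -> np.ndarray:
    """k-vectors of attribution scores at the observed nucleotides."""
    obs = np.sum(map_scores * onehot, axis=1)  # score of the actual base per position
    return np.lib.stride_tricks.sliding_window_view(obs, k)


def _tokenize(windows: np.ndarray) -> np.ndarray:
    """Quantize each window to (sign pattern, argmax-|.| position) token ids."""
    k = windows.shape[1]
    signs = (windows >= 0).astype(np.int64)
    sign_id = signs @ (1 << np.arange(k, dtype=np.int64))
    arg = np.argmax(np.abs(windows), axis=1)
    return sign_id * k + arg


def token_space_size(k: int) -> int:
    """Number of possible tokens: 2^k sign patterns times k argmax positions."""
    return (1 << k) * k


def kattr_consistency(
    maps: Sequence[AttributionMap | np.ndarray],
    sequences: OneHotBatch | np.ndarray,
    config: ConsistencyConfig | None = None,
) -> float:
    """KLD between the salient-window token distribution and a uniform prior.

    Every length-k window of every map is reduced to the k-vector of
    scores at the observed nucleotides, quantized to a discrete token
    (sign pattern and within-window argmax-magnitude position), and the
    empirical distribution P over tokens from the top-decile-norm
    (salient) windows is compared against U uniform over the space of
    2^k * k possible tokens: KLD(P||U) = log(2^k * k) - H(P). The score
    is 0 iff P is uniform over the full token space and maximal
    (= log token-space size) for a point mass; higher values mean the
    salient windows share recurring local patterns.
    """
    if config is None:
        config = ConsistencyConfig()
    onehots = sequences.data if isinstance(sequences, OneHotBatch) else np.asarray(sequences)
    if len(maps) < 2:
        raise ValueError("population size must be >= 2")
    if len(maps) != onehots.shape[0]:
        raise ValueError("maps and sequences must have equal length")
    L = onehots.shape[1]
    if config.k > L:
        raise ValueError(f"k ({config.k}) must be <= sequence length ({L})")
    windows = []
    for m, x in zip(maps, onehots):
        scores = m.scores if isinstance(m, AttributionMap) else np.asarray(m, dtype=np.float64)
        if scores.shape != x.shape:
            raise ValueError("map/sequence shape mismatch")
        windows.append(_window_vectors(scores, x, config.k))
    windows = np.concatenate(windows, axis=0)
    norms = np.linalg.norm(windows, axis=1)
    thresh = np.quantile(norms, 1.0 - config.salient_fraction)
    salient = windows[norms >= thresh]
    if salient.shape[0] == 0:
        salient = windows
    tokens = _tokenize(salient)
    _, counts = np.unique(tokens, return_counts=True)
    counts = counts[counts >= config.min_occurrences]
    p = counts / counts.sum()
    entropy = float(-np.sum(p * np.log(p)))
    return float(np.log(token_space_size(config.k)) - entropy)


def population_select(dataset: LabeledDataset, task_index: int, n: int) -> np.ndarray:
    """Indices of the n sequences with the highest label for one task.

    Ties are broken by index order (stable sort), mirroring the practice
    of analysing the sequences with the highest observed activity.
    """
    if n > len(dataset):
        raise ValueError(f"n ({n}) exceeds dataset size ({len(dataset)})")
    order = np.argsort(-dataset.y[:, task_index], kind="stable")
    return order[:n]


def plot_attribution(attr_map: AttributionMap, sequence: np.ndarray | None = None,
                     ax=None, window: tuple[int, int] | None = None):
    """Bar plot of per-position attribution, one colour per nucleotide.

    If ``sequence`` (one-hot) is given, only the observed-nucleotide score
    is drawn per position, coloured by base; otherwise all four channels
    are stacked. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 2))
    s = attr_map.scores
    lo, hi = window if window is not None else (0, s.shape[0])
    pos = np.arange(lo, hi)
    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    if sequence is not None:
        seq = np.asarray(sequence)
        obs = np.argmax(seq, axis=1)
        vals = s[np.arange(s.shape[0]), obs]
        for b, letter in enumerate("ACGT"):
            mask = obs[lo:hi] == b
            ax.bar(pos[mask], vals[lo:hi][mask], color=colors[letter], label=letter)
        ax.legend(ncol=4, fontsize=8)
    else:
        bottom = np.zeros(hi - lo)
        for b, letter in enumerate("ACGT"):
            ax.bar(pos, s[lo:hi, b], bottom=bottom, color=colors[letter], label=letter)
            bottom += s[lo:hi, b]
        ax.legend(ncol=4, fontsize=8)
    ax.set_xlabel("position")
    ax.set_ylabel("attribution")
    ax.axhline(0, lw=0.5, color="k")
    return ax


def compare_populations(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two score populations.

    Returns (U statistic, p-value).
    """
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
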