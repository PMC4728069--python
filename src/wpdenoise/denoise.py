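"""Entropy-guided wavelet packet shrinkage of noisy audio.

The pipeline:

1. choose a mother wavelet (``dmey`` by default, or data-driven via
   :func:`select_wavelet`);
2. choose the decomposition depth by a top-down entropy rule
   (:func:`best_level`);
3. decompose to that depth;
4. estimate the noise scale from the finest-scale detail coefficients and
   soft-threshold every leaf at ``threshold_multiplier`` times that scale
   (4.5 by default, covering ~99.999% of Gaussian noise);
5. invert the transform.

Band-pass/low-pass post-filtering (step 6) lives in
:mod:`wpdenoise.filtering`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .audio import AudioSignal
from .errors import DegenerateInputError, ParameterError
from .wavelet import WaveletSpec, WPTree, wavelet_filters, wp_decompose, wp_reconstruct


@dataclass(frozen=True)
class DenoiseConfig:
    """All the knobs of the denoising pipeline.

    Parameters
    ----------
    wavelet_name
        Mother wavelet; ``dmey`` is the default (it gave the highest
        input/output correlation across bird calls in our experience).
    level_cap
        Hard ceiling on the decomposition depth.  The effective cap is
        ``min(level_cap, floor(log2(n / filter_length)))`` so the deepest
        nodes never hold fewer coefficients than filter taps.
    threshold_multiplier
        Threshold in units of the estimated noise standard deviation.
        4.5 covers 99.999% of a Gaussian.
    threshold_mode
        ``soft`` (shrink towards zero; continuous, default) or ``hard``
        (keep-or-kill).
    boundary_mode
        ``symmetric`` (default; fewer edge artifacts) or ``periodic``
        (exact energy conservation with orthonormal filters).
    exempt_approximation
        If True the all-approximation leaf (index 0) is left untouched;
        by default it is thresholded like every other leaf.
    post_filter_band
        Optional ``(low_hz, high_hz)`` band for the post-filter stage;
        only used by :func:`wpdenoise.filtering.denoise_and_filter`.
    """

    wavelet_name: str = "dmey"
    level_cap: int = 10
    threshold_multiplier: float = 4.5
    threshold_mode: str = "soft"
    boundary_mode: str = "symmetric"
    exempt_approximation: bool = False
    post_filter_band: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ParameterError("threshold_multiplier must be > 0")
        if self.level_cap < 1:
            raise ParameterError("level_cap must be >= 1")
        if self.threshold_mode not in ("soft", "hard"):
            raise ParameterError(f"unknown threshold_mode {self.threshold_mode!r}")


def soft_threshold(values: Sequence[float], thr: float) -> np.ndarray:
    """Soft shrinkage: ``sign(x) * max(|x| - thr, 0)`` elementwise.

    Continuous in ``x`` and non-expansive (never increases magnitudes or
    distances), unlike hard thresholding which cuts off sharply.
    """
    if thr < 0:
        raise ParameterError(f"threshold must be non-negative, got {thr}")
    x = np.asarray(values, dtype=np.float64)
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def hard_threshold(values: Sequence[float], thr: float) -> np.ndarray:
    """Keep-or-kill: zero everything with ``|x| <= thr``, keep the rest."""
    if thr < 0:
        raise ParameterError(f"threshold must be non-negative, got {thr}")
    x = np.asarray(values, dtype=np.float64)
    return np.where(np.abs(x) > thr, x, 0.0)


def estimate_noise_sigma(tree: WPTree) -> float:
    """Noise scale estimate: population standard deviation of the
    finest-scale (level-1) detail coefficients.

    Stationary background noise is approximately Gaussian, most visibly in
    the high-frequency half of the spectrum where birdsong rarely carries
    sustained energy; the level-1 detail node isolates exactly that half.
    """
    detail = tree.node(1, 1).coeffs
    return float(np.std(detail))


def effective_level_cap(n: int, filter_length: int, level_cap: int) -> int:
    """``min(level_cap, floor(log2(n / filter_length)))``; raises if < 1."""
    if n < 2 * filter_length:
        raise DegenerateInputError(
            f"signal of length {n} too short for wavelet with {filter_length} taps"
        )
    return min(level_cap, int(math.floor(math.log2(n / filter_length))))


def _grow_to_best_level(signal: AudioSignal, wavelet: WaveletSpec,
                        config: DenoiseConfig) -> Tuple[int, WPTree]:
    """Top-down entropy rule; returns (level, tree decomposed to >= level).

    Starting from level 1, keep deepening while the maximum node entropy
    does not drop from one level to the next; stop at the first level L
    whose maximum entropy is strictly smaller than level L+1's, and use L.
    Ties deepen (strict '<' required to stop).  Capped by
    :func:`effective_level_cap`.
    """
    cap = effective_level_cap(len(signal), wavelet.filter_length, config.level_cap)
    tree = wp_decompose(signal, wavelet, 1, config.boundary_mode)
    level = 1
    while level < cap:
        tree.extend()
        if tree.max_entropy(level) < tree.max_entropy(level + 1):
            return level, tree
        level += 1
    return cap, tree


def best_level(signal: AudioSignal, wavelet: WaveletSpec,
               config: DenoiseConfig = DenoiseConfig()) -> int:
    """The entropy-selected decomposition depth for ``signal``.

    Implements the top-down stopping rule described in
    :func:`_grow_to_best_level`; the tree built along the way is discarded
    (use :func:`denoise` to reuse it).
    """
    level, _ = _grow_to_best_level(signal, wavelet, config)
    return level


def threshold_tree(tree: WPTree, thr: float,
                   config: DenoiseConfig = DenoiseConfig()) -> WPTree:
    """Apply the configured threshold to every leaf of ``tree``.

    A single global threshold is applied at each leaf node of the selected
    level.  With ``exempt_approximation`` the index-0 (all-approximation)
    leaf is passed through unchanged.  Interior nodes are untouched — they
    only carry length metadata for reconstruction.
    """
    fn = soft_threshold if config.threshold_mode == "soft" else hard_threshold
    new_leaves = {}
    for node in tree.leaves():
        if config.exempt_approximation and node.index == 0:
            continue
        new_leaves[node.index] = fn(node.coeffs, thr)
    return tree.copy_with_leaves(new_leaves)


def denoise(signal: AudioSignal, config: DenoiseConfig = DenoiseConfig()) -> AudioSignal:
    """Full wavelet-packet shrinkage pipeline (steps 2–5).

    Returns a signal of the same length and sample rate.
    """
    wavelet = wavelet_filters(config.wavelet_name)
    level, tree = _grow_to_best_level(signal, wavelet, config)
    tree = tree.truncated(level)
    thr = config.threshold_multiplier * estimate_noise_sigma(tree)
    return wp_reconstruct(threshold_tree(tree, thr, config))


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between two equal-length sample arrays.

    Degenerate cases: raises if ``a`` is constant; returns 0.0 if only
    ``b`` is constant (an all-zero denoised output carries no linear
    relationship to its input).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.std() == 0.0:
        raise DegenerateInputError("correlation undefined for a constant signal")
    if b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_wavelet(signal: AudioSignal, candidates: Sequence[str],
                   config: DenoiseConfig = DenoiseConfig()
                   ) -> Tuple[str, List[float]]:
    """Pick the mother wavelet that best preserves ``signal`` under denoising.

    Denoises once per candidate and scores each by the Pearson correlation
    between the input and its denoised output; returns the argmax (ties
    broken by candidate order) together with all scores.
    """
    if len(candidates) == 0:
        raise ParameterError("candidates must be non-empty")
    if signal.samples.std() == 0.0:
        raise DegenerateInputError("wavelet selection undefined for a constant signal")
    scores: List[float] = []
    for name in candidates:
        cfg = DenoiseConfig(
            wavelet_name=name,
            level_cap=config.level_cap,
            threshold_multiplier=config.threshold_multiplier,
            threshold_mode=config.threshold_mode,
            boundary_mode=config.boundary_mode,
            exempt_approximation=config.exempt_approximation,
            post_filter_band=config.post_filter_band,
        )
        out = denoise(signal, cfg)
        scores.append(pearson_correlation(signal.samples, out.samples))
    best = int(np.argmax(scores))
    return candidates[best], scores
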