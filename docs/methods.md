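# Methods

## Model and assumptions

The denoiser targets recordings of the form `x[n] = s[n] + e[n]` where
the song `s` is transient and sparse in a wavelet packet basis, and the
noise `e` is (quasi-)stationary with an approximately Gaussian amplitude
distribution — wind, rain, recorder hum, distant machinery. Noise that is
itself transient (other animals, switching clicks) is outside the model
and is not removed.

Under these assumptions the song concentrates into few large packet
coefficients while stationary noise spreads thinly across all of them, so
shrinking every coefficient towards zero by a threshold proportional to
the noise scale removes mostly noise. Soft thresholding is used rather
than hard: it is continuous and non-expansive, which avoids the musical
artifacts of keep-or-kill rules.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `wavelet_name` | `dmey` | analysis/synthesis filter bank; `haar`, `db1`…`db20` also supported |
| `level_cap` | 10 | ceiling on tree depth; effective cap is `min(cap, ⌊log₂(n/filter_length)⌋)` so leaves never hold fewer coefficients than filter taps |
| `threshold_multiplier` | 4.5 | threshold in units of σ̂; a ±4.5σ band covers ≥ 99.99% of a Gaussian (the measured coverage on 10⁷ draws is ≈ 99.9993%) |
| `threshold_mode` | `soft` | `hard` available for comparison |
| `boundary_mode` | `symmetric` | mirror extension (fewer edge artifacts); `periodic` gives exact dyadic lengths and energy conservation for orthonormal filters |
| `exempt_approximation` | off | leave the all-low-pass leaf untouched; by default it is thresholded like every other leaf, since the post-filter can remove low-frequency residue either way |

### Depth selection

The tree is grown top-down from level 1; at each step the maximum node
entropy `S = −Σ sᵢ² ln sᵢ²` of the current level is compared with the
next level's. Growth stops at the first strict decrease from parent level
to child level; ties keep deepening. The entropy is computed on raw
coefficients (no normalization to probabilities), so it is
amplitude-dependent: the convention that samples live in [−1, 1] (as any
normalized recording does) is what makes small coefficients — where
`−s² ln s² > 0` — the common case. The selection is aggregated as a
maximum over all nodes of a level, not per parent–child triple; with
per-level thresholding either aggregation leads to the same kind of
uniform-depth tree, and the level-wise maximum is the simpler rule.

### Noise scale

σ̂ is the population standard deviation of the *level-1* detail node —
the finest-scale detail, covering the top half of the spectrum, where
sustained song energy is rarest and the Gaussian noise approximation is
best. (An alternative reading — the highest-frequency node at the deepest
level — estimates from `n/2^L` coefficients instead of `n/2` and is much
noisier; the finest-scale convention is also the standard one in wavelet
shrinkage.) For unit-variance white noise the estimate is unbiased to
within sampling error because an orthonormal filter bank preserves
white-noise variance.

### Thresholding

A single global threshold `4.5 σ̂` is applied at every leaf of the
selected level ("applied at each node", not recomputed per node — a
per-node σ would erase narrowband song nodes whose own coefficients set
their σ). Interior nodes only carry the length metadata needed to undo
boundary extension during inversion.

## The discrete Meyer filter is approximately orthogonal

The classical 62-tap FIR table for `dmey` does not satisfy the
power-complementarity condition exactly: `|H(ω)|² + |H(ω+π)|²` deviates
from 2 by about 1.2 × 10⁻², so a decompose/reconstruct roundtrip carries
a relative error of order 1% per level. This is a property of the filter
table itself, not of the implementation — longer truncations of the ideal
Meyer response reduce but never eliminate it. The error is far below the
noise floors the method operates on and does not affect any metric
visibly. Exact perfect reconstruction (max error < 1e-8) and exact energy
conservation (periodic mode, relative error < 1e-10) hold for the
orthogonal family (`haar`, `dbN`) and are tested there; `dmey`'s
roundtrip error is pinned by its own test at its true scale.

## Post-filter

The band-pass/low-pass stage is a linear-phase FIR designed with a Kaiser
window for ≥ 40 dB stopband attenuation over a transition band of 10% of
the governing cutoff, applied with group-delay compensation (zero overall
phase). Species bands ship as an editable `key = low,high` text file; a
band whose upper edge exceeds the recording's Nyquist is clipped with a
warning, and a band covering (0, ≥ Nyquist) is the all-pass limit — the
filter stage is skipped, making that case exactly equal to denoising
alone. A band starting at 0 Hz selects a low-pass design.

## Synthetic fixtures

The generator reproduces the study conditions the pipeline is evaluated
under at desk scale:

* **stepped tones** — phase-continuous constant-frequency segments
  (default 20/40/80 Hz, 100 ms each, 8 kHz rate): a minimal
  non-stationary signal;
* **clicks** — single-sample impulses (flat spectrum);
* **coloured noise** — seeded Gaussian white noise, or pink/brown noise
  produced by `f^(−β/2)` spectral shaping (β = 1, 2) with the DC bin
  zeroed and renormalized to unit variance so that strength scaling stays
  meaningful for every colour;
* **mixing** — noise is added at a stated percentage of the signal RMS
  (100% ⇔ 0 dB true SNR). For the annotated fixture the reference RMS is
  that of the active tone span only; the 500 ms pure-noise margins are
  measurement scaffolding for SnNR and the success ratio, not signal.
* **normalization** — the noisy mixture is scaled to a 0.95 peak, with
  the clean and noise tracks scaled by the same factor, exactly as
  digitising a recording at full scale does. This anchors the [−1, 1]
  amplitude convention the entropy rule relies on; all segment metrics
  are scale-invariant, and each fixture keeps its ground-truth tracks so
  true SNR is computable alongside SnNR.

What the fixtures do *not* emulate: harmonic stacks, frequency sweeps,
amplitude envelopes, reverberation, or non-stationary field noise
(insect choruses, gusts). Passing the synthetic suite therefore shows
that the machinery implements the method correctly and that the
qualitative colour ordering (white easiest, pink harder, brown hardest)
holds; it does not certify performance on any particular field corpus.

## Numerical choices

* Single-level analysis/synthesis steps delegate to PyWavelets
  (`pywt.dwt`/`idwt`); `periodic` boundary mode maps to pywt's
  `periodization` variant, the one with exact dyadic lengths.
* Population (1/n) variance everywhere a variance or σ is taken.
* Multichannel input is reduced to channel 0 with a logged warning.
* PCM16 WAV I/O scales by 2¹⁵ in both directions, so a write/read
  roundtrip stays within one quantization step.
* The Pearson correlation for wavelet selection is computed over the
  full-length time-domain samples; a constant input is an error, and an
  all-zero denoised output scores 0.
* Spectrograms use Hann-windowed frames (default 512 samples, 50%
  overlap) and report one-sided magnitude; the frame count is
  `⌊(n − overlap)/(window − overlap)⌋` with no padding.
* Down-sampling uses polyphase resampling with its built-in anti-alias
  filter and supports arbitrary lower target rates.

## Desk-scale problem sizes

The seeded experiments run on ~10⁴-sample fixtures (1.3 s at 8 kHz): the
colour/strength sweep uses 20 seeds per cell over strengths
{25, 50, 100, 150, 200}% (the sweep grid is a parameter, not a finding),
spectral-slope checks use 2¹⁶-sample noise tracks, and σ-recovery uses
2¹⁵ samples. One denoise run takes ~20 ms, so the whole evaluation is
interactive.

## Known limitations

* Brown (1/f²) noise is strongly non-Gaussian in the scale distribution
  the threshold assumes; the pipeline barely improves it. This is
  inherent to the method, not a defect of the implementation.
* Transient noise (clicks, other animals) overlaps the song's own
  wavelet signature and is not removed.
* The entropy stopping rule is amplitude-dependent by construction;
  inputs far outside [−1, 1] can stop the tree at depth 1 and
  over-threshold. Normalize recordings at load time (the I/O layer does).
* No source separation: overlapping songs are denoised as a unit.
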