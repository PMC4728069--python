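# wpdenoise

Wavelet-packet denoising for bioacoustic field recordings.

Autonomous acoustic recorders capture birdsong together with wind, rain,
insects, machinery and recorder hum. The resulting low signal-to-noise
ratio is the main obstacle to both manual spectrogram reading and
automated song recognition. `wpdenoise` removes the *stationary* part of
that noise while preserving the transient song, using wavelet packet
shrinkage followed by an ordinary band-pass or low-pass filter keyed to
the species' frequency range.

## The algorithm

Given a recording `x` with samples nominally in [−1, 1]:

1. **Mother wavelet.** Default is the discrete Meyer wavelet (`dmey`,
   62-tap FIR); alternatively `select_wavelet` denoises once per candidate
   (`db1`…`db20`, `dmey`) and picks the one maximising the Pearson
   correlation between input and output.
2. **Decomposition depth.** A full wavelet packet tree (both the
   approximation and detail branches are split, so level *L* holds 2^*L*
   nodes) is grown top-down. Each node is scored by the nonnormalized
   Shannon entropy of its coefficients,
   `S = −Σᵢ sᵢ² ln(sᵢ²)` (with `0·ln 0 = 0`), and growth stops at the
   first level *L* whose maximum node entropy is strictly smaller than
   level *L*+1's.
3. **Threshold.** The noise scale σ̂ is the standard deviation of the
   level-1 (finest-scale) detail coefficients, where stationary noise is
   closest to Gaussian. Every leaf is soft-thresholded at
   `t = 4.5 σ̂` — `sign(c)·max(|c| − t, 0)` — which covers ≥ 99.99% of
   Gaussian noise.
4. **Inversion.** The tree is inverted from its thresholded leaves,
   reproducing length and sample rate.
5. **Post-filter.** A linear-phase FIR band-pass/low-pass (≥ 40 dB
   stopband, zero-phase after delay compensation) removes residual noise
   outside the species band (e.g. kakapo *booming* 0–800 Hz ⇒ low-pass).

Evaluation uses annotated recordings with *noise-only* margins and *song*
regions: `SnNR = 10·log₁₀(P_song/P_noise)`, the success ratio
`log₁₀(var(N_before)/var(N_after))` (> 0 means the noise floor dropped),
and a modified `PSNR = 20·log₁₀(max|x| / RMS error)`.

## Worked example

`examples/denoise_noisy_tone.py` builds a 20/40/80 Hz stepped tone with
500 ms pure-noise margins, adds white Gaussian noise at 100% of the tone
RMS, and denoises with the defaults:

```
true SNR of fixture :   0.07 dB
SnNR before         :   3.02 dB
SnNR after          :  27.04 dB
success ratio       :   3.06
PSNR (noisy vs out) :  12.91 dB
```

SnNR rises by 24 dB and the success ratio of 3.06 means the noise-floor
variance in the silent margins dropped by a factor ≈ 10³, while the tone
survives. The other examples show the colour sweep (white noise is removed
far better than pink, and brown barely at all), data-driven wavelet
selection (`dmey` wins), the D vs DF comparison on a band-limited song,
and the down-sampling rescue for high-frequency non-Gaussian interference.

A thin CLI wraps the same functions:

```sh
wpdenoise synth tone --noise white --strength 100 --out noisy.wav
wpdenoise denoise noisy.wav --variant D --out clean.wav
wpdenoise metrics noisy.wav noisy.labels.tsv --band 10,120
```

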