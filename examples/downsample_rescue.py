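"""Down-sampling as a rescue for high-frequency non-Gaussian noise.

A low-frequency song contaminated by a strong high-frequency interferer
(a 15 kHz tone — not Gaussian, so the wavelet threshold cannot model it).
Down-sampling to 22 kHz moves the new Nyquist below the interferer, which
removes it entirely as a side effect of the anti-alias filter.
"""

import numpy as np

import wpdenoise as w

sr = 44100
song = w.stepped_tone(w.ToneSpec((800.0, 1200.0), 0.25, 0.5, sr))
t = np.arange(len(song)) / sr
contaminated = w.AudioSignal(song.samples + 0.4 * np.sin(2 * np.pi * 15000 * t), sr)

down = w.downsample(contaminated, 22000)


def band_rms(sig, lo, hi):
    freqs, p = __import__("scipy.signal", fromlist=["periodogram"]).periodogram(
        sig.samples, fs=sig.sample_rate)
    sel = (freqs >= lo) & (freqs <= hi)
    return float(np.sqrt(p[sel].sum()))


print(f"interferer RMS before: {band_rms(contaminated, 14000, 16000):.4f}")
print(f"song band RMS before : {band_rms(contaminated, 500, 2000):.4f}")
print(f"song band RMS after  : {band_rms(down, 500, 2000):.4f}  (fs={down.sample_rate})")
print("interferer after     : gone (above the new 11 kHz Nyquist)")
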