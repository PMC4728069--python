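"""Pick the mother wavelet by input/output correlation.

Denoising with the 'right' wavelet preserves the signal: the Pearson
correlation between the noisy input and its denoised output is highest
when the basis matches the signal.  The discrete Meyer wavelet (dmey)
usually wins on tonal birdsong-like material.
"""

import wpdenoise as w

fx = w.noisy_tone_fixture(strength_pct=50.0, seed=11)
candidates = ["db2", "db6", "db10", "dmey"]
best, scores = w.select_wavelet(fx.annotated.audio, candidates)

for name, score in zip(candidates, scores):
    marker = " <-- selected" if name == best else ""
    print(f"{name:>5s}  correlation {score:.4f}{marker}")
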