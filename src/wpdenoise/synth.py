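"""Synthetic test signals and coloured noise.

Generates the kinds of fixture the denoiser is evaluated on when no field
recordings are at hand: stepped multi-frequency tones, impulse clicks, and
white / pink / brown noise mixed in at a stated percentage of the signal's
strength.  All randomness is seeded, so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .audio import AudioSignal
from .errors import DegenerateInputError, ParameterError
from .metrics import AnnotatedRecording, SegmentLabel

COLORS = ("white", "pink", "brown")

#: spectral exponent beta of the power law power ~ 1/f**beta per colour
_BETA = {"white": 0.0, "pink": 1.0, "brown": 2.0}


@dataclass(frozen=True)
class ToneSpec:
    """A stepped tone: constant-frequency segments played back to back.

    The classic example is 20/40/80 Hz at 100 ms per segment — a simple
    non-stationary signal whose frequency content changes abruptly.
    """

    segment_freqs: Tuple[float, ...] = (20.0, 40.0, 80.0)
    segment_dur_s: float = 0.1
    amplitude: float = 1.0
    sample_rate: int = 8000

    def __post_init__(self) -> None:
        if self.segment_dur_s <= 0:
            raise ParameterError("segment duration must be positive")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")
        nyq = self.sample_rate / 2.0
        for f in self.segment_freqs:
            if not (0 < f < nyq):
                raise ParameterError(f"frequency {f} Hz outside (0, Nyquist={nyq})")


@dataclass(frozen=True)
class NoiseSpec:
    """Colour, strength (percent of signal RMS) and seed of an added noise."""

    color: str = "white"
    strength_pct: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ParameterError(f"unknown noise colour {self.color!r}")
        if self.strength_pct < 0:
            raise ParameterError("strength_pct must be >= 0")


def stepped_tone(spec: ToneSpec) -> AudioSignal:
    """Concatenated constant-frequency sinusoid segments, phase-continuous
    at the joins (the phase accumulates across segment boundaries)."""
    sr = spec.sample_rate
    n_seg = int(round(spec.segment_dur_s * sr))
    phase = 0.0
    parts = []
    for f in spec.segment_freqs:
        t = np.arange(n_seg) / sr
        parts.append(spec.amplitude * np.sin(phase + 2 * np.pi * f * t))
        phase += 2 * np.pi * f * n_seg / sr
    return AudioSignal(np.concatenate(parts), sr)


def click(dur_s: float, position_s: float, amplitude: float = 1.0,
          sample_rate: int = 8000) -> AudioSignal:
    """A single-sample impulse in silence.

    An ideal impulse has a flat magnitude spectrum — energy at every
    frequency equally — which makes it a hard case for any band-limited
    noise model.
    """
    n = int(round(dur_s * sample_rate))
    if n < 1:
        raise ParameterError("duration too short for one sample")
    k = int(round(position_s * sample_rate))
    if not (0 <= position_s < dur_s) or k >= n:
        raise ParameterError(f"click position {position_s}s outside [0, {dur_s}s)")
    x = np.zeros(n)
    x[k] = amplitude
    return AudioSignal(x, sample_rate)


def colored_noise(n: int, color: str = "white", seed: int = 0,
                  sample_rate: int = 8000) -> AudioSignal:
    """Seeded Gaussian noise with a 1/f**beta power spectrum.

    ``white`` is i.i.d. standard Gaussian (flat spectrum, beta=0).
    ``pink`` (beta=1) and ``brown`` (beta=2) are produced by shaping the
    spectrum of white noise with ``f**(-beta/2)`` amplitude weights (DC
    forced to zero) and renormalizing to unit variance, so ``strength_pct``
    scaling stays meaningful for every colour.
    """
    if n < 2:
        raise ParameterError("need at least 2 samples of noise")
    if color not in COLORS:
        raise ParameterError(f"unknown noise colour {color!r}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    if color == "white":
        return AudioSignal(white, sample_rate)
    beta = _BETA[color]
    spec = np.fft.rfft(white)
    k = np.arange(spec.size, dtype=np.float64)
    weights = np.zeros_like(k)
    weights[1:] = k[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * weights, n)
    x /= x.std()
    return AudioSignal(x, sample_rate)


def noise_gain(signal: AudioSignal, noise: AudioSignal, strength_pct: float,
               reference: Optional[np.ndarray] = None) -> float:
    """The gain scaling ``noise`` to ``strength_pct`` percent of the RMS of
    ``signal`` (or of ``reference`` samples when given)."""
    ref = signal.samples if reference is None else np.asarray(reference)
    rms_s = float(np.sqrt(np.mean(ref**2)))
    rms_n = float(np.sqrt(np.mean(noise.samples**2)))
    if strength_pct == 0:
        return 0.0
    if rms_s == 0:
        raise DegenerateInputError("cannot scale noise against a zero-RMS signal")
    if rms_n == 0:
        raise DegenerateInputError("noise track has zero RMS")
    return (strength_pct / 100.0) * rms_s / rms_n


def mix_at_strength(signal: AudioSignal, noise: AudioSignal,
                    strength_pct: float) -> AudioSignal:
    """``signal + g*noise`` with the noise RMS scaled to ``strength_pct``
    percent of the signal RMS (100% = equal powers = 0 dB true SNR)."""
    if len(signal) != len(noise) or signal.sample_rate != noise.sample_rate:
        raise ParameterError("signal and noise must share length and sample rate")
    g = noise_gain(signal, noise, strength_pct)
    return signal.replace_samples(signal.samples + g * noise.samples)


@dataclass
class SynthFixture:
    """A noisy annotated fixture with its ground truth attached.

    ``annotated`` carries the noisy waveform plus noise/song labels for
    the 500 ms pure-noise margins and the active region; ``clean`` and
    ``noise`` are the separate tracks (``noisy = clean + noise``), so the
    true SNR of the active region is computable alongside SnNR.
    """

    annotated: AnnotatedRecording
    clean: AudioSignal
    noise: AudioSignal

    @property
    def true_snr_db(self) -> float:
        """10*log10 of clean vs noise power over the song-labelled region."""
        rec = self.annotated
        s = rec.extract("song", self.clean.samples)
        n = rec.extract("song", self.noise.samples)
        return 10.0 * float(np.log10(np.mean(s * s) / np.mean(n * n)))


def noisy_tone_fixture(strength_pct: float = 100.0, seed: int = 0,
                       color: str = "white",
                       tone: ToneSpec = ToneSpec(),
                       margin_s: float = 0.5,
                       peak: float = 0.95) -> SynthFixture:
    """A stepped tone padded with pure-noise margins and polluted at the
    given strength.

    ``margin_s`` of noise-only signal is prepended and appended, labelled
    ``noise``; the tone span is labelled ``song``.  The noise is scaled
    against the RMS of the *tone portion* (the margins are measurement
    scaffolding, not signal).

    The noisy mixture is then normalized so its largest sample is
    ``peak``, with the clean and noise tracks scaled by the same factor —
    exactly what digitising a recording at full scale does.  All the
    segment metrics are scale-invariant, so this only anchors the
    amplitude convention (samples in [-1, 1]).
    """
    sr = tone.sample_rate
    t = stepped_tone(tone)
    n_margin = int(round(margin_s * sr))
    clean = np.concatenate([np.zeros(n_margin), t.samples, np.zeros(n_margin)])
    total = clean.size
    raw_noise = colored_noise(total, color, seed, sr)
    clean_sig = AudioSignal(clean, sr)
    g = noise_gain(clean_sig, raw_noise, strength_pct, reference=t.samples)
    mixture = clean + g * raw_noise.samples
    rescale = peak / float(np.max(np.abs(mixture)))
    clean_sig = AudioSignal(rescale * clean, sr)
    scaled = AudioSignal(rescale * g * raw_noise.samples, sr)
    noisy = AudioSignal(rescale * mixture, sr)
    dur = total / sr
    labels = [
        SegmentLabel(0.0, n_margin / sr, "noise"),
        SegmentLabel(n_margin / sr, (n_margin + len(t)) / sr, "song"),
        SegmentLabel((n_margin + len(t)) / sr, dur, "noise"),
    ]
    return SynthFixture(AnnotatedRecording(noisy, labels), clean_sig, scaled)
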