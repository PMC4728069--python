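"""Segment-based evaluation metrics for denoising.

In a field recording the clean song is unobservable, so classical SNR
cannot be computed.  Instead the recording is annotated with *noise-only*
intervals (short silences before/after the call) and *song* intervals
(song plus overlapping noise), and three quantities are derived:

* **SnNR** — signal-plus-noise to noise ratio,
  ``10*log10(P_song / P_noise)`` over the labelled regions;
* **success ratio** — ``log10(var(noise_before) / var(noise_after))``
  computed on the noise-only intervals before and after denoising; a
  positive value means the noise floor dropped;
* **modified PSNR** — ``20*log10(max|reference| / rms_error)`` with the
  noisy recording as reference and the denoised one as test.

"Power" is the mean squared amplitude per sample, so song and noise
regions of different lengths compare fairly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .audio import AudioSignal
from .denoise import DenoiseConfig, denoise
from .errors import AnnotationError, DegenerateMetricError

KINDS = ("noise", "song")


@dataclass(frozen=True)
class SegmentLabel:
    """A labelled time interval: ``kind`` is ``"noise"`` or ``"song"``."""

    start_s: float
    end_s: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise AnnotationError(f"unknown label kind {self.kind!r}")
        if not (0 <= self.start_s < self.end_s):
            raise AnnotationError(
                f"need 0 <= start < end, got [{self.start_s}, {self.end_s}]"
            )


def _validate_labels(labels: Sequence[SegmentLabel], duration_s: Optional[float]) -> None:
    for kind in KINDS:
        ivs = sorted((l.start_s, l.end_s) for l in labels if l.kind == kind)
        for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise AnnotationError(f"overlapping {kind} intervals at {s1:g}s")
    if duration_s is not None:
        for l in labels:
            if l.end_s > duration_s + 1e-9:
                raise AnnotationError(
                    f"label [{l.start_s}, {l.end_s}] outside recording of {duration_s:g}s"
                )


@dataclass
class AnnotatedRecording:
    """A waveform plus the labels needed for SnNR / success-ratio.

    Requires at least one noise-only and one song interval.
    """

    audio: AudioSignal
    labels: List[SegmentLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        kinds = {l.kind for l in self.labels}
        if not {"noise", "song"} <= kinds:
            raise AnnotationError("need at least one 'noise' and one 'song' interval")
        _validate_labels(self.labels, self.audio.duration_s)

    def mask(self, kind: str) -> np.ndarray:
        """Boolean sample mask of the union of intervals of ``kind``."""
        sr = self.audio.sample_rate
        m = np.zeros(len(self.audio), dtype=bool)
        for l in self.labels:
            if l.kind == kind:
                m[int(round(l.start_s * sr)): int(round(l.end_s * sr))] = True
        return m

    def extract(self, kind: str, samples: Optional[np.ndarray] = None) -> np.ndarray:
        """The concatenated samples under the ``kind`` mask (optionally from
        another equal-length sample array, e.g. the denoised waveform)."""
        x = self.audio.samples if samples is None else np.asarray(samples)
        return x[self.mask(kind)]

    def with_audio(self, audio: AudioSignal) -> "AnnotatedRecording":
        return AnnotatedRecording(audio, self.labels)


def segment_power(audio: AudioSignal,
                  labels: Iterable[SegmentLabel]) -> float:
    """Mean squared amplitude over the union of the given intervals."""
    labels = list(labels)
    sr = audio.sample_rate
    m = np.zeros(len(audio), dtype=bool)
    for l in labels:
        m[int(round(l.start_s * sr)): int(round(l.end_s * sr))] = True
    if not m.any():
        raise AnnotationError("labelled intervals cover no samples")
    x = audio.samples[m]
    return float(np.mean(x * x))


def snr(signal_power: float, noise_power: float) -> float:
    """Classical SNR in dB: ``10*log10(S/N)``."""
    if noise_power <= 0:
        raise DegenerateMetricError("noise power must be positive")
    if signal_power < 0:
        raise DegenerateMetricError("signal power must be non-negative")
    return 10.0 * math.log10(signal_power / noise_power)


def snnr(rec: AnnotatedRecording,
         samples: Optional[np.ndarray] = None) -> float:
    """Signal-plus-noise to noise ratio in dB over the labelled regions.

    With ``samples`` given, the labels of ``rec`` are applied to that
    waveform instead (e.g. to score a denoised version).
    """
    x = rec.audio.samples if samples is None else np.asarray(samples, dtype=np.float64)
    song = x[rec.mask("song")]
    noise = x[rec.mask("noise")]
    p_noise = float(np.mean(noise * noise))
    if p_noise <= 0:
        raise DegenerateMetricError("noise-region power is zero")
    return 10.0 * math.log10(float(np.mean(song * song)) / p_noise)


def success_ratio(noise_before: Sequence[float], noise_after: Sequence[float]) -> float:
    """``log10(var(Nb) / var(Na))`` over the same noise-only region.

    Population variances; > 0 means the denoiser reduced the noise floor.
    """
    nb = np.asarray(noise_before, dtype=np.float64)
    na = np.asarray(noise_after, dtype=np.float64)
    if nb.size == 0 or na.size == 0:
        raise AnnotationError("noise regions must be non-empty")
    vb, va = float(np.var(nb)), float(np.var(na))
    if va <= 0:
        raise DegenerateMetricError("after-denoising noise variance is zero")
    if vb <= 0:
        raise DegenerateMetricError("before-denoising noise variance is zero")
    return math.log10(vb / va)


def psnr(reference: AudioSignal, test: AudioSignal) -> float:
    """Modified peak signal-to-noise ratio in dB.

    ``20*log10(max|reference| / sqrt(MSE))`` with the noisy recording as
    reference and its denoised version as test.  Insensitive by design:
    the peak barely changes under denoising.
    """
    if len(reference) != len(test):
        raise DegenerateMetricError("reference and test must have equal length")
    diff = reference.samples - test.samples
    mse = float(np.mean(diff * diff))
    if mse <= 0:
        raise DegenerateMetricError("identical signals: PSNR undefined")
    peak = float(np.max(np.abs(reference.samples)))
    return 20.0 * math.log10(peak / math.sqrt(mse))


@dataclass(frozen=True)
class MetricsReport:
    """One row of an evaluation table."""

    variant: str
    snnr_db: float
    success: Optional[float]
    psnr_db: Optional[float]
    song_power: float
    noise_power: float


def _report(variant: str, rec: AnnotatedRecording,
            processed: Optional[np.ndarray]) -> MetricsReport:
    x = rec.audio.samples if processed is None else processed
    song = rec.extract("song", x)
    noise = rec.extract("noise", x)
    s = None
    p = None
    if processed is not None:
        s = success_ratio(rec.extract("noise"), noise)
        p = psnr(rec.audio, rec.audio.replace_samples(processed))
    return MetricsReport(
        variant=variant,
        snnr_db=snnr(rec, x),
        success=s,
        psnr_db=p,
        song_power=float(np.mean(song * song)),
        noise_power=float(np.mean(noise * noise)),
    )


def evaluate_variants(rec: AnnotatedRecording,
                      config: DenoiseConfig = DenoiseConfig(),
                      band: Union[str, tuple, None] = None) -> pd.DataFrame:
    """Score the original (O), filtered (F), denoised (D) and
    denoised+filtered (DF) treatments of an annotated recording.

    Returns a DataFrame with one row per variant and columns
    ``variant, SnNR, S_ratio, PSNR``.  F/DF rows require ``band``.
    """
    from .filtering import apply_filter, denoise_and_filter, resolve_band, _clip_to_nyquist

    rows = [_report("O", rec, None)]
    spec = resolve_band(band if band is not None else config.post_filter_band)
    if spec is not None:
        spec = _clip_to_nyquist(spec, rec.audio.sample_rate)
    if spec is not None:
        rows.append(_report("F", rec, apply_filter(rec.audio, spec).samples))
    d = denoise(rec.audio, config)
    rows.append(_report("D", rec, d.samples))
    if spec is not None:
        rows.append(_report("DF", rec, apply_filter(d, spec).samples))
    return pd.DataFrame(
        {
            "variant": [r.variant for r in rows],
            "SnNR": [r.snnr_db for r in rows],
            "S_ratio": [r.success for r in rows],
            "PSNR": [r.psnr_db for r in rows],
        }
    )
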