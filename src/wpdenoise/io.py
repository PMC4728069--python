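"""WAV and label-file I/O, resampling, and spectrograms."""

from __future__ import annotations

import logging
import struct
from fractions import Fraction
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .audio import AudioSignal
from .errors import AnnotationError, FormatError, ParameterError
from .metrics import SegmentLabel, _validate_labels

log = logging.getLogger(__name__)

_INT_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


def read_wav(path: Union[str, Path]) -> AudioSignal:
    """Read a WAV file into float samples normalized to [-1, 1].

    Accepts PCM 16/24/32-bit and float encodings.  Multichannel files are
    reduced to channel 0 with a logged warning.
    """
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, EOFError, OSError, struct.error) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        log.warning("%s: %d channels, using channel 0", path, data.shape[1])
        data = data[:, 0]
    if data.dtype in _INT_SCALE:
        samples = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.dtype("float32"), np.dtype("float64")):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioSignal(samples, int(rate))


def write_wav(path: Union[str, Path], signal: AudioSignal,
              encoding: str = "pcm16") -> None:
    """Write ``signal`` as a WAV file (``pcm16`` or ``float32``).

    Samples outside [-1, 1] are clipped with a logged warning.
    """
    x = signal.samples
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    if peak > 1.0:
        log.warning("%s: clipping %d samples exceeding full scale (peak %.3f)",
                    path, int(np.sum(np.abs(x) > 1.0)), peak)
        x = np.clip(x, -1.0, 1.0)
    if encoding == "pcm16":
        # symmetric with read_wav's /2^15 so roundtrip stays within one LSB
        data = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    elif encoding == "float32":
        data = x.astype(np.float32)
    else:
        raise ParameterError(f"unknown encoding {encoding!r}")
    wavfile.write(str(path), signal.sample_rate, data)


def downsample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Anti-aliased sample-rate reduction to an arbitrary lower rate.

    Polyphase resampling with the built-in anti-alias low-pass; content
    above the new Nyquist is removed, which on noisy recordings doubles
    as free high-frequency denoising.
    """
    if target_rate >= signal.sample_rate:
        raise ParameterError(
            f"target rate {target_rate} must be below current {signal.sample_rate}"
        )
    if target_rate <= 0:
        raise ParameterError("target rate must be positive")
    frac = Fraction(int(target_rate), int(signal.sample_rate))
    out = sps.resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(out, int(target_rate))


def read_labels(path: Union[str, Path]) -> List[SegmentLabel]:
    """Parse a tab-separated label file: ``start_s<TAB>end_s<TAB>label``.

    The Audacity label-track dialect; ``label`` must be ``noise`` or
    ``song``.  Returns the labels sorted by start time.
    """
    labels: List[SegmentLabel] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise AnnotationError(f"{path}:{lineno}: expected 3 tab-separated fields")
        try:
            start, end = float(parts[0]), float(parts[1])
        except ValueError:
            raise AnnotationError(f"{path}:{lineno}: non-numeric interval") from None
        labels.append(SegmentLabel(start, end, parts[2].strip()))
    if not labels:
        raise AnnotationError(f"{path}: no labels found")
    labels.sort(key=lambda l: l.start_s)
    _validate_labels(labels, None)
    return labels


def write_labels(path: Union[str, Path], labels: List[SegmentLabel]) -> None:
    """Write labels in the same tab-separated dialect."""
    lines = [f"{l.start_s:.6f}\t{l.end_s:.6f}\t{l.kind}" for l in labels]
    Path(path).write_text("\n".join(lines) + "\n")


def spectrogram(signal: AudioSignal, window_len: int = 512,
                overlap: Optional[int] = None
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude grid of ``signal``.

    Hann-windowed frames of ``window_len`` samples with ``overlap``
    samples shared between consecutive frames (default 50%).  Returns
    ``(freqs_hz, times_s, mag)`` where ``mag`` has shape
    ``(window_len//2 + 1, n_frames)`` with
    ``n_frames = (n - overlap) // (window_len - overlap)``.
    """
    n = len(signal)
    if overlap is None:
        overlap = window_len // 2
    if window_len < 2 or window_len > n:
        raise ParameterError(f"window_len {window_len} not in [2, {n}]")
    if not (0 <= overlap < window_len):
        raise ParameterError(f"overlap {overlap} not in [0, {window_len})")
    hop = window_len - overlap
    n_frames = (n - overlap) // hop
    win = sps.get_window("hann", window_len, fftbins=True)
    idx = hop * np.arange(n_frames)[:, None] + np.arange(window_len)[None, :]
    frames = signal.samples[idx] * win
    mag = np.abs(np.fft.rfft(frames, axis=1)).T
    freqs = np.fft.rfftfreq(window_len, d=1.0 / signal.sample_rate)
    times = (hop * np.arange(n_frames) + window_len / 2) / signal.sample_rate
    return freqs, times, mag


def render_spectrogram(signal: AudioSignal, path: Union[str, Path],
                       window_len: int = 512, overlap: Optional[int] = None,
                       floor_db: float = -80.0) -> None:
    """Render a dB-scaled grayscale spectrogram image to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freqs, times, mag = spectrogram(signal, window_len, overlap)
    db = 20.0 * np.log10(np.maximum(mag, 1e-12))
    db = np.maximum(db - db.max(), floor_db)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.pcolormesh(times, freqs, db, cmap="gray_r", shading="auto")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
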