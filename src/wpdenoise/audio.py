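"""The sampled-waveform container used throughout the package."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples
        Amplitude values, nominally in [-1, 1].  Multichannel arrays are
        reduced to channel 0 with a logged warning (the pipeline is mono).
    sample_rate
        Sampling frequency in Hz; must be positive.
    """

    samples: np.ndarray
    sample_rate: int
    # normalized in __post_init__; frozen dataclass, so use object.__setattr__
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim == 2:
            log.warning("multichannel input: using channel 0 of %d", x.shape[1])
            x = x[:, 0]
        if x.ndim != 1:
            raise ParameterError(f"samples must be 1-D (or 2-D multichannel), got ndim={x.ndim}")
        if x.size < 1:
            raise ParameterError("signal must contain at least one sample")
        if not np.all(np.isfinite(x)):
            raise ParameterError("signal contains NaN or Inf samples")
        sr = int(self.sample_rate)
        if sr <= 0:
            raise ParameterError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "sample_rate", sr)
        object.__setattr__(self, "_validated", True)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def nyquist(self) -> float:
        """Nyquist frequency (half the sample rate) in Hz."""
        return self.sample_rate / 2.0

    def replace_samples(self, samples: np.ndarray) -> "AudioSignal":
        """A new signal with the same sample rate and different samples."""
        return AudioSignal(samples, self.sample_rate)
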