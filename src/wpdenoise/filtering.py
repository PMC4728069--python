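"""Conventional post-filtering keyed to species frequency bands.

After wavelet shrinkage, any residual noise outside the frequency range a
species actually uses can be removed with an ordinary band-pass or
low-pass filter.  Filters are linear-phase FIR (Kaiser window design, >=
40 dB stopband by default) applied with group-delay compensation so the
overall operation is zero-phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal
from .denoise import DenoiseConfig, denoise
from .errors import FilterDesignError, ParameterError

log = logging.getLogger(__name__)

#: fraction of Nyquist above which a clipped band edge counts as "all-pass"
_NYQ_MARGIN = 0.995


@dataclass(frozen=True)
class FilterSpec:
    """A low-pass or band-pass filter specification.

    ``kind`` is ``"low-pass"`` (``low_hz`` absent or 0) or ``"band-pass"``
    (``low_hz > 0``).  ``transition_frac`` sets the transition width as a
    fraction of the governing cutoff (the lower edge for band-pass, the
    upper edge for low-pass).
    """

    kind: str
    high_hz: float
    low_hz: Optional[float] = None
    stopband_atten_db: float = 40.0
    transition_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("low-pass", "band-pass"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.high_hz <= 0:
            raise ParameterError("high_hz must be positive")
        if self.kind == "band-pass":
            if self.low_hz is None or self.low_hz <= 0:
                raise ParameterError("band-pass requires low_hz > 0")
            if self.low_hz >= self.high_hz:
                raise ParameterError("need low_hz < high_hz")
        elif self.low_hz not in (None, 0, 0.0):
            raise ParameterError("low-pass must have low_hz absent or 0")
        if self.stopband_atten_db <= 0 or not (0 < self.transition_frac < 1):
            raise ParameterError("invalid attenuation or transition fraction")

    @classmethod
    def from_band(cls, low_hz: float, high_hz: float, **kw) -> "FilterSpec":
        """Band edges to spec; a band starting at 0 Hz becomes low-pass."""
        if low_hz <= 0:
            return cls("low-pass", high_hz=high_hz, **kw)
        return cls("band-pass", high_hz=high_hz, low_hz=low_hz, **kw)


def design_filter(spec: FilterSpec, sample_rate: int) -> np.ndarray:
    """Design the FIR taps for ``spec`` at ``sample_rate``.

    Kaiser-window design sized for ``stopband_atten_db`` (plus a small
    margin) over a transition band of ``transition_frac`` times the
    governing cutoff.  Returns an odd-length, linear-phase tap array.

    Raises
    ------
    FilterDesignError
        If any cutoff reaches the Nyquist frequency.
    """
    nyq = sample_rate / 2.0
    if spec.high_hz >= nyq:
        raise FilterDesignError(
            f"cutoff {spec.high_hz} Hz >= Nyquist {nyq} Hz at fs={sample_rate}"
        )
    governing = spec.low_hz if spec.kind == "band-pass" else spec.high_hz
    width_hz = spec.transition_frac * governing
    # keep the transition band inside (0, Nyquist)
    width_hz = min(width_hz, 2 * (nyq - spec.high_hz) * 0.95)
    if spec.kind == "band-pass":
        width_hz = min(width_hz, 2 * spec.low_hz * 0.95)
    if width_hz <= 0:
        raise FilterDesignError("transition band does not fit below Nyquist")
    numtaps, beta = sps.kaiserord(spec.stopband_atten_db + 5.0, width_hz / nyq)
    numtaps |= 1  # linear phase type I
    if spec.kind == "band-pass":
        taps = sps.firwin(numtaps, [spec.low_hz, spec.high_hz],
                          window=("kaiser", beta), pass_zero=False, fs=sample_rate)
    else:
        taps = sps.firwin(numtaps, spec.high_hz,
                          window=("kaiser", beta), pass_zero=True, fs=sample_rate)
    return taps


def apply_filter(signal: AudioSignal, spec: FilterSpec) -> AudioSignal:
    """Filter ``signal`` with zero overall phase shift.

    The FIR filter has exactly linear phase, so the output is shifted back
    by the (numtaps-1)/2 group delay; length and sample rate are
    preserved.
    """
    taps = design_filter(spec, signal.sample_rate)
    delay = (len(taps) - 1) // 2
    padded = np.concatenate([signal.samples, np.zeros(delay)])
    out = sps.lfilter(taps, 1.0, padded)[delay:]
    return signal.replace_samples(out)


class SpeciesBandTable:
    """Mapping from ``species.calltype`` keys to (low_hz, high_hz) bands.

    The packaged defaults cover New Zealand species commonly targeted by
    acoustic monitoring (kiwi, kakapo, ruru, robin, tui, kaka, hihi,
    saddleback) plus a few North American songbirds; the file format is
    plain ``key = low,high`` text so field teams can edit it.
    """

    def __init__(self, bands: Dict[str, Tuple[float, float]]):
        for key, (lo, hi) in bands.items():
            if not (0 <= lo < hi):
                raise ParameterError(f"invalid band for {key!r}: ({lo}, {hi})")
        self.bands = dict(bands)

    def __getitem__(self, key: str) -> Tuple[float, float]:
        try:
            return self.bands[key]
        except KeyError:
            raise LookupError(
                f"unknown species key {key!r}; known: {sorted(self.bands)}"
            ) from None

    def __contains__(self, key: str) -> bool:
        return key in self.bands

    def __len__(self) -> int:
        return len(self.bands)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SpeciesBandTable":
        bands: Dict[str, Tuple[float, float]] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, value = line.split("=", 1)
                lo, hi = value.split(",")
                bands[key.strip()] = (float(lo), float(hi))
            except ValueError:
                raise ParameterError(f"{path}:{lineno}: cannot parse {raw!r}") from None
        return cls(bands)

    @classmethod
    def default(cls) -> "SpeciesBandTable":
        """The packaged species-band table."""
        ref = resources.files("wpdenoise") / "data" / "species_bands.cfg"
        with resources.as_file(ref) as path:
            return cls.from_file(path)


def resolve_band(band: Union[str, FilterSpec, Tuple[float, float], None],
                 table: Optional[SpeciesBandTable] = None
                 ) -> Optional[FilterSpec]:
    """Turn a species key, (low, high) pair or FilterSpec into a FilterSpec."""
    if band is None:
        return None
    if isinstance(band, FilterSpec):
        return band
    if isinstance(band, str):
        table = table if table is not None else SpeciesBandTable.default()
        lo, hi = table[band]
        return FilterSpec.from_band(lo, hi)
    lo, hi = band
    return FilterSpec.from_band(lo, hi)


def _clip_to_nyquist(spec: FilterSpec, sample_rate: int) -> Optional[FilterSpec]:
    """Clip a band that exceeds the signal's Nyquist; None means all-pass."""
    nyq = sample_rate / 2.0
    if spec.high_hz < _NYQ_MARGIN * nyq:
        return spec
    if spec.kind == "low-pass":
        log.warning("band (0, %g) covers the whole spectrum at fs=%d; "
                    "skipping post-filter", spec.high_hz, sample_rate)
        return None
    log.warning("band upper edge %g Hz exceeds Nyquist %g Hz; clipping",
                spec.high_hz, nyq)
    return FilterSpec("band-pass", high_hz=_NYQ_MARGIN * nyq, low_hz=spec.low_hz,
                      stopband_atten_db=spec.stopband_atten_db,
                      transition_frac=spec.transition_frac)


def denoise_and_filter(signal: AudioSignal,
                       config: DenoiseConfig = DenoiseConfig(),
                       band: Union[str, FilterSpec, Tuple[float, float], None] = None,
                       table: Optional[SpeciesBandTable] = None) -> AudioSignal:
    """Wavelet shrinkage followed by the species band post-filter.

    ``band`` may be a ``species.calltype`` key, an explicit ``(low, high)``
    pair, a :class:`FilterSpec`, or None (falls back to
    ``config.post_filter_band``; if that is also unset the filter stage is
    skipped).  A band reaching from 0 Hz to at least Nyquist is the
    all-pass limit and likewise skips the filter.
    """
    if band is None:
        band = config.post_filter_band
    spec = resolve_band(band, table)
    out = denoise(signal, config)
    if spec is None:
        return out
    spec = _clip_to_nyquist(spec, signal.sample_rate)
    if spec is None:
        return out
    return apply_filter(out, spec)
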