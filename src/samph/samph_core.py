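"""Stage 1 of the S-AMPH model: spectral filterbank and Hilbert envelopes.

The z-scored acoustic signal is split into five spectral bands by adjacent FIR
band-pass filters (edges 100, 300, 700, 1750, 3900, 7250 Hz), the Hilbert
envelope is extracted from each band-limited signal at the full audio rate, and
the five envelopes are polyphase-resampled to the envelope rate (1050 Hz) at
which all modulation-rate analysis happens.  Band 1 (100-300 Hz) corresponds to
the fundamental-frequency region of adult speech.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import hilbert, resample_poly

from .errors import ConfigurationError, InputError
from .filters import design_bandpass, max_taps_for, zero_phase_filter
from .io_segments import AudioSegment

DEFAULT_EDGES = (100.0, 300.0, 700.0, 1750.0, 3900.0, 7250.0)
DEFAULT_ENV_RATE = 1050.0
#: Fastest modulation band extends to 40 Hz; the envelope rate must exceed 2x.
MIN_ENV_RATE = 2 * 40.0


@dataclass(frozen=True)
class SpectralBandSpec:
    """The 5-band spectral decomposition: 6 ascending edge frequencies in Hz."""

    edges: tuple[float, ...] = DEFAULT_EDGES
    transition_frac: float = 0.25  # FIR transition width / band low edge

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or any(
            b <= a for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ConfigurationError(f"edges must be strictly ascending, got {self.edges}")

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    @property
    def bands(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))


@dataclass
class EnvelopeSet:
    """Five nonnegative spectral-band envelopes at the envelope sampling rate."""

    envelopes: np.ndarray  # shape (n_bands, n_samples)
    env_rate: float = DEFAULT_ENV_RATE

    def __post_init__(self) -> None:
        self.envelopes = np.atleast_2d(np.asarray(self.envelopes, dtype=float))

    @property
    def n_bands(self) -> int:
        return self.envelopes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.envelopes.shape[1]


def spectral_filterbank(
    segment: AudioSegment, spec: SpectralBandSpec | None = None
) -> np.ndarray:
    """Band-pass the segment into the spectral bands; returns (n_bands, n) array.

    Each band is the zero-phase FIR band-pass of the input between adjacent
    edges; signal length is preserved.
    """
    spec = spec or SpectralBandSpec()
    x = segment.samples
    fs = segment.rate
    if spec.edges[-1] >= fs / 2:
        raise InputError(
            f"top spectral edge {spec.edges[-1]} Hz requires rate > "
            f"{2 * spec.edges[-1]:.0f} Hz, got {fs} Hz"
        )
    cap = max_taps_for(x.size)
    out = np.empty((spec.n_bands, x.size))
    for i, (lo, hi) in enumerate(spec.bands):
        taps = design_bandpass(
            fs, lo, hi,
            transition_frac=spec.transition_frac,
            max_taps=cap,
            min_taps=int(np.ceil(fs / lo)),
        )
        out[i] = zero_phase_filter(x, taps)
    return out


def hilbert_envelope(band_signal: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal; same length as input, >= 0 everywhere."""
    x = np.asarray(band_signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("band signal contains non-finite values")
    n = x.size
    nfft = next_fast_len(n)
    return np.abs(hilbert(x, N=nfft)[:n])


def downsample_envelopes(
    envelopes: np.ndarray,
    rate: float,
    target_rate: float = DEFAULT_ENV_RATE,
) -> EnvelopeSet:
    """Anti-alias filter and polyphase-resample envelopes to the envelope rate.

    The rate ratio is taken as the nearest rational with denominator <= 1000.
    Filter-ringing negatives are clipped to zero to preserve envelope
    nonnegativity.
    """
    if target_rate <= MIN_ENV_RATE:
        raise ConfigurationError(
            f"target envelope rate {target_rate} Hz cannot resolve 40 Hz "
            f"modulations; need > {MIN_ENV_RATE:.0f} Hz"
        )
    frac = Fraction(rate / target_rate).limit_denominator(1000)
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    down = resample_poly(env, up=frac.denominator, down=frac.numerator, axis=-1)
    np.clip(down, 0.0, None, out=down)
    return EnvelopeSet(envelopes=down, env_rate=float(target_rate))


def segment_envelopes(
    segment: AudioSegment,
    spec: SpectralBandSpec | None = None,
    env_rate: float = DEFAULT_ENV_RATE,
) -> EnvelopeSet:
    """Convenience: filterbank -> Hilbert envelopes -> downsample, in one call."""
    bands = spectral_filterbank(segment, spec)
    envs = np.stack([hilbert_envelope(b) for b in bands])
    return downsample_envelopes(envs, segment.rate, env_rate)
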