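"""Zero-phase FIR band-pass filtering shared by the spectral and modulation stages.

All band-pass filters in the pipeline are windowed-sinc (Hamming) FIRs applied
forward-backward, so no stage introduces group delay.  This is load-bearing:
the phase synchronisation index compares instantaneous phases of waveforms that
were filtered independently, and any differential delay between bands would
masquerade as (de)synchronisation.

The Hamming design rule targets a transition width of ``transition_frac`` times
the band's low edge.  For modulation-rate bands (low edges down to 0.9 Hz) the
ideal order can exceed the signal itself, so the order is capped by the
available signal length; callers pass ``max_taps`` (conventionally
``(n_samples - 1) // 3``) and a floor of one cycle of the low edge is enforced
before giving up with :class:`~samph.errors.DegenerateInputError`.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve, firwin

from .errors import ConfigurationError, DegenerateInputError

#: Hamming-window transition-bandwidth constant: width ~ HAMMING_TBW * fs / ntaps.
HAMMING_TBW = 3.3


def max_taps_for(n_samples: int) -> int:
    """Largest admissible filter length for a signal of ``n_samples`` samples."""
    return (int(n_samples) - 1) // 3


def design_bandpass(
    fs: float,
    low: float,
    high: float,
    *,
    transition_frac: float = 0.25,
    max_taps: int | None = None,
    min_taps: int | None = None,
) -> np.ndarray:
    """Design a linear-phase FIR band-pass for the band [low, high] Hz.

    Parameters
    ----------
    fs : sampling rate in Hz.
    low, high : band edges in Hz, 0 < low < high < fs/2.
    transition_frac : target transition width as a fraction of ``low``.
    max_taps : cap on the number of taps (typically from signal length).
    min_taps : floor below which the band is unresolvable; violating it raises
        :class:`DegenerateInputError`.
    """
    if not (0.0 < low < high):
        raise ConfigurationError(f"band edges must satisfy 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ConfigurationError(f"high edge {high} Hz not below Nyquist {fs / 2} Hz")
    width = transition_frac * low
    ntaps = int(np.ceil(HAMMING_TBW * fs / width))
    if max_taps is not None and ntaps > max_taps:
        ntaps = int(max_taps)
    if ntaps % 2 == 0:
        ntaps -= 1
    if ntaps < 3 or (min_taps is not None and ntaps < min_taps):
        raise DegenerateInputError(
            f"signal too short to resolve the {low}-{high} Hz band "
            f"(usable taps {ntaps}, need >= {min_taps})"
        )
    return firwin(ntaps, [low, high], pass_zero=False, window="hamming", fs=fs)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR forward-backward (zero phase) with reflect padding.

    Equivalent to filtfilt with the same taps, but via FFT convolution so
    multi-thousand-tap modulation filters remain cheap on minute-long signals.
    The signal is reflect-padded by one filter length before filtering, and the
    output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    n = len(taps)
    if x.size <= n:
        raise DegenerateInputError(
            f"signal of {x.size} samples shorter than filter of {n} taps"
        )
    padded = np.pad(x, n, mode="reflect")
    y = fftconvolve(padded, taps, mode="same")
    # second (time-reversed) pass; taps are symmetric so this is the backward run
    y = fftconvolve(y, taps[::-1], mode="same")
    return y[n:-n]


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    *,
    transition_frac: float = 0.25,
    min_taps: int | None = None,
) -> np.ndarray:
    """Zero-phase band-pass of ``x``, order adapted to the signal length."""
    taps = design_bandpass(
        fs, low, high,
        transition_frac=transition_frac,
        max_taps=max_taps_for(len(x)),
        min_taps=min_taps,
    )
    return zero_phase_filter(x, taps)


def noise_bandwidth(taps: np.ndarray, fs: float, nfft: int = 1 << 17) -> float:
    """Equivalent noise bandwidth (Hz) of the two-pass (forward-backward) filter.

    The two-pass power gain is |H(f)|^4.  ENBW = integral |H|^4 df / max |H|^4,
    i.e. the width of the ideal rectangular filter passing the same white-noise
    power at the realised peak gain.
    """
    h = np.abs(np.fft.rfft(taps, nfft)) ** 4
    peak = h.max()
    if peak <= 0:
        raise ConfigurationError("filter has zero response")
    df = fs / nfft
    return float(h.sum() * df / peak)
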