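"""n:m phase synchronisation between nested amplitude-modulation bands.

The phase synchronisation index between a slow AM with instantaneous phase
theta1 and a faster AM with phase theta2 is

    PSI = | < exp(i (n*theta1 - theta2)) > |

where n is the integer frequency multiplier (2 for delta-theta, 3 for
theta-beta/low-gamma: the theta rate sits near twice the delta rate and the
beta/low-gamma rate near three times the theta rate) and the angle brackets
average over time points.  PSI is the resultant length of the generalised
phase difference on the unit circle: 0 means no synchronisation (random
rhythm), 1 perfect n:m locking (perfect rhythmic regularity).  Computing on
complex unit phasors makes the statistic invariant to phase wrapping.

Aggregation follows the study design: the two PSIs are computed in each of the
five spectral bands, averaged across bands within a segment, and a grand mean
over a participant's segments (separately by speech register) gives the
participant-level value.  Means are unweighted at both levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import hilbert

from .errors import DegenerateInputError, InputError
from .modulation import AMDecomposition

#: Seconds trimmed from each end of the phase series before averaging;
#: drops filter edge transients (delta-band FIRs ring for hundreds of ms).
DEFAULT_TRIM_S = 0.5
#: Minimum phase-series length after trimming, in seconds.
MIN_SERIES_S = 2.0


@dataclass
class PhasePair:
    """Two instantaneous-phase series plus the integer multiplier n on the slower one."""

    theta1: np.ndarray  # phase of the slower AM, radians
    theta2: np.ndarray  # phase of the faster AM, radians
    n: int

    def __post_init__(self) -> None:
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.theta2 = np.asarray(self.theta2, dtype=float)
        if self.theta1.shape != self.theta2.shape:
            raise InputError("phase series must have equal length")
        if self.n < 1:
            raise InputError(f"multiplier n must be a positive integer, got {self.n}")


@dataclass
class PSIResult:
    """Delta-theta and theta-beta/low-gamma PSI per spectral band plus band means."""

    per_band_delta_theta: np.ndarray       # (n_spectral_bands,)
    per_band_theta_betagamma: np.ndarray   # (n_spectral_bands,)
    delta_theta: float                     # mean over spectral bands / segments
    theta_betagamma: float


def instantaneous_phase(am_waveform: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal of a zero-mean AM waveform, in (-pi, pi]."""
    x = np.asarray(am_waveform, dtype=float)
    if not np.any(x):
        raise DegenerateInputError("all-zero waveform has no instantaneous phase")
    n = x.size
    nfft = next_fast_len(n)
    return np.angle(hilbert(x, N=nfft)[:n])


def psi(pair: PhasePair, trim: float = DEFAULT_TRIM_S, rate: float = 1050.0) -> float:
    """Phase synchronisation index of a phase pair; always in [0, 1].

    ``trim`` seconds are dropped from each end before averaging.
    """
    k = int(round(trim * rate))
    sl = slice(k, pair.theta1.size - k if k else None)
    th1, th2 = pair.theta1[sl], pair.theta2[sl]
    if th1.size < MIN_SERIES_S * rate:
        raise DegenerateInputError(
            f"phase series of {th1.size} samples after trimming is shorter than "
            f"{MIN_SERIES_S} s at {rate} Hz"
        )
    return float(np.abs(np.mean(np.exp(1j * (pair.n * th1 - th2)))))


def segment_psi(
    am: AMDecomposition, trim: float = DEFAULT_TRIM_S
) -> PSIResult:
    """Per-spectral-band delta-theta (n=2) and theta-beta/gamma (n=3) PSI of a segment."""
    nb = am.n_spectral_bands
    dt = np.empty(nb)
    tbg = np.empty(nb)
    for b in range(nb):
        ph = [instantaneous_phase(am.waveforms[b, j]) for j in range(3)]
        dt[b] = psi(PhasePair(ph[0], ph[1], n=2), trim=trim, rate=am.env_rate)
        tbg[b] = psi(PhasePair(ph[1], ph[2], n=3), trim=trim, rate=am.env_rate)
    return PSIResult(
        per_band_delta_theta=dt,
        per_band_theta_betagamma=tbg,
        delta_theta=float(dt.mean()),
        theta_betagamma=float(tbg.mean()),
    )


def participant_psi(segments: Sequence[PSIResult]) -> PSIResult:
    """Grand mean of segment-level PSI results (unweighted over segments).

    Callers are responsible for passing segments of a single speech register.
    """
    if not segments:
        raise InputError("participant has no segments to average")
    dt = np.mean([s.per_band_delta_theta for s in segments], axis=0)
    tbg = np.mean([s.per_band_theta_betagamma for s in segments], axis=0)
    return PSIResult(
        per_band_delta_theta=dt,
        per_band_theta_betagamma=tbg,
        delta_theta=float(np.mean([s.delta_theta for s in segments])),
        theta_betagamma=float(np.mean([s.theta_betagamma for s in segments])),
    )
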