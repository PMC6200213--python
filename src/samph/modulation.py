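"""Stage 2 of the S-AMPH model: modulation-rate analysis of the band envelopes.

Three things are computed from each spectral band's envelope:

* the three band-limited amplitude-modulation (AM) waveforms — delta
  (0.9-2.5 Hz), theta (2.5-12 Hz) and beta/low-gamma (12-40 Hz) — which feed
  the phase-synchronisation analysis;
* a 24-channel modulation spectrum with logarithmically spaced channels over
  0.9-40 Hz, expressed per spectral band as the relative power difference of
  each channel from the across-channel mean (so it is unitless, scale
  invariant, and averages to zero by construction), then averaged across the
  five spectral bands;
* band energies: the (signed) area under the differenced modulation spectrum
  within each AM band, integrated against log10 frequency so octaves are
  weighted evenly.  The three band areas partition the full-range area exactly.

Channel power is the mean-square channel-filter output normalised by the
realised filter's equivalent noise bandwidth, i.e. a power spectral density
estimate: a spectrally flat envelope yields a flat (near-zero differenced)
modulation spectrum regardless of the geometric channel spacing.  Raw
mean-square power is available via ``normalize_bandwidth=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .filters import design_bandpass, max_taps_for, noise_bandwidth, zero_phase_filter
from .samph_core import EnvelopeSet

AM_BANDS = (
    ("delta", 0.9, 2.5),
    ("theta", 2.5, 12.0),
    ("beta_low_gamma", 12.0, 40.0),
)

#: Seconds trimmed from each end before computing channel power (edge transients).
POWER_TRIM_S = 0.5


@dataclass(frozen=True)
class AMBandSpec:
    """The three contiguous AM bands spanning 0.9-40 Hz."""

    bands: tuple[tuple[str, float, float], ...] = AM_BANDS
    transition_frac: float = 0.25

    def __post_init__(self) -> None:
        for (_, _, hi_a), (_, lo_b, _) in zip(self.bands, self.bands[1:]):
            if hi_a != lo_b:
                raise ValueError("AM bands must be contiguous and ascending")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def full_range(self) -> tuple[float, float]:
        return self.bands[0][1], self.bands[-1][2]


@dataclass
class AMDecomposition:
    """Per spectral band, the three band-limited zero-mean AM waveforms."""

    waveforms: np.ndarray  # shape (n_spectral_bands, 3, n_samples)
    env_rate: float
    band_names: tuple[str, ...] = tuple(b[0] for b in AM_BANDS)

    @property
    def n_spectral_bands(self) -> int:
        return self.waveforms.shape[0]


@dataclass
class ModulationSpectrum:
    """24-channel differenced modulation spectrum per spectral band and averaged."""

    channel_centers: np.ndarray          # (n_channels,) Hz, geometric spacing
    differenced_power: np.ndarray        # (n_spectral_bands, n_channels)
    averaged: np.ndarray                 # (n_channels,) mean over spectral bands


@dataclass
class BandEnergy:
    """Signed AUC of the differenced modulation spectrum per AM band.

    ``per_band`` has shape (n_spectral_bands, 3); the scalar attributes are the
    across-spectral-band averages.  delta + theta + beta/gamma equals the AUC
    over the full modulation range on the shared integration grid.
    """

    per_band: np.ndarray
    delta_auc: float
    theta_auc: float
    beta_gamma_auc: float
    total_auc: float


def am_filterbank(env_set: EnvelopeSet, spec: AMBandSpec | None = None) -> AMDecomposition:
    """Isolate the three AM bands from each spectral-band envelope.

    Zero-phase FIR band-passes; output waveforms are mean-removed.  Raises
    :class:`DegenerateInputError` when the envelope is too short for even a
    one-cycle delta-band filter (~3.3 s at 1050 Hz).
    """
    spec = spec or AMBandSpec()
    fs = env_set.env_rate
    n = env_set.n_samples
    cap = max_taps_for(n)
    out = np.empty((env_set.n_bands, len(spec.bands), n))
    for j, (_, lo, hi) in enumerate(spec.bands):
        taps = design_bandpass(
            fs, lo, hi,
            transition_frac=spec.transition_frac,
            max_taps=cap,
            min_taps=int(np.ceil(fs / lo)),
        )
        for i in range(env_set.n_bands):
            y = zero_phase_filter(env_set.envelopes[i], taps)
            out[i, j] = y - y.mean()
    return AMDecomposition(waveforms=out, env_rate=fs, band_names=spec.names)


def modulation_channel_edges(
    n_channels: int = 24, frange: tuple[float, float] = (0.9, 40.0)
) -> np.ndarray:
    """n_channels+1 logarithmically spaced channel edges over ``frange``."""
    return np.geomspace(frange[0], frange[1], n_channels + 1)


def modulation_spectrum(
    env_set: EnvelopeSet,
    n_channels: int = 24,
    frange: tuple[float, float] = (0.9, 40.0),
    mode: str = "relative",
    normalize_bandwidth: bool = True,
    trim: float = POWER_TRIM_S,
) -> ModulationSpectrum:
    """Differenced modulation power spectrum of a set of band envelopes.

    Per spectral band: channel power P_c -> mean over channels P̄ ->
    D_c = (P_c - P̄)/P̄ (``mode="relative"``) or P_c - P̄ (``mode="difference"``);
    the averaged spectrum is the mean of D over spectral bands.
    """
    if mode not in ("relative", "difference"):
        raise ValueError(f"mode must be 'relative' or 'difference', got {mode!r}")
    fs = env_set.env_rate
    edges = modulation_channel_edges(n_channels, frange)
    centers = np.sqrt(edges[:-1] * edges[1:])
    cap = max_taps_for(env_set.n_samples)
    k = int(round(trim * fs))
    sl = slice(k, env_set.n_samples - k if k else None)

    power = np.empty((env_set.n_bands, n_channels))
    for c in range(n_channels):
        taps = design_bandpass(
            fs, edges[c], edges[c + 1],
            transition_frac=0.25,
            max_taps=cap,
            min_taps=int(np.ceil(fs / edges[c])),
        )
        enbw = noise_bandwidth(taps, fs) if normalize_bandwidth else 1.0
        for i in range(env_set.n_bands):
            y = zero_phase_filter(env_set.envelopes[i], taps)[sl]
            power[i, c] = np.mean(y**2) / enbw

    pbar = power.mean(axis=1, keepdims=True)
    if np.any(pbar <= 0):
        raise DegenerateInputError("silent envelope: mean modulation power is zero")
    diff = power - pbar
    if mode == "relative":
        diff = diff / pbar
    return ModulationSpectrum(
        channel_centers=centers,
        differenced_power=diff,
        averaged=diff.mean(axis=0),
    )


def _auc_on_log_grid(
    logf: np.ndarray, values: np.ndarray, lo: float, hi: float
) -> float:
    """Trapezoidal integral of values(logf) restricted to [log10 lo, log10 hi].

    Band limits falling between channel centers are handled by linear
    interpolation, so adjacent bands share their boundary ordinate exactly and
    the per-band areas partition the full-range area.
    """
    llo, lhi = max(np.log10(lo), logf[0]), min(np.log10(hi), logf[-1])
    if lhi <= llo:
        return 0.0
    grid = np.concatenate(([llo], logf[(logf > llo) & (logf < lhi)], [lhi]))
    vals = np.interp(grid, logf, values)
    return float(np.trapezoid(vals, grid))


def band_energy(mod_spec: ModulationSpectrum, spec: AMBandSpec | None = None) -> BandEnergy:
    """Signed AUC of the differenced spectrum within each AM band's limits."""
    spec = spec or AMBandSpec()
    logf = np.log10(mod_spec.channel_centers)
    d = mod_spec.differenced_power
    per_band = np.array([
        [_auc_on_log_grid(logf, d[i], lo, hi) for (_, lo, hi) in spec.bands]
        for i in range(d.shape[0])
    ])
    avg = per_band.mean(axis=0)
    total = float(np.mean([
        _auc_on_log_grid(logf, d[i], *spec.full_range) for i in range(d.shape[0])
    ]))
    return BandEnergy(
        per_band=per_band,
        delta_auc=float(avg[0]),
        theta_auc=float(avg[1]),
        beta_gamma_auc=float(avg[2]),
        total_auc=total,
    )
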