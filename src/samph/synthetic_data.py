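"""Synthetic speech-like audio with known hierarchical AM structure.

Real recordings for this kind of study are rarely shareable, so every upstream
stage is validated against signals whose modulation hierarchy is known exactly.
A synthetic segment is a sum of five band-limited noise (or tone) carriers,
one per spectral band, each multiplied by the product of three nonnegative
modulators:

    m_j(t) = 1 + depth_j * cos(phi_j(t)),   j in {delta, theta, beta/gamma}

The modulator phases are chained so the n:m coupling is controllable:
``phi_theta = 2*phi_delta + eps_dt(t)`` and ``phi_bg = 3*phi_theta +
eps_tbg(t)``, where each jitter process ``eps`` is a slowly varying
(band-limited below ~0.5 Hz) random process whose marginal distribution is
von Mises(0, kappa).  ``kappa -> inf`` gives deterministic n:m locking
(PSI -> 1); ``kappa = 0`` gives independent phase drift (PSI -> 0); in between
the expected PSI on the true phases is the Bessel ratio I1(kappa)/I0(kappa).
The jitter is slow rather than i.i.d. per sample because i.i.d. jitter at the
envelope rate is broadband noise that no modulation filter could pass, whereas
speech-like desynchronisation (slowing down, hesitation) evolves over seconds.

The 1:2:6 rate chain fixes the modulator frequencies at f_delta, 2*f_delta and
6*f_delta; the default f_delta = 2.3 Hz (jittered +-8% per realisation) keeps
all three realised rates inside their nominal AM bands (delta 0.9-2.5, theta
2.5-12, beta/low-gamma 12-40 Hz).

Cohort generation produces an on-disk dataset in the manifest dialect of
:mod:`samph.io_segments`: per-participant coupling concentrations drawn from
group-level distributions, WAV files, and a ground-truth table.  Rhythmic
register segments are generated with high kappa for every group, emulating the
finding that deliberately rhythmic speech shows no group differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.special import i0e, i1e, ndtr
from scipy.stats import vonmises

from .errors import ConfigurationError, InputError
from .filters import bandpass
from .io_segments import GROUPS, REQUIRED_COLUMNS, AudioSegment
from .samph_core import DEFAULT_EDGES, DEFAULT_ENV_RATE


def bessel_ratio(kappa: float) -> float:
    """Mean resultant length I1(kappa)/I0(kappa) of a von Mises(0, kappa) variable."""
    if kappa == np.inf:
        return 1.0
    if kappa <= 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic segment."""

    duration: float = 10.0            # s
    rate: float = 44100.0             # audio sampling rate, Hz
    env_rate: float = DEFAULT_ENV_RATE
    carrier_mode: str = "noise"       # "noise" | "tones"
    f_delta: float = 2.3              # nominal delta modulator rate, Hz
    rate_jitter: float = 0.08         # fractional +- jitter of f_delta per segment
    depths: float | tuple = 0.5       # scalar, per-AM-band (3,) or per (5, 3)
    kappa_dt: float = 4.0             # delta-theta von Mises concentration
    kappa_tbg: float = 4.0            # theta-beta/gamma concentration
    jitter_band: tuple[float, float] = (0.08, 0.4)  # phase-jitter passband, Hz
    edges: tuple[float, ...] = DEFAULT_EDGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 3.0:
            raise ConfigurationError("synthetic segments must last at least 3 s")
        d = np.asarray(self.depths, dtype=float)
        if np.any(d < 0) or np.any(d > 1):
            raise ConfigurationError("modulation depths must lie in [0, 1]")
        if self.carrier_mode not in ("noise", "tones"):
            raise ConfigurationError(f"unknown carrier mode {self.carrier_mode!r}")


@dataclass
class Modulators:
    """True modulator phases (radians, at env_rate) and unit-depth waveforms."""

    t: np.ndarray
    phase_delta: np.ndarray
    phase_theta: np.ndarray
    phase_bg: np.ndarray
    f_delta: float           # realised delta rate, Hz
    env_rate: float

    @property
    def phases(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.phase_delta, self.phase_theta, self.phase_bg

    def true_psi(self) -> tuple[float, float]:
        """PSI evaluated on the true phases: (delta-theta, theta-beta/gamma)."""
        dt = np.abs(np.mean(np.exp(1j * (2 * self.phase_delta - self.phase_theta))))
        tbg = np.abs(np.mean(np.exp(1j * (3 * self.phase_theta - self.phase_bg))))
        return float(dt), float(tbg)


def _band_limited_gaussian(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Stationary Gaussian process, flat spectrum over ``band``, exact N(0,1) marginal.

    Synthesised in the Fourier domain (i.i.d. complex normal coefficients in
    the passband, zero elsewhere) and scaled analytically, so every time point
    is exactly standard normal regardless of realisation.
    """
    nf = n // 2 + 1
    freqs = np.fft.rfftfreq(n, 1 / fs)
    w = (freqs >= band[0]) & (freqs <= band[1])
    w[0] = False
    if n % 2 == 0:
        w[-1] = False
    if not np.any(w):
        raise ConfigurationError(
            f"jitter band {band} Hz contains no Fourier bins at {n} samples"
        )
    coeff = np.zeros(nf, dtype=complex)
    k = int(w.sum())
    coeff[w] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    g = np.fft.irfft(coeff, n)
    # Var[g_t] = 4 * (number of active interior bins) / n^2, exactly
    return g / np.sqrt(4.0 * k) * n


def _slow_vonmises_jitter(
    n: int, fs: float, kappa: float, band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited process with a von Mises(0, kappa) marginal.

    A band-limited Gaussian process is mapped through the Gaussian CDF and the
    von Mises quantile function: the map is monotone, so slowness is preserved,
    while the marginal becomes exactly von Mises.  The band excludes
    near-DC components so the jitter decorrelates within one segment (a
    constant phase offset would not reduce the PSI at all — the modulus
    removes it — so unmixed ultra-slow jitter would bias per-segment PSI
    upward relative to the ensemble Bessel-ratio target).
    """
    if kappa == np.inf:
        return np.zeros(n)
    g = _band_limited_gaussian(n, fs, band, rng)
    u = ndtr(g)
    if kappa <= 0:
        return 2 * np.pi * (u - 0.5)
    # quantile via interpolated CDF grid (pointwise ppf is prohibitively slow)
    grid = np.linspace(-np.pi, np.pi, 8193)
    cdf = vonmises.cdf(grid, kappa)
    return np.interp(u, cdf, grid)


def make_modulators(spec: SynthSpec, rng: np.random.Generator) -> Modulators:
    """Draw the three chained modulator phase series for one segment.

    ``kappa = 0`` means *independent* modulators: bounded jitter (which keeps
    the faster phase within +-pi of its locked position, flooring the PSI at
    the finite-mixing level) cannot express independence, so the coupling term
    becomes a free-running phase drift — an independent frequency offset plus
    a uniform start — that cycles the relative phase through the whole circle.
    """
    n = int(round(spec.duration * spec.env_rate))
    t = np.arange(n) / spec.env_rate

    def jitter(kappa: float) -> np.ndarray:
        if kappa == 0:
            f_off = rng.uniform(0.1, 0.4) * (1 if rng.uniform() < 0.5 else -1)
            return 2 * np.pi * f_off * t + rng.uniform(0, 2 * np.pi)
        return _slow_vonmises_jitter(n, spec.env_rate, kappa,
                                     spec.jitter_band, rng)

    f_d = spec.f_delta * (1 + spec.rate_jitter * rng.uniform(-1, 1))
    phi0 = rng.uniform(0, 2 * np.pi)
    phase_delta = 2 * np.pi * f_d * t + phi0
    phase_theta = 2 * phase_delta + jitter(spec.kappa_dt)
    phase_bg = 3 * phase_theta + jitter(spec.kappa_tbg)
    return Modulators(
        t=t, phase_delta=phase_delta, phase_theta=phase_theta, phase_bg=phase_bg,
        f_delta=f_d, env_rate=spec.env_rate,
    )


def synth_segment(
    spec: SynthSpec,
    segment_id: str = "synthetic",
    participant_id: str = "",
    register: str = "conversational",
) -> tuple[AudioSegment, dict]:
    """Render one synthetic segment; returns the audio plus its ground truth.

    The ground-truth record carries the realised modulator rate, the kappas,
    the depths, the true phase series and the true-phase PSIs.
    """
    rng = np.random.default_rng(spec.seed)
    mods = make_modulators(spec, rng)
    n_audio = int(round(spec.duration * spec.rate))
    t_audio = np.arange(n_audio) / spec.rate

    depths = np.broadcast_to(
        np.asarray(spec.depths, dtype=float), (len(spec.edges) - 1, 3)
    )
    # modulators rendered at the envelope rate, then interpolated up: they are
    # band-limited far below env_rate/2, so linear interpolation is exact enough
    mod_audio = [
        np.interp(t_audio, mods.t, np.cos(ph)) for ph in mods.phases
    ]

    samples = np.zeros(n_audio)
    for k, (lo, hi) in enumerate(zip(spec.edges[:-1], spec.edges[1:])):
        if spec.carrier_mode == "noise":
            carrier = bandpass(rng.standard_normal(n_audio), spec.rate, lo, hi)
            carrier /= carrier.std()
        else:
            fc = np.sqrt(lo * hi)
            carrier = np.cos(2 * np.pi * fc * t_audio + rng.uniform(0, 2 * np.pi))
        gain = np.ones(n_audio)
        for j in range(3):
            gain *= 1.0 + depths[k, j] * mod_audio[j]
        samples += carrier * gain

    segment = AudioSegment(
        samples=samples, rate=spec.rate, segment_id=segment_id,
        participant_id=participant_id, register=register,
    )
    true_dt, true_tbg = mods.true_psi()
    truth = {
        "segment_id": segment_id,
        "participant_id": participant_id,
        "register": register,
        "kappa_dt": spec.kappa_dt,
        "kappa_tbg": spec.kappa_tbg,
        "f_delta": mods.f_delta,
        "depths": np.array(depths),
        "true_psi_delta_theta": true_dt,
        "true_psi_theta_betagamma": true_tbg,
        "expected_psi_delta_theta": bessel_ratio(spec.kappa_dt),
        "expected_psi_theta_betagamma": bessel_ratio(spec.kappa_tbg),
        "modulators": mods,
    }
    return segment, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Group-level behavioural score distributions (mean, sd) per group, plus the
#: maximum attainable score; loosely modelled on an elderly Portuguese cohort
#: spanning zero to university-level literacy.
BEHAVIOURAL_SCORES = {
    "syllabic_division": (((11.0, 3.4), (19.7, 4.3), (23.8, 0.5)), 24.0),
    "rhyme_detection": (((12.8, 3.2), (16.1, 3.8), (21.0, 3.1)), 24.0),
    "phoneme_deletion": (((0.0, 0.0), (22.6, 6.0), (30.1, 2.4)), 32.0),
    "vocabulary": (((9.7, 3.6), (26.5, 11.5), (54.8, 5.7)), 66.0),
    "token_test": (((11.8, 3.0), (16.6, 2.7), (19.5, 1.7)), 22.0),
}
YEARS_LITERACY = ((0.0, 0.0), (3.3, 0.75), (15.5, 2.47))
AGES = ((80.4, 4.4), (77.9, 5.7), (79.7, 6.3))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    Defaults describe a three-group literacy cohort: 15/19/12 participants
    contributing 89/107/90 conversational segments (3-11 each) plus 6
    rhythmic proverb repetitions; conversational coupling is weakest in the
    illiterate group, and rhythmic coupling is uniformly high.
    """

    group_names: tuple[str, ...] = GROUPS
    group_sizes: tuple[int, ...] = (15, 19, 12)
    conversational_totals: tuple[int, ...] | None = (89, 107, 90)
    segments_per_participant: int | None = None   # overrides totals when set
    rhythmic_per_participant: int = 6
    conv_duration: tuple[float, float] = (4.0, 20.0)
    rhythmic_duration: tuple[float, float] = (4.0, 8.0)
    rate: float = 44100.0
    kappa_dt: tuple[float, ...] = (1.2, 3.5, 4.5)
    kappa_tbg: tuple[float, ...] = (1.2, 3.5, 4.5)
    kappa_sd: float = 0.3
    rhythmic_kappa: float = 8.0
    depths: float = 0.5
    speech_rate_mean: tuple[float, ...] = (3.2, 3.4, 4.2)  # syll/s, conversational
    speech_rate_sd: float = 0.3
    rhythmic_speech_rate: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes):
            raise ConfigurationError("group sizes must be positive")
        if len(self.group_sizes) != len(self.group_names):
            raise ConfigurationError("group_sizes and group_names must align")


@dataclass
class CohortResult:
    """On-disk synthetic dataset: manifest, ground truth, and file locations."""

    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    out_dir: Path
    manifest_path: Path | None = None
    ground_truth_path: Path | None = None


def _allocate_segments(
    total: int, n: int, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Split ``total`` segments over ``n`` participants, each within [lo, hi]."""
    if not (n * lo <= total <= n * hi):
        raise ConfigurationError(
            f"cannot allocate {total} segments over {n} participants within [{lo}, {hi}]"
        )
    base, rem = divmod(total, n)
    counts = np.array([base + 1] * rem + [base] * (n - rem))
    rng.shuffle(counts)
    return counts


def synth_cohort(
    spec: CohortSpec, out_dir: str | Path, write_audio: bool = True
) -> CohortResult:
    """Generate a complete synthetic cohort dataset on disk.

    Writes ``manifest.csv``, ``ground_truth.csv`` and (unless
    ``write_audio=False``) one WAV file per segment under ``audio/``.
    Reproducible from (spec, spec.seed) alone.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        if write_audio:
            (out_dir / "audio").mkdir(exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc

    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    rows: list[dict] = []
    truth_rows: list[dict] = []
    seg_seed = int(rng.integers(0, 2**31 - 1000000))

    for gi, (gname, gn) in enumerate(zip(spec.group_names, spec.group_sizes)):
        if spec.segments_per_participant is not None:
            conv_counts = np.full(gn, spec.segments_per_participant)
        else:
            conv_counts = _allocate_segments(
                spec.conversational_totals[gi], gn, 3, 11, rng
            )
        for pi in range(gn):
            pid = f"{gname[:4]}{pi + 1:02d}"
            kdt = max(0.05, rng.normal(spec.kappa_dt[gi], spec.kappa_sd))
            ktbg = max(0.05, rng.normal(spec.kappa_tbg[gi], spec.kappa_sd))
            conv_rate = max(1.0, rng.normal(spec.speech_rate_mean[gi], spec.speech_rate_sd))
            rhy_rate = max(1.0, rng.normal(spec.rhythmic_speech_rate, spec.speech_rate_sd))
            scores = {
                name: float(np.clip(rng.normal(*dists[gi]), 0.0, smax))
                for name, (dists, smax) in BEHAVIOURAL_SCORES.items()
            }
            years = float(max(0.0, rng.normal(*YEARS_LITERACY[gi])))
            age = float(rng.normal(*AGES[gi]))

            plan = [("conversational", int(conv_counts[pi]), kdt, ktbg,
                     spec.conv_duration, conv_rate)]
            if spec.rhythmic_per_participant:
                plan.append(("rhythmic", spec.rhythmic_per_participant,
                             spec.rhythmic_kappa, spec.rhythmic_kappa,
                             spec.rhythmic_duration, rhy_rate))
            for register, count, reg_kdt, reg_ktbg, drange, srate in plan:
                for si in range(count):
                    seg_seed += 1
                    sid = f"{pid}_{register[:4]}{si + 1:02d}"
                    duration = float(rng.uniform(*drange))
                    syllables = max(1, int(round(
                        duration * max(0.5, rng.normal(srate, 0.2))
                    )))
                    rel_path = f"audio/{sid}.wav"
                    sspec = SynthSpec(
                        duration=duration, rate=spec.rate,
                        kappa_dt=reg_kdt, kappa_tbg=reg_ktbg,
                        depths=spec.depths, seed=seg_seed,
                    )
                    truth: dict = {}
                    if write_audio:
                        segment, truth = synth_segment(
                            sspec, segment_id=sid, participant_id=pid,
                            register=register,
                        )
                        peak = np.abs(segment.samples).max()
                        wavfile.write(
                            out_dir / rel_path, int(spec.rate),
                            (segment.samples / peak * 0.9).astype(np.float32),
                        )
                    rows.append({
                        "participant_id": pid, "group": gname,
                        "years_literacy": round(years, 1), "age": round(age, 1),
                        "register": register, "audio_path": rel_path,
                        "syllable_count": syllables,
                        **{k: round(v, 1) for k, v in scores.items()},
                        "segment_id": sid, "duration": round(duration, 3),
                    })
                    truth_rows.append({
                        "segment_id": sid, "participant_id": pid,
                        "register": register, "kappa_dt": reg_kdt,
                        "kappa_tbg": reg_ktbg, "seed": seg_seed,
                        "expected_psi_delta_theta": bessel_ratio(reg_kdt),
                        "expected_psi_theta_betagamma": bessel_ratio(reg_ktbg),
                        "true_psi_delta_theta": truth.get("true_psi_delta_theta"),
                        "true_psi_theta_betagamma": truth.get("true_psi_theta_betagamma"),
                    })

    manifest = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["segment_id", "duration"])
    ground_truth = pd.DataFrame(truth_rows)
    manifest_path = out_dir / "manifest.csv"
    truth_path = out_dir / "ground_truth.csv"
    manifest.to_csv(manifest_path, index=False)
    ground_truth.to_csv(truth_path, index=False)
    return CohortResult(
        manifest=manifest, ground_truth=ground_truth, out_dir=out_dir,
        manifest_path=manifest_path, ground_truth_path=truth_path,
    )


def simulate_participant_summaries(
    group_means_dt: tuple[float, ...],
    group_means_tbg: tuple[float, ...],
    within_sd: float,
    group_sizes: tuple[int, ...] = (15, 19, 12),
    group_names: tuple[str, ...] = GROUPS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw participant-level PSI summaries directly from group distributions.

    A lightweight stand-in for the full audio pipeline when only the
    statistics layer is exercised (power and type-I calibration need thousands
    of cohorts).
    """
    rng = rng or np.random.default_rng()
    rows = []
    for gname, gn, mdt, mtbg in zip(group_names, group_sizes,
                                    group_means_dt, group_means_tbg):
        dt = rng.normal(mdt, within_sd, gn)
        tbg = rng.normal(mtbg, within_sd, gn)
        for i in range(gn):
            rows.append({
                "participant_id": f"{gname[:4]}{i + 1:02d}", "group": gname,
                "psi_delta_theta": dt[i], "psi_theta_betagamma": tbg[i],
            })
    return pd.DataFrame(rows)
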