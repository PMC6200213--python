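"""Reading, validation and standardisation of speech segments and cohort manifests.

A *segment* is a short stretch of mono audio (one phrase or proverb) cut from a
longer recording; a *manifest* is a CSV with one row per segment carrying the
speaker's identity, literacy group, behavioural scores and the manual syllable
count for that segment.  All acoustic analysis downstream assumes segments have
been z-scored so that amplitude units cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import DegenerateInputError, InputError, SchemaError

#: Top spectral band edge (Hz); audio must be sampled above twice this.
TOP_SPECTRAL_EDGE = 7250.0
MIN_RATE = 2 * TOP_SPECTRAL_EDGE

GROUPS = ("illiterate", "low_literate", "high_literate")
REGISTERS = ("conversational", "rhythmic")

#: Segments shorter than this cannot resolve delta-band (0.9 Hz) modulation.
MIN_DURATION_S = 1.0
#: Below this a warning is issued: delta-band estimates will be edge-dominated.
WARN_DURATION_S = 3.0

REQUIRED_COLUMNS = (
    "participant_id", "group", "years_literacy", "age", "register",
    "audio_path", "syllable_count", "syllabic_division", "rhyme_detection",
    "phoneme_deletion", "vocabulary", "token_test",
)


@dataclass
class AudioSegment:
    """One mono speech segment plus its manifest metadata.

    ``samples`` are dimensionless after z-scoring; ``rate`` is in Hz.
    """

    samples: np.ndarray
    rate: float
    segment_id: str = ""
    participant_id: str = ""
    register: str = "conversational"
    syllable_count: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("AudioSegment samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InputError(f"segment {self.segment_id!r} contains non-finite samples")

    @property
    def duration(self) -> float:
        """Segment duration in seconds (= n_samples / rate)."""
        return self.samples.size / self.rate


def load_segment(path: str | Path, manifest_row: dict | pd.Series | None = None) -> AudioSegment:
    """Read a WAV file into an :class:`AudioSegment`.

    Stereo files are downmixed by per-sample channel averaging.  Sampling rates
    at or below twice the top spectral edge (14.5 kHz) are rejected because the
    5-band filterbank would not be representable.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read audio file {path}: {exc}") from exc
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.size == 0:
        raise InputError(f"audio file {path} is empty")
    if rate <= MIN_RATE:
        raise InputError(
            f"sampling rate {rate} Hz of {path} is not above {MIN_RATE:.0f} Hz "
            f"(2 x top spectral edge {TOP_SPECTRAL_EDGE:.0f} Hz)"
        )
    row = dict(manifest_row) if manifest_row is not None else {}
    count = row.get("syllable_count")
    if count is not None and not pd.isna(count):
        count = int(count)
    else:
        count = None
    seg = AudioSegment(
        samples=data,
        rate=float(rate),
        segment_id=str(row.get("segment_id", path.stem)),
        participant_id=str(row.get("participant_id", "")),
        register=str(row.get("register", "conversational")),
        syllable_count=count,
    )
    if seg.duration < MIN_DURATION_S:
        raise InputError(
            f"segment {seg.segment_id!r} lasts {seg.duration:.2f} s; "
            f"below {MIN_DURATION_S} s the delta band is unresolvable"
        )
    if seg.duration < WARN_DURATION_S:
        warnings.warn(
            f"segment {seg.segment_id!r} lasts {seg.duration:.2f} s "
            f"(< {WARN_DURATION_S} s); delta-band estimates will be edge-dominated",
            stacklevel=2,
        )
    return seg


def zscore(segment: AudioSegment) -> AudioSegment:
    """Standardise a segment to mean 0 and population standard deviation 1.

    Population (not sample) SD: we are standardising a fixed signal, not
    estimating a dispersion.  Idempotent to floating-point precision.
    """
    x = segment.samples
    sd = x.std()  # population (ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError(
            f"segment {segment.segment_id!r} has zero variance; cannot z-score"
        )
    return replace(segment, samples=(x - x.mean()) / sd)


@dataclass
class CohortManifest:
    """Validated cohort manifest: one row per segment, participant attributes repeated."""

    table: pd.DataFrame
    base_dir: Path = field(default_factory=Path)

    def participants(self) -> pd.DataFrame:
        """One row per participant with the participant-level attributes."""
        cols = ["participant_id", "group", "years_literacy", "age",
                "syllabic_division", "rhyme_detection", "phoneme_deletion",
                "vocabulary", "token_test"]
        return (self.table[cols].drop_duplicates("participant_id")
                .reset_index(drop=True))

    def group_sizes(self) -> dict[str, int]:
        return (self.participants().groupby("group")["participant_id"]
                .count().to_dict())

    def n_segments(self, register: str | None = None) -> int:
        t = self.table
        if register is not None:
            t = t[t["register"] == register]
        return int(len(t))

    def mean_segments_per_participant(self, register: str | None = None) -> float:
        t = self.table
        if register is not None:
            t = t[t["register"] == register]
        return float(t.groupby("participant_id").size().mean())

    def audio_path(self, row: pd.Series) -> Path:
        return self.base_dir / str(row["audio_path"])


def load_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    ``check_files=False`` skips audio-file existence checks, for manifests used
    only for row accounting (e.g. cohort-size arithmetic).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot read manifest {path}: {exc}") from exc
    if table.empty:
        raise SchemaError(f"manifest {path} has no rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"manifest {path} missing required columns: {missing}")
    bad_groups = set(table["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise SchemaError(f"unknown group labels {sorted(bad_groups)}; expected {GROUPS}")
    bad_reg = set(table["register"].unique()) - set(REGISTERS)
    if bad_reg:
        raise SchemaError(f"unknown registers {sorted(bad_reg)}; expected {REGISTERS}")
    n_groups_per_pid = table.groupby("participant_id")["group"].nunique()
    inconsistent = n_groups_per_pid[n_groups_per_pid > 1]
    if len(inconsistent):
        raise SchemaError(
            f"participants with inconsistent group labels: {list(inconsistent.index)}"
        )
    manifest = CohortManifest(table=table, base_dir=path.parent)
    if check_files:
        missing_files = [
            str(p) for p in (manifest.audio_path(row) for _, row in table.iterrows())
            if not p.exists()
        ]
        if missing_files:
            raise SchemaError(
                f"manifest references {len(missing_files)} missing audio files, "
                f"first: {missing_files[0]}"
            )
    return manifest
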