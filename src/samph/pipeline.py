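"""End-to-end analysis: manifest -> per-segment measures -> participant summaries.

Glues the stages together: load + z-score each segment, run the spectral
filterbank and envelope extraction, the AM decomposition and phase
synchronisation, and the modulation spectrum and band energies; then aggregate
to one row per participant x register.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SamphError
from .io_segments import AudioSegment, CohortManifest, load_segment, zscore
from .modulation import AMBandSpec, am_filterbank, band_energy, modulation_spectrum
from .phase_sync import DEFAULT_TRIM_S, segment_psi
from .samph_core import DEFAULT_ENV_RATE, SpectralBandSpec, segment_envelopes

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the measurement chain (defaults = study settings)."""

    spectral: SpectralBandSpec = field(default_factory=SpectralBandSpec)
    am: AMBandSpec = field(default_factory=AMBandSpec)
    env_rate: float = DEFAULT_ENV_RATE
    n_channels: int = 24
    mod_range: tuple[float, float] = (0.9, 40.0)
    trim: float = DEFAULT_TRIM_S
    compute_spectrum: bool = True


def analyze_segment(segment: AudioSegment, config: AnalysisConfig | None = None) -> dict:
    """All acoustic measures of one (not yet z-scored) segment, as a flat record."""
    config = config or AnalysisConfig()
    seg = zscore(segment)
    env_set = segment_envelopes(seg, config.spectral, config.env_rate)
    am = am_filterbank(env_set, config.am)
    psi_res = segment_psi(am, trim=config.trim)
    row = {
        "segment_id": seg.segment_id,
        "participant_id": seg.participant_id,
        "register": seg.register,
        "duration": seg.duration,
        "syllable_count": seg.syllable_count,
        "psi_delta_theta": psi_res.delta_theta,
        "psi_theta_betagamma": psi_res.theta_betagamma,
    }
    for b in range(len(psi_res.per_band_delta_theta)):
        row[f"psi_dt_b{b + 1}"] = float(psi_res.per_band_delta_theta[b])
        row[f"psi_tbg_b{b + 1}"] = float(psi_res.per_band_theta_betagamma[b])
    if config.compute_spectrum:
        spec = modulation_spectrum(env_set, config.n_channels, config.mod_range)
        energy = band_energy(spec, config.am)
        row.update(
            delta_auc=energy.delta_auc,
            theta_auc=energy.theta_auc,
            beta_gamma_auc=energy.beta_gamma_auc,
        )
    if seg.syllable_count is not None and seg.duration > 0:
        row["syllable_rate"] = seg.syllable_count / seg.duration
    return row


def analyze_manifest(
    manifest: CohortManifest, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Analyse every segment in a manifest.

    Returns (segment table, participant table, errors).  Per-segment failures
    are recorded and skipped so one corrupt file does not abort a cohort run.
    """
    config = config or AnalysisConfig()
    seg_rows: list[dict] = []
    errors: list[dict] = []
    for _, mrow in manifest.table.iterrows():
        sid = mrow.get("segment_id", mrow["audio_path"])
        try:
            segment = load_segment(manifest.audio_path(mrow), mrow)
            seg_rows.append(analyze_segment(segment, config))
        except (SamphError, OSError) as exc:
            log.warning("segment %s failed: %s", sid, exc)
            errors.append({"segment_id": str(sid), "error": str(exc)})
    segments = pd.DataFrame(seg_rows)
    participants = summarize_participants(segments, manifest) if len(segments) else pd.DataFrame()
    return segments, participants, errors


def summarize_participants(
    segments: pd.DataFrame, manifest: CohortManifest | None = None
) -> pd.DataFrame:
    """Unweighted grand means over segments, per participant x register.

    Speech rate is the mean of per-segment syllable rates; PSI and energy
    measures are means over segments of the (already band-averaged) values.
    """
    measure_cols = [
        c for c in segments.columns
        if c.startswith(("psi_", "delta_auc", "theta_auc", "beta_gamma_auc"))
        or c == "syllable_rate"
    ]
    agg = (segments.groupby(["participant_id", "register"])[measure_cols]
           .mean().reset_index()
           .rename(columns={"syllable_rate": "speech_rate"}))
    counts = (segments.groupby(["participant_id", "register"]).size()
              .rename("n_segments").reset_index())
    agg = agg.merge(counts, on=["participant_id", "register"])
    if manifest is not None:
        agg = agg.merge(manifest.participants(), on="participant_id", how="left")
    return agg


def participant_table_to_long(participants: pd.DataFrame) -> pd.DataFrame:
    """Long (participant, band_pair, spectral_band, psi) table for the rm-ANOVA."""
    rows = []
    for _, r in participants.iterrows():
        for pair, prefix in (("delta_theta", "psi_dt_b"),
                             ("theta_betagamma", "psi_tbg_b")):
            for b in range(1, 6):
                col = f"{prefix}{b}"
                if col in participants.columns and not np.isnan(r[col]):
                    rows.append({
                        "participant_id": r["participant_id"],
                        "group": r.get("group"),
                        "register": r["register"],
                        "band_pair": pair,
                        "spectral_band": b,
                        "psi": float(r[col]),
                    })
    return pd.DataFrame(rows)
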