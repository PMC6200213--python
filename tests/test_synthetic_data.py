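"""Synthetic-signal generator: coupling ground truth, determinism, cohorts."""

import numpy as np
import pandas as pd
import pytest

from samph.errors import ConfigurationError
from samph.io_segments import load_manifest, zscore
from samph.modulation import am_filterbank, band_energy, modulation_spectrum
from samph.phase_sync import segment_psi
from samph.samph_core import segment_envelopes
from samph.synthetic_data import (
    CohortSpec,
    SynthSpec,
    bessel_ratio,
    make_modulators,
    simulate_participant_summaries,
    synth_cohort,
    synth_segment,
)


class TestMakeModulators:
    def _true_psi_mean(self, kappa, duration, seeds):
        vals = []
        for seed in seeds:
            spec = SynthSpec(duration=duration, kappa_dt=kappa, kappa_tbg=kappa,
                             seed=seed)
            mods = make_modulators(spec, np.random.default_rng(seed))
            vals.append(mods.true_psi())
        return np.mean(vals, axis=0)

    def test_deterministic_locking_gives_unit_psi(self):
        spec = SynthSpec(duration=30, kappa_dt=np.inf, kappa_tbg=np.inf, seed=0)
        mods = make_modulators(spec, np.random.default_rng(0))
        dt, tbg = mods.true_psi()
        assert dt == pytest.approx(1.0, abs=1e-12)
        assert tbg == pytest.approx(1.0, abs=1e-12)

    def test_independent_phases_give_low_psi(self):
        dt, tbg = self._true_psi_mean(0.0, 60, range(6))
        assert dt < 0.1 and tbg < 0.1

    def test_kappa_two_matches_bessel_ratio(self):
        # marginal jitter is exactly von Mises; long duration + several seeds
        # average out the finite-mixing noise of the slow jitter process
        dt, tbg = self._true_psi_mean(2.0, 120, range(8))
        assert abs(dt - bessel_ratio(2.0)) < 0.05
        assert abs(tbg - bessel_ratio(2.0)) < 0.05

    def test_realised_rates_stay_inside_am_bands(self):
        for seed in range(10):
            spec = SynthSpec(duration=10, seed=seed)
            mods = make_modulators(spec, np.random.default_rng(seed))
            assert 0.9 <= mods.f_delta <= 2.5
            assert 2.5 <= 2 * mods.f_delta <= 12.0
            assert 12.0 <= 6 * mods.f_delta <= 40.0

    def test_bessel_ratio_endpoints(self):
        assert bessel_ratio(np.inf) == 1.0
        assert bessel_ratio(0.0) == 0.0
        assert bessel_ratio(2.0) == pytest.approx(0.69777, abs=1e-4)


class TestSynthSegment:
    def test_same_seed_is_bitwise_identical(self):
        spec = SynthSpec(duration=4.0, seed=123)
        a, _ = synth_segment(spec)
        b, _ = synth_segment(spec)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self):
        a, _ = synth_segment(SynthSpec(duration=4.0, seed=1))
        b, _ = synth_segment(SynthSpec(duration=4.0, seed=2))
        assert not np.array_equal(a.samples, b.samples)

    def test_zero_depths_give_stationary_noise(self):
        # no modulators: segment PSI low, modulation spectrum flat
        psis, peaks = [], []
        for seed in range(3):
            seg, _ = synth_segment(SynthSpec(duration=20, depths=0.0, seed=seed))
            env = segment_envelopes(zscore(seg))
            psis.append(segment_psi(am_filterbank(env)).delta_theta)
            peaks.append(np.abs(modulation_spectrum(env).averaged).max())
        assert np.mean(psis) < 0.2
        assert np.mean(peaks) < 0.5

    def test_dominant_theta_depth_maximises_theta_auc(self):
        seg, _ = synth_segment(SynthSpec(duration=20, depths=(0.1, 0.9, 0.1),
                                         seed=5))
        env = segment_envelopes(zscore(seg))
        be = band_energy(modulation_spectrum(env))
        assert be.theta_auc > be.delta_auc
        assert be.theta_auc > be.beta_gamma_auc

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthSpec(duration=1.0)
        with pytest.raises(ConfigurationError):
            SynthSpec(depths=1.5)
        with pytest.raises(ConfigurationError):
            SynthSpec(carrier_mode="violin")

    def test_ground_truth_record_contents(self):
        seg, truth = synth_segment(SynthSpec(duration=5.0, kappa_dt=3.0, seed=9),
                                   segment_id="s9", participant_id="p1")
        assert truth["segment_id"] == "s9"
        assert truth["kappa_dt"] == 3.0
        assert 0.0 <= truth["true_psi_delta_theta"] <= 1.0
        assert truth["expected_psi_delta_theta"] == pytest.approx(bessel_ratio(3.0))
        assert seg.duration == pytest.approx(5.0)


class TestSynthCohort:
    def test_default_cohort_counts(self, tmp_path):
        res = synth_cohort(CohortSpec(), tmp_path / "c", write_audio=False)
        m = res.manifest
        assert m["participant_id"].nunique() == 46
        conv = m[m.register == "conversational"]
        assert len(conv) == 286
        per_p = conv.groupby("participant_id").size()
        assert per_p.between(3, 11).all()
        assert len(m[m.register == "rhythmic"]) == 46 * 6

    def test_cohort_reproducible_from_seed(self, tmp_path):
        a = synth_cohort(CohortSpec(seed=4), tmp_path / "a", write_audio=False)
        b = synth_cohort(CohortSpec(seed=4), tmp_path / "b", write_audio=False)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_tiny_cohort_audio_on_disk_and_loadable(self, tmp_path):
        spec = CohortSpec(group_sizes=(1, 1, 1), conversational_totals=None,
                          segments_per_participant=1, rhythmic_per_participant=1,
                          conv_duration=(4.0, 5.0), rhythmic_duration=(4.0, 5.0),
                          seed=11)
        res = synth_cohort(spec, tmp_path / "tiny")
        manifest = load_manifest(res.manifest_path)   # validates file existence
        assert manifest.n_segments() == 6
        assert set(res.ground_truth.columns) >= {
            "segment_id", "kappa_dt", "expected_psi_delta_theta",
            "true_psi_delta_theta"}

    def test_group_effect_sizes_zero_is_allocatable(self, tmp_path):
        with pytest.raises(ConfigurationError):
            CohortSpec(group_sizes=(0, 3, 3))


class TestSimulateSummaries:
    def test_shapes_and_groups(self, rng):
        df = simulate_participant_summaries((0.4, 0.5, 0.6), (0.4, 0.5, 0.6),
                                            0.04, rng=rng)
        assert len(df) == 46
        assert df.group.value_counts().to_dict() == {
            "low_literate": 19, "illiterate": 15, "high_literate": 12}
        assert df.psi_delta_theta.between(0, 1).all()
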