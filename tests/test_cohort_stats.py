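"""Cohort statistics: speech rate, MANOVA, mixed rm-ANOVA, post-hocs, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samph.cohort_stats import (
    cohort_report,
    correlate,
    group_manova,
    nonparametric_groups,
    posthoc_tukey,
    rm_anova_psi,
    shapiro_normality,
    speech_rate,
)
from samph.errors import DegenerateInputError, InputError
from samph.io_segments import AudioSegment
from samph.synthetic_data import simulate_participant_summaries


def _seg(count, duration, sid="s"):
    n = int(duration * 44100)
    return AudioSegment(np.random.default_rng(0).normal(0, 1, n), 44100.0,
                        segment_id=sid, syllable_count=count)


class TestSpeechRate:
    def test_single_segment_arithmetic(self):
        assert speech_rate([_seg(14, 7.0)]) == pytest.approx(2.0)

    def test_mean_of_rates_not_pooled_counts(self):
        segs = [_seg(8, 4.0, "a"), _seg(4, 1.0, "b")]  # 2.0 and 4.0 syll/s
        assert speech_rate(segs) == pytest.approx(3.0)

    def test_missing_count_lists_offenders(self):
        segs = [_seg(10, 5.0, "ok"), _seg(None, 5.0, "bad")]
        with pytest.raises(InputError, match="bad"):
            speech_rate(segs)


class TestGroupManova:
    def test_identical_groups_lambda_one(self, rng):
        base = rng.normal(0.5, 0.05, (10, 2))
        rows = []
        for g in ("illiterate", "low_literate", "high_literate"):
            for i in range(10):
                rows.append({"group": g, "psi_delta_theta": base[i, 0],
                             "psi_theta_betagamma": base[i, 1]})
        rep = group_manova(pd.DataFrame(rows))
        assert rep.effect["wilks_lambda"] == pytest.approx(1.0, abs=1e-9)
        assert rep.statistic == pytest.approx(0.0, abs=1e-9)

    def test_against_eigenvalue_oracle_small_example(self):
        # direct eigen-decomposition of W^-1 B: Lambda = prod 1/(1+lambda_i)
        df = pd.DataFrame({
            "group": ["a", "a", "a", "b", "b", "b"],
            "psi_delta_theta": [0.40, 0.45, 0.42, 0.55, 0.58, 0.52],
            "psi_theta_betagamma": [0.30, 0.28, 0.33, 0.41, 0.44, 0.38],
        })
        Y = df[["psi_delta_theta", "psi_theta_betagamma"]].to_numpy()
        grand = Y.mean(0)
        W = np.zeros((2, 2))
        B = np.zeros((2, 2))
        for g in ("a", "b"):
            Yg = Y[(df.group == g).to_numpy()]
            d = Yg - Yg.mean(0)
            W += d.T @ d
            m = (Yg.mean(0) - grand)[:, None]
            B += len(Yg) * m @ m.T
        eig = np.linalg.eigvals(np.linalg.solve(W, B))
        lam_oracle = np.prod(1.0 / (1.0 + eig.real))
        rep = group_manova(df)
        assert rep.effect["wilks_lambda"] == pytest.approx(lam_oracle, abs=1e-10)

    def test_against_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        df = simulate_participant_summaries(
            (0.45, 0.53, 0.55), (0.44, 0.50, 0.56), 0.04, rng=rng)
        rep = group_manova(df)
        sm = MANOVA.from_formula(
            "psi_delta_theta + psi_theta_betagamma ~ group", data=df
        ).mv_test().results["group"]["stat"].loc["Wilks' lambda"]
        assert rep.effect["wilks_lambda"] == pytest.approx(sm["Value"], abs=1e-8)
        assert rep.statistic == pytest.approx(sm["F Value"], abs=1e-6)
        assert rep.df == (pytest.approx(sm["Num DF"]), pytest.approx(sm["Den DF"]))

    def test_df_structure_three_groups_two_dvs(self, rng):
        # 3 groups x 2 dependents, N=46: Rao's approximation gives F(4, 84)
        df = simulate_participant_summaries(
            (0.45, 0.50, 0.55), (0.45, 0.50, 0.55), 0.05, rng=rng)
        rep = group_manova(df)
        assert rep.df == (4.0, 84.0)
        lam = rep.effect["wilks_lambda"]
        assert rep.effect["partial_eta_sq"] == pytest.approx(1 - np.sqrt(lam))

    def test_singular_covariance_rejected(self):
        rows = [{"group": g, "psi_delta_theta": v, "psi_theta_betagamma": v}
                for g in ("a", "b", "c") for v in (0.4, 0.4, 0.4)]
        with pytest.raises((DegenerateInputError, InputError)):
            group_manova(pd.DataFrame(rows))


def _rm_fixture():
    """Seeded unbalanced mixed-design dataset (3 groups, 2 x 5 within cells)."""
    g2 = np.random.default_rng(7)
    rows = []
    for g, n, base in (("A", 5, 0.4), ("B", 6, 0.5), ("C", 4, 0.55)):
        for i in range(n):
            se = g2.normal(0, 0.05)
            for a in ("p1", "p2"):
                for b in range(1, 6):
                    y = (base + se + (0.03 if a == "p2" else 0)
                         + 0.01 * b + g2.normal(0, 0.03))
                    rows.append(dict(participant_id=f"{g}{i}", group=g,
                                     band_pair=a, spectral_band=b, psi=y))
    return pd.DataFrame(rows)


class TestRmAnova:
    #: F values for _rm_fixture computed once with R's aov
    #: (Error(participant/(band_pair*spectral_band)) strata).
    R_AOV_F = {
        "group": 9.96192,
        "band_pair": 34.73100,
        "band_pair*group": 0.33055,
        "spectral_band": 12.25207,
        "spectral_band*group": 1.76145,
        "band_pair*spectral_band": 0.52098,
        "band_pair*spectral_band*group": 0.54351,
    }

    def test_matches_frozen_reference_fit(self):
        out = rm_anova_psi(_rm_fixture())
        for effect, f_ref in self.R_AOV_F.items():
            assert out[effect].statistic == pytest.approx(f_ref, abs=5e-5), effect

    def test_identical_cells_give_zero_f(self):
        df = _rm_fixture()
        df["psi"] = 0.5
        out = rm_anova_psi(df)
        for rep in out.values():
            assert rep.statistic == pytest.approx(0.0, abs=1e-9)

    def test_pure_group_shift_hits_group_effect_only(self):
        df = _rm_fixture()
        df["psi"] = 0.5
        g = np.random.default_rng(3)
        df["psi"] += g.normal(0, 0.01, len(df))        # noise floor
        df.loc[df.group == "A", "psi"] -= 0.2          # constant in all cells
        out = rm_anova_psi(df)
        assert out["group"].p < 1e-6
        assert out["band_pair*group"].p > 0.01
        assert out["spectral_band*group"].p > 0.01

    def test_missing_cells_rejected(self):
        df = _rm_fixture().iloc[:-3]
        with pytest.raises(InputError):
            rm_anova_psi(df)


class TestTukey:
    def test_identical_groups_p_one(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        df = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4, "m": vals * 2})
        rep = posthoc_tukey(df, "m")
        assert rep.pairwise[0]["p"] == pytest.approx(1.0, abs=1e-9)

    def test_separated_group_detected(self, rng):
        df = pd.DataFrame({
            "group": ["a"] * 8 + ["b"] * 8 + ["c"] * 8,
            "m": np.concatenate([rng.normal(0, 1, 8), rng.normal(0.5, 1, 8),
                                 rng.normal(10, 1, 8)]),
        })
        rep = posthoc_tukey(df, "m")
        pac = [p for p in rep.pairwise if {p["a"], p["b"]} == {"a", "c"}][0]
        assert pac["p"] < 0.001

    def test_matches_scipy_tukey_hsd(self, rng):
        from scipy.stats import tukey_hsd

        samples = [rng.normal(m, 1, n) for m, n in ((0, 7), (0.8, 9), (1.5, 5))]
        df = pd.DataFrame({
            "group": np.repeat(["a", "b", "c"], [7, 9, 5]),
            "m": np.concatenate(samples),
        })
        rep = posthoc_tukey(df, "m")
        ref = tukey_hsd(*samples)
        lookup = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for pw in rep.pairwise:
            i, j = lookup[(pw["a"], pw["b"])]
            assert pw["p"] == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_relabeling_symmetry(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(1, 1, 6)])
        df = pd.DataFrame({"group": ["x"] * 6 + ["y"] * 6, "m": vals})
        df2 = df.assign(group=df.group.map({"x": "y", "y": "x"}))
        p1 = posthoc_tukey(df, "m").pairwise[0]["p"]
        p2 = posthoc_tukey(df2, "m").pairwise[0]["p"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_tiny_group_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "m": [1.0, 2.0, 3.0]})
        with pytest.raises(InputError):
            posthoc_tukey(df, "m")


class TestCorrelate:
    def test_linear_and_monotone_relations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        df = pd.DataFrame({"x": x, "lin": 2 * x + 3, "cube": -(x**3)})
        assert correlate(df, "x", "lin", "spearman").statistic == pytest.approx(1.0)
        assert correlate(df, "x", "lin", "pearson").statistic == pytest.approx(1.0)
        assert correlate(df, "x", "cube", "spearman").statistic == pytest.approx(-1.0)

    def test_hand_computed_rank_example(self):
        # ranks (1..5) vs (2,1,4,3,5): sum d^2 = 4 -> rho = 1 - 24/120 = 0.8
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        assert correlate(df, "x", "y", "spearman").statistic == pytest.approx(0.8)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_spearman_invariant_to_monotone_transforms(self, seed):
        g = np.random.default_rng(seed)
        x = g.normal(size=12)
        y = g.normal(size=12)
        df = pd.DataFrame({"x": x, "y": y})
        base = correlate(df, "x", "y", "spearman").statistic
        warped = pd.DataFrame({"x": np.exp(x), "y": y**3})
        assert correlate(warped, "x", "y", "spearman").statistic == pytest.approx(
            base, abs=1e-12)

    def test_bonferroni_adjustment_recorded(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20), "y": rng.normal(size=20)})
        rep = correlate(df, "x", "y", "spearman", bonferroni_family=32)
        assert rep.effect["p_bonferroni"] == pytest.approx(min(1.0, rep.p * 32))

    def test_degenerate_inputs_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1, 2, 3, 4]})
        with pytest.raises(DegenerateInputError):
            correlate(df, "x", "y")
        small = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
        with pytest.raises(InputError):
            correlate(small, "x", "y")


class TestNonparametric:
    def test_fully_separated_groups_u_zero(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                           "m": [1.0, 2, 3, 4, 5, 6]})
        rep = nonparametric_groups(df, "m")
        assert rep.pairwise[0]["U"] == 0.0

    def test_identical_groups_h_zero(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                           "m": [1.0, 2, 3, 1, 2, 3]})
        rep = nonparametric_groups(df, "m")
        assert rep.statistic == pytest.approx(0.0, abs=1e-9)

    def test_all_tied_rejected(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3, "m": [2.0] * 6})
        with pytest.raises(DegenerateInputError):
            nonparametric_groups(df, "m")

    def test_shapiro_rejects_bimodal(self, rng):
        bimodal = np.concatenate([rng.normal(-6, 0.3, 25), rng.normal(6, 0.3, 25)])
        assert shapiro_normality(bimodal).p < 0.05


class TestCohortReport:
    def test_report_structure_and_family_size(self, rng):
        df = simulate_participant_summaries(
            (0.45, 0.53, 0.55), (0.44, 0.50, 0.56), 0.04, rng=rng)
        df["register"] = "conversational"
        df["speech_rate"] = rng.normal(3.5, 0.4, len(df))
        df["years_literacy"] = rng.normal(5, 3, len(df)).clip(0)
        df["age"] = rng.normal(79, 5, len(df))
        df["delta_auc"] = rng.normal(0, 0.2, len(df))
        df["theta_auc"] = rng.normal(0.5, 0.2, len(df))
        for c in ("syllabic_division", "rhyme_detection", "phoneme_deletion",
                  "vocabulary", "token_test"):
            df[c] = rng.normal(15, 5, len(df)).clip(0)
        report = cohort_report(df)
        conv = report["registers"]["conversational"]
        assert "manova_psi" in conv and "statistic" in conv["manova_psi"]
        cells = report["correlations"]["cells"]
        assert len(cells) == 8 * 4
        assert report["correlations"]["bonferroni_family"] == 32
        assert set(report["behavioural_tasks"]) == {
            "syllabic_division", "rhyme_detection", "phoneme_deletion",
            "vocabulary", "token_test"}

    def test_empty_and_bad_alpha_rejected(self):
        with pytest.raises(InputError):
            cohort_report(pd.DataFrame())
        with pytest.raises(InputError):
            cohort_report(pd.DataFrame({"register": ["conversational"]}), alpha=1.5)
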