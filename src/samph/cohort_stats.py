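"""Group-level statistics over participant summaries.

Implements the statistical layer of the cohort analysis: speech rate,
one-way MANOVA (Wilks' lambda with Rao's F approximation), the 3 x 2 x 5 mixed
repeated-measures ANOVA over (group) x (AM band pair) x (spectral band),
Tukey-Kramer post-hocs, Pearson/Spearman correlations with optional Bonferroni
adjustment, and the non-parametric battery (Shapiro-Wilk gate, Kruskal-Wallis,
pairwise Mann-Whitney).

Wilks' lambda and the mixed ANOVA are computed from the standard multivariate
GLM / sums-of-squares formulas directly (no installed package offers the
two-within-factor mixed design in one call); the ordinary univariate tests go
through scipy.stats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError
from .io_segments import AudioSegment


@dataclass
class StatReport:
    """One statistical test: statistic, degrees of freedom, p, effect size."""

    test: str
    statistic: float
    df: tuple | None
    p: float
    effect: dict = field(default_factory=dict)
    pairwise: list[dict] | None = None

    def to_dict(self) -> dict:
        out = {
            "test": self.test, "statistic": self.statistic,
            "df": list(self.df) if self.df is not None else None,
            "p": self.p, "effect": self.effect,
        }
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise
        return out


# ---------------------------------------------------------------------------
# Speech rate
# ---------------------------------------------------------------------------

def speech_rate(segments: Sequence[AudioSegment]) -> float:
    """Mean of per-segment syllable rates (syllables/second), unweighted.

    The participant rate is the mean of segment rates, not the pooled
    count-over-duration rate; a 2.0 and a 4.0 syll/s segment average to 3.0.
    """
    missing = [s.segment_id for s in segments
               if s.syllable_count is None or s.duration <= 0]
    if missing:
        raise InputError(f"segments without usable syllable counts: {missing}")
    rates = [s.syllable_count / s.duration for s in segments]
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# One-way MANOVA (Wilks' lambda)
# ---------------------------------------------------------------------------

def group_manova(
    summaries: pd.DataFrame,
    dependents: Sequence[str] = ("psi_delta_theta", "psi_theta_betagamma"),
    group_col: str = "group",
) -> StatReport:
    """One-way MANOVA: Wilks' lambda, Rao's F approximation, partial eta^2.

    Lambda = det(W)/det(W+B) with W/B the within/between SSCP matrices;
    partial eta^2 = 1 - Lambda^(1/s).
    """
    data = summaries.dropna(subset=list(dependents) + [group_col])
    groups = data[group_col].unique()
    k = len(groups)
    p = len(dependents)
    if k < 2 or p < 2:
        raise InputError("MANOVA needs >= 2 groups and >= 2 dependent variables")
    Y = data[list(dependents)].to_numpy(dtype=float)
    N = len(Y)
    grand = Y.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        Yg = Y[(data[group_col] == g).to_numpy()]
        mg = Yg.mean(axis=0)
        dev = Yg - mg
        W += dev.T @ dev
        dg = (mg - grand)[:, None]
        B += len(Yg) * (dg @ dg.T)
    detW = np.linalg.det(W)
    detT = np.linalg.det(W + B)
    if detT <= 0 or detW < 0 or not np.isfinite(detW):
        raise DegenerateInputError("singular within-group covariance; cannot form Wilks' lambda")
    lam = detW / detT
    q = k - 1
    v = N - k
    s = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
    df1 = p * q
    m = v + q - (p + q + 1) / 2
    df2 = m * s - p * q / 2 + 1
    lam_s = lam ** (1 / s)
    F = (1 - lam_s) / lam_s * df2 / df1 if lam_s > 0 else np.inf
    pval = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return StatReport(
        test="manova_wilks",
        statistic=float(F),
        df=(float(df1), float(df2)),
        p=pval,
        effect={"wilks_lambda": float(lam), "partial_eta_sq": float(1 - lam_s)},
    )


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA: group (between) x band pair x spectral band
# ---------------------------------------------------------------------------

def rm_anova_psi(
    long: pd.DataFrame,
    dv: str = "psi",
    subject: str = "participant_id",
    group: str = "group",
    within_a: str = "band_pair",
    within_b: str = "spectral_band",
) -> dict[str, StatReport]:
    """Mixed-design ANOVA with one between factor and two crossed within factors.

    Expects a long table with one row per subject x within_a x within_b cell
    (the design must be complete and balanced within subjects).  Returns F
    tests with partial eta^2 for: group, each within main effect, their
    interactions with group, and the within-within interaction(s).  Error
    strata are subjects-within-group and its interactions with the within
    factors (standard univariate mixed-model sums of squares, uncorrected df).
    """
    df = long[[subject, group, within_a, within_b, dv]].dropna().copy()
    a_levels = sorted(df[within_a].unique())
    b_levels = sorted(df[within_b].unique())
    na, nb = len(a_levels), len(b_levels)
    cell = na * nb
    counts = df.groupby(subject).size()
    if counts.nunique() != 1 or counts.iloc[0] != cell:
        raise InputError(
            f"unbalanced within-subject design: every subject needs {cell} cells"
        )
    subjects = df[[subject, group]].drop_duplicates(subject)
    N = len(subjects)
    k = subjects[group].nunique()

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    sst = ((y - grand) ** 2).sum()

    m_subj = df.groupby(subject)[dv].mean()
    m_grp = df.groupby(group)[dv].mean()
    n_per_grp = subjects.groupby(group).size()

    ss_group = float((cell * n_per_grp * (m_grp - grand) ** 2).sum())
    subj_grp = subjects.set_index(subject)[group]
    ss_subj = float((cell * (m_subj - grand) ** 2).sum())
    ss_err_subj = ss_subj - ss_group

    def _within_tables(factor: str, nlev: int):
        m_f = df.groupby(factor)[dv].mean()
        weight = N * cell / nlev
        ss_f = float((weight * (m_f - grand) ** 2).sum())
        m_gf = df.groupby([group, factor])[dv].mean()
        ss_gf = 0.0
        for (g, f), mgf in m_gf.items():
            w = n_per_grp[g] * cell / nlev
            ss_gf += w * (mgf - m_grp[g] - m_f[f] + grand) ** 2
        # error: factor x subject within group
        m_sf = df.groupby([subject, factor])[dv].mean()
        ss_err = 0.0
        for (s, f), msf in m_sf.items():
            g = subj_grp[s]
            ss_err += (cell / nlev) * (msf - m_subj[s] - m_gf[(g, f)] + m_grp[g]) ** 2
        return ss_f, float(ss_gf), float(ss_err)

    ss_a, ss_ga, ss_err_a = _within_tables(within_a, na)
    ss_b, ss_gb, ss_err_b = _within_tables(within_b, nb)

    # A x B and A x B x group from cell means; residual error by subtraction
    m_ab = df.groupby([within_a, within_b])[dv].mean()
    m_a = df.groupby(within_a)[dv].mean()
    m_b = df.groupby(within_b)[dv].mean()
    ss_ab = float(sum(
        N * (m_ab[(a, b)] - m_a[a] - m_b[b] + grand) ** 2
        for a in a_levels for b in b_levels
    ))
    m_gab = df.groupby([group, within_a, within_b])[dv].mean()
    m_ga = df.groupby([group, within_a])[dv].mean()
    m_gb = df.groupby([group, within_b])[dv].mean()
    ss_gab = float(sum(
        n_per_grp[g] * (m_gab[(g, a, b)] - m_ga[(g, a)] - m_gb[(g, b)]
                        + m_grp[g] + m_a[a] + m_b[b] - m_ab[(a, b)] - grand) ** 2
        for g in n_per_grp.index for a in a_levels for b in b_levels
    ))
    ss_err_ab = sst - (ss_group + ss_err_subj + ss_a + ss_ga + ss_err_a
                       + ss_b + ss_gb + ss_err_b + ss_ab + ss_gab)

    df_g, df_s = k - 1, N - k
    df_a, df_b = na - 1, nb - 1
    effects = {
        "group": (ss_group, df_g, ss_err_subj, df_s),
        within_a: (ss_a, df_a, ss_err_a, df_s * df_a),
        f"{within_a}*group": (ss_ga, df_g * df_a, ss_err_a, df_s * df_a),
        within_b: (ss_b, df_b, ss_err_b, df_s * df_b),
        f"{within_b}*group": (ss_gb, df_g * df_b, ss_err_b, df_s * df_b),
        f"{within_a}*{within_b}": (ss_ab, df_a * df_b, ss_err_ab, df_s * df_a * df_b),
        f"{within_a}*{within_b}*group": (
            ss_gab, df_g * df_a * df_b, ss_err_ab, df_s * df_a * df_b),
    }
    out: dict[str, StatReport] = {}
    for name, (ss_eff, df_eff, ss_err, df_err) in effects.items():
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else np.inf)
        pval = float(stats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out[name] = StatReport(
            test=f"rm_anova[{name}]", statistic=float(F),
            df=(df_eff, df_err), p=pval,
            effect={"partial_eta_sq": float(peta), "ss": float(ss_eff)},
        )
    return out


# ---------------------------------------------------------------------------
# Tukey post-hocs
# ---------------------------------------------------------------------------

def posthoc_tukey(
    summaries: pd.DataFrame, measure: str, group_col: str = "group"
) -> StatReport:
    """Pairwise Tukey-Kramer comparisons via the studentised range distribution."""
    data = summaries.dropna(subset=[measure, group_col])
    names = list(data[group_col].unique())
    samples = [data.loc[data[group_col] == g, measure].to_numpy(dtype=float)
               for g in names]
    if len(names) < 2:
        raise InputError("Tukey post-hocs need >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise InputError("every group needs n >= 2 for Tukey post-hocs")
    k = len(names)
    N = sum(len(s) for s in samples)
    msw = sum(((s - s.mean()) ** 2).sum() for s in samples) / (N - k)
    pairs = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        diff = samples[i].mean() - samples[j].mean()
        if msw <= 0:
            q, pval = 0.0, 1.0
        else:
            se = np.sqrt(msw / 2 * (1 / len(samples[i]) + 1 / len(samples[j])))
            q = abs(diff) / se
            pval = float(np.clip(stats.studentized_range.sf(q, k, N - k), 0, 1))
        pairs.append({"a": a, "b": b, "diff": float(diff),
                      "q": float(q), "p": pval})
    return StatReport(
        test=f"tukey[{measure}]",
        statistic=float(max(p["q"] for p in pairs)),
        df=(k, N - k), p=float(min(p["p"] for p in pairs)),
        pairwise=pairs,
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlate(
    summaries: pd.DataFrame,
    x: str,
    y: str,
    method: str = "spearman",
    bonferroni_family: int | None = None,
) -> StatReport:
    """Pearson r or Spearman rho (midranks for ties) between two measures."""
    data = summaries[[x, y]].dropna()
    if len(data) < 4:
        raise InputError(f"need >= 4 complete pairs for {x} vs {y}, have {len(data)}")
    xv, yv = data[x].to_numpy(dtype=float), data[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError(f"constant variable in correlation {x} vs {y}")
    if method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    elif method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    effect = {"r": float(r), "n": int(len(data))}
    if bonferroni_family:
        effect["p_bonferroni"] = float(min(1.0, p * bonferroni_family))
        effect["family_size"] = int(bonferroni_family)
    return StatReport(
        test=f"{method}[{x}~{y}]", statistic=float(r),
        df=(len(data) - 2,), p=float(p), effect=effect,
    )


# ---------------------------------------------------------------------------
# Non-parametric battery
# ---------------------------------------------------------------------------

def shapiro_normality(values: np.ndarray) -> StatReport:
    """Shapiro-Wilk normality check."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return StatReport(test="shapiro", statistic=float(w), df=None, p=float(p))


def nonparametric_groups(
    summaries: pd.DataFrame, measure: str, group_col: str = "group"
) -> StatReport:
    """Kruskal-Wallis over groups plus pairwise Mann-Whitney U (exact when feasible)."""
    data = summaries.dropna(subset=[measure, group_col])
    names = list(data[group_col].unique())
    samples = [data.loc[data[group_col] == g, measure].to_numpy(dtype=float)
               for g in names]
    if len(names) < 2 or any(len(s) < 2 for s in samples):
        raise InputError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        raise DegenerateInputError(f"all values of {measure} tied")
    H, p = stats.kruskal(*samples)
    pairs = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        si, sj = samples[i], samples[j]
        ties = len(np.unique(np.concatenate([si, sj]))) < len(si) + len(sj)
        method = "exact" if (len(si) <= 20 and len(sj) <= 20 and not ties) else "asymptotic"
        U, pu = stats.mannwhitneyu(si, sj, alternative="two-sided", method=method)
        pairs.append({"a": a, "b": b, "U": float(U), "p": float(pu)})
    return StatReport(
        test=f"kruskal[{measure}]", statistic=float(H),
        df=(len(names) - 1,), p=float(p), pairwise=pairs,
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

#: Table-2-style correlation layout: rows are behavioural measures,
#: columns the speech modulation measures.
CORRELATION_ROWS = (
    "years_literacy", "syllabic_division", "rhyme_detection",
    "phoneme_deletion", "vocabulary", "token_test", "speech_rate", "age",
)
CORRELATION_COLS = (
    "delta_auc", "theta_auc", "psi_delta_theta", "psi_theta_betagamma",
)


def cohort_report(participants: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Full statistics report over a participant-summary table.

    Expects one row per participant x register with PSI, band-energy,
    speech-rate and behavioural columns.  Returns a JSON-serialisable dict:
    per-register MANOVA + Tukey post-hocs, the mixed repeated-measures ANOVA
    on per-spectral-band PSI, the Spearman correlation matrix with Bonferroni
    family equal to the number of cells actually computed, Pearson
    speech-rate-vs-PSI checks, and the non-parametric battery on the
    behavioural scores.
    """
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    if participants.empty:
        raise InputError("empty participant summary")
    report: dict = {"alpha": alpha, "registers": {}}
    for register, sub in participants.groupby("register"):
        entry: dict = {"n_participants": int(len(sub))}
        if sub["group"].nunique() >= 3:
            try:
                entry["manova_psi"] = group_manova(sub).to_dict()
            except (InputError, DegenerateInputError) as exc:
                entry["manova_psi"] = {"error": str(exc)}
            for measure in ("psi_delta_theta", "psi_theta_betagamma", "speech_rate"):
                if measure in sub and sub[measure].notna().all():
                    try:
                        entry[f"tukey_{measure}"] = posthoc_tukey(sub, measure).to_dict()
                    except (InputError, DegenerateInputError) as exc:
                        entry[f"tukey_{measure}"] = {"error": str(exc)}
            if "speech_rate" in sub and sub["speech_rate"].notna().all():
                groups = [g[1].to_numpy() for g in sub.groupby("group")["speech_rate"]]
                F, p = stats.f_oneway(*groups)
                entry["anova_speech_rate"] = StatReport(
                    test="anova_speech_rate", statistic=float(F),
                    df=(sub["group"].nunique() - 1,
                        len(sub) - sub["group"].nunique()),
                    p=float(p),
                ).to_dict()
            band_cols = [c for c in sub.columns if c.startswith(("psi_dt_b", "psi_tbg_b"))]
            if band_cols:
                try:
                    long = _per_band_long(sub)
                    entry["rm_anova_psi"] = {
                        name: rep.to_dict() for name, rep in rm_anova_psi(long).items()
                    }
                except (InputError, DegenerateInputError) as exc:
                    entry["rm_anova_psi"] = {"error": str(exc)}
        report["registers"][register] = entry

    conv = participants[participants["register"] == "conversational"]
    rows = [r for r in CORRELATION_ROWS if r in conv.columns]
    cols = [c for c in CORRELATION_COLS if c in conv.columns]
    family = sum(
        1 for r in rows for c in cols if conv[[r, c]].dropna().shape[0] >= 4
        and np.ptp(conv[r].dropna().to_numpy()) > 0
    )
    corr: dict = {"method": "spearman", "bonferroni_family": family, "cells": {}}
    for r in rows:
        for c in cols:
            try:
                rep = correlate(conv, r, c, method="spearman", bonferroni_family=family)
            except (InputError, DegenerateInputError):
                continue
            corr["cells"][f"{r}~{c}"] = rep.to_dict()
    report["correlations"] = corr

    if "speech_rate" in conv.columns:
        pearson = {}
        for gname, gsub in conv.groupby("group"):
            for c in ("psi_delta_theta", "psi_theta_betagamma"):
                try:
                    pearson[f"{gname}:{c}"] = correlate(
                        gsub, "speech_rate", c, method="pearson"
                    ).to_dict()
                except (InputError, DegenerateInputError):
                    continue
        report["pearson_speech_rate_psi"] = pearson

    behavioural = {}
    for task in ("syllabic_division", "rhyme_detection", "phoneme_deletion",
                 "vocabulary", "token_test"):
        if task not in conv.columns:
            continue
        try:
            rep = nonparametric_groups(conv, task)
        except (InputError, DegenerateInputError):
            continue
        entry = rep.to_dict()
        entry["shapiro"] = shapiro_normality(conv[task].dropna().to_numpy()).to_dict()
        behavioural[task] = entry
    report["behavioural_tasks"] = behavioural
    return report


def _per_band_long(sub: pd.DataFrame) -> pd.DataFrame:
    """Reshape per-band PSI columns (psi_dt_b1.., psi_tbg_b1..) to long format."""
    rows = []
    for _, r in sub.iterrows():
        for pair, prefix in (("delta_theta", "psi_dt_b"), ("theta_betagamma", "psi_tbg_b")):
            for b in range(1, 6):
                col = f"{prefix}{b}"
                if col in sub.columns:
                    rows.append({
                        "participant_id": r["participant_id"], "group": r["group"],
                        "band_pair": pair, "spectral_band": b, "psi": r[col],
                    })
    return pd.DataFrame(rows)


def render_report_text(report: dict) -> str:
    """Human-readable rendering of :func:`cohort_report` output."""
    lines = [f"Cohort statistics report (alpha = {report['alpha']})", ""]
    for register, entry in report.get("registers", {}).items():
        lines.append(f"== {register} register (n = {entry['n_participants']}) ==")
        man = entry.get("manova_psi")
        if man:
            lines.append(
                "  MANOVA (PSI pair ~ group): "
                f"F({man['df'][0]:.0f},{man['df'][1]:.0f}) = {man['statistic']:.3f}, "
                f"p = {man['p']:.4g}, Wilks' lambda = {man['effect']['wilks_lambda']:.3f}, "
                f"partial eta^2 = {man['effect']['partial_eta_sq']:.3f}"
            )
        for key, val in entry.items():
            if key.startswith("tukey_"):
                lines.append(f"  Tukey ({key[6:]}):")
                for pw in val["pairwise"]:
                    lines.append(
                        f"    {pw['a']} vs {pw['b']}: diff = {pw['diff']:+.4f}, p = {pw['p']:.4g}"
                    )
        rm = entry.get("rm_anova_psi")
        if rm:
            lines.append("  Mixed rm-ANOVA (group x band pair x spectral band):")
            for name, rep in rm.items():
                lines.append(
                    f"    {name}: F({rep['df'][0]},{rep['df'][1]}) = "
                    f"{rep['statistic']:.3f}, p = {rep['p']:.4g}"
                )
        lines.append("")
    corr = report.get("correlations", {})
    if corr.get("cells"):
        lines.append(
            f"Spearman correlations (Bonferroni family = {corr['bonferroni_family']}):"
        )
        for cell, rep in corr["cells"].items():
            extra = rep["effect"].get("p_bonferroni")
            tail = f", p_bonf = {extra:.4g}" if extra is not None else ""
            lines.append(
                f"  {cell}: rho = {rep['statistic']:+.3f}, p = {rep['p']:.4g}{tail}"
            )
    return "\n".join(lines)
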