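#!/usr/bin/env python
"""Group statistics over the demo-cohort participant summaries.

Per register: one-way MANOVA (Wilks' lambda) of the two PSI measures over
literacy group with Tukey-Kramer post-hocs, and the mixed 3 x 2 x 5
repeated-measures ANOVA over group x AM band pair x spectral band; plus the
Spearman correlation matrix between the speech modulation measures and the
behavioural scores (Bonferroni-adjusted over the computed family) and the
non-parametric battery on the behavioural tasks.

Reads results/participant_summaries.csv (from 02_analyze_segments.py); writes
results/cohort_report.json and results/cohort_report.txt.
"""

import json
from pathlib import Path

import pandas as pd

from samph.cohort_stats import cohort_report, render_report_text

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    participants = pd.read_csv(RESULTS / "participant_summaries.csv")
    report = cohort_report(participants)
    (RESULTS / "cohort_report.json").write_text(json.dumps(report, indent=2))
    text = render_report_text(report)
    (RESULTS / "cohort_report.txt").write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
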